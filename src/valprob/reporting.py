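"""High-level analysis entry point shared by the CLI and the library API."""

from __future__ import annotations

from typing import Any

from .posterior import (
    PriorSpec,
    UNIFORM_PRIOR,
    ValidationOutcome,
    credible_interval,
    make_adaptive_prior,
    posterior_mean_fdr,
    update_posterior,
    validation_probability,
)
from .resampling import bootstrap_validation_probability

__all__ = ["analyze_validation", "resolve_prior"]


def resolve_prior(mode: str, claimed_fdr: float, adaptive_a: float = 0.01) -> PriorSpec:
    if mode == "uniform":
        return UNIFORM_PRIOR
    if mode == "adaptive":
        return make_adaptive_prior(claimed_fdr, adaptive_a)
    raise ValueError(f"unknown prior mode {mode!r}; expected 'uniform' or 'adaptive'")


def analyze_validation(
    n: float,
    n_fp: float,
    claimed_fdr: float,
    prior: PriorSpec = UNIFORM_PRIOR,
    level: float = 0.95,
    deltas=None,
    bootstrap_B: int | None = None,
    seed: int = 0,
) -> dict[str, Any]:
    """Full posterior summary of one validation experiment.

    Returns a JSON-ready mapping with the prior, posterior shapes,
    validation probability, posterior-mean FDR and equal-tailed credible
    interval; when a per-feature outcome vector and a replicate count are
    supplied, a percentile-bootstrap block for the validation probability is
    added.
    """
    outcome = ValidationOutcome(n, n_fp, claimed_fdr)
    post = update_posterior(prior, outcome)
    ci = credible_interval(post, level)
    report: dict[str, Any] = {
        "n": n,
        "n_fp": n_fp,
        "claimed_fdr": claimed_fdr,
        "prior": {"a": prior.a, "b": prior.b},
        "posterior": {"a": post.a_post, "b": post.b_post},
        "validation_probability": validation_probability(post, claimed_fdr),
        "posterior_mean_fdr": posterior_mean_fdr(post),
        "credible_interval": {"lower": ci.lower, "upper": ci.upper, "level": level},
    }
    if bootstrap_B and deltas is not None:
        boot = bootstrap_validation_probability(
            deltas, claimed_fdr, prior=prior, B=bootstrap_B, level=level, seed=seed
        )
        report["bootstrap"] = {
            "lower": boot.lower,
            "upper": boot.upper,
            "level": boot.level,
            "replicates": boot.replicates,
            "seed": boot.seed,
        }
    return report
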