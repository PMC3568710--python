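"""Validation experiment design: minimum sample size and design curves.

The planning question is: at FDR cutoff ``q``, how many randomly sampled
significant features must be confirmed so that — if the claimed FDR is
accurate, i.e. about ``q * n`` of them fail validation — the validation
probability Pr(pi0 < q | n_fp, n) exceeds a target?  The minimum such ``n``
is found by scanning n = 1, 2, ... and cannot exceed the number of features
significant at ``q``.

Two conventions for the expected failure count are exposed:

* ``floor`` (default): n_fp = floor(q * n).  Under this rule finite design
  sizes exist for any target below 1.
* ``continuous``: n_fp = q * n exactly.  For q < 1/2 under a uniform prior
  the posterior Beta(1 + qn, 1 + n - qn) has mode q and mean > q, so its
  median exceeds q and the validation probability is pinned below 0.5 for
  every n: a 0.5 target is provably unachievable, which is why low-FDR
  design points often render as "not achievable".

An ``fp_multiplier`` generalizes the expected failure count to
``multiplier * q * n`` for what-if curves (e.g. assuming the assay will do
somewhat better than the claimed FDR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import betainc
from statsmodels.stats.multitest import multipletests

from .posterior import PriorSpec, UNIFORM_PRIOR

__all__ = [
    "SignificanceProfile",
    "SampleSizePlan",
    "n_significant",
    "min_validation_sample_size",
    "sample_size_curve",
    "probability_vs_sample_size",
]

FpRule = Literal["floor", "continuous"]

# default cap on the scan when n_sig is effectively unbounded
DEFAULT_SCAN_CAP = 1_000_000


@dataclass(frozen=True)
class SignificanceProfile:
    """P-values from the original analysis, queried for list sizes at FDR cutoffs."""

    pvalues: np.ndarray

    def __init__(self, pvalues) -> None:
        p = np.asarray(pvalues, dtype=float)
        if p.size and ((p < 0) | (p > 1)).any():
            bad = p[(p < 0) | (p > 1)]
            raise ValueError(f"p-values outside [0, 1]: {bad[:5]}")
        object.__setattr__(self, "pvalues", p)

    def n_sig(self, q: float) -> int:
        return n_significant(self, q)


@dataclass(frozen=True)
class SampleSizePlan:
    """Result of a minimum-sample-size search at one FDR cutoff.

    ``min_n`` is None when the target probability cannot be reached;
    ``capped_by_nsig`` distinguishes "not enough significant features to
    validate" from "unachievable at any sample size".
    """

    fdr_cutoff: float
    target_probability: float
    min_n: int | None
    capped_by_nsig: bool = False
    n_sig: int | None = None

    @property
    def achievable(self) -> bool:
        return self.min_n is not None


def n_significant(profile: SignificanceProfile, q: float) -> int:
    """Number of features with Benjamini-Hochberg adjusted p-value <= q."""
    p = profile.pvalues
    if p.size == 0:
        return 0
    _, qvals, _, _ = multipletests(p, method="fdr_bh")
    return int((qvals <= q).sum())


def _expected_nfp(n: np.ndarray, q: float, fp_rule: FpRule, fp_multiplier: float) -> np.ndarray:
    raw = fp_multiplier * q * n
    if fp_rule == "floor":
        return np.floor(raw)
    if fp_rule == "continuous":
        return raw
    raise ValueError(f"unknown fp_rule {fp_rule!r}; expected 'floor' or 'continuous'")


def min_validation_sample_size(
    q: float,
    target: float,
    n_sig: int | None = None,
    fp_rule: FpRule = "floor",
    prior: PriorSpec = UNIFORM_PRIOR,
    fp_multiplier: float = 1.0,
    scan_cap: int = DEFAULT_SCAN_CAP,
) -> SampleSizePlan:
    """Smallest n with Pr(pi0 < q | expected n_fp, n) > target.

    Scans n = 1..min(n_sig, scan_cap) by direct evaluation: under the floor
    rule the probability is sawtoothed in n (it drops each time another
    expected failure is added), so bisection is unsafe.  When no n within the
    feature budget qualifies but some larger n would, the plan is flagged
    ``capped_by_nsig``.
    """
    if not (0 < q < 1):
        raise ValueError(f"q must lie in (0, 1), got {q}")
    if not (0 < target < 1):
        raise ValueError(f"target must lie in (0, 1), got {target}")
    if n_sig is not None and n_sig < 0:
        raise ValueError(f"n_sig must be nonnegative, got {n_sig}")

    def first_hit(lo: int, hi: int, chunk: int = 20_000) -> int | None:
        # chunked scan with early exit; probability is sawtoothed in n under
        # the floor rule, so no bisection
        for start in range(lo, hi + 1, chunk):
            n = np.arange(start, min(start + chunk, hi + 1), dtype=float)
            nfp = _expected_nfp(n, q, fp_rule, fp_multiplier)
            probs = betainc(prior.a + nfp, prior.b + n - nfp, q)
            # strict inequality up to roundoff: a symmetric posterior sitting
            # exactly at the target (e.g. q=1/2, continuous rule) must not count
            hits = np.flatnonzero(probs - target > 1e-12)
            if hits.size:
                return int(n[hits[0]])
        return None

    budget = scan_cap if n_sig is None else min(n_sig, scan_cap)
    if budget >= 1:
        hit = first_hit(1, budget)
        if hit is not None:
            return SampleSizePlan(q, target, hit, False, n_sig)

    # nothing within the feature budget: check whether a larger n would work
    capped = False
    if n_sig is not None and n_sig < scan_cap:
        capped = first_hit(n_sig + 1, scan_cap) is not None
    return SampleSizePlan(q, target, None, capped, n_sig)


def sample_size_curve(
    profile: SignificanceProfile,
    q_grid: Sequence[float],
    target: float = 0.5,
    fp_rule: FpRule = "floor",
    prior: PriorSpec = UNIFORM_PRIOR,
    fp_multiplier: float = 1.0,
) -> list[SampleSizePlan]:
    """Minimum validation sample size at each FDR cutoff of a study.

    Unachievable cutoffs (typically the low-FDR end) come back with
    ``min_n=None`` and plot as crosses rather than points.
    """
    return [
        min_validation_sample_size(
            q,
            target,
            n_sig=n_significant(profile, q),
            fp_rule=fp_rule,
            prior=prior,
            fp_multiplier=fp_multiplier,
        )
        for q in q_grid
    ]


def probability_vs_sample_size(
    q: float,
    n_grid: Iterable[int],
    fp_multiplier: float = 0.7,
    prior: PriorSpec = UNIFORM_PRIOR,
) -> list[tuple[int, float]]:
    """Validation probability versus sample size at a fixed FDR cutoff.

    Assumes ``fp_multiplier * q * n`` failures will be observed (default 0.7:
    the assay does a bit better than the claimed FDR, so the probability
    climbs toward 1 with n).  Larger cutoffs give uniformly higher curves.
    """
    if not (0 < q < 1):
        raise ValueError(f"q must lie in (0, 1), got {q}")
    if not (0 < fp_multiplier <= 1):
        raise ValueError(f"fp_multiplier must lie in (0, 1], got {fp_multiplier}")
    out = []
    for n in n_grid:
        nfp = fp_multiplier * q * n
        p = float(betainc(prior.a + nfp, prior.b + n - nfp, q))
        out.append((int(n), p))
    return out
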