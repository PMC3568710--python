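"""Synthetic two-group expression experiments and validation-probability
operating characteristics.

The engine simulates repeated differential-expression experiments, forms
significance lists at several FDR cutoffs, validates every listed gene with
a modelled independent assay ("exhaustive validation"), and summarizes how
the validation probability, its credible interval and the posterior-expected
FDR behave across replications.  Three assay scenarios are modelled:

* ``errorless`` — the independent assay is a perfect oracle: a validated
  gene fails exactly when it is truly null.  Lists at accurate FDR cutoffs
  should validate, with probability approaching 1 at generous cutoffs.
* ``noisy_validation`` — the assay re-tests each listed gene on freshly
  generated data with a larger sample size (default 3x) at a fixed per-gene
  test level; truly-DE genes occasionally fail and nulls occasionally pass.
* ``misspecified`` — the original technology is systematically wrong: a
  random third of the genes that carry signal in the original data are in
  truth not differentially expressed (their apparent signal is artifact),
  and the perfect assay exposes them.  Significance lists then hold ~1/3
  false positives regardless of the claimed FDR, so claims at 5-10% should
  decisively fail to validate.

Generative model per gene: baseline 0, Gaussian noise (sd 1) per sample,
and for DE genes a group-mean shift drawn uniformly from [0.5, 2] with
random sign — a power mix that leaves lists at 5-50% FDR nonempty with two
groups of 10 samples.  P-values come from two-sided two-sample t-tests and
q-values from Benjamini-Hochberg (pi0 = 1 by default; Storey's pi0 estimate
is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

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

__all__ = [
    "ExperimentConfig",
    "ScenarioConfig",
    "ExperimentData",
    "LevelSummary",
    "ScenarioSummary",
    "simulate_experiment",
    "pvalues_from_experiment",
    "estimate_qvalues",
    "apply_validation_model",
    "run_scenario",
]

Scenario = Literal["errorless", "noisy_validation", "misspecified"]
PriorMode = Literal["uniform", "adaptive"]


@dataclass(frozen=True)
class ExperimentConfig:
    n_genes: int = 1000
    n_de: int = 300
    group_sizes: tuple[int, int] = (10, 10)
    effect_size_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_de <= self.n_genes):
            raise ValueError("need 0 <= n_de <= n_genes")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: Scenario = "errorless"
    prior_mode: PriorMode = "uniform"
    fdr_levels: tuple[float, ...] = (0.05, 0.10, 0.50)
    n_reps: int = 100
    validation_sample_factor: float = 3.0  # noisy_validation sample-size multiplier
    validation_alpha: float = 0.05  # per-gene test level in the noisy assay
    misspecification_rate: float = 1 / 3
    adaptive_a: float = 0.01

    def __post_init__(self) -> None:
        if self.scenario not in ("errorless", "noisy_validation", "misspecified"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.prior_mode not in ("uniform", "adaptive"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        if not (0 <= self.misspecification_rate <= 1):
            raise ValueError("misspecification_rate must lie in [0, 1]")
        if self.validation_sample_factor <= 0:
            raise ValueError("validation_sample_factor must be positive")

    def prior_for(self, claimed_fdr: float) -> PriorSpec:
        if self.prior_mode == "adaptive":
            return make_adaptive_prior(claimed_fdr, self.adaptive_a)
        return UNIFORM_PRIOR


@dataclass(frozen=True)
class ExperimentData:
    """One simulated experiment: expression matrix plus per-gene ground truth."""

    matrix: np.ndarray  # n_genes x (n1 + n2)
    group_labels: np.ndarray  # 0/1 per sample column
    is_de: np.ndarray  # bool per gene
    effects: np.ndarray  # signed group-mean shift per gene (0 for nulls)
    config: ExperimentConfig


def simulate_experiment(config: ExperimentConfig) -> ExperimentData:
    """Draw one two-group expression experiment; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.group_sizes
    n_total = n1 + n2
    lo, hi = config.effect_size_range
    is_de = np.zeros(config.n_genes, dtype=bool)
    de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
    is_de[de_idx] = True
    effects = np.zeros(config.n_genes)
    effects[de_idx] = rng.uniform(lo, hi, size=config.n_de) * rng.choice((-1.0, 1.0), size=config.n_de)
    matrix = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_total))
    matrix[:, n1:] += effects[:, None]  # shift applies to group 2
    labels = np.repeat([0, 1], [n1, n2])
    return ExperimentData(matrix, labels, is_de, effects, config)


def pvalues_from_experiment(matrix: np.ndarray, group_labels: np.ndarray) -> np.ndarray:
    """Two-sided two-sample t-test per gene (row).

    Genes where both groups are constant have an undefined t statistic; they
    get p = 1 with a warning rather than NaN.
    """
    matrix = np.asarray(matrix, dtype=float)
    group_labels = np.asarray(group_labels)
    g1 = matrix[:, group_labels == 0]
    g2 = matrix[:, group_labels == 1]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(g1, g2, axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(pvals)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} gene(s) with degenerate variance; setting p = 1", UserWarning
        )
        pvals[bad] = 1.0
    return pvals


def estimate_qvalues(
    pvalues, pi0: float | Literal["storey"] | None = None, storey_lambda: float = 0.5
) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, optionally scaled by a pi0 estimate.

    With the default ``pi0=None`` the null proportion is fixed at 1
    (deterministic and conservative).  ``pi0="storey"`` plugs in the
    smoothed-tail estimate ``min(1, mean(p > lambda) / (1 - lambda))``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(p, method="fdr_bh")
    if pi0 == "storey":
        pi0 = min(1.0, float((p > storey_lambda).mean()) / (1.0 - storey_lambda))
    if pi0 is not None:
        if not (0 < pi0 <= 1):
            raise ValueError(f"pi0 must lie in (0, 1], got {pi0}")
        qvals = np.minimum(qvals * pi0, 1.0)
    return qvals


def apply_validation_model(
    data: ExperimentData,
    sig_idx: np.ndarray,
    scenario: ScenarioConfig,
    seed: int,
    validation_truth: np.ndarray | None = None,
) -> np.ndarray:
    """Validate every listed gene with the modelled independent assay.

    Returns the outcome vector delta (1 = validation failure) over
    ``sig_idx``.  ``validation_truth`` overrides the per-gene truth the assay
    sees (used by the misspecified scenario, where validation truth differs
    from the labels the data were generated with).
    """
    sig_idx = np.asarray(sig_idx)
    if sig_idx.size == 0:
        raise ValueError("significance list is empty; nothing to validate")
    truth = data.is_de if validation_truth is None else validation_truth
    if scenario.scenario in ("errorless", "misspecified"):
        return (~truth[sig_idx]).astype(np.int64)

    # noisy_validation: re-test each listed gene on fresh data at a larger n
    rng = np.random.default_rng(seed)
    cfg = data.config
    n1 = int(round(cfg.group_sizes[0] * scenario.validation_sample_factor))
    n2 = int(round(cfg.group_sizes[1] * scenario.validation_sample_factor))
    effects = np.where(truth[sig_idx], data.effects[sig_idx], 0.0)
    g1 = rng.normal(0.0, cfg.noise_sd, size=(sig_idx.size, n1))
    g2 = rng.normal(effects[:, None], cfg.noise_sd, size=(sig_idx.size, n2))
    pvals = np.asarray(stats.ttest_ind(g1, g2, axis=1).pvalue)
    return (pvals > scenario.validation_alpha).astype(np.int64)  # fail to confirm


@dataclass(frozen=True)
class LevelSummary:
    """Operating characteristics at one FDR cutoff, across replications."""

    fdr_level: float
    median_validation_probability: float
    iqr: tuple[float, float]
    ci_coverage: float  # fraction of reps whose 95% credible interval holds the level
    median_posterior_fdr: float
    n_reps_used: int
    n_reps_excluded: int  # reps with an empty significance list


@dataclass(frozen=True)
class ScenarioSummary:
    scenario: ScenarioConfig
    experiment: ExperimentConfig
    levels: dict[float, LevelSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lvl, s in sorted(self.levels.items()):
            rows.append(
                {
                    "fdr_level": lvl,
                    "median_validation_probability": s.median_validation_probability,
                    "iqr_25": s.iqr[0],
                    "iqr_75": s.iqr[1],
                    "ci_coverage": s.ci_coverage,
                    "median_posterior_fdr": s.median_posterior_fdr,
                    "n_reps_used": s.n_reps_used,
                    "n_reps_excluded": s.n_reps_excluded,
                }
            )
        return pd.DataFrame(rows)


def run_scenario(
    scenario: ScenarioConfig,
    experiment: ExperimentConfig = ExperimentConfig(),
    ci_level: float = 0.95,
) -> ScenarioSummary:
    """Replicate the full pipeline and summarize validation behaviour.

    Per replication and FDR cutoff: simulate an experiment, test every gene,
    list the genes with q-value <= cutoff, validate the whole list with the
    scenario's assay, and compute the validation probability, credible
    interval and posterior-mean FDR from the failure count.  Reps whose list
    is empty at a cutoff are excluded from that cutoff's summaries (their
    count is reported).  Deterministic given ``experiment.seed``.
    """
    ss = np.random.SeedSequence(experiment.seed)
    rep_seeds = ss.generate_state(2 * scenario.n_reps, dtype=np.uint32).reshape(-1, 2)
    records: dict[float, dict[str, list[float]]] = {
        lvl: {"vp": [], "mean": [], "cover": []} for lvl in scenario.fdr_levels
    }
    excluded = {lvl: 0 for lvl in scenario.fdr_levels}

    for r in range(scenario.n_reps):
        sim_seed, val_seed = (int(s) for s in rep_seeds[r])
        data = simulate_experiment(
            ExperimentConfig(**{**experiment.__dict__, "seed": sim_seed})
        )
        validation_truth = None
        if scenario.scenario == "misspecified":
            rng = np.random.default_rng(val_seed + 1)
            de_idx = np.flatnonzero(data.is_de)
            n_flip = int(round(scenario.misspecification_rate * de_idx.size))
            flipped = rng.choice(de_idx, size=n_flip, replace=False)
            validation_truth = data.is_de.copy()
            validation_truth[flipped] = False
        pvals = pvalues_from_experiment(data.matrix, data.group_labels)
        qvals = estimate_qvalues(pvals)
        for lvl in scenario.fdr_levels:
            sig_idx = np.flatnonzero(qvals <= lvl)
            if sig_idx.size == 0:
                excluded[lvl] += 1
                continue
            deltas = apply_validation_model(
                data, sig_idx, scenario, val_seed, validation_truth
            )
            outcome = ValidationOutcome(sig_idx.size, float(deltas.sum()), lvl)
            post = update_posterior(scenario.prior_for(lvl), outcome)
            ci = credible_interval(post, ci_level)
            records[lvl]["vp"].append(validation_probability(post, lvl))
            records[lvl]["mean"].append(posterior_mean_fdr(post))
            records[lvl]["cover"].append(float(ci.contains(lvl)))

    levels = {}
    for lvl in scenario.fdr_levels:
        vp = np.array(records[lvl]["vp"])
        if vp.size == 0:
            levels[lvl] = LevelSummary(lvl, float("nan"), (float("nan"), float("nan")),
                                       float("nan"), float("nan"), 0, excluded[lvl])
            continue
        q25, med, q75 = np.percentile(vp, [25, 50, 75])
        levels[lvl] = LevelSummary(
            fdr_level=lvl,
            median_validation_probability=float(med),
            iqr=(float(q25), float(q75)),
            ci_coverage=float(np.mean(records[lvl]["cover"])),
            median_posterior_fdr=float(np.median(records[lvl]["mean"])),
            n_reps_used=int(vp.size),
            n_reps_excluded=excluded[lvl],
        )
    return ScenarioSummary(scenario, experiment, levels)
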