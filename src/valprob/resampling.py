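"""Bootstrap confidence intervals for the validation probability.

Given the per-feature outcome vector (delta_i = 1 for a validation failure),
resample it with replacement B times, recompute the validation probability
for each replicate's failure count, and take empirical quantiles of the
replicate distribution.  Because the statistic depends on the resample only
through the failure count, the bootstrap distribution of n_fp is exactly
Binomial(n, mean(delta)) — which tests exploit as an enumeration oracle.

The bootstrap is not justified for very small validation samples; a warning
is emitted when n < 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .posterior import (
    PriorSpec,
    UNIFORM_PRIOR,
    ValidationOutcome,
    update_posterior,
    validation_probability,
)

__all__ = ["BootstrapResult", "bootstrap_validation_probability"]

SMALL_SAMPLE_WARNING_N = 10


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    lower: float
    upper: float
    level: float
    replicates: int
    seed: int


def _check_outcomes(deltas: np.ndarray) -> np.ndarray:
    deltas = np.asarray(deltas)
    if deltas.size == 0:
        raise ValueError("outcome vector is empty")
    if not np.isin(deltas, (0, 1)).all():
        raise ValueError("outcome vector must contain only 0/1 indicators")
    return deltas.astype(np.int64)


def bootstrap_validation_probability(
    outcomes,
    claimed_fdr: float,
    prior: PriorSpec = UNIFORM_PRIOR,
    B: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap interval for Pr(pi0 <= claimed_fdr | n_fp, n).

    Each replicate resamples the n outcome indicators with replacement and
    recomputes the validation probability from the resampled failure count.
    Interval endpoints are type-7 (linearly interpolated) empirical quantiles
    of the replicate values; the point estimate is the validation probability
    of the original, un-resampled vector.  Deterministic given ``seed``.
    """
    deltas = _check_outcomes(outcomes)
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    n = deltas.size
    if n < SMALL_SAMPLE_WARNING_N:
        warnings.warn(
            f"bootstrap intervals may be unreliable for small validation samples (n={n} < 10)",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    # resample indices; the statistic only needs the per-replicate failure count
    idx = rng.integers(0, n, size=(B, n))
    nfp_b = deltas[idx].sum(axis=1)

    def prob(nfp: float) -> float:
        post = update_posterior(prior, ValidationOutcome(n, float(nfp), claimed_fdr))
        return validation_probability(post, claimed_fdr)

    point = prob(int(deltas.sum()))
    uniq, inverse = np.unique(nfp_b, return_inverse=True)
    probs = np.array([prob(int(k)) for k in uniq])[inverse]
    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(probs, [tail, 1.0 - tail])  # type-7 default
    return BootstrapResult(point, float(lower), float(upper), level, B, seed)
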