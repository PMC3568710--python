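"""Beta-Binomial model for validating false-discovery-rate claims.

A high-throughput study declares a list of features significant at a claimed
FDR ``alpha_hat``.  A random sample of ``n`` of those features is confirmed
with an independent assay, yielding ``n_fp`` validation failures.  Each
failure indicator is Bernoulli with success probability equal to the true
false-discovery proportion ``pi0`` of the list, so ``n_fp`` is Binomial(n,
pi0).  Under a conjugate Beta(a, b) prior on ``pi0`` the posterior is
Beta(a + n_fp, b + n - n_fp), and the *validation probability*

    Pr(pi0 <= alpha_hat | n_fp, n)

is the posterior CDF at the claimed FDR.  Values above 0.5 indicate the
validation sample supports the original FDR claim; the posterior mean
(a + n_fp) / (a + b + n) estimates the actual FDR of the list.

``n_fp`` may be non-integer: an expected count (e.g. the average number of
failures over repeated random subsamples) is a legitimate input, and the
Beta posterior is well defined for real-valued shape parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import beta as _beta

__all__ = [
    "PriorSpec",
    "ValidationOutcome",
    "BetaPosterior",
    "CredibleInterval",
    "UNIFORM_PRIOR",
    "make_adaptive_prior",
    "update_posterior",
    "validation_probability",
    "posterior_mean_fdr",
    "credible_interval",
]


@dataclass(frozen=True)
class PriorSpec:
    """Beta(a, b) prior on the true false-discovery proportion.

    The uniform prior ``a = b = 1`` is the conservative default: it puts no
    prior weight on the validation succeeding.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"Beta shapes must be positive, got a={self.a}, b={self.b}")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


UNIFORM_PRIOR = PriorSpec(1.0, 1.0)


@dataclass(frozen=True)
class ValidationOutcome:
    """Summary of a validation experiment.

    Parameters
    ----------
    n : float
        Number of features confirmed with the independent assay.
    n_fp : float
        Number of validation failures among them.  Non-integer values are
        allowed and represent expected counts.
    claimed_fdr : float
        The FDR level at which the original list was declared significant.
    """

    n: float
    n_fp: float
    claimed_fdr: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be nonnegative, got {self.n}")
        if not (0 <= self.n_fp <= self.n):
            raise ValueError(f"n_fp must lie in [0, n]={[0, self.n]}, got {self.n_fp}")
        if not (0 < self.claimed_fdr < 1):
            raise ValueError(f"claimed_fdr must lie in (0, 1), got {self.claimed_fdr}")


@dataclass(frozen=True)
class BetaPosterior:
    """Posterior Beta(a_post, b_post) law of the false-discovery proportion."""

    a_post: float
    b_post: float

    def __post_init__(self) -> None:
        if not (self.a_post > 0 and self.b_post > 0):
            raise ValueError("posterior shapes must be positive")

    def cdf(self, x: float) -> float:
        return float(_beta.cdf(x, self.a_post, self.b_post))

    def quantile(self, p: float) -> float:
        return float(_beta.ppf(p, self.a_post, self.b_post))

    @property
    def mean(self) -> float:
        return self.a_post / (self.a_post + self.b_post)


@dataclass(frozen=True)
class CredibleInterval:
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper <= 1):
            raise ValueError("need 0 <= lower <= upper <= 1")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def make_adaptive_prior(claimed_fdr: float, a: float = 0.01) -> PriorSpec:
    """Beta prior whose mean equals the claimed FDR.

    Encodes optimism that the list will validate.  With ``a`` small the prior
    variance is near its maximum for the given mean, so the data dominate
    quickly.  ``b = (1 - claimed_fdr) / claimed_fdr * a``, hence the prior
    mean ``a / (a + b)`` equals ``claimed_fdr`` exactly.  Note this prior can
    be slightly anti-conservative relative to the uniform default.
    """
    if not (0 < claimed_fdr < 1):
        raise ValueError(f"claimed_fdr must lie in (0, 1), got {claimed_fdr}")
    if a <= 0:
        raise ValueError(f"shape a must be positive, got {a}")
    b = (1.0 - claimed_fdr) / claimed_fdr * a
    return PriorSpec(a, b)


def update_posterior(prior: PriorSpec, outcome: ValidationOutcome) -> BetaPosterior:
    """Conjugate update: Beta(a, b) -> Beta(a + n_fp, b + n - n_fp)."""
    return BetaPosterior(prior.a + outcome.n_fp, prior.b + outcome.n - outcome.n_fp)


def validation_probability(posterior: BetaPosterior, claimed_fdr: float) -> float:
    """Pr(pi0 <= claimed_fdr | data): posterior CDF at the claimed FDR.

    This is the regularized incomplete beta function I_x(a_post, b_post)
    evaluated at x = claimed_fdr.  The distribution is continuous, so strict
    and non-strict inequalities coincide.
    """
    if not (0 < claimed_fdr < 1):
        raise ValueError(f"claimed_fdr must lie in (0, 1), got {claimed_fdr}")
    return posterior.cdf(claimed_fdr)


def posterior_mean_fdr(posterior: BetaPosterior) -> float:
    """Posterior expected FDR: a_post / (a_post + b_post)."""
    return posterior.mean


def credible_interval(posterior: BetaPosterior, level: float = 0.95) -> CredibleInterval:
    """Equal-tailed posterior credible interval for the FDR.

    Lower and upper are the (1-level)/2 and 1-(1-level)/2 posterior
    quantiles, so exactly ``level`` posterior mass lies between them.
    """
    if not (0 < level < 1):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    return CredibleInterval(posterior.quantile(tail), posterior.quantile(1.0 - tail), level)
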