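"""Beta-Binomial posterior: conjugate updates, validation probability,
credible intervals, and the binomial-tail identity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from valprob import (
    PriorSpec,
    UNIFORM_PRIOR,
    ValidationOutcome,
    BetaPosterior,
    make_adaptive_prior,
    update_posterior,
    validation_probability,
    posterior_mean_fdr,
    credible_interval,
)


class TestAdaptivePrior:
    @pytest.mark.parametrize(
        "fdr, a, expected_b",
        [(0.05, 0.01, 0.19), (0.5, 0.01, 0.01), (0.10, 0.01, 0.09)],
    )
    def test_shapes_and_mean(self, fdr, a, expected_b):
        prior = make_adaptive_prior(fdr, a)
        assert prior.a == a
        assert prior.b == pytest.approx(expected_b)
        assert prior.mean == pytest.approx(fdr)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_fdr_outside_unit_interval(self, bad):
        with pytest.raises(ValueError):
            make_adaptive_prior(bad)

    def test_rejects_nonpositive_shape(self):
        with pytest.raises(ValueError):
            make_adaptive_prior(0.05, a=0.0)


class TestConjugateUpdate:
    @pytest.mark.parametrize(
        "n, n_fp, expected",
        [(31, 3, (4, 29)), (0.0, 0.0, (1, 1)), (20, 1.65, (2.65, 19.35))],
    )
    def test_posterior_shapes(self, n, n_fp, expected):
        post = update_posterior(UNIFORM_PRIOR, ValidationOutcome(n, n_fp, 0.1))
        assert (post.a_post, post.b_post) == pytest.approx(expected)

    def test_rejects_more_failures_than_validated(self):
        with pytest.raises(ValueError):
            ValidationOutcome(5, 6, 0.1)


class TestValidationProbability:
    @pytest.mark.parametrize(
        "shapes, fdr, expected, tol",
        [
            # printed values from the worked examples; closed forms are exact
            ((1, 3), 0.05, 0.142625, 1e-12),
            ((4, 29), 0.01, 2.874736e-4, 1e-9),
            ((1, 21), 1.09e-7, 1 - (1 - 1.09e-7) ** 21, 1e-12),
            ((2.65, 19.35), 0.10, 0.44513, 1e-4),
        ],
    )
    def test_worked_examples(self, shapes, fdr, expected, tol):
        post = BetaPosterior(*shapes)
        assert validation_probability(post, fdr) == pytest.approx(expected, abs=tol)

    def test_uniform_posterior_cdf_is_identity(self):
        post = BetaPosterior(1, 1)
        for x in (0.01, 0.3, 0.97):
            assert validation_probability(post, x) == pytest.approx(x)

    @given(
        n=st.integers(1, 200),
        nfp=st.floats(0, 1, exclude_max=True),
        fdr=st.floats(0.01, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_decreasing_in_failure_count(self, n, nfp, fdr):
        """More validation failures can only weaken support for the claim."""
        lo = update_posterior(UNIFORM_PRIOR, ValidationOutcome(n, nfp * n, fdr))
        hi = update_posterior(
            UNIFORM_PRIOR, ValidationOutcome(n, min(n, nfp * n + 1), fdr)
        )
        p_lo, p_hi = validation_probability(lo, fdr), validation_probability(hi, fdr)
        assert p_lo >= p_hi
        if p_lo < 1 - 1e-9:  # strict except where both saturate in float64
            assert p_lo > p_hi

    @given(fdr=st.floats(0.01, 0.98))
    @settings(max_examples=50, deadline=None)
    def test_increasing_in_claimed_fdr(self, fdr):
        post = BetaPosterior(4, 29)
        p_hi = validation_probability(post, fdr + 0.01)
        p_lo = validation_probability(post, fdr)
        assert p_hi >= p_lo
        if p_hi < 1 - 1e-9:
            assert p_hi > p_lo

    def test_binomial_tail_identity(self):
        """I_x(a, b) = Pr(Binomial(a+b-1, x) >= a) for integer shapes.

        The implementation goes through the regularized incomplete beta; the
        oracle is the exact binomial survival function.
        """
        xs = np.round(np.arange(0.01, 1.0, 0.07), 2)
        for a in range(1, 31, 3):
            for b in range(1, 61, 5):
                post = BetaPosterior(a, b)
                for x in xs:
                    oracle = binom.sf(a - 1, a + b - 1, x)
                    assert abs(post.cdf(x) - oracle) <= 1e-10

    def test_robust_to_prior_choice_on_worked_example(self):
        """A failed validation fails under both the uniform and adaptive prior."""
        outcome = ValidationOutcome(31, 3, 0.01)
        for prior in (UNIFORM_PRIOR, make_adaptive_prior(0.01)):
            post = update_posterior(prior, outcome)
            assert validation_probability(post, 0.01) < 0.01

    @pytest.mark.parametrize("pi0, expect_high", [(0.02, True), (0.4, False)])
    def test_frequentist_calibration(self, pi0, expect_high):
        """With the true failure rate far below (above) the claimed FDR, the
        validation probability concentrates near 1 (0) as n grows."""
        rng = np.random.default_rng(7)
        n = 400
        probs = []
        for _ in range(50):
            nfp = rng.binomial(n, pi0)
            post = update_posterior(UNIFORM_PRIOR, ValidationOutcome(n, nfp, 0.1))
            probs.append(validation_probability(post, 0.1))
        med = np.median(probs)
        assert med > 0.95 if expect_high else med < 0.05


class TestPosteriorMean:
    @pytest.mark.parametrize(
        "shapes, expected",
        [((4, 29), 4 / 33), ((1, 1), 0.5), ((2.65, 19.35), 2.65 / 22)],
    )
    def test_mean(self, shapes, expected):
        assert posterior_mean_fdr(BetaPosterior(*shapes)) == pytest.approx(expected)


class TestCredibleInterval:
    def test_printed_intervals(self):
        ci = credible_interval(BetaPosterior(4, 29))
        assert (round(ci.lower, 2), round(ci.upper, 2)) == (0.04, 0.25)
        ci = credible_interval(BetaPosterior(1, 21))
        assert (round(ci.lower, 3), round(ci.upper, 3)) == (0.001, 0.161)

    def test_uniform_interval(self):
        ci = credible_interval(BetaPosterior(1, 1))
        assert (ci.lower, ci.upper) == pytest.approx((0.025, 0.975))

    @given(
        a=st.floats(0.5, 50),
        b=st.floats(0.5, 50),
        level=st.floats(0.5, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_interval_mass_equals_level(self, a, b, level):
        post = BetaPosterior(a, b)
        ci = credible_interval(post, level)
        assert post.cdf(ci.upper) - post.cdf(ci.lower) == pytest.approx(level, abs=1e-8)

    def test_interval_mass_with_tiny_adaptive_shapes(self):
        # quantile inversion is less accurate when a shape is far below 1
        post = BetaPosterior(0.01, 0.19)
        ci = credible_interval(post, 0.95)
        assert post.cdf(ci.upper) - post.cdf(ci.lower) == pytest.approx(0.95, abs=1e-6)

    def test_rejects_bad_level(self):
        with pytest.raises(ValueError):
            credible_interval(BetaPosterior(2, 2), level=1.0)


def test_prior_requires_positive_shapes():
    with pytest.raises(ValueError):
        PriorSpec(0, 1)
    with pytest.raises(ValueError):
        PriorSpec(1, -2)
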