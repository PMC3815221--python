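import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from aoalearn.models import (
    HazardShape,
    LearningParams,
    LogisticParams,
    ModelKind,
    aoa_cdf,
    aoa_hazard,
    aoa_mean,
    aoa_pdf,
    aoa_quantile,
    classify_hazard_shape,
    cumulative_intensity,
)

from conftest import kind_params, random_learning_params

ACCUMULATOR_KINDS = (ModelKind.GAMMA, ModelKind.WEIBULL, ModelKind.WEIBULL_GAMMA)


class TestParamValidation:
    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    @pytest.mark.parametrize("field", ["accumulation", "rate_exponent", "base_rate"])
    def test_rejects_nonpositive(self, bad, field):
        kwargs = {"accumulation": 2.0, "rate_exponent": 1.0, "base_rate": 0.5}
        kwargs[field] = bad
        with pytest.raises(ValueError):
            LearningParams(**kwargs)

    def test_logistic_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            LogisticParams(slope=0.0, intercept=5.0)

    def test_family_recovery(self):
        assert LearningParams(5, 1.0, 0.2).kind is ModelKind.GAMMA
        assert LearningParams(1.0, 3.0, 0.2).kind is ModelKind.WEIBULL
        assert LearningParams(8, 0.5, 0.2).kind is ModelKind.WEIBULL_GAMMA

    def test_kind_param_mismatch(self):
        with pytest.raises(ValueError):
            aoa_cdf(ModelKind.GAMMA, LearningParams(5, 2.0, 0.2), 5.0)
        with pytest.raises(ValueError):
            aoa_cdf(ModelKind.WEIBULL, LearningParams(5, 2.0, 0.2), 5.0)
        with pytest.raises(TypeError):
            aoa_cdf(ModelKind.LOGISTIC, LearningParams(5, 1.0, 0.2), 5.0)


class TestCumulativeIntensity:
    def test_linear_case(self):
        params = LearningParams(3, 1.0, 2.0)
        assert cumulative_intensity(params, 3.0) == pytest.approx(6.0)

    def test_quadratic_case(self):
        params = LearningParams(1, 2.0, 0.01)
        assert cumulative_intensity(params, 10.0) == pytest.approx(1.0)

    def test_square_root_case(self):
        delta = 3.7947331922020533
        params = LearningParams(8, 0.5, delta)
        # hand-check oracle: delta * sqrt(5)
        assert cumulative_intensity(params, 5.0) == pytest.approx(delta * math.sqrt(5.0), rel=1e-12)

    def test_zero_and_monotone(self):
        params = LearningParams(2, 0.7, 0.3)
        assert cumulative_intensity(params, 0.0) == 0.0
        grid = np.linspace(0.1, 40, 200)
        assert np.all(np.diff(cumulative_intensity(params, grid)) > 0)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            cumulative_intensity(LearningParams(1, 1, 1), -1.0)


class TestCdf:
    def test_gamma_poisson_tail_oracle(self):
        # P(>=5 events by t=5 at unit rate) = 1 - e^-5 * sum_{k<5} 5^k/k!
        expected = 1.0 - math.exp(-5.0) * sum(5.0**k / math.factorial(k) for k in range(5))
        got = aoa_cdf(ModelKind.GAMMA, LearningParams(5, 1.0, 1.0), 5.0)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.559507, abs=1e-6)

    def test_weibull_closed_form(self):
        got = aoa_cdf(ModelKind.WEIBULL, LearningParams(1, 2.0, 0.01), 10.0)
        assert got == pytest.approx(1.0 - math.exp(-1.0), abs=1e-12)

    @pytest.mark.parametrize("kind", ACCUMULATOR_KINDS)
    def test_zero_at_origin(self, kind, rng=np.random.default_rng(0)):
        assert aoa_cdf(kind, kind_params(kind, rng), 0.0) == 0.0

    def test_logistic_any_real_age(self):
        params = LogisticParams(1.0, 5.0)
        assert aoa_cdf(ModelKind.LOGISTIC, params, -10.0) < 0.5
        assert aoa_cdf(ModelKind.LOGISTIC, params, 5.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("kind", list(ModelKind))
    def test_monotone_and_bounded(self, kind):
        rng = np.random.default_rng(7)
        for _ in range(10):
            params = kind_params(kind, rng)
            grid = np.linspace(0.0, 200.0, 400)
            values = aoa_cdf(kind, params, grid)
            assert np.all(np.diff(values) >= -1e-15)
            assert np.all((values >= 0) & (values <= 1))
            assert aoa_cdf(kind, params, 1e6) > 0.999

    def test_reduction_identities(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0.1, 60, 50)
        for _ in range(20):
            p = random_learning_params(rng)
            weib = LearningParams(1.0, p.rate_exponent, p.base_rate)
            np.testing.assert_allclose(
                aoa_cdf(ModelKind.WEIBULL_GAMMA, weib, t),
                aoa_cdf(ModelKind.WEIBULL, weib, t),
                rtol=0,
                atol=1e-10,
            )
            np.testing.assert_allclose(
                aoa_cdf(ModelKind.WEIBULL, weib, t),
                1.0 - np.exp(-p.base_rate * t**p.rate_exponent),
                rtol=0,
                atol=1e-10,
            )
            gam = LearningParams(p.accumulation, 1.0, p.base_rate)
            from scipy import stats

            np.testing.assert_allclose(
                aoa_cdf(ModelKind.WEIBULL_GAMMA, gam, t),
                stats.gamma.cdf(t, a=p.accumulation, scale=1.0 / p.base_rate),
                rtol=0,
                atol=1e-10,
            )

    def test_scale_covariance(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0.1, 40, 30)
        for _ in range(20):
            p = random_learning_params(rng)
            c = 10.0 ** rng.uniform(-0.5, 0.5)
            rescaled = LearningParams(
                p.accumulation, p.rate_exponent, p.base_rate * c**-p.rate_exponent
            )
            np.testing.assert_allclose(
                aoa_cdf(ModelKind.WEIBULL_GAMMA, rescaled, c * t),
                aoa_cdf(ModelKind.WEIBULL_GAMMA, p, t),
                rtol=0,
                atol=1e-10,
            )


class TestPdf:
    def test_gamma_shape_two(self):
        got = aoa_pdf(ModelKind.GAMMA, LearningParams(2, 1.0, 1.0), 1.0)
        assert got == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_exponential(self):
        got = aoa_pdf(ModelKind.GAMMA, LearningParams(1, 1.0, 2.0), 0.5)
        assert got == pytest.approx(2.0 * math.exp(-1.0), rel=1e-12)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            aoa_pdf(ModelKind.GAMMA, LearningParams(2, 1.0, 1.0), 0.0)

    @pytest.mark.parametrize("kind", list(ModelKind))
    def test_matches_cdf_derivative(self, kind):
        rng = np.random.default_rng(3)
        h = 1e-5
        for _ in range(10):
            params = kind_params(kind, rng)
            mean = aoa_mean(kind, params)
            for t in np.linspace(0.3 * mean, 2.0 * mean, 7):
                if t <= h:
                    continue
                numeric = (aoa_cdf(kind, params, t + h) - aoa_cdf(kind, params, t - h)) / (2 * h)
                assert aoa_pdf(kind, params, t) == pytest.approx(numeric, rel=1e-6, abs=1e-9)

    @pytest.mark.parametrize("kind", ACCUMULATOR_KINDS)
    def test_integrates_to_one(self, kind):
        rng = np.random.default_rng(4)
        for _ in range(5):
            params = kind_params(kind, rng)
            total, _ = integrate.quad(
                lambda t: aoa_pdf(kind, params, t), 0, np.inf, limit=300
            )
            assert total == pytest.approx(1.0, abs=1e-6)


class TestHazard:
    def test_constant_rate_case(self):
        params = LearningParams(1, 1.0, 0.3)
        for t in [0.1, 1.0, 10.0, 42.0]:
            assert aoa_hazard(ModelKind.WEIBULL, params, t) == pytest.approx(0.3, rel=1e-12)

    def test_weibull_accelerating_increases(self):
        params = LearningParams(1, 3.0, 0.01)
        grid = np.linspace(0.5, 10, 50)
        assert np.all(np.diff(aoa_hazard(ModelKind.WEIBULL, params, grid)) > 0)

    def test_peaked_case(self):
        # decelerating rate with a multi-event threshold: hazard rises then falls
        params = LearningParams(8, 0.5, 3.7947331922020533)
        grid = np.linspace(0.05, 50, 2000)
        h = aoa_hazard(ModelKind.WEIBULL_GAMMA, params, grid)
        peak = int(np.argmax(h))
        assert 0 < peak < len(grid) - 1
        assert np.all(np.diff(h[: peak + 1]) > 0)
        assert np.all(np.diff(h[peak:]) < 0)

    def test_saturated_survival_gives_inf(self):
        params = LearningParams(1, 1.0, 5.0)
        assert aoa_hazard(ModelKind.GAMMA, params, 1e6) == np.inf

    @pytest.mark.parametrize("kind", list(ModelKind))
    def test_mutual_consistency(self, kind):
        # hazard * survival == pdf on a grid spanning the bulk of the law
        rng = np.random.default_rng(5)
        for _ in range(10):
            params = kind_params(kind, rng)
            grid = np.asarray(
                aoa_quantile(kind, params, np.linspace(0.01, 0.99, 40))
            )
            grid = grid[grid > 0]
            f = np.asarray(aoa_pdf(kind, params, grid))
            s = 1.0 - np.asarray(aoa_cdf(kind, params, grid))
            h = np.asarray(aoa_hazard(kind, params, grid))
            np.testing.assert_allclose(h * s, f, rtol=1e-8)


class TestMean:
    def test_logistic_fig_values(self):
        assert aoa_mean(ModelKind.LOGISTIC, LogisticParams(1.0, 5.0)) == pytest.approx(5.0)

    def test_gamma(self):
        assert aoa_mean(ModelKind.GAMMA, LearningParams(5, 1.0, 1.0)) == pytest.approx(5.0)

    def test_exponential(self):
        assert aoa_mean(ModelKind.GAMMA, LearningParams(1, 1.0, 2.0)) == pytest.approx(0.5)

    @pytest.mark.parametrize("kind", ACCUMULATOR_KINDS)
    def test_matches_numeric_integration(self, kind):
        # bounded quadrature out to the 1 - 1e-12 quantile; the truncated
        # tail is negligible at the 1e-6 relative tolerance for the rate
        # exponents drawn here
        rng = np.random.default_rng(6)
        for _ in range(34):  # ~100 draws across the three kinds
            base = kind_params(kind, rng)
            d = base.rate_exponent if kind is not ModelKind.GAMMA else 1.0
            d = float(np.clip(d, 0.4, 5.0))
            params = LearningParams(
                base.accumulation if kind is not ModelKind.WEIBULL else 1.0, d, base.base_rate
            )
            closed = aoa_mean(kind, params)
            upper = float(aoa_quantile(kind, params, 1.0 - 1e-12))
            interior = [float(aoa_quantile(kind, params, q)) for q in (0.05, 0.5, 0.95)]
            numeric, _ = integrate.quad(
                lambda t: t * aoa_pdf(kind, params, t), 0, upper, points=interior, limit=500
            )
            assert closed == pytest.approx(numeric, rel=1e-6)


class TestQuantile:
    def test_exponential_median(self):
        got = aoa_quantile(ModelKind.WEIBULL, LearningParams(1, 1.0, 1.0), 0.5)
        assert got == pytest.approx(math.log(2.0), rel=1e-10)

    def test_logistic_median(self):
        assert aoa_quantile(ModelKind.LOGISTIC, LogisticParams(1.0, 5.0), 0.5) == pytest.approx(5.0)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_level_rejected(self, q):
        with pytest.raises(ValueError):
            aoa_quantile(ModelKind.GAMMA, LearningParams(2, 1.0, 1.0), q)

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        q=st.floats(1e-6, 1.0 - 1e-6, allow_nan=False),
        kind=st.sampled_from(list(ModelKind)),
    )
    def test_round_trip(self, seed, q, kind):
        params = kind_params(kind, np.random.default_rng(seed))
        t = aoa_quantile(kind, params, q)
        assert aoa_cdf(kind, params, t) == pytest.approx(q, abs=1e-8)

    def test_monotone_in_level(self):
        params = LearningParams(8, 0.5, 3.7947331922020533)
        qs = np.linspace(0.01, 0.99, 50)
        ts = aoa_quantile(ModelKind.WEIBULL_GAMMA, params, qs)
        assert np.all(np.diff(ts) > 0)


def _scan_hazard_shape(params, t_max=50.0, n=4000):
    """Numeric oracle: classify by scanning the hazard on a dense grid."""
    grid = np.linspace(t_max / n, t_max, n)
    h = np.asarray(aoa_hazard(ModelKind.WEIBULL_GAMMA, params, grid))
    finite = np.isfinite(h)
    h = h[finite]
    d = np.diff(h)
    rel = np.abs(d) / np.maximum(np.abs(h[:-1]), 1e-300)
    if np.all(rel < 1e-6):
        return HazardShape.CONSTANT
    increasing, decreasing = np.any(d > 0), np.any(d < 0)
    if increasing and not decreasing:
        return HazardShape.MONOTONE_INCREASING
    if decreasing and not increasing:
        return HazardShape.MONOTONE_DECREASING
    peak = int(np.argmax(h))
    if 0 < peak < len(h) - 1 and np.all(d[:peak] > 0) and np.all(d[peak:] < 0):
        return HazardShape.PEAKED
    return HazardShape.BATHTUB


class TestClassifyHazardShape:
    def test_peaked_prototype(self):
        assert classify_hazard_shape(LearningParams(8, 0.5, 1.0)) is HazardShape.PEAKED

    def test_constant(self):
        assert classify_hazard_shape(LearningParams(1, 1.0, 0.7)) is HazardShape.CONSTANT

    def test_gamma_increasing(self):
        assert (
            classify_hazard_shape(LearningParams(5, 1.0, 0.2)) is HazardShape.MONOTONE_INCREASING
        )

    def test_weibull_decelerating_decreasing(self):
        assert (
            classify_hazard_shape(LearningParams(1, 0.5, 0.2)) is HazardShape.MONOTONE_DECREASING
        )

    def test_matches_numeric_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            params = random_learning_params(rng, log10_range=(-0.6, 0.8))
            label = classify_hazard_shape(params)
            # scan over a window covering the bulk of the distribution
            t_hi = float(aoa_quantile(ModelKind.WEIBULL_GAMMA, params, 0.999)) * 1.5
            assert _scan_hazard_shape(params, t_max=t_hi) is label
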