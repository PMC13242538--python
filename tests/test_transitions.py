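"""Progression-time laws: closed forms, inverses, sampling, serialization."""

import numpy as np
import pytest
from scipy import integrate, stats

from tristate import TransitionSpec, ThreeStateSpec, weibull_dgp


WEIBULL_X = TransitionSpec("weibull", intercept=3.0, scale=0.2)
WEIBULL_T = TransitionSpec("weibull", intercept=1.2, scale=0.3)


class TestLinearPredictor:
    @pytest.mark.parametrize("intercept,coefs,z,expected", [
        (3.0, (), None, 3.0),
        (3.0, (0.5, 0.5), (1.0, 1.0), 4.0),
        (1.2, (0.5, 0.5), (0.0, 0.0), 1.2),
    ])
    def test_values(self, intercept, coefs, z, expected):
        spec = TransitionSpec("weibull", intercept, coefs, 0.2)
        assert spec.linear_predictor(z) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        spec = TransitionSpec("weibull", 3.0, (0.5, 0.5), 0.2)
        with pytest.raises(ValueError, match="does not match"):
            spec.linear_predictor([1.0])
        with pytest.raises(ValueError):
            spec.linear_predictor(None)


class TestSurvival:
    def test_no_mass_at_origin(self):
        for spec in (WEIBULL_X, TransitionSpec("exponential", 0.7)):
            assert spec.survival(0.0) == pytest.approx(1.0)

    def test_weibull_median_is_printed_value(self):
        # median solves S = 0.5: exp(3) * (ln 2)^0.2 = 18.67 -> "18.7"
        med = np.exp(3.0) * np.log(2.0) ** 0.2
        assert WEIBULL_X.survival(med) == pytest.approx(0.5, abs=1e-12)
        assert round(med, 1) == 18.7

    def test_unit_rate_exponential_median(self):
        spec = TransitionSpec("exponential", 0.0)
        assert spec.survival(np.log(2.0)) == pytest.approx(0.5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            WEIBULL_X.survival(-1.0)

    def test_monotone_and_limits(self):
        u = np.linspace(0, 200, 500)
        s = WEIBULL_X.survival(u)
        assert np.all(np.diff(s) <= 1e-15)
        assert s[0] == 1.0 and s[-1] < 1e-6

    def test_weibull_sigma_one_equals_exponential(self):
        w = TransitionSpec("weibull", 1.4, scale=1.0)
        e = TransitionSpec("exponential", 1.4)
        u = np.linspace(0.0, 30.0, 200)
        assert np.allclose(w.survival(u), e.survival(u), atol=1e-12)
        assert np.allclose(w.density(u[1:]), e.density(u[1:]), atol=1e-12)

    def test_single_piece_piecewise_equals_exponential(self):
        pw = TransitionSpec("piecewise_constant", log_rates=(np.log(0.3),))
        e = TransitionSpec("exponential", -np.log(0.3))
        u = np.linspace(0.0, 20.0, 100)
        assert np.allclose(pw.survival(u), e.survival(u), atol=1e-12)


class TestDensityHazardQuantile:
    def test_density_integrates_to_one(self):
        for spec in (WEIBULL_X, WEIBULL_T, TransitionSpec("exponential", 1.2),
                     TransitionSpec("piecewise_constant", cuts=(2.0, 5.0),
                                    log_rates=(-2.0, -1.0, -0.5))):
            hi = float(np.atleast_1d(spec.quantile(1 - 1e-12))[0])
            val, _ = integrate.quad(lambda u: float(spec.density(u)), 0, hi, limit=400)
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_quantile_closed_forms(self):
        assert WEIBULL_X.quantile(0.5) == pytest.approx(
            np.exp(3.0) * np.log(2.0) ** 0.2, abs=1e-12)
        spec = TransitionSpec("exponential", 1.2)
        assert spec.quantile(0.5) == pytest.approx(np.exp(1.2) * np.log(2.0))

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_quantile_survival_roundtrip(self, p):
        for spec in (WEIBULL_X, TransitionSpec("exponential", 0.3),
                     TransitionSpec("piecewise_constant", cuts=(1.0, 3.0),
                                    log_rates=(-1.0, -2.0, 0.0))):
            q = float(np.atleast_1d(spec.quantile(p))[0])
            assert spec.survival(q) == pytest.approx(1 - p, abs=1e-10)

    def test_quantile_level_validated(self):
        with pytest.raises(ValueError):
            WEIBULL_X.quantile(0.0)
        with pytest.raises(ValueError):
            WEIBULL_X.quantile(1.2)

    def test_hazard_is_density_over_survival(self):
        for spec in (WEIBULL_X, WEIBULL_T):
            u = np.linspace(0.5, float(spec.quantile(0.999)), 50)
            assert np.allclose(spec.hazard(u),
                               spec.density(u) / spec.survival(u), rtol=1e-10)


class TestSampling:
    def test_weibull_medians_match_generating_models(self):
        rng = np.random.default_rng(7)
        x = WEIBULL_X.sample(rng, size=10**6)
        assert np.median(x) == pytest.approx(18.7, abs=0.1)
        t = WEIBULL_T.sample(rng, size=10**6)
        assert np.median(t) == pytest.approx(3.0, abs=0.05)

    def test_fixed_seed_reproducible(self):
        a = WEIBULL_X.sample(np.random.default_rng(42), size=100)
        b = WEIBULL_X.sample(np.random.default_rng(42), size=100)
        assert np.array_equal(a, b)

    def test_empirical_cdf_matches_survival(self):
        rng = np.random.default_rng(3)
        for spec in (WEIBULL_T, TransitionSpec("exponential", 1.0),
                     TransitionSpec("piecewise_constant", cuts=(2.0,),
                                    log_rates=(-1.5, -0.5))):
            draws = spec.sample(rng, size=10**5)
            res = stats.kstest(draws, lambda u: 1 - spec.survival(np.maximum(u, 0.0)))
            assert res.statistic < 0.01


class TestSpecValidation:
    def test_exponential_scale_fixed(self):
        with pytest.raises(ValueError):
            TransitionSpec("exponential", scale=0.5)

    def test_piecewise_shapes(self):
        with pytest.raises(ValueError):
            TransitionSpec("piecewise_constant", cuts=(1.0,), log_rates=(0.0,))
        with pytest.raises(ValueError):
            TransitionSpec("piecewise_constant", cuts=(3.0, 1.0),
                           log_rates=(0.0, 0.0, 0.0))

    def test_clock_constraints(self):
        pw = TransitionSpec("piecewise_constant", log_rates=(0.0,))
        wb = TransitionSpec("weibull", 1.0, scale=0.5)
        with pytest.raises(ValueError):
            ThreeStateSpec(wb, pw, "state_entry")
        with pytest.raises(ValueError):
            ThreeStateSpec(wb, wb, "process_time")

    def test_serialization_roundtrip(self):
        dgp = weibull_dgp(2)
        again = ThreeStateSpec.from_dict(dgp.to_dict())
        assert again == dgp
        pw = TransitionSpec("piecewise_constant", coefficients=(0.2,),
                            cuts=(1.0, 2.0), log_rates=(-1.0, -2.0, 0.5))
        assert TransitionSpec.from_dict(pw.to_dict()) == pw


class TestPropertyBased:
    from hypothesis import given, settings, strategies as st

    @given(intercept=st.floats(-1.0, 3.5), sigma=st.floats(0.1, 2.0),
           p=st.floats(0.01, 0.99))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_quantile_survival_inverse_pair(self, intercept, sigma, p):
        spec = TransitionSpec("weibull", intercept, scale=sigma)
        q = float(spec.quantile(p))
        assert spec.survival(q) == pytest.approx(1.0 - p, abs=1e-10)

    @given(intercept=st.floats(-1.0, 3.5), u=st.floats(0.0, 50.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_weibull_sigma_one_is_exponential_everywhere(self, intercept, u):
        w = TransitionSpec("weibull", intercept, scale=1.0)
        e = TransitionSpec("exponential", intercept)
        assert float(w.survival(u)) == pytest.approx(float(e.survival(u)),
                                                     abs=1e-12)
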