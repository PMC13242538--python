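"""CIF estimands: closed forms, convolution, quantiles, bands, hazard
ratios, sojourn summaries."""

import numpy as np
import pytest

from tristate import (ThreeStateSpec, TransitionSpec, conditional_cif,
                      hazard_ratio, marginal_cif, marginal_cif_quantile,
                      sojourn_summary, weibull_dgp)
from tristate.cif import cif_curve
from tristate.evaluation import true_percentile

EMPTY_BANK = np.empty((1, 0))


class TestConditionalCIF:
    def test_zero_at_origin(self):
        spec = weibull_dgp(0)
        for tr in ("1->2", "2->3", "1->3"):
            assert conditional_cif(spec, tr, None, [0.0])[0] == pytest.approx(0.0)

    def test_exponential_closed_form(self):
        spec = ThreeStateSpec(TransitionSpec("exponential", 2.0),
                              TransitionSpec("exponential", 1.0))
        u = np.linspace(0, 30, 40)
        theta = np.exp(-2.0)
        assert np.allclose(conditional_cif(spec, "1->2", None, u),
                           1 - np.exp(-theta * u), atol=1e-12)

    def test_sum_transition_matches_monte_carlo(self):
        spec = weibull_dgp(0)
        rng = np.random.default_rng(4)
        x = spec.spec12.sample(rng, size=10**6)
        t = spec.spec23.sample(rng, size=10**6)
        for u in (15.0, 20.0, 25.0):
            mc = np.mean(x + t <= u)
            assert conditional_cif(spec, "1->3", None, [u])[0] == pytest.approx(
                mc, abs=0.003)

    def test_sum_cif_below_first_transition_cif(self):
        spec = weibull_dgp(0)
        u = np.linspace(0.5, 40, 60)
        assert np.all(conditional_cif(spec, "1->3", None, u)
                      <= conditional_cif(spec, "1->2", None, u) + 1e-12)


class TestMarginalCIF:
    def test_p0_marginal_equals_conditional(self):
        spec = weibull_dgp(0)
        u = np.linspace(0, 30, 31)
        assert np.allclose(marginal_cif(spec, "1->2", u, EMPTY_BANK),
                           conditional_cif(spec, "1->2", None, u))

    def test_single_member_bank_equals_conditional(self):
        spec = weibull_dgp(2)
        z = np.array([0.7, 1.0])
        u = np.linspace(0, 40, 20)
        assert np.allclose(marginal_cif(spec, "1->2", u, z.reshape(1, 2)),
                           conditional_cif(spec, "1->2", z, u))

    def test_marginal_median_matches_monte_carlo_truth(self):
        # the p=2 generator's marginal median of x is ~23.1; the CIF
        # averaged over a large covariate bank must cross 0.5 there
        spec = weibull_dgp(2)
        rng = np.random.default_rng(9)
        from tristate import generate_covariates

        bank = generate_covariates(4000, 2, rng)
        med = true_percentile(spec, "1->2", 0.5)
        assert med == pytest.approx(23.1, abs=0.15)
        val = marginal_cif(spec, "1->2", [med], bank)[0]
        assert val == pytest.approx(0.5, abs=0.02)


class TestCIFQuantile:
    def test_printed_medians(self):
        spec = weibull_dgp(0)
        assert round(marginal_cif_quantile(spec, "1->2", 0.5, EMPTY_BANK), 1) == 18.7
        assert round(marginal_cif_quantile(spec, "2->3", 0.5, EMPTY_BANK), 1) == 3.0

    @pytest.mark.parametrize("tr", ["1->2", "2->3", "1->3"])
    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_roundtrip(self, tr, p):
        spec = weibull_dgp(0)
        q = marginal_cif_quantile(spec, tr, p, EMPTY_BANK)
        assert marginal_cif(spec, tr, [q], EMPTY_BANK)[0] == pytest.approx(
            p, abs=1e-6)

    def test_unreachable_level_raises_with_asymptote(self):
        # a hazard that switches off leaves the CIF defective: high levels
        # are unreachable and must be reported, not looped on
        spec = ThreeStateSpec(
            TransitionSpec("weibull", 1.0, scale=0.5),
            TransitionSpec("piecewise_constant", cuts=(5.0,),
                           log_rates=(-1.0, -800.0)), "process_time")
        with pytest.raises(ValueError, match="plateau"):
            marginal_cif_quantile(spec, "2->3", 0.99, EMPTY_BANK)


class TestBands:
    def test_band_ordering_and_nesting(self, weibull_bayes_fit):
        res = weibull_bayes_fit
        times = np.linspace(0.5, 25, 30)
        wide = res.cif("1->2", times=times, level=0.95)
        narrow = res.cif("1->2", times=times, level=0.5)
        assert np.all(wide.lower <= wide.upper)
        assert np.all(wide.lower - 1e-12 <= narrow.lower)
        assert np.all(narrow.upper <= wide.upper + 1e-12)

    def test_band_contains_draw_median(self, weibull_bayes_fit):
        res = weibull_bayes_fit
        times = np.linspace(0.5, 25, 15)
        curve = res.cif("1->2", times=times)
        mat = np.array([marginal_cif(s, "1->2", times, EMPTY_BANK)
                        for s in res.draw_specs()])
        med = np.median(mat, axis=0)
        assert np.all(curve.lower - 1e-12 <= med)
        assert np.all(med <= curve.upper + 1e-12)

    def test_too_few_draws_refused(self):
        spec = weibull_dgp(0)
        with pytest.raises(ValueError, match="50 draws"):
            cif_curve(spec, "1->2", np.linspace(0, 10, 5), EMPTY_BANK,
                      draw_specs=[spec] * 10)


class TestCumulativeHazard:
    def test_exponential_linear(self, exp_strong_design):
        from tristate import ThreeStateModel, exponential_dgp, generate_cohort

        design, _ = exp_strong_design
        cohort = generate_cohort(500, 0, exponential_dgp(0), design, seed=2)
        res = ThreeStateModel(cohort.histories, family12="exponential",
                              family23="exponential").fit(seed=0)
        times = np.linspace(0.0, 10.0, 11)
        ch = res.cumulative_hazard("1->2", times)
        assert ch[0] == pytest.approx(0.0)
        assert np.all(np.diff(ch) > 0)
        slopes = np.diff(ch) / np.diff(times)
        assert np.allclose(slopes, slopes[0], rtol=1e-6)


class TestHazardRatio:
    def test_zero_coefficient_gives_unity(self):
        spec = ThreeStateSpec(TransitionSpec("weibull", 3.0, (0.0,), 0.2),
                              TransitionSpec("weibull", 1.2, (0.0,), 0.3))
        assert hazard_ratio(spec, "1->2", 0) == pytest.approx(1.0)

    def test_aft_transform_closed_forms(self):
        spec = ThreeStateSpec(TransitionSpec("weibull", 3.0, (0.5,), 0.5),
                              TransitionSpec("exponential", 1.2, (-0.2,)))
        assert hazard_ratio(spec, "1->2", 0) == pytest.approx(np.exp(-1.0))
        assert hazard_ratio(spec, "2->3", 0) == pytest.approx(np.exp(0.2))

    def test_weibull_proportionality(self):
        tspec = TransitionSpec("weibull", 2.0, (0.4, -0.3), 0.25)
        spec = ThreeStateSpec(tspec, TransitionSpec("weibull", 1.0, (0.0, 0.0), 0.3))
        hr = hazard_ratio(spec, "1->2", 0)
        z = np.array([0.3, 1.0])
        z1 = z + np.array([1.0, 0.0])
        for u in (2.0, 7.0, 19.0):
            ratio = float(tspec.hazard(u, z1) / tspec.hazard(u, z))
            assert abs(ratio - hr) < 1e-10


class TestSojourn:
    def test_exponential_mean(self):
        out = sojourn_summary(TransitionSpec("exponential", 1.2))
        assert out["mean"] == pytest.approx(np.exp(1.2))

    def test_weibull_scale_one_limits_to_exponential(self):
        w = sojourn_summary(TransitionSpec("weibull", 1.2, scale=1.0))
        e = sojourn_summary(TransitionSpec("exponential", 1.2))
        assert w["mean"] == pytest.approx(e["mean"])
        assert w["median"] == pytest.approx(e["median"])

    def test_restricted_mean_below_mean(self):
        out = sojourn_summary(TransitionSpec("weibull", 1.2, scale=0.3), tau=3.0)
        assert out["restricted_mean"] <= out["mean"]
        assert out["restricted_mean"] > 0


class TestCurveObject:
    def test_monotone_validation(self):
        with pytest.raises(ValueError):
            from tristate.cif import CIFCurve

            CIFCurve("1->2", np.array([0.0, 1.0]), np.array([0.5, 0.2]))

    def test_to_frame(self, weibull_ml_fit):
        curve = weibull_ml_fit.cif("1->2", times=np.linspace(0, 20, 5), band=False)
        df = curve.to_frame()
        assert list(df.columns) == ["time", "estimate"]
        assert len(df) == 5
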