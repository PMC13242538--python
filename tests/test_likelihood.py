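"""Interval-censored likelihood: oracle equivalence, quadrature accuracy,
probability decomposition, process-time variant."""

import numpy as np
import pytest

from tristate import (LikelihoodOptions, SubjectHistory, ThreeStateSpec,
                      TransitionSpec, closed_form_exponential_loglik,
                      cohort_loglik, exponential_dgp, process_time_loglik,
                      subject_loglik, weibull_dgp)
from tristate.likelihood import DEFAULT_OPTIONS, _interval_probs


def _history(delta, left, right):
    visits = np.array([right]) if left == 0 else np.array([left, right])
    return SubjectHistory(0, visits, delta, left if delta != 1 else 0.0, right)


class TestRightCensored:
    def test_exponential_survival(self):
        model = ThreeStateSpec(TransitionSpec("exponential", 2.0),
                               TransitionSpec("exponential", 1.0))
        h = _history(1, 0.0, 7.5)
        theta = np.exp(-2.0)
        assert subject_loglik(model, h) == pytest.approx(-theta * 7.5, abs=1e-12)
        assert closed_form_exponential_loglik(model, h) == pytest.approx(
            subject_loglik(model, h), abs=1e-12)


class TestExponentialOracle:
    def test_randomized_sweeps_agree(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            b12, b23 = rng.uniform(-1.0, 3.5, size=2)
            l = rng.uniform(0.0, 10.0)
            r = l + rng.uniform(0.1, 8.0)
            model = ThreeStateSpec(TransitionSpec("exponential", b12),
                                   TransitionSpec("exponential", b23))
            for delta in (2, 3):
                h = _history(delta, l, r)
                assert closed_form_exponential_loglik(model, h) == pytest.approx(
                    subject_loglik(model, h), abs=1e-8)

    def test_equal_rate_limit_continuous(self):
        l, r = 2.0, 5.0
        model_eq = ThreeStateSpec(TransitionSpec("exponential", 1.3),
                                  TransitionSpec("exponential", 1.3))
        for delta in (2, 3):
            h = _history(delta, l, r)
            ll_eq = closed_form_exponential_loglik(model_eq, h)
            for eps in (1e-6, -1e-6):
                model = ThreeStateSpec(TransitionSpec("exponential", 1.3),
                                       TransitionSpec("exponential", 1.3 + eps))
                assert closed_form_exponential_loglik(model, h) == pytest.approx(
                    ll_eq, abs=1e-6)

    def test_non_exponential_rejected(self):
        model = weibull_dgp(0)
        with pytest.raises(ValueError):
            closed_form_exponential_loglik(model, _history(2, 1.0, 2.0))


class TestDecomposition:
    @pytest.mark.parametrize("model", [exponential_dgp(0), weibull_dgp(0)],
                             ids=["exponential", "weibull"])
    def test_three_outcomes_sum_to_survival_at_left(self, model):
        # P(delta2 in (l,r]) + P(delta3 in (l,r]) + S_x(r) = S_x(l)
        rng = np.random.default_rng(5)
        for _ in range(50):
            l = rng.uniform(0.0, 25.0)
            r = l + rng.uniform(0.5, 10.0)
            p2, p3 = _interval_probs(model, [l], [r], np.empty((1, 0)),
                                     DEFAULT_OPTIONS)
            assert 0.0 <= p2[0] <= 1.0 and 0.0 <= p3[0] <= 1.0
            total = p2[0] + p3[0] + float(model.spec12.survival(r))
            assert total == pytest.approx(float(model.spec12.survival(l)), abs=1e-8)


class TestQuadratureAccuracy:
    def test_node_doubling_stable(self):
        model = weibull_dgp(0)
        for delta, l, r in [(2, 10.0, 14.0), (3, 15.0, 22.0), (2, 0.0, 6.0)]:
            h = _history(delta, l, r)
            a = subject_loglik(model, h, LikelihoodOptions(quadrature_nodes=64))
            b = subject_loglik(model, h, LikelihoodOptions(quadrature_nodes=128))
            assert abs(a - b) < 1e-8

    def test_riemann_brute_force_agreement(self):
        model = weibull_dgp(0)
        l, r = 12.0, 17.0
        u = np.linspace(l, r, 10**6)
        fx = model.spec12.density(u)
        st = model.spec23.survival(r - u)
        p2_brute = np.trapezoid(fx * st, u)
        p2, p3 = _interval_probs(model, [l], [r], np.empty((1, 0)), DEFAULT_OPTIONS)
        assert p2[0] == pytest.approx(p2_brute, rel=1e-6)
        p3_brute = np.trapezoid(fx * (1 - st), u)
        assert p3[0] == pytest.approx(p3_brute, rel=1e-6)

    def test_minimum_nodes_enforced(self):
        with pytest.raises(ValueError):
            LikelihoodOptions(quadrature_nodes=4)


class TestProcessTimeClock:
    def _pw_model(self, log_rates=(-1.2,), cuts=()):
        return ThreeStateSpec(
            TransitionSpec("exponential", 3.0),
            TransitionSpec("piecewise_constant", cuts=cuts, log_rates=log_rates),
            "process_time")

    def test_single_piece_matches_memoryless_state_entry(self):
        # constant hazard: time-in-state and process-time clocks coincide
        pw = self._pw_model()
        se = ThreeStateSpec(TransitionSpec("exponential", 3.0),
                            TransitionSpec("exponential", 1.2))
        for delta, l, r in [(2, 2.0, 5.0), (3, 2.0, 5.0), (2, 0.0, 4.0), (1, 0.0, 9.0)]:
            h = _history(delta, l, r)
            assert process_time_loglik(pw, h) == pytest.approx(
                subject_loglik(se, h), abs=1e-8)

    def test_cumulative_hazard_additive_over_pieces(self):
        spec = TransitionSpec("piecewise_constant", cuts=(2.0, 5.0),
                              log_rates=(-1.0, -0.3, 0.2))
        for a, b, c in [(0.5, 2.0, 4.0), (1.0, 3.0, 7.0)]:
            full = spec._baseline_cumhaz(np.array([c]))[0] - spec._baseline_cumhaz(np.array([a]))[0]
            split = (spec._baseline_cumhaz(np.array([b]))[0] - spec._baseline_cumhaz(np.array([a]))[0]
                     + spec._baseline_cumhaz(np.array([c]))[0] - spec._baseline_cumhaz(np.array([b]))[0])
            assert full == pytest.approx(split, abs=1e-12)

    def test_riemann_agreement(self):
        model = self._pw_model(log_rates=(-1.5, -0.5, 0.0), cuts=(3.0, 6.0))
        l, r = 2.0, 7.0
        u = np.linspace(l, r, 10**6)
        fx = model.spec12.density(u)
        lam_r = model.spec23._baseline_cumhaz(np.array([r]))[0]
        st = np.exp(-(lam_r - model.spec23._baseline_cumhaz(u)))
        p2_brute = np.trapezoid(fx * st, u)
        p2, p3 = _interval_probs(model, [l], [r], np.empty((1, 0)), DEFAULT_OPTIONS)
        assert p2[0] == pytest.approx(p2_brute, rel=1e-6)

    def test_clock_mismatch_rejected(self):
        with pytest.raises(ValueError):
            process_time_loglik(exponential_dgp(0), _history(2, 1.0, 2.0))
        with pytest.raises(ValueError):
            subject_loglik(self._pw_model(), _history(2, 1.0, 2.0))


class TestCohortLoglik:
    def test_empty_cohort_zero(self):
        assert cohort_loglik(weibull_dgp(0), []) == 0.0

    def test_sum_and_permutation_invariance(self):
        model = weibull_dgp(0)
        hs = [_history(2, 10.0, 14.0), _history(1, 0.0, 20.0), _history(3, 8.0, 16.0)]
        total = cohort_loglik(model, hs)
        assert total == pytest.approx(sum(subject_loglik(model, h) for h in hs))
        assert cohort_loglik(model, hs[::-1]) == pytest.approx(total)

    def test_continuity_in_parameters(self):
        hs = [_history(2, 10.0, 14.0), _history(3, 8.0, 16.0), _history(1, 0.0, 20.0)]
        rng = np.random.default_rng(2)
        for _ in range(20):
            b12 = rng.uniform(2.0, 4.0)
            s12 = rng.uniform(0.1, 1.0)
            model = ThreeStateSpec(TransitionSpec("weibull", b12, scale=s12),
                                   TransitionSpec("weibull", 1.2, scale=0.3))
            model_eps = ThreeStateSpec(TransitionSpec("weibull", b12 + 1e-7, scale=s12),
                                       TransitionSpec("weibull", 1.2, scale=0.3))
            assert abs(cohort_loglik(model, hs) - cohort_loglik(model_eps, hs)) < 1e-4
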