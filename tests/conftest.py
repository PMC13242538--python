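"""Shared fixtures: calibrated visit designs and reference cohorts.

Calibration is Monte-Carlo based and takes a few seconds per setting, so the
designs are session-scoped and shared across test modules.
"""

import numpy as np
import pytest

from tristate import (ThreeStateModel, VisitDesign, calibrate_design,
                      exponential_dgp, generate_cohort, weibull_dgp)


@pytest.fixture(scope="session")
def weibull_strong_design():
    rng = np.random.default_rng(20260901)
    design, achieved = calibrate_design(weibull_dgp(0), (0.30, 0.10),
                                        VisitDesign(gap_scale=1.0), rng)
    return design, achieved


@pytest.fixture(scope="session")
def weibull_medium_design():
    rng = np.random.default_rng(20260902)
    design, achieved = calibrate_design(weibull_dgp(0), (0.45, 0.20),
                                        VisitDesign(gap_scale=1.0), rng)
    return design, achieved


@pytest.fixture(scope="session")
def exp_strong_design():
    rng = np.random.default_rng(20260903)
    design, achieved = calibrate_design(exponential_dgp(0), (0.30, 0.10),
                                        VisitDesign(gap_scale=1.0), rng)
    return design, achieved


@pytest.fixture(scope="session")
def weibull_cohort(weibull_strong_design):
    """One n=1000 cohort from the Weibull generator under strong censoring."""
    design, _ = weibull_strong_design
    return generate_cohort(1000, 0, weibull_dgp(0), design, seed=11)


@pytest.fixture(scope="session")
def weibull_ml_fit(weibull_cohort):
    model = ThreeStateModel(weibull_cohort.histories, family12="weibull",
                            family23="weibull")
    res = model.fit(starts=3, seed=0)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def weibull_bayes_fit(weibull_cohort):
    model = ThreeStateModel(weibull_cohort.histories, family12="weibull",
                            family23="weibull")
    return model.fit_bayes(chains=2, iters=2000, seed=5)
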