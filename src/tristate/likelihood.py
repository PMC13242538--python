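"""Interval-censored log-likelihood for the progressive three-state model.

Under censoring after intervention each subject contributes through exactly
one of three terms, determined by the censoring state delta and the last
interval (l, r]:

* delta = 1 (healthy at last visit v_m):  S_x(v_m | z)
* delta = 2 (precursor found):            int_l^r f_x(u|z) S_t(r - u|z) du
* delta = 3 (cancer found):               int_l^r f_x(u|z) F_t(r - u|z) du

where S_t / F_t describe the sojourn time t from state entry.  With the
process-time clock the second transition's hazard runs on the process time
scale instead: the delta = 2 survivor factor becomes
exp(-(Lambda23(r) - Lambda23(u))) for onset at u.

Integrals use fixed-node Gauss-Legendre quadrature on (l, r); the integrands
are smooth there, and a node-doubling check guards accuracy.  A closed-form
evaluation for the doubly exponential (memoryless) model serves as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .simulate import SubjectHistory
from .transitions import ThreeStateSpec, TransitionSpec

__all__ = [
    "LikelihoodOptions",
    "CompiledCohort",
    "subject_loglik",
    "process_time_loglik",
    "closed_form_exponential_loglik",
    "cohort_loglik",
]


@dataclass(frozen=True)
class LikelihoodOptions:
    quadrature_nodes: int = 64
    log_floor: float = 1e-300

    def __post_init__(self):
        if self.quadrature_nodes < 8:
            raise ValueError("need at least 8 quadrature nodes")
        if self.log_floor <= 0:
            raise ValueError("log floor must be positive")


DEFAULT_OPTIONS = LikelihoodOptions()


@lru_cache(maxsize=8)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


def _eta(spec: TransitionSpec, Z: np.ndarray) -> np.ndarray:
    """Per-subject linear predictor for an (n, p) covariate matrix."""
    if len(spec.coefficients) == 0:
        return np.full(Z.shape[0], spec.intercept)
    return spec.intercept + Z @ np.asarray(spec.coefficients)


def _weib_logsurv(u, eta, sigma):
    """log S(u) of the AFT Weibull/exponential family, broadcasting."""
    with np.errstate(divide="ignore", over="ignore"):
        w = (np.log(u) - eta) / sigma
        return -np.exp(w)


def _weib_logpdf(u, eta, sigma):
    with np.errstate(divide="ignore", over="ignore"):
        logu = np.log(u)
        w = (logu - eta) / sigma
        return w - np.log(sigma) - logu - np.exp(w)


@dataclass
class CompiledCohort:
    """Cohort reduced to the arrays the likelihood needs, grouped by delta."""

    t1: np.ndarray   # last visit, delta = 1
    Z1: np.ndarray
    l2: np.ndarray
    r2: np.ndarray
    Z2: np.ndarray
    l3: np.ndarray
    r3: np.ndarray
    Z3: np.ndarray

    @classmethod
    def from_histories(cls, histories) -> "CompiledCohort":
        def rows(delta):
            return [h for h in histories if h.delta == delta]

        d1, d2, d3 = rows(1), rows(2), rows(3)
        pack_z = lambda hs: (np.array([h.covariates for h in hs])
                             if hs else np.empty((0, 0)))
        return cls(
            t1=np.array([h.interval_right for h in d1]), Z1=pack_z(d1),
            l2=np.array([h.interval_left for h in d2]),
            r2=np.array([h.interval_right for h in d2]), Z2=pack_z(d2),
            l3=np.array([h.interval_left for h in d3]),
            r3=np.array([h.interval_right for h in d3]), Z3=pack_z(d3),
        )

    @property
    def n(self) -> int:
        return self.t1.size + self.l2.size + self.l3.size


def _interval_probs(model: ThreeStateSpec, l, r, Z, opts: LikelihoodOptions):
    """Vectorised (P[delta=2 interval], P[delta=3 interval]) for intervals (l, r].

    Returns a pair of arrays: the probability of precursor onset in (l, r]
    without progression by r, and of onset plus progression by r.
    """
    l = np.atleast_1d(np.asarray(l, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(l < 0) or np.any(r <= l):
        raise ValueError("censoring intervals must satisfy 0 <= l < r")
    eta_x = _eta(model.spec12, Z)[:, None]

    if model.clock23 == "state_entry":
        nodes, weights = _leggauss(opts.quadrature_nodes)
        half = 0.5 * (r - l)
        u = l[:, None] + half[:, None] * (nodes[None, :] + 1.0)   # (n, q)
        w = half[:, None] * weights[None, :]
        fx = np.exp(_weib_logpdf(u, eta_x, model.spec12.scale))
        eta_t = _eta(model.spec23, Z)[:, None]
        log_st = _weib_logsurv(r[:, None] - u, eta_t, model.spec23.scale)
        # r - u touches 0 at the last node only in the limit; guard anyway
        st = np.exp(np.where(r[:, None] - u > 0, log_st, 0.0))
        p2 = np.einsum("ij,ij->i", w, fx * st)
        p3 = np.einsum("ij,ij->i", w, fx * (1.0 - st))
        return p2, p3

    # process-time clock: the integrand has kinks at the hazard cut points,
    # so integrate piece by piece (the onset mass over (l, r] is closed form
    # and yields p3 by complement)
    zeta = (Z @ np.asarray(model.spec23.coefficients)
            if len(model.spec23.coefficients) else np.zeros(l.size))
    lam_r = model.spec23._baseline_cumhaz(r)
    edges = np.concatenate([[0.0], np.asarray(model.spec23.cuts), [np.inf]])
    nodes, weights = _leggauss(max(16, opts.quadrature_nodes // 4))
    p2 = np.zeros(l.size)
    for k in range(edges.size - 1):
        lo = np.maximum(l, edges[k])
        hi = np.minimum(r, edges[k + 1])
        width = np.clip(hi - lo, 0.0, None)
        if not np.any(width > 0):
            continue
        half = 0.5 * width
        u = lo[:, None] + half[:, None] * (nodes[None, :] + 1.0)
        w = half[:, None] * weights[None, :]
        fx = np.exp(_weib_logpdf(np.maximum(u, 1e-300), eta_x, model.spec12.scale))
        lam_u = model.spec23._baseline_cumhaz(u)
        st = np.exp(-(lam_r[:, None] - lam_u) * np.exp(zeta)[:, None])
        p2 += np.einsum("ij,ij->i", w, fx * st)
    onset = (np.exp(_weib_logsurv(np.maximum(l, 0.0), eta_x[:, 0], model.spec12.scale))
             - np.exp(_weib_logsurv(r, eta_x[:, 0], model.spec12.scale)))
    # l = 0 has survival 1 by definition
    onset = np.where(l > 0, onset,
                     1.0 - np.exp(_weib_logsurv(r, eta_x[:, 0], model.spec12.scale)))
    p3 = np.clip(onset - p2, 0.0, 1.0)
    return p2, p3


def _compiled_loglik(model: ThreeStateSpec, cc: CompiledCohort,
                     opts: LikelihoodOptions) -> float:
    total = 0.0
    floor = opts.log_floor
    if cc.t1.size:
        eta_x = _eta(model.spec12, cc.Z1)
        total += float(np.sum(_weib_logsurv(cc.t1, eta_x, model.spec12.scale)))
    if cc.l2.size:
        p2, _ = _interval_probs(model, cc.l2, cc.r2, cc.Z2, opts)
        total += float(np.sum(np.log(np.maximum(p2, floor))))
    if cc.l3.size:
        _, p3 = _interval_probs(model, cc.l3, cc.r3, cc.Z3, opts)
        total += float(np.sum(np.log(np.maximum(p3, floor))))
    if not np.isfinite(total):
        return -np.inf
    return total


def subject_loglik(model: ThreeStateSpec, h: SubjectHistory,
                   opts: LikelihoodOptions = DEFAULT_OPTIONS) -> float:
    """Log-likelihood contribution of one subject (state-entry clock)."""
    if model.clock23 != "state_entry":
        raise ValueError("subject_loglik expects the state-entry clock; "
                         "see process_time_loglik")
    return _subject_loglik_any(model, h, opts)


def process_time_loglik(model: ThreeStateSpec, h: SubjectHistory,
                        opts: LikelihoodOptions = DEFAULT_OPTIONS) -> float:
    """Subject log-likelihood when the 2 -> 3 hazard runs on process time."""
    if model.clock23 != "process_time":
        raise ValueError("process_time_loglik expects clock23='process_time'")
    return _subject_loglik_any(model, h, opts)


def _subject_loglik_any(model, h, opts):
    z = h.covariates
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    if h.delta == 1:
        eta_x = _eta(model.spec12, Z)[0]
        return float(_weib_logsurv(h.interval_right, eta_x, model.spec12.scale))
    if not (0 <= h.interval_left < h.interval_right):
        raise ValueError("invalid censoring interval")
    p2, p3 = _interval_probs(model, [h.interval_left], [h.interval_right], Z, opts)
    val = p2[0] if h.delta == 2 else p3[0]
    out = float(np.log(max(val, opts.log_floor)))
    if not np.isfinite(out):
        raise FloatingPointError(
            f"non-finite likelihood for subject {h.subject_id}: delta={h.delta}, "
            f"interval=({h.interval_left}, {h.interval_right}]")
    return out


def closed_form_exponential_loglik(model: ThreeStateSpec, h: SubjectHistory) -> float:
    """Analytic subject log-likelihood when both transitions are exponential.

    With rates theta_x = exp(-eta_x), theta_t = exp(-eta_t) the delta = 2
    integral has antiderivative

        theta_x e^{-theta_t r} (e^{-D l} - e^{-D r}) / D,   D = theta_x - theta_t,

    evaluated through expm1 so the D -> 0 (equal-rate) limit is stable.
    """
    if model.spec12.family != "exponential" or model.spec23.family != "exponential":
        raise ValueError("closed form requires exponential families on both transitions")
    Z = np.atleast_2d(np.asarray(h.covariates, dtype=float))
    theta_x = float(np.exp(-_eta(model.spec12, Z)[0]))
    theta_t = float(np.exp(-_eta(model.spec23, Z)[0]))
    if h.delta == 1:
        return -theta_x * h.interval_right
    l, r = h.interval_left, h.interval_right
    width = r - l
    D = theta_x - theta_t
    if D == 0.0:
        integral = width * np.exp(-D * l)
    else:
        integral = np.exp(-D * l) * (-np.expm1(-D * width)) / D
    p2 = theta_x * np.exp(-theta_t * r) * integral
    if h.delta == 2:
        return float(np.log(max(p2, DEFAULT_OPTIONS.log_floor)))
    p_onset = np.exp(-theta_x * l) - np.exp(-theta_x * r)
    p3 = p_onset - p2
    return float(np.log(max(p3, DEFAULT_OPTIONS.log_floor)))


def cohort_loglik(model: ThreeStateSpec, histories,
                  opts: LikelihoodOptions = DEFAULT_OPTIONS) -> float:
    """Sum of subject contributions (subjects are independent).

    ``histories`` may be a list of :class:`SubjectHistory` or an already
    compiled :class:`CompiledCohort` (the fast path used by the fitters).
    """
    if isinstance(histories, CompiledCohort):
        return _compiled_loglik(model, histories, opts)
    cc = CompiledCohort.from_histories(list(histories))
    if cc.n == 0:
        return 0.0
    return _compiled_loglik(model, cc, opts)
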