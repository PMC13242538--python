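"""Cumulative incidence functions and derived estimands.

Transitions are named "1->2" (healthy to precursor, time x), "2->3"
(precursor to cancer, sojourn time t from state entry) and "1->3" (the sum
x + t, i.e. healthy to cancer).  Marginal curves average conditional CIFs
over a bank of covariate profiles (by default the fitted cohort's own
covariates, i.e. empirical standardisation); with no covariates marginal and
conditional coincide.

The "1->3" CIF is a convolution P(x + t <= u) = int_0^u f_x(s) F_t(u-s) ds
evaluated with the same fixed-node Gauss-Legendre rule as the likelihood.
For the process-time clock the sojourn CDF given onset at s is
1 - exp(-(Lambda23(u) - Lambda23(s))) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .likelihood import DEFAULT_OPTIONS, LikelihoodOptions, _leggauss
from .transitions import ThreeStateSpec, TransitionSpec

__all__ = [
    "CIFCurve",
    "conditional_cif",
    "marginal_cif",
    "marginal_cif_quantile",
    "cif_curve",
    "hazard_ratio",
    "sojourn_summary",
]

TRANSITIONS = ("1->2", "2->3", "1->3")


@dataclass
class CIFCurve:
    """Time grid with CIF point estimates and optional pointwise bands."""

    transition: str
    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    level: float = 0.95

    def __post_init__(self):
        est = np.asarray(self.estimate)
        if np.any(est < -1e-12) or np.any(est > 1 + 1e-12):
            raise ValueError("CIF values must lie in [0, 1]")
        if np.any(np.diff(est) < -1e-9):
            raise ValueError("CIF must be nondecreasing in time")

    def to_frame(self):
        import pandas as pd

        d = {"time": self.times, "estimate": self.estimate}
        if self.lower is not None:
            d["lower"], d["upper"] = self.lower, self.upper
        return pd.DataFrame(d)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.plot(self.times, self.estimate, **kwargs)
        if self.lower is not None:
            ax.fill_between(self.times, self.lower, self.upper, alpha=0.25)
        ax.set_xlabel("time")
        ax.set_ylabel(f"CIF {self.transition}")
        return ax


def _bank2d(bank) -> np.ndarray:
    bank = np.asarray(bank, dtype=float)
    if bank.ndim == 1:
        bank = bank.reshape(1, -1) if bank.size else bank.reshape(1, 0)
    if bank.shape[0] == 0:
        raise ValueError("covariate bank must be nonempty")
    if bank.shape[1] == 0:
        # no covariates: every profile is identical
        return bank[:1]
    return bank


def _sojourn_cdf_from_entry(spec: ThreeStateSpec, u, bank, opts):
    """Marginal CDF of the sojourn time t measured from state entry.

    For the state-entry clock this is the AFT CDF averaged over the bank.
    For the process-time clock it is averaged over the onset-time density as
    well (the sojourn law then depends on the age at onset).
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if spec.clock23 == "state_entry":
        vals = np.array([spec.spec23.cdf(np.maximum(u, 0.0), z if z.size else None)
                         for z in bank])
        return vals.mean(axis=0)
    # average over onset times s ~ f_x, conditional CDF 1 - e^{-(L(s+u)-L(s))}
    nodes, weights = _leggauss(opts.quadrature_nodes)
    out = np.zeros_like(u)
    for z in bank:
        zz = z if z.size else None
        hi = spec.spec12.quantile(0.999, zz)
        s = 0.5 * hi * (nodes + 1.0)
        w = 0.5 * hi * weights
        fx = spec.spec12.density(s, zz)
        lam_s = spec.spec23._baseline_cumhaz(s)
        zeta = spec.spec23._ph_eta(zz) if spec.spec23.coefficients else 0.0
        lam_su = spec.spec23._baseline_cumhaz(s[None, :] + u[:, None])
        cond = 1.0 - np.exp(-(lam_su - lam_s[None, :]) * np.exp(zeta))
        mass = float(np.sum(w * fx))
        out += (cond * (w * fx)[None, :]).sum(axis=1) / mass
    return out / len(bank)


def conditional_cif(spec: ThreeStateSpec, transition: str, z, times,
                    opts: LikelihoodOptions = DEFAULT_OPTIONS) -> np.ndarray:
    """CIF at one covariate profile, evaluated on a time grid."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    z = np.asarray(z, dtype=float) if z is not None else np.empty(0)
    zz = z if z.size else None
    if transition == "1->2":
        return spec.spec12.cdf(times, zz)
    if transition == "2->3":
        return _sojourn_cdf_from_entry(spec, times, _bank2d(z), opts)
    if transition != "1->3":
        raise ValueError(f"unknown transition {transition!r}")
    # P(x + t <= u | z) by quadrature convolution over the onset time s
    nodes, weights = _leggauss(opts.quadrature_nodes)
    out = np.zeros_like(times)
    pos = times > 0
    if not np.any(pos):
        return out
    u = times[pos]
    s = 0.5 * u[:, None] * (nodes[None, :] + 1.0)      # (m, q)
    w = 0.5 * u[:, None] * weights[None, :]
    fx = spec.spec12.density(s, zz)
    if spec.clock23 == "state_entry":
        ft = spec.spec23.cdf(np.maximum(u[:, None] - s, 0.0), zz)
    else:
        zeta = spec.spec23._ph_eta(zz) if spec.spec23.coefficients else 0.0
        lam_u = spec.spec23._baseline_cumhaz(u)
        lam_s = spec.spec23._baseline_cumhaz(s)
        ft = 1.0 - np.exp(-(lam_u[:, None] - lam_s) * np.exp(zeta))
    out[pos] = np.einsum("ij,ij->i", w, fx * ft)
    return np.clip(out, 0.0, 1.0)


def marginal_cif(spec: ThreeStateSpec, transition: str, times, bank,
                 opts: LikelihoodOptions = DEFAULT_OPTIONS) -> np.ndarray:
    """CIF averaged pointwise over the covariate bank."""
    bank = _bank2d(bank)
    if transition == "2->3":
        return _sojourn_cdf_from_entry(spec, times, bank, opts)
    vals = np.array([conditional_cif(spec, transition,
                                     z if z.size else None, times, opts)
                     for z in bank])
    return vals.mean(axis=0)


def marginal_cif_quantile(spec: ThreeStateSpec, transition: str, p: float,
                          bank, opts: LikelihoodOptions = DEFAULT_OPTIONS,
                          tol: float = 1e-10) -> float:
    """Time at which the marginal CIF reaches probability p (root-find with
    geometric bracket expansion)."""
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    bank = _bank2d(bank)
    # single covariate profile + AFT law: the quantile is closed form
    if (bank.shape[0] == 1 and transition in ("1->2", "2->3")
            and spec.clock23 == "state_entry"):
        tspec = spec.spec12 if transition == "1->2" else spec.spec23
        z = bank[0] if bank.shape[1] else None
        return float(tspec.quantile(p, z))

    def g(u):
        return float(marginal_cif(spec, transition, [u], bank, opts)[0]) - p

    hi = 1.0
    for _ in range(200):
        if g(hi) > 0:
            break
        hi *= 2.0
    else:
        asym = float(marginal_cif(spec, transition, [hi], bank, opts)[0])
        raise ValueError(f"CIF plateaus at {asym:.6f} < p = {p}; quantile unreachable")
    root = optimize.brentq(g, 0.0, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    return float(root)


def cif_curve(spec: ThreeStateSpec, transition: str, times, bank,
              draw_specs=None, level: float = 0.95,
              opts: LikelihoodOptions = DEFAULT_OPTIONS) -> CIFCurve:
    """Point-estimate CIF curve, with equal-tailed percentile bands across
    draws (posterior samples or bootstrap replicates) when provided."""
    est = marginal_cif(spec, transition, times, bank, opts)
    lower = upper = None
    if draw_specs is not None:
        if len(draw_specs) < 50:
            raise ValueError("need at least 50 draws for interval bands")
        mat = np.array([marginal_cif(s, transition, times, bank, opts)
                        for s in draw_specs])
        alpha = (1.0 - level) / 2.0
        lower, upper = np.quantile(mat, [alpha, 1.0 - alpha], axis=0)
    return CIFCurve(transition=transition, times=np.asarray(times, float),
                    estimate=est, lower=lower, upper=upper, level=level)


def hazard_ratio(spec: ThreeStateSpec, transition: str, covariate_index: int) -> float:
    """Per-unit hazard ratio for one covariate.

    AFT families: HR = exp(-beta/sigma) (the AFT-to-proportional-hazards
    transform for Weibull/exponential).  Piecewise family: covariates already
    act proportionally, so HR = exp(beta).
    """
    tspec = spec.spec12 if transition == "1->2" else spec.spec23
    beta = tspec.coefficients[covariate_index]
    if tspec.family == "piecewise_constant":
        return float(np.exp(beta))
    return float(np.exp(-beta / tspec.scale))


def sojourn_summary(tspec: TransitionSpec, z=None, tau: float | None = None) -> dict:
    """Mean, median and restricted mean (up to tau) of one transition's
    sojourn law at a covariate profile (defaults to the baseline profile)."""
    zz = None
    if z is not None and np.asarray(z).size:
        zz = np.asarray(z, dtype=float)
    if tspec.family == "piecewise_constant":
        median = float(np.atleast_1d(tspec.quantile(0.5, zz))[0])
        hi = float(np.atleast_1d(tspec.quantile(1 - 1e-9, zz))[0])
        mean = _restricted_mean(tspec, zz, hi)
    else:
        eta = tspec.linear_predictor(zz)
        mean = float(np.exp(eta) * special.gamma(1.0 + tspec.scale))
        median = float(tspec.quantile(0.5, zz))
    out = {"mean": mean, "median": median}
    if tau is not None:
        out["restricted_mean"] = _restricted_mean(tspec, zz, tau)
    return out


def _restricted_mean(tspec: TransitionSpec, z, tau: float) -> float:
    nodes, weights = _leggauss(256)
    u = 0.5 * tau * (nodes + 1.0)
    w = 0.5 * tau * weights
    return float(np.sum(w * tspec.survival(u, z)))
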