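"""Parametric progression-time laws for the three-state model.

Each transition (healthy -> precursor, precursor -> cancer) is governed by a
:class:`TransitionSpec`: an accelerated failure time (AFT) law with
extreme-value (Gumbel-minimum) errors, so that

    log T = beta0 + z' beta + sigma * W,     W ~ Gumbel-min,

gives T a Weibull distribution with scale ``exp(eta)`` and shape ``1/sigma``
(``eta`` the linear predictor); ``sigma = 1`` is the exponential special case.
A third family uses piecewise-constant hazards with covariates acting
proportionally on the hazard, for models whose clock is process time (age)
rather than time since state entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FAMILIES",
    "TransitionSpec",
    "ThreeStateSpec",
    "linear_predictor",
]

FAMILIES = ("exponential", "weibull", "piecewise_constant")


def _as_tuple(x) -> tuple[float, ...]:
    if x is None:
        return ()
    return tuple(float(v) for v in np.atleast_1d(np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class TransitionSpec:
    """Parametric law for one transition's progression time.

    Parameters
    ----------
    family : {"exponential", "weibull", "piecewise_constant"}
    intercept : float
        beta0 on the log-time scale (AFT families) or unused for the
        piecewise family (set it to 0 there).
    coefficients : sequence of float
        Covariate coefficients: log-time scale for AFT families, log-hazard
        (proportional hazards) scale for the piecewise family.
    scale : float
        sigma > 0; fixed at 1 for the exponential family.
    cuts : sequence of float
        Increasing positive cut points of the piecewise hazard grid
        (piecewise family only).
    log_rates : sequence of float
        Log baseline hazard per piece; ``len(log_rates) == len(cuts) + 1``.
    """

    family: str
    intercept: float = 0.0
    coefficients: tuple[float, ...] = ()
    scale: float = 1.0
    cuts: tuple[float, ...] = ()
    log_rates: tuple[float, ...] = ()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        object.__setattr__(self, "coefficients", _as_tuple(self.coefficients))
        object.__setattr__(self, "cuts", _as_tuple(self.cuts))
        object.__setattr__(self, "log_rates", _as_tuple(self.log_rates))
        object.__setattr__(self, "intercept", float(self.intercept))
        object.__setattr__(self, "scale", float(self.scale))
        if self.family == "exponential" and self.scale != 1.0:
            raise ValueError("exponential family fixes scale at 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.family == "piecewise_constant":
            cuts = np.asarray(self.cuts)
            if len(self.log_rates) != len(self.cuts) + 1:
                raise ValueError("piecewise family needs len(log_rates) == len(cuts) + 1")
            if cuts.size and (np.any(np.diff(cuts) <= 0) or cuts[0] <= 0):
                raise ValueError("cuts must be strictly increasing and positive")

    # -- linear predictor -------------------------------------------------

    def linear_predictor(self, z=None):
        """eta = intercept + z' coefficients (vectorised over rows of z)."""
        p = len(self.coefficients)
        if z is None:
            if p:
                raise ValueError(f"spec expects {p} covariates, got none")
            return self.intercept
        z = np.asarray(z, dtype=float)
        if z.ndim == 0:
            z = z.reshape(1)
        if not np.all(np.isfinite(z)):
            raise ValueError("covariates must be finite")
        if z.shape[-1] != p:
            if p == 0 and z.size == 0:
                return self.intercept
            raise ValueError(f"covariate length {z.shape[-1]} does not match "
                             f"{p} coefficients")
        return self.intercept + z @ np.asarray(self.coefficients)

    # -- piecewise helpers -------------------------------------------------

    def _ph_eta(self, z):
        """Log proportional-hazards multiplier z' beta of the piecewise family."""
        if not self.coefficients:
            return 0.0
        if z is None:
            raise ValueError(f"spec expects {len(self.coefficients)} covariates, got none")
        return np.asarray(z, dtype=float) @ np.asarray(self.coefficients)

    def _baseline_cumhaz(self, u):
        """Integrated baseline hazard of the piecewise family at times u."""
        u = np.asarray(u, dtype=float)
        edges = np.concatenate([[0.0], np.asarray(self.cuts)])
        rates = np.exp(np.asarray(self.log_rates))
        # time spent in each piece, clipped at u
        upper = np.concatenate([np.asarray(self.cuts), [np.inf]])
        dur = np.clip(u[..., None] - edges, 0.0, upper - edges)
        return dur @ rates

    # -- distribution functions -------------------------------------------

    def survival(self, u, z=None):
        """S(u | z) = P(T > u); u >= 0 required."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0):
            raise ValueError("time must be nonnegative")
        if self.family == "piecewise_constant":
            eta = self._ph_eta(z)
            return np.exp(-self._baseline_cumhaz(u) * np.exp(eta))
        eta = self.linear_predictor(z)
        with np.errstate(divide="ignore"):
            w = np.where(u > 0, (np.log(np.where(u > 0, u, 1.0)) - eta) / self.scale, -np.inf)
        return np.exp(-np.exp(w))

    def hazard(self, u, z=None):
        u = np.asarray(u, dtype=float)
        if self.family == "piecewise_constant":
            eta = self._ph_eta(z)
            edges = np.asarray(self.cuts)
            idx = np.searchsorted(edges, u, side="left")
            return np.exp(np.asarray(self.log_rates)[idx] + eta) * np.ones_like(u, dtype=float)
        eta = self.linear_predictor(z)
        shape = 1.0 / self.scale
        lam = np.exp(eta)
        return shape / lam * (u / lam) ** (shape - 1.0)

    def density(self, u, z=None):
        """f(u | z) = -dS/du."""
        if self.family == "piecewise_constant":
            return self.hazard(u, z) * self.survival(u, z)
        u = np.asarray(u, dtype=float)
        eta = self.linear_predictor(z)
        shape = 1.0 / self.scale
        lam = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = shape / lam * (u / lam) ** (shape - 1.0) * np.exp(-((u / lam) ** shape))
        return np.where(u > 0, out, np.where(shape > 1, 0.0, out))

    def cdf(self, u, z=None):
        return 1.0 - self.survival(u, z)

    def quantile(self, p, z=None):
        """Inverse of the CDF: smallest u with 1 - S(u|z) >= p, 0 < p < 1."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("quantile level must lie strictly in (0, 1)")
        target = -np.log1p(-p)  # cumulative hazard at the quantile
        if self.family == "piecewise_constant":
            eta = self._ph_eta(z)
            c = target / np.exp(eta)
            return self._invert_baseline_cumhaz(c)
        eta = self.linear_predictor(z)
        return np.exp(eta) * target ** self.scale

    def _invert_baseline_cumhaz(self, c):
        c = np.atleast_1d(np.asarray(c, dtype=float))
        edges = np.concatenate([[0.0], np.asarray(self.cuts)])
        rates = np.exp(np.asarray(self.log_rates))
        widths = np.diff(np.concatenate([edges, [np.inf]]))
        cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * widths[:-1])])
        idx = np.searchsorted(cum, c, side="right") - 1
        out = edges[idx] + (c - cum[idx]) / rates[idx]
        return out if out.size > 1 else float(out[0])

    def cumulative_hazard(self, u, z=None):
        s = self.survival(u, z)
        with np.errstate(divide="ignore"):
            return -np.log(s)

    # -- sampling ----------------------------------------------------------

    def sample(self, rng: np.random.Generator, z=None, size=None):
        """Draw progression times; log T = eta + sigma W with W Gumbel-min
        for the AFT families, inverse cumulative hazard otherwise."""
        if self.family == "piecewise_constant":
            e = rng.exponential(size=size)
            eta = self._ph_eta(z)
            return self._invert_baseline_cumhaz(np.atleast_1d(e / np.exp(eta)))
        eta = self.linear_predictor(z)
        e = rng.exponential(size=size)  # -log U, so e**sigma is Weibull(shape 1/sigma)
        return np.exp(eta) * e ** self.scale

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {"family": self.family, "intercept": self.intercept,
             "coefficients": list(self.coefficients), "scale": self.scale}
        if self.family == "piecewise_constant":
            d["cuts"] = list(self.cuts)
            d["log_rates"] = list(self.log_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionSpec":
        return cls(family=d["family"], intercept=d.get("intercept", 0.0),
                   coefficients=tuple(d.get("coefficients", ())),
                   scale=d.get("scale", 1.0), cuts=tuple(d.get("cuts", ())),
                   log_rates=tuple(d.get("log_rates", ())))


def linear_predictor(spec: TransitionSpec, z=None) -> float:
    """Module-level convenience wrapper for :meth:`TransitionSpec.linear_predictor`."""
    return spec.linear_predictor(z)


@dataclass(frozen=True)
class ThreeStateSpec:
    """Full data-generating/fitted specification of the progressive model.

    ``spec12`` governs x (healthy -> precursor, clock starts at the process
    origin); ``spec23`` governs t (precursor -> cancer). ``clock23`` says which
    clock drives the second transition: ``"state_entry"`` (semi-Markov, or
    time-homogeneous Markov when both families are exponential) or
    ``"process_time"`` (hazard a function of time since the origin, e.g. age;
    only meaningful with a piecewise-constant spec23).
    """

    spec12: TransitionSpec
    spec23: TransitionSpec
    clock23: str = "state_entry"

    def __post_init__(self):
        if self.clock23 not in ("state_entry", "process_time"):
            raise ValueError("clock23 must be 'state_entry' or 'process_time'")
        if self.clock23 == "process_time" and self.spec23.family != "piecewise_constant":
            raise ValueError("process_time clock requires a piecewise_constant spec23")
        if self.clock23 == "state_entry" and self.spec23.family == "piecewise_constant":
            raise ValueError("piecewise_constant spec23 requires the process_time clock")

    def to_dict(self) -> dict:
        return {"spec12": self.spec12.to_dict(), "spec23": self.spec23.to_dict(),
                "clock23": self.clock23}

    @classmethod
    def from_dict(cls, d: dict) -> "ThreeStateSpec":
        return cls(TransitionSpec.from_dict(d["spec12"]),
                   TransitionSpec.from_dict(d["spec23"]), d.get("clock23", "state_entry"))


# The two generating models of the simulation study: Weibull (hazards depend
# on time since state entry) and exponential (time-homogeneous Markov).
def weibull_dgp(p: int = 0, beta=(0.5, 0.5)) -> ThreeStateSpec:
    """Semi-Markov Weibull generator: log x = 3 + z'b + 0.2 eps,
    log t = 1.2 + z'b + 0.3 xi."""
    b = () if p == 0 else tuple(beta)
    return ThreeStateSpec(
        TransitionSpec("weibull", intercept=3.0, coefficients=b, scale=0.2),
        TransitionSpec("weibull", intercept=1.2, coefficients=b, scale=0.3),
    )


def exponential_dgp(p: int = 0, beta=(0.5, 0.5)) -> ThreeStateSpec:
    """Time-homogeneous Markov generator: log x = 3 + z'b + eps,
    log t = 1.2 + z'b + xi."""
    b = () if p == 0 else tuple(beta)
    return ThreeStateSpec(
        TransitionSpec("exponential", intercept=3.0, coefficients=b),
        TransitionSpec("exponential", intercept=1.2, coefficients=b),
    )
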