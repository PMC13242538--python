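"""Fitting the progressive three-state model: maximum likelihood,
Metropolis-within-Gibbs MCMC, and nonparametric bootstrap.

The entry point is :class:`ThreeStateModel`, built from a cohort of subject
histories plus a choice of transition families.  ``fit()`` maximises the
interval-censored likelihood with multiple jittered starts and returns
:class:`MLResults`; ``fit_bayes()`` runs a block Metropolis sampler (one
block per transition, multivariate normal proposals adapted during burn-in)
under weakly informative priors and returns :class:`BayesResults`.  Both
results objects expose the study estimands (CIFs, CIF quantiles, hazard
ratios, sojourn summaries) and a ``summary()`` table.

All parameters are estimated unconstrained: scales enter as log(sigma), so
positivity never needs boundary handling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from . import cif as _cif
from .likelihood import (DEFAULT_OPTIONS, CompiledCohort, LikelihoodOptions,
                         cohort_loglik)
from .simulate import SimulatedCohort, SubjectHistory
from .transitions import ThreeStateSpec, TransitionSpec

__all__ = ["ParamMap", "PriorSpec", "ThreeStateModel", "MLResults", "BayesResults"]


class ParamMap:
    """Bijection between a flat unconstrained vector and a ThreeStateSpec.

    Layout per transition: intercept, coefficients..., log(sigma) for the
    Weibull family (sigma fixed at 1 for exponential); log baseline rates
    plus coefficients for the piecewise family.
    """

    def __init__(self, template: ThreeStateSpec, n_covariates: int,
                 covariate_names=None):
        self.template = template
        self.p = n_covariates
        covariate_names = covariate_names or [f"z{j+1}" for j in range(n_covariates)]
        self.names: list[str] = []
        self.kinds: list[str] = []
        self._blocks: list[np.ndarray] = []
        start = 0
        for label, spec in (("12", template.spec12), ("23", template.spec23)):
            if spec.family == "piecewise_constant":
                for k in range(len(spec.log_rates)):
                    self.names.append(f"lograte{label}_{k}")
                    self.kinds.append("lograte")
                for nm in covariate_names:
                    self.names.append(f"beta{label}_{nm}")
                    self.kinds.append("coefficient")
            else:
                self.names.append(f"beta{label}_0")
                self.kinds.append("intercept")
                for nm in covariate_names:
                    self.names.append(f"beta{label}_{nm}")
                    self.kinds.append("coefficient")
                if spec.family == "weibull":
                    self.names.append(f"log_sigma{label}")
                    self.kinds.append("log_scale")
            self._blocks.append(np.arange(start, len(self.names)))
            start = len(self.names)

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def blocks(self) -> list[np.ndarray]:
        """Index blocks for the two transitions (MCMC update blocks)."""
        return self._blocks

    def unpack(self, theta: np.ndarray) -> ThreeStateSpec:
        theta = np.asarray(theta, dtype=float)
        specs = []
        i = 0
        for spec in (self.template.spec12, self.template.spec23):
            if spec.family == "piecewise_constant":
                nr = len(spec.log_rates)
                log_rates = theta[i:i + nr]; i += nr
                coefs = theta[i:i + self.p]; i += self.p
                specs.append(TransitionSpec("piecewise_constant", intercept=0.0,
                                            coefficients=tuple(coefs), cuts=spec.cuts,
                                            log_rates=tuple(log_rates)))
            else:
                b0 = theta[i]; i += 1
                coefs = theta[i:i + self.p]; i += self.p
                if spec.family == "weibull":
                    sigma = float(np.exp(theta[i])); i += 1
                else:
                    sigma = 1.0
                specs.append(TransitionSpec(spec.family, intercept=float(b0),
                                            coefficients=tuple(coefs), scale=sigma))
        return ThreeStateSpec(specs[0], specs[1], self.template.clock23)

    def pack(self, spec: ThreeStateSpec) -> np.ndarray:
        out = []
        for s in (spec.spec12, spec.spec23):
            if s.family == "piecewise_constant":
                out.extend(s.log_rates)
                out.extend(s.coefficients)
            else:
                out.append(s.intercept)
                out.extend(s.coefficients)
                if s.family == "weibull":
                    out.append(np.log(s.scale))
        return np.array(out, dtype=float)


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors per parameter class.

    Defaults are weakly informative (regularising rather than encoding
    beliefs): N(0, 10) on intercepts, coefficients and log baseline rates,
    N(0, 1) on log scales.
    """

    loc_intercept: float = 0.0
    sd_intercept: float = 10.0
    loc_coefficient: float = 0.0
    sd_coefficient: float = 10.0
    loc_log_scale: float = 0.0
    sd_log_scale: float = 1.0
    loc_lograte: float = 0.0
    sd_lograte: float = 10.0

    def __post_init__(self):
        if min(self.sd_intercept, self.sd_coefficient,
               self.sd_log_scale, self.sd_lograte) <= 0:
            raise ValueError("prior spreads must be positive")

    def loc_sd(self, kind: str) -> tuple[float, float]:
        return {"intercept": (self.loc_intercept, self.sd_intercept),
                "coefficient": (self.loc_coefficient, self.sd_coefficient),
                "log_scale": (self.loc_log_scale, self.sd_log_scale),
                "lograte": (self.loc_lograte, self.sd_lograte)}[kind]


class ThreeStateModel:
    """Progressive three-state model bound to a cohort of screening histories.

    Parameters
    ----------
    histories : sequence of SubjectHistory
    family12, family23 : transition families ("exponential", "weibull", or
        "piecewise_constant" for the second transition with the process-time
        clock).
    clock23 : {"state_entry", "process_time"}
    cuts23 : cut points for a piecewise second transition; defaults to unit
        spacing up to the largest interval endpoint.
    """

    def __init__(self, histories, family12: str = "weibull",
                 family23: str = "weibull", clock23: str = "state_entry",
                 cuts23=None, covariate_names=None,
                 options: LikelihoodOptions = DEFAULT_OPTIONS):
        self.histories = list(histories)
        if not self.histories:
            raise ValueError("empty cohort")
        self.compiled = CompiledCohort.from_histories(self.histories)
        self.p = int(np.asarray(self.histories[0].covariates).size)
        self.covariate_names = (list(covariate_names) if covariate_names
                                else [f"z{j+1}" for j in range(self.p)])
        self.options = options
        if family23 == "piecewise_constant":
            if cuts23 is None:
                horizon = max(h.interval_right for h in self.histories)
                cuts23 = tuple(np.arange(1.0, np.ceil(horizon)))
            spec23 = TransitionSpec("piecewise_constant", intercept=0.0,
                                    coefficients=(0.0,) * self.p, cuts=cuts23,
                                    log_rates=(0.0,) * (len(cuts23) + 1))
        else:
            spec23 = TransitionSpec(family23, coefficients=(0.0,) * self.p,
                                    scale=1.0 if family23 == "exponential" else np.e ** 0)
        spec12 = TransitionSpec(family12, coefficients=(0.0,) * self.p,
                                scale=1.0)
        self.template = ThreeStateSpec(spec12, spec23, clock23)
        self.map = ParamMap(self.template, self.p, self.covariate_names)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_cohort(cls, cohort: SimulatedCohort, **kwargs) -> "ThreeStateModel":
        return cls(cohort.histories, **kwargs)

    @classmethod
    def from_dataframe(cls, visits: pd.DataFrame, subjects: pd.DataFrame | None = None,
                       covariate_columns=(), **kwargs) -> "ThreeStateModel":
        """Build from a long-format visit table (subject_id, visit_time,
        observed_state) and an optional subject table with covariates."""
        from .io import histories_from_frames
        histories = histories_from_frames(visits, subjects, covariate_columns)
        return cls(histories, covariate_names=list(covariate_columns) or None, **kwargs)

    # -- likelihood --------------------------------------------------------

    def loglik(self, theta: np.ndarray) -> float:
        spec = self.map.unpack(theta)
        return cohort_loglik(spec, self.compiled, self.options)

    def loglik_at_spec(self, spec: ThreeStateSpec) -> float:
        return cohort_loglik(spec, self.compiled, self.options)

    # -- starting values ---------------------------------------------------

    def _moment_start(self) -> np.ndarray:
        """Method-of-moments style initials using interval midpoints as
        pseudo event times."""
        cc = self.compiled
        onset = np.concatenate([0.5 * (cc.l2 + cc.r2), 0.5 * (cc.l3 + cc.r3)])
        n_event = onset.size
        exposure = float(np.sum(cc.t1) + np.sum(onset))
        b0x = np.log(max(exposure / max(n_event, 1), 1e-3))
        soj = np.concatenate([cc.r2 - 0.5 * (cc.l2 + cc.r2),
                              0.25 * (cc.r3 - cc.l3)])
        n3 = cc.l3.size
        b0t = np.log(max(float(np.sum(soj)) / max(n3, 1), 1e-3))
        theta = []
        for label, spec, b0 in (("12", self.template.spec12, b0x),
                                ("23", self.template.spec23, b0t)):
            if spec.family == "piecewise_constant":
                theta.extend([-b0] * len(spec.log_rates))
                theta.extend([0.0] * self.p)
            else:
                theta.append(b0)
                theta.extend([0.0] * self.p)
                if spec.family == "weibull":
                    theta.append(0.0)
        return np.array(theta, dtype=float)

    # -- maximum likelihood ------------------------------------------------

    def fit(self, starts: int = 3, seed: int = 0, maxiter: int = 1000) -> "MLResults":
        """Multi-start maximum likelihood.

        The fit is declared converged when the two best starts agree within
        1e-4 in log-likelihood and the gradient norm at the optimum is below
        1e-3.  A cohort with no detected events carries no information on the
        second transition and is flagged unconverged instead of raising.
        """
        rng = np.random.default_rng(seed)
        base = self._moment_start()

        def neg(th):
            ll = self.loglik(th)
            # large finite penalty keeps finite-difference steps well defined
            return -ll if np.isfinite(ll) else 1e12
        solutions = []
        failures = []
        for s in range(max(starts, 1)):
            x0 = base if s == 0 else base + rng.uniform(-0.5, 0.5, size=base.size)
            try:
                res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                        options={"maxiter": maxiter,
                                                 "ftol": 1e-13, "gtol": 1e-10})
                if np.isfinite(res.fun) and res.fun < 1e11:
                    solutions.append(res)
                else:
                    failures.append("non-finite objective")
            except Exception as e:  # noqa: BLE001 -- a failing start is data, not a crash
                failures.append(str(e))
        diagnostics: dict = {"n_starts": starts, "n_failed_starts": len(failures),
                             "failures": failures}
        if not solutions:
            return MLResults(self, np.full(self.map.k, np.nan), -np.inf,
                             converged=False, diagnostics=diagnostics)
        best = min(solutions, key=lambda r: r.fun)
        # polish: quasi-Newton refinement tightens the gradient norm beyond
        # what L-BFGS-B's stopping rule delivers
        try:
            polished = optimize.minimize(neg, best.x, method="BFGS",
                                         options={"gtol": 1e-5, "maxiter": 200})
            if np.isfinite(polished.fun) and polished.fun <= best.fun:
                best = polished
        except Exception:  # noqa: BLE001
            pass
        gnorm = float(np.linalg.norm(_central_gradient(neg, best.x)))
        lls = sorted(-r.fun for r in solutions)[::-1]
        agree = len(lls) >= 2 and (lls[0] - lls[1]) < 1e-4
        identified = self.compiled.l2.size + self.compiled.l3.size > 0
        converged = agree and gnorm < 1e-3 and identified
        diagnostics.update({"gradient_norm": gnorm,
                            "loglik_spread": (lls[0] - lls[-1]) if len(lls) > 1 else 0.0,
                            "start_agreement": agree,
                            "identified": identified})
        if not identified:
            diagnostics["failures"] = failures + [
                "no interval-censored subjects: transition 2->3 not identified"]
        return MLResults(self, best.x, float(-best.fun),
                         converged=bool(converged), diagnostics=diagnostics)

    # -- Bayesian fit ------------------------------------------------------

    def fit_bayes(self, priors: PriorSpec | None = None, chains: int = 4,
                  iters: int = 5000, burnin: int | None = None, seed: int = 0,
                  prior_only: bool = False, target_accept: float = 0.3,
                  init: np.ndarray | None = None) -> "BayesResults":
        """Metropolis-within-Gibbs sampling: one multivariate-normal proposal
        block per transition, proposal scale adapted toward 20-40% acceptance
        during burn-in and frozen afterwards; convergence via split-R-hat
        over >= 2 chains from dispersed starts."""
        priors = priors or PriorSpec()
        if chains < 2:
            raise ValueError("need at least 2 chains for split-R-hat")
        burnin = iters // 2 if burnin is None else burnin
        locs = np.array([priors.loc_sd(k)[0] for k in self.map.kinds])
        sds = np.array([priors.loc_sd(k)[1] for k in self.map.kinds])

        def logprior(th):
            return float(-0.5 * np.sum(((th - locs) / sds) ** 2))

        def logpost(th):
            lp = logprior(th)
            if prior_only:
                return lp
            ll = self.loglik(th)
            return lp + ll if np.isfinite(ll) else -np.inf

        base = self._moment_start() if init is None else np.asarray(init, float)
        k = self.map.k
        blocks = self.map.blocks
        keep = iters - burnin
        all_chains = np.empty((chains, keep, k))
        accept_rates = []
        master = np.random.SeedSequence(seed)
        for c, ss in enumerate(master.spawn(chains)):
            rng = np.random.default_rng(ss)
            th = base + rng.uniform(-0.5, 0.5, size=k)
            lp = logpost(th)
            scales = [0.3 for _ in blocks]
            chol = [np.eye(idx.size) for idx in blocks]
            acc = [0 for _ in blocks]
            tries = [0 for _ in blocks]
            acc_window = [0 for _ in blocks]
            history = np.empty((burnin, k))
            for it in range(iters):
                for b, idx in enumerate(blocks):
                    prop = th.copy()
                    prop[idx] = th[idx] + scales[b] * (chol[b] @ rng.standard_normal(idx.size))
                    lp_prop = logpost(prop)
                    tries[b] += 1
                    if np.log(rng.uniform()) < lp_prop - lp:
                        th, lp = prop, lp_prop
                        acc[b] += 1
                        acc_window[b] += 1
                    if it < burnin and tries[b] % 50 == 0:
                        rate = acc_window[b] / 50
                        scales[b] *= float(np.exp(rate - target_accept))
                        acc_window[b] = 0
                if it < burnin:
                    history[it] = th
                    # shape the proposal from the burn-in sample so blocks
                    # with correlated parameters mix; frozen after burn-in
                    if it >= 200 and it % 200 == 0:
                        for b, idx in enumerate(blocks):
                            cov = np.cov(history[it // 2:it, idx].T)
                            cov = np.atleast_2d(cov) + 1e-10 * np.eye(idx.size)
                            try:
                                chol[b] = np.linalg.cholesky(cov)
                            except np.linalg.LinAlgError:
                                pass
                else:
                    all_chains[c, it - burnin] = th
            accept_rates.append([a / t for a, t in zip(acc, tries)])

        rhat, ess = _split_rhat_ess(all_chains)
        draws = all_chains.reshape(-1, k)
        point = np.median(draws, axis=0)
        converged = bool(np.all(rhat < 1.1))
        diagnostics = {"rhat": dict(zip(self.map.names, rhat.tolist())),
                       "ess": dict(zip(self.map.names, ess.tolist())),
                       "acceptance_rates": accept_rates,
                       "chains": chains, "iters": iters, "burnin": burnin}
        ll = self.loglik(point) if not prior_only else np.nan
        return BayesResults(self, point, float(ll), converged=converged,
                            diagnostics=diagnostics, draws=draws,
                            chain_draws=all_chains)


def _split_rhat_ess(chains: np.ndarray):
    """Split-R-hat and bulk ESS via arviz."""
    import arviz as az

    names = [f"p{j}" for j in range(chains.shape[2])]
    data = az.from_dict({nm: chains[:, :, j] for j, nm in enumerate(names)})
    rh = az.rhat(data)
    es = az.ess(data)
    rhat = np.array([float(rh[nm].values) for nm in names])
    ess = np.array([float(es[nm].values) for nm in names])
    return rhat, ess


class _ResultsBase:
    """Estimates plus uncertainty draws for a fitted three-state model."""

    def __init__(self, model: ThreeStateModel, params: np.ndarray,
                 loglik: float, converged: bool, diagnostics: dict,
                 draws: np.ndarray | None = None):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.loglik = loglik
        self.converged = converged
        self.diagnostics = diagnostics
        self.draws = draws

    @property
    def param_names(self) -> list[str]:
        return self.model.map.names

    @property
    def spec(self) -> ThreeStateSpec:
        """The fitted specification at the point estimate."""
        return self.model.map.unpack(self.params)

    def draw_specs(self):
        if self.draws is None:
            return None
        return [self.model.map.unpack(d) for d in self.draws]

    def _require_converged(self, force: bool):
        if not self.converged and not force:
            raise RuntimeError("fit did not converge; pass force=True to override")

    # -- estimands --------------------------------------------------------

    def cif(self, transition: str = "1->2", times=None, kind: str = "marginal",
            z=None, level: float = 0.95, band: bool = None, force: bool = False):
        """CIF curve for one transition; marginal curves average conditional
        CIFs over the cohort's covariate bank."""
        self._require_converged(force)
        if times is None:
            horizon = max(h.interval_right for h in self.model.histories)
            times = np.linspace(0.0, horizon, 101)
        bank = self._bank(kind, z)
        if band is None:
            band = self.draws is not None and len(self.draws) >= 50
        draw_specs = self.draw_specs() if band else None
        return _cif.cif_curve(self.spec, transition, np.asarray(times, float),
                              bank, draw_specs=draw_specs, level=level,
                              opts=self.model.options)

    def _bank(self, kind, z):
        if kind == "marginal":
            return np.array([h.covariates for h in self.model.histories])
        if kind != "conditional":
            raise ValueError("kind must be 'marginal' or 'conditional'")
        z = np.empty(0) if z is None else np.asarray(z, dtype=float)
        return np.atleast_2d(z)

    def cif_quantile(self, transition: str, p: float, kind: str = "marginal",
                     z=None, force: bool = False) -> float:
        self._require_converged(force)
        bank = self._bank(kind, z)
        return _cif.marginal_cif_quantile(self.spec, transition, p, bank,
                                          opts=self.model.options)

    def cif_quantile_interval(self, transition: str, p: float,
                              level: float = 0.95, kind: str = "marginal",
                              z=None, force: bool = False,
                              max_draws: int = 500):
        """Point estimate and draw-based interval for the time at which the
        marginal CIF reaches probability p.  Draws are thinned to at most
        ``max_draws`` for the per-draw quantile recomputation."""
        self._require_converged(force)
        bank = self._bank(kind, z)
        point = _cif.marginal_cif_quantile(self.spec, transition, p, bank,
                                           opts=self.model.options)
        specs = self.draw_specs()
        if specs is None or len(specs) < 50:
            raise ValueError("need at least 50 draws for interval estimates; "
                             "run fit_bayes or bootstrap first")
        if len(specs) > max_draws:
            step = max(1, len(specs) // max_draws)
            specs = specs[::step]
        vals = np.array([_cif.marginal_cif_quantile(s, transition, p, bank,
                                                    opts=self.model.options)
                         for s in specs])
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
        return point, (float(lo), float(hi))

    def cumulative_hazard(self, transition: str, times, kind: str = "marginal",
                          z=None, force: bool = False):
        self._require_converged(force)
        bank = self._bank(kind, z)
        vals = _cif.marginal_cif(self.spec, transition, np.asarray(times, float),
                                 bank, opts=self.model.options)
        return -np.log1p(-vals)

    def hazard_ratio(self, covariate, transition: str = "1->2",
                     level: float = 0.95):
        """Per-unit hazard ratio for one covariate (AFT transform
        HR = exp(-beta/sigma); exp(beta) for the piecewise family)."""
        idx = (self.model.covariate_names.index(covariate)
               if isinstance(covariate, str) else int(covariate))
        point = _cif.hazard_ratio(self.spec, transition, idx)
        interval = None
        specs = self.draw_specs()
        if specs is not None and len(specs) >= 50:
            vals = np.array([_cif.hazard_ratio(s, transition, idx) for s in specs])
            alpha = (1.0 - level) / 2.0
            interval = tuple(float(v) for v in np.quantile(vals, [alpha, 1 - alpha]))
        return point, interval

    def sojourn_summary(self, transition: str = "2->3", z=None,
                        tau: float | None = None):
        spec = self.spec.spec12 if transition == "1->2" else self.spec.spec23
        return _cif.sojourn_summary(spec, z=z, tau=tau)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [f"{type(self).__name__}: progressive three-state model",
                 f"families: {self.spec.spec12.family} (1->2), "
                 f"{self.spec.spec23.family} (2->3, clock={self.spec.clock23})",
                 f"n = {len(self.model.histories)}, log-likelihood = {self.loglik:.4f}",
                 f"converged: {self.converged}", "",
                 f"{'parameter':<18}{'estimate':>12}{'2.5%':>12}{'97.5%':>12}"]
        qs = (np.quantile(self.draws, [0.025, 0.975], axis=0)
              if self.draws is not None and len(self.draws) >= 50 else None)
        for j, nm in enumerate(self.param_names):
            lo = f"{qs[0][j]:12.4f}" if qs is not None else " " * 12
            hi = f"{qs[1][j]:12.4f}" if qs is not None else " " * 12
            lines.append(f"{nm:<18}{self.params[j]:12.4f}{lo}{hi}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"parameter": self.param_names, "estimate": self.params}
                     ).to_csv(directory / "point.csv", index=False)
        if self.draws is not None:
            pd.DataFrame(self.draws, columns=self.param_names
                         ).to_csv(directory / "draws.csv", index=False)
        meta = {"kind": type(self).__name__, "loglik": self.loglik,
                "converged": self.converged,
                "diagnostics": _jsonable(self.diagnostics),
                "template": self.model.template.to_dict()}
        (directory / "fit.json").write_text(json.dumps(meta, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


class MLResults(_ResultsBase):
    """Maximum-likelihood fit; uncertainty draws come from the bootstrap."""

    def bse(self) -> np.ndarray:
        """Asymptotic standard errors from the inverse observed information
        (central-difference Hessian of the log-likelihood)."""
        H = _numerical_hessian(self.model.loglik, self.params)
        try:
            cov = np.linalg.inv(-H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(self.params.size, np.nan)
        return se

    def bootstrap(self, B: int = 200, seed: int = 0) -> "MLResults":
        """Nonparametric bootstrap: resample subjects with replacement and
        refit, starting each replicate at the original optimum.  Returns a
        new results object whose draws are the replicate estimates; failed
        replicates are counted and excluded, and more than 20% failures
        marks the bootstrap layer unconverged."""
        if not self.converged:
            raise RuntimeError("bootstrap requires a converged ML fit")
        if B == 0:
            return self
        rng = np.random.default_rng(seed)
        histories = self.model.histories
        n = len(histories)
        reps = []
        n_failed = 0
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            boot = ThreeStateModel(
                [histories[i] for i in idx],
                family12=self.model.template.spec12.family,
                family23=self.model.template.spec23.family,
                clock23=self.model.template.clock23,
                cuts23=self.model.template.spec23.cuts or None,
                covariate_names=self.model.covariate_names,
                options=self.model.options)
            def neg(th):
                ll = boot.loglik(th)
                return -ll if np.isfinite(ll) else 1e12

            try:
                res = optimize.minimize(neg, self.params,
                                        method="L-BFGS-B",
                                        options={"maxiter": 500, "ftol": 1e-11})
                if res.success and np.isfinite(res.fun) and res.fun < 1e11:
                    reps.append(res.x)
                else:
                    n_failed += 1
            except Exception:  # noqa: BLE001
                n_failed += 1
        diagnostics = dict(self.diagnostics)
        diagnostics.update({"bootstrap_B": B, "bootstrap_failed": n_failed})
        converged = self.converged and (n_failed <= 0.2 * B)
        out = MLResults(self.model, self.params, self.loglik,
                        converged=converged, diagnostics=diagnostics,
                        draws=np.array(reps) if reps else None)
        return out


def _central_gradient(f, x, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = rel_step * np.maximum(1.0, np.abs(x))
    g = np.empty(x.size)
    for i in range(x.size):
        e = np.zeros(x.size)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2 * h[i])
    return g


def _numerical_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                     - f(x - ei + ej) + f(x - ei - ej)) / (4 * h[i] * h[j])
    return H


class BayesResults(_ResultsBase):
    """Posterior sample from the Metropolis-within-Gibbs fit; the point
    estimate is the marginal posterior median."""

    def __init__(self, model, params, loglik, converged, diagnostics,
                 draws, chain_draws=None):
        super().__init__(model, params, loglik, converged, diagnostics, draws)
        self.chain_draws = chain_draws

    def rhat(self) -> dict[str, float]:
        return self.diagnostics["rhat"]
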