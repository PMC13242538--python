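"""Simulation-study harness: factorial design cells, true CIF percentiles,
relative error / rMSE / coverage metrics, and the Turnbull NPMLE fit check.

The study design is a 2x2x2x2 factorial: generating family (exponential or
Weibull), censoring strength (medium ~45%/20% or strong ~30%/10% of subjects
detected in states 2 and 3), number of covariates p (0 or 2), and sample
size n (1000 or 2000).  For each cell, replicate cohorts are generated, each
requested estimator fitted, and the 10th/50th/90th percentiles of the
marginal CIF compared with the truth.  Unconverged fits are excluded from
metric aggregation but counted, since convergence failures are themselves a
finding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cif as _cif
from .model import ThreeStateModel
from .simulate import VisitDesign, generate_cohort, replicate_seed
from .transitions import ThreeStateSpec, exponential_dgp, weibull_dgp

__all__ = [
    "DesignCell",
    "CENSORING_TARGETS",
    "true_percentile",
    "relative_error",
    "rmse",
    "coverage",
    "run_cell",
    "aggregate_metrics",
    "turnbull_npmle",
    "TurnbullCIF",
]

CENSORING_TARGETS = {"medium": (0.45, 0.20), "strong": (0.30, 0.10)}
PERCENTILES = (0.1, 0.5, 0.9)
TRANSITIONS = ("1->2", "2->3")


@dataclass(frozen=True)
class DesignCell:
    """One cell of the factorial simulation design."""

    family: str = "weibull"
    censoring: str = "strong"
    p: int = 0
    n: int = 1000
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("exponential", "weibull"):
            raise ValueError("family must be 'exponential' or 'weibull'")
        if self.censoring not in CENSORING_TARGETS:
            raise ValueError("censoring must be 'medium' or 'strong'")
        if self.p not in (0, 2):
            raise ValueError("the factorial design uses p in {0, 2}")

    def dgp(self) -> ThreeStateSpec:
        make = weibull_dgp if self.family == "weibull" else exponential_dgp
        return make(self.p)

    def label(self) -> str:
        return f"{self.family}-{self.censoring}-p{self.p}-n{self.n}"


def true_percentile(dgp: ThreeStateSpec, transition: str, prob: float,
                    mc_draws: int = 1_000_000, seed: int = 12345) -> float:
    """True time at which the marginal CIF reaches ``prob``.

    Without covariates this is the closed-form AFT quantile; with covariates
    it is the empirical quantile of a large Monte-Carlo sample from the
    marginal law (and the 1->3 transition always uses sampled x + t sums
    when covariates are present).
    """
    p_cov = len(dgp.spec12.coefficients)
    if p_cov == 0:
        if transition == "1->2":
            return float(dgp.spec12.quantile(prob))
        if transition == "2->3":
            return float(dgp.spec23.quantile(prob))
        return _cif.marginal_cif_quantile(dgp, "1->3", prob, np.empty((1, 0)))
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(mc_draws)
    z2 = rng.binomial(1, 0.5, size=mc_draws).astype(float)
    Z = np.column_stack([z1, z2])

    def draw(spec):
        eta = spec.linear_predictor(Z)
        return np.exp(eta) * rng.exponential(size=mc_draws) ** spec.scale

    if transition == "1->2":
        samples = draw(dgp.spec12)
    elif transition == "2->3":
        samples = draw(dgp.spec23)
    else:
        samples = draw(dgp.spec12) + draw(dgp.spec23)
    return float(np.quantile(samples, prob))


def relative_error(estimate: float, truth: float) -> float:
    """(phi_hat - phi) / phi."""
    if truth <= 0:
        raise ValueError("truth must be positive")
    return (estimate - truth) / truth


def rmse(estimates, truth: float) -> float:
    """Root mean squared error of replicate estimates around the truth."""
    estimates = np.asarray(estimates, dtype=float)
    return float(np.sqrt(np.mean((estimates - truth) ** 2)))


def coverage(intervals, truth: float) -> float:
    """Fraction of (lo, hi) intervals containing the truth."""
    intervals = np.asarray(intervals, dtype=float).reshape(-1, 2)
    return float(np.mean((intervals[:, 0] <= truth) & (truth <= intervals[:, 1])))


# -- method registry -------------------------------------------------------

def _fit_exp_ml(cohort, seed):
    m = ThreeStateModel(cohort.histories, family12="exponential",
                        family23="exponential")
    return m.fit(starts=3, seed=seed)


def _fit_weibull_ml(cohort, seed):
    m = ThreeStateModel(cohort.histories, family12="weibull", family23="weibull")
    return m.fit(starts=3, seed=seed)


def _fit_weibull_bayes(cohort, seed, chains=2, iters=3000):
    m = ThreeStateModel(cohort.histories, family12="weibull", family23="weibull")
    return m.fit_bayes(chains=chains, iters=iters, seed=seed)


def _fit_piecewise_ml(cohort, seed, cut_spacing=5.0):
    horizon = max(h.interval_right for h in cohort.histories)
    cuts = tuple(np.arange(cut_spacing, horizon, cut_spacing))
    m = ThreeStateModel(cohort.histories, family12="weibull",
                        family23="piecewise_constant", clock23="process_time",
                        cuts23=cuts)
    return m.fit(starts=3, seed=seed)


METHODS = {
    "exp-ml": _fit_exp_ml,
    "weibull-ml": _fit_weibull_ml,
    "weibull-bayes": _fit_weibull_bayes,
    "piecewise-ml": _fit_piecewise_ml,
}


def run_cell(cell: DesignCell, methods, design: VisitDesign,
             out_dir=None, truths: dict | None = None) -> pd.DataFrame:
    """Run one design cell: simulate replicates, fit each method, record the
    percentile estimates (and intervals when draws exist).

    Returns the per-replicate long table (one row per method x replicate x
    transition x percentile).  When ``out_dir`` is given, rows are appended
    to ``<out_dir>/<cell>.csv`` after every replicate and previously
    completed (method, replicate) pairs are skipped, so an interrupted run
    resumes where it stopped.
    """
    dgp = cell.dgp()
    if truths is None:
        truths = {(tr, q): true_percentile(dgp, tr, q, seed=cell.seed + 991)
                  for tr in TRANSITIONS for q in PERCENTILES}
    out_path = None
    done = set()
    rows = []
    if out_dir is not None:
        out_path = Path(out_dir) / f"{cell.label()}.csv"
        out_path.parent.mkdir(parents=True, exist_ok=True)
        if out_path.exists():
            prev = pd.read_csv(out_path)
            rows = prev.to_dict("records")
            done = set(zip(prev["method"], prev["replicate"]))

    for j in range(cell.replicates):
        seed = replicate_seed(cell.seed, j)
        cohort = None
        for name in methods:
            if (name, j) in done:
                continue
            if cohort is None:
                cohort = generate_cohort(cell.n, cell.p, dgp, design, seed)
            fit = METHODS[name](cohort, seed=seed)
            new = _replicate_rows(cell, name, j, fit, truths)
            rows.extend(new)
            if out_path is not None:
                pd.DataFrame(rows).to_csv(out_path, index=False)
    return pd.DataFrame(rows)


def _replicate_rows(cell, method, replicate, fit, truths):
    rows = []
    has_draws = fit.draws is not None and len(fit.draws) >= 50
    for tr in TRANSITIONS:
        for q in PERCENTILES:
            row = {"cell": cell.label(), "method": method, "replicate": replicate,
                   "transition": tr, "percentile": q,
                   "truth": truths[(tr, q)], "converged": fit.converged,
                   "estimate": np.nan, "lower": np.nan, "upper": np.nan}
            if fit.converged:
                try:
                    if has_draws:
                        est, (lo, hi) = fit.cif_quantile_interval(tr, q)
                        row.update(estimate=est, lower=lo, upper=hi)
                    else:
                        row["estimate"] = fit.cif_quantile(tr, q)
                except ValueError:
                    # CIF plateau below q under a degenerate fit
                    row["converged"] = False
            rows.append(row)
    return rows


def aggregate_metrics(replicate_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the per-replicate table to the study metrics (mean relative
    error, rMSE, coverage, convergence count) per method x transition x
    percentile."""
    out = []
    grp = replicate_table.groupby(["cell", "method", "transition", "percentile"])
    for key, g in grp:
        ok = g[g["converged"] & np.isfinite(g["estimate"])]
        truth = float(g["truth"].iloc[0])
        rec = {"cell": key[0], "method": key[1], "transition": key[2],
               "percentile": key[3], "n_replicates": len(g),
               "n_converged": len(ok), "truth": truth,
               "mean_relative_error": np.nan, "rmse": np.nan, "coverage": np.nan}
        if len(ok):
            rel = (ok["estimate"] - truth) / truth
            rec["mean_relative_error"] = float(rel.mean())
            rec["rmse"] = rmse(ok["estimate"].to_numpy(), truth)
            with_iv = ok[np.isfinite(ok["lower"])]
            if len(with_iv):
                rec["coverage"] = coverage(with_iv[["lower", "upper"]].to_numpy(), truth)
        out.append(rec)
    return pd.DataFrame(out)


# -- Turnbull NPMLE --------------------------------------------------------

@dataclass
class TurnbullCIF:
    """Nonparametric MLE of the first-event CDF: probability mass on the
    Turnbull innermost intervals (p_j, q_j]."""

    left: np.ndarray     # innermost interval open left endpoints
    right: np.ndarray    # innermost interval closed right endpoints
    prob: np.ndarray     # estimated mass per innermost interval
    n_iter: int = 0

    def cif(self, times) -> np.ndarray:
        """Step CDF: all of an interval's mass is placed at its right
        endpoint (the CDF is only identified up to the innermost grid)."""
        times = np.asarray(times, dtype=float)
        cum = np.cumsum(self.prob)
        idx = np.searchsorted(self.right, times, side="right") - 1
        return np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)


def first_event_intervals(histories) -> tuple[np.ndarray, np.ndarray]:
    """Reduce histories to first-event (leaving state 1) censoring intervals:
    delta = 1 becomes (v_m, inf); delta in {2, 3} becomes (l, r]."""
    L, R = [], []
    for h in histories:
        if h.delta == 1:
            L.append(h.interval_right)
            R.append(np.inf)
        else:
            L.append(h.interval_left)
            R.append(h.interval_right)
    return np.array(L), np.array(R)


def turnbull_npmle(histories, tol: float = 1e-8, max_iter: int = 100_000) -> TurnbullCIF:
    """Turnbull's self-consistency (EM) estimator of the first-event CDF.

    Innermost intervals (p, q] are formed from the unique left endpoints
    (open) and right endpoints (closed) with no other endpoint strictly
    between; the EM iteration redistributes each subject's mass over the
    innermost intervals contained in its censoring interval until the
    largest change in mass is below ``tol``.
    """
    L, R = first_event_intervals(histories)
    finite = np.isfinite(R)
    if not finite.any():
        import warnings

        warnings.warn("all subjects right-censored: NPMLE is degenerate at 0")
        return TurnbullCIF(left=np.array([]), right=np.array([]), prob=np.array([]))
    lefts = np.unique(L)
    rights = np.unique(R[finite])
    # innermost intervals (p, q]: p a left endpoint, q the next right
    # endpoint, with no left endpoint strictly between
    pts = []
    for p in lefts:
        j = np.searchsorted(rights, p, side="right")
        if j == rights.size:
            continue
        q = rights[j]
        k = np.searchsorted(lefts, p, side="right")
        if k < lefts.size and lefts[k] < q:
            continue
        pts.append((p, q))
    left = np.array([p for p, _ in pts])
    right = np.array([q for _, q in pts])
    m = left.size
    # a virtual tail interval (max endpoint, inf) absorbs the residual mass
    # of right-censored subjects; it never appears in the reported CDF
    tail_left = max(lefts[-1], rights[-1])
    left_ext = np.append(left, tail_left)
    right_ext = np.append(right, np.inf)
    # each subject's interval (L, R] covers a contiguous index range [a, b]
    # of innermost intervals (both endpoint arrays are sorted), so the EM
    # runs in O(n + m) per sweep via cumulative sums
    a = np.searchsorted(left_ext, L, side="left")
    b = np.searchsorted(right_ext, R, side="right") - 1
    if np.any(a > b):
        raise RuntimeError("inconsistent Turnbull interval construction")
    n = L.size
    s = np.full(m + 1, 1.0 / (m + 1))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        C = np.concatenate([[0.0], np.cumsum(s)])
        denom = C[b + 1] - C[a]
        w = 1.0 / denom
        cover = (np.bincount(a, weights=w, minlength=m + 2)
                 - np.bincount(b + 1, weights=w, minlength=m + 2))
        s_new = s * np.cumsum(cover[: m + 1]) / n
        if np.max(np.abs(s_new - s)) < tol:
            s = s_new
            break
        s = s_new
    return TurnbullCIF(left=left, right=right, prob=s[:m], n_iter=n_iter)
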