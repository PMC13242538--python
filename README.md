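# tristate

Progressive three-state natural-history models for cancer screening and
surveillance data with **censoring after intervention**.

## The problem

Screening programmes for cervical, breast and colorectal cancer detect and
remove precancerous lesions. That is the point of screening — but it creates
an awkward observation scheme for anyone trying to estimate the natural
history of the disease. Consider the progressive model

```
healthy (1)  --x-->  precursor (2)  --t-->  cancer (3)
```

where `x` is the time from the process origin to precursor onset and `t` the
sojourn time in the precursor state. Subjects are examined at discrete
visits `v_1 < v_2 < ... < v_m`, and each ends in one of three censoring
states:

* **δ = 1** — healthy at the last visit: `x` is right censored at `v_m`;
* **δ = 2** — precursor found at `v_m`: `x` is interval censored in
  `(v_{m-1}, v_m]`, the lesion is removed, follow-up ends, and the
  transition to cancer is **never observed**;
* **δ = 3** — cancer found at `v_m`: both transitions happened inside
  `(v_{m-1}, v_m]`.

Quantities such as the sojourn-time distribution and the cancer risk after
precursor onset must therefore be inferred from a likelihood in which the
2→3 transition is only ever seen "bundled" into a single interval. This
package provides the full toolkit for studying estimators in this setting:
a synthetic-cohort generator, the interval-censored likelihood, maximum
likelihood / MCMC / bootstrap fitting, cumulative-incidence estimands, a
Turnbull NPMLE cross-check, and a factorial simulation-study harness.

## The model

Progression times follow accelerated failure time (AFT) laws

```
log x = βx,0 + z'βx + σx ε ,     log t = βt,0 + z'βt + σt ξ ,
```

with standard extreme-value (Gumbel-minimum) errors, so `x` and `t` are
Weibull with scale `exp(η)` and shape `1/σ`; `σ = 1` is the exponential
(time-homogeneous Markov) special case, `σ ≠ 1` a semi-Markov model whose
2→3 hazard runs from state entry. A third family uses piecewise-constant
hazards on the *process time* scale (an inhomogeneous Markov model, as used
when age drives progression). The subject likelihood contributions are

* δ = 1: `S_x(v_m | z)`
* δ = 2: `∫_l^r f_x(u|z) S_t(r−u|z) du`
* δ = 3: `∫_l^r f_x(u|z) F_t(r−u|z) du`

with `(l, r]` the last interval, evaluated by fixed-node Gauss–Legendre
quadrature. Estimands follow the screening literature: marginal and
conditional CIFs, their time percentiles, cumulative hazards, sojourn
summaries, and per-unit hazard ratios via the AFT→PH transform
`HR = exp(−β/σ)`.

## Worked example

```python
import numpy as np
from tristate import ThreeStateModel, VisitDesign, generate_cohort, weibull_dgp

# a semi-Markov cohort: median onset time 18.7, median sojourn 3.0
design = VisitDesign(gap_scale=1.1, admin_horizon=20.0)
cohort = generate_cohort(1000, 0, weibull_dgp(0), design, seed=7)
print("delta counts:", cohort.delta_counts())

model = ThreeStateModel(cohort.histories, family12="weibull", family23="weibull")
res = model.fit(starts=3, seed=0)
print(res.summary())
for tr in ("1->2", "2->3", "1->3"):
    print(f"median time, transition {tr}: {res.cif_quantile(tr, 0.5):.2f}")

boot = res.bootstrap(B=200, seed=1)
pt, (lo, hi) = boot.cif_quantile_interval("2->3", 0.5)
print(f"sojourn median with 95% bootstrap interval: {pt:.2f} ({lo:.2f}, {hi:.2f})")
```

prints

```
delta counts: {1: 620, 2: 285, 3: 95}
MLResults: progressive three-state model
families: weibull (1->2), weibull (2->3, clock=state_entry)
n = 1000, log-likelihood = -1087.5409
converged: True

parameter             estimate        2.5%       97.5%
beta12_0                3.0063
log_sigma12            -1.6371
beta23_0                1.1363
log_sigma23            -1.5476

median time, transition 1->2: 18.82
median time, transition 2->3: 2.88
median time, transition 1->3: 21.67
sojourn median with 95% bootstrap interval: 2.88 (2.59, 3.20)
```

The fitted intercepts and log-scales recover the generating values
(3, log 0.2 = −1.61, 1.2, log 0.3 = −1.20) to within sampling error, and the
fitted median onset time 18.82 sits next to the true 18.7 — even though 62%
of subjects are right censored and the 2→3 transition is never observed
directly. A Bayesian fit of the same model is one call away
(`model.fit_bayes(chains=4, iters=5000, seed=0)`), returning posterior draws
with split-R̂ and effective-sample-size diagnostics.

The simulation-study harness in `tristate.evaluation` runs factorial design
cells (generating family × censoring strength × covariates × sample size),
compares fitted 10th/50th/90th CIF percentiles with the exact truth, and
reports mean relative error, rMSE, coverage and convergence counts. A CLI
(`tristate simulate / calibrate / fit / cif / study / npmle`) wraps the same
library calls for shell use.

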