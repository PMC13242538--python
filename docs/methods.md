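# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `tristate`.

## Model and likelihood

The package models a progressive three-state process (healthy → precursor →
cancer) observed through intermittent screening visits, with the precursor
removed upon detection so that follow-up stops at the detecting visit and
the precursor→cancer transition is never observed. Everyone is healthy at
the process origin (time 0); the screening test is perfect; visit times are
noninformative (independent of the progression times, by construction in
the generator).

Progression times follow AFT laws `log T = η + σW` with Gumbel-minimum
errors, i.e. Weibull with scale `exp(η)` and shape `1/σ`:

* `family="exponential"`: σ fixed at 1 — constant hazards, a
  time-homogeneous Markov model;
* `family="weibull"`: the 2→3 hazard runs from state entry — a semi-Markov
  model;
* `family="piecewise_constant"` (second transition only, with
  `clock23="process_time"`): the 2→3 hazard is a step function of time
  since the origin — an inhomogeneous Markov model of the kind used when
  age drives progression. Covariates act proportionally on the hazard.
  Cut points default to unit spacing (hazard changes at integer process
  times, e.g. whole years of age) and are user-overridable.

Subject contributions to the likelihood, with `(l, r]` the last interval:

| δ | contribution |
|---|---|
| 1 | `S_x(v_m | z)` |
| 2 | `∫_l^r f_x(u|z) S_t(r−u|z) du` |
| 3 | `∫_l^r f_x(u|z) F_t(r−u|z) du` |

Under the process-time clock the δ = 2 survivor factor is
`exp(−(Λ23(r) − Λ23(u)))` for onset at `u`, and the δ = 3 term is obtained
by complementing against the closed-form onset mass
`S_x(l) − S_x(r)`.

**Quadrature.** Fixed 64-node Gauss–Legendre on `(l, r)`. The integrands
are smooth there for the AFT families; a node-doubling test keeps the
error below 1e−8 for shapes in the study's range. For the piecewise family
the integrand has kinks at the cut points, so the integral is accumulated
piece by piece (16 nodes per piece) — a single rule across the kinks loses
five orders of magnitude of accuracy.

**Probability floor.** Interval probabilities are floored at 1e−300 before
the log so that optimisers and samplers see a finite surface rather than
−∞; the floor is never active at any optimum we have observed.

**Baseline intervals.** Subjects detected at their first visit have
`(0, v_1]` as their censoring interval, which is exact under the
healthy-at-origin assumption.

**Closed-form oracle.** For the doubly exponential model the δ = 2 integral
has the antiderivative `θx e^{−θt r}(e^{−Dl} − e^{−Dr})/D` with
`D = θx − θt`, evaluated via `expm1` so the equal-rate limit
`θx (r−l) e^{−θx r}` is reached continuously. This independent path is used
to validate the quadrature in the tests, never as the fitting route.

## Synthetic-data generator

The generator emulates surveillance data with censoring after intervention:

* **Covariates** (`p = 2`): `z1 ~ N(0,1)`, `z2 ~ Bernoulli(0.5)`, entering
  both transitions with coefficients (0.5, 0.5); `p = 0` omits them. Only
  these two designs are accepted — they are the factorial levels studied.
* **Progression times**: from the Weibull generator
  (`log x = 3 + z'β + 0.2ε`, `log t = 1.2 + z'β + 0.3ξ`) or its exponential
  counterpart (σ = 1). Without covariates the implied medians are 18.7 (x)
  and 3.0 (t); with covariates the exact marginal medians are 23.147 and
  3.656 (by quadrature; Monte Carlo agrees).
* **Visits**: cumulative sums of i.i.d. gamma(shape 4, scale) gaps,
  truncated at `max_visits = 40` and an administrative horizon; if the
  first gap overshoots the horizon the single visit is clamped to the
  horizon, so every subject is screened at least once. The gamma family
  was chosen because one shape knob spans regular to irregular schedules
  while keeping the schedule independent of the disease process
  (noninformative censoring); shape 4 gives moderately irregular,
  realistic recall patterns.
* **Censoring strength calibration**: the two free knobs (gap scale,
  admin horizon) are tuned by nested bisection on a common-random-numbers
  Monte-Carlo cohort (default 40 000 subjects): for each candidate gap
  scale the horizon is solved so the δ = 2 fraction hits its target (the
  fraction is monotone in the horizon), and the resulting δ = 3 fraction
  is then monotone in the gap scale. Targets: 45%/20% ("medium") and
  30%/10% ("strong"), to ±0.4 percentage points internally so that an
  independent cohort of 10⁴ subjects lands within ±1 point. The two knobs
  interact strongly (alternating one-dimensional searches oscillate),
  which is why the nesting matters.
* **Replication**: per-replicate seeds derive from
  `SeedSequence([master_seed, replicate_index])`, so multi-dataset studies
  are reproducible and embarrassingly parallel.

What the generator does **not** emulate: imperfect tests
(misclassification), prevalent lesions at baseline, state-dependent
(informative) scheduling, competing mortality. Passing tests therefore
speak to estimator behaviour under the stated censoring structure, not to
robustness against those violations.

## Estimation

**Maximum likelihood.** Parameters are unconstrained — `(intercepts,
coefficients, log σ)`, or log piecewise rates — so no boundary handling is
needed. Multi-start L-BFGS-B (default 3 starts: method-of-moments initials
using interval midpoints as pseudo event times, then uniform ±0.5 jitter),
followed by a BFGS polish. A fit is declared converged when the two best
starts agree within 1e−4 in log-likelihood and the central-difference
gradient norm is below 1e−3 (forward differences are too biased here: the
information on the onset intercept is large, and the truncation error
0.5·f″·h would dominate the check). A cohort with no detected events
carries no information on the 2→3 transition and is flagged unconverged
rather than raising. Standard errors come from the inverse observed
information (central-difference Hessian).

**Bayesian fit.** Metropolis-within-Gibbs with one multivariate-normal
proposal block per transition. Proposal scale adapts toward 30% acceptance
during burn-in, and the proposal *shape* is refreshed every 200 burn-in
iterations from the empirical covariance of the chain's second half —
without this the correlated (intercept, log σ) pairs mix far too slowly.
All adaptation freezes at the end of burn-in, preserving detailed balance
for the retained draws. Defaults: 4 chains × 5000 iterations, 50% burn-in;
convergence requires split-R̂ < 1.1 for every parameter (computed via
arviz), with acceptance rates and bulk ESS reported. Priors are weakly
informative and regularising rather than belief-encoding: N(0, 10) on
intercepts, coefficients and log piecewise rates, N(0, 1) on log scales.
`prior_only=True` switches the likelihood off, which the tests use to
verify the sampler against the known prior.

**Bootstrap.** Nonparametric resampling of subjects with replacement;
each replicate refits from the original optimum. Failed replicates are
excluded and counted; more than 20% failures marks the bootstrap layer
unconverged. Default B = 200.

## Estimands

Marginal CIFs average conditional CIFs over a covariate bank — by default
the estimation cohort's own covariates (empirical standardisation). This
was a genuinely open choice; standardising over a hypothetical covariate
law would require the user to supply one at fit time, and the empirical
bank reproduces "averaged over the population" without extra assumptions.
With no covariates the marginal and conditional CIFs coincide and the bank
collapses to a single profile (with closed-form quantiles for the AFT
families). The healthy→cancer CIF is the convolution
`∫ f_x(s) F_t(u−s) ds`, computed with the same quadrature rule as the
likelihood so there is a single accuracy knob. CIF time-percentiles are
found by bracketed root-finding (geometric bracket expansion, then Brent);
an unreachable level — possible for defective piecewise models whose
hazard switches off — raises with the plateau value rather than looping.
Interval bands are equal-tailed percentile intervals across draws
(posterior or bootstrap), requiring at least 50 draws; per-draw quantile
recomputation thins to 500 draws. Hazard ratios use the AFT→proportional
hazards transform `exp(−β/σ)`; for the piecewise family the coefficient is
already on the log-hazard scale, so `exp(β)`.

## Evaluation harness

The factorial design crosses generating family {exponential, weibull} ×
censoring {medium, strong} × covariates {0, 2} × n {1000, 2000}, with 100
replicates per cell at full scale; the test suite runs 20-replicate
versions of the key cells (recovery, misspecification bias, coverage),
which is where the suite's runtime mostly goes. True CIF percentiles come
from closed forms (p = 0) or 10⁶-draw Monte Carlo with a fixed seed
(p = 2). Metrics: relative error `(φ̂−φ)/φ`, rMSE `sqrt(mean((φ̂_j−φ)²))`,
and the coverage of nominal 95% intervals (empirical band 91–99% counts as
acceptable at 100 replicates). Unconverged fits are excluded from metric
aggregation but counted and reported — convergence failure is a finding,
not noise. `run_cell` persists per-replicate rows after each fit and skips
completed (method, replicate) pairs on restart, so interrupted studies
resume.

**Turnbull NPMLE.** Histories reduce to first-event intervals (δ = 1 →
`(v_m, ∞)`; δ ∈ {2,3} → `(l, r]`). Innermost intervals are constructed
from the endpoint grid, a virtual tail interval absorbs the residual mass
of right-censored subjects, and the self-consistency (EM) iteration runs
until the largest mass change is below 1e−8. EM was chosen over iterative
convex minorant algorithms for its guaranteed monotone ascent and
simplicity; because each subject's interval covers a *contiguous* run of
innermost intervals, the E-step is O(n + m) via cumulative sums, so even
the slow EM tail (tens of thousands of sweeps on continuous-time data) is
a few seconds at n = 8000. The estimated CDF is reported with each
interval's mass at its right endpoint; within innermost intervals the
NPMLE is not identified.

## Known limitations

* Phase-type (Coxian) sojourn distributions, misclassification/hidden-state
  models, death as a competing risk, and time-varying covariates are out of
  scope.
* The piecewise process-time model estimates one rate per piece; with many
  pieces and few δ = 3 events the rates are weakly identified — the same
  phenomenon the convergence diagnostics are designed to surface.
* The marginal CIF for the 2→3 transition under the process-time clock
  averages the onset-conditional CDF over the fitted onset density; it is
  a model-based estimand, not directly nonparametrically identified.
* CSV round-trips are lossless only through the provided readers/writers
  (`%.17g` formatting and round-trip float parsing).
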