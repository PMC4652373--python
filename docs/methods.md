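# Methods

## The model

`ccistate` models the Charlson Comorbidity Index (CCI) of a subject as an
irreversible, piecewise-constant accumulation process observed together with
mortality. A subject occupies one of the states {CCI = 0, 1, 2, ...} or the
absorbing state *dead*; the CCI can only increase. Follow-up is discretized
into steps of Δ = 28 days (four weeks). Within each step, exactly one of
three things happens: the subject dies, the CCI jumps by some positive
amount, or nothing changes. Death takes precedence: a step in which the
subject dies carries no CCI change, so the fitted transition law has no
joint death-and-change outcome.

The per-step transition law is the product of four regressions fitted to
the person-period (long-format) data:

1. **Death** (logistic): `logit P(die in step) = b0 + b1*age + b2*cci +
   b3*age*cci`, with age and CCI evaluated at the step start (4
   coefficients).
2. **Change** (logistic, on steps survived): `logit P(any CCI change)` on
   treatment (AS/RP/RT, reference AS), age (linear), CCI category
   (0/1/2/3/4+, reference 0), time since previous CCI change, time since
   radical prostatectomy (RP) and time since radiotherapy (RT) — each clock
   categorized as 1, 2–3, 4–6, or >6 steps with ">6" also covering "never"
   — plus an age × treatment interaction (19 coefficients under reference
   coding).
3. **Size** (Poisson, log link, on steps with a change): the outcome is the
   *transformed* change `c - 1`, or `c - 6` when `c >= 6`, so that the
   smallest outcome 0 corresponds to a change of 1 or 6. Same 19-term
   design as the change model.
4. **≥6 indicator** (logistic, on the same changed steps): whether the
   change was ≥ 6, i.e. which shift to add back when simulating. Regressors:
   treatment, CCI as 0/1/2+ dummies together with a linear CCI term, the
   change clock, and age (10 coefficients).

The size transform reflects the structure of the CCI: increments are sums of
disease weights in {1, 2, 3, 6}, and jumps of six or more are dominated by
the weight-6 diseases, which breaks a single-Poisson description of the jump
size. The transform is inverted exactly during simulation:
`ΔCCI = y + 6` if the ≥6 draw fires, else `y + 1`, with `y` the Poisson
draw.

Clock semantics: a qualifying event in step *j* gives clock value `k - j`
at step *k* (so the smallest observable value is 1; an event in the current
interval affects the *next* interval). A procedure at follow-up start is
therefore not yet "ticking" in step 0. Clock categories are in steps; we
equate one month with one four-week step. All clocks saturate in the
">6/none" category, which makes the expanded state space finite.

## Discretization

Events are mapped to half-open intervals `[entry + kΔ, entry + (k+1)Δ)`.
Multiple events in one interval are pooled (weights summed) into a single
change; events falling in the terminal interval of a subject who died are
discarded and counted in the pooling report (death precedence, see above).
A censored subject's partial terminal interval is kept with its observed
outcomes. Age advances by Δ/365.25 years per step from the continuous age
at entry. The pooling report gives the fraction of daily-resolution events
that shared an interval with another event — the information lost to the
four-week grid; with the default generator this is a few percent, the same
order as reported for four-week steps on real registry data.

## Fitting

All four models are plain maximum likelihood with canonical links, fitted
by iteratively reweighted least squares with the normal equations
accumulated in row chunks (`ccistate._glmfit`). This keeps peak memory near
the size of the design matrix itself: the full-scale person-period table
(50,000 subjects × 130 steps ≈ 6.5M rows × 19 columns) fits comfortably in
a few GB, where a generic GLM implementation would need several times that.
For tables above ~1.2M rows a staged warm start (recursive quarter
subsample, tolerance 1e-6) brings the full-data IRLS down to about three
passes. Convergence is declared at a relative deviance change below 1e-8;
non-convergence, separation (single-class outcomes), or a singular
information matrix raise `FitError` — never a silently wrong result. The
covariance is the inverse observed information at the optimum. The test
suite cross-checks coefficients and standard errors against statsmodels GLM
on moderate-size data.

Structurally empty dummy columns (e.g. no RT arm in a reduced scenario) are
dropped with a warning and recorded in `FittedModel.dropped_terms`; a
dropped term acts as coefficient 0 everywhere downstream. A degenerate size
outcome (every change of size 1 or 6, so every transformed size is 0) is
rejected: the Poisson intercept is unbounded below.

The four models are fitted independently; the stacked covariance of all 52
coefficients is block-diagonal by construction. No cross-model covariance is
estimated.

## Microsimulation and the exact oracle

`simulate_cohort` advances all subjects of a profile (treatment, age at
start, initial CCI) in lock-step. Per step it draws four uniform vectors —
death, change, size, ≥6 — and maps them through inverse CDFs (the Poisson
draw via `poisson.ppf`). Consequently the random stream consumed is
independent of the coefficient values, so runs with perturbed coefficients
under the same seed are coupled (common random numbers). Occupancy index
*k* is the state distribution at time *kΔ*; a run over *n* steps yields
*n* + 1 distributions, the zeroth being degenerate at the initial state. A
safety cap (default CCI 100) turns runaway size coefficients into an error
rather than an unbounded loop.

`exact_occupancy` propagates the distribution over the expanded alive state
(CCI level × change-clock value 1..7, with 7 = ">6/none") exactly, which is
finite once CCI is capped; probability of jumps beyond the cap accumulates
in an absorbing *overflow* state reported separately. Age and the
procedure clocks are deterministic in the step index, so they need not be
part of the state. This oracle verifies the simulator to binomial
Monte-Carlo error and serves as a cheap deterministic evaluator for
uncertainty propagation.

Functionals of a curve at step *k*: `alive_at_initial` (alive and still at
the initial CCI), `died_or_changed` (its complement), and `stay_initial`
(conditional on being alive). `contrast` differences a functional between
two profiles on a common step grid.

`model_implied_first_increase` computes the time-to-first-increase survival
curve in closed form: before the first change the covariate path is
deterministic, so `S` is a product over per-step probabilities. Death is
treated as right-censoring by default (per-step hazard
`(1 - p_death) * p_change`), matching how the Kaplan-Meier comparison
censors deaths; the composite convention (`(1-p_death)(1-p_change)`) is
available via `death="composite"`. At the default per-step rates the two
conventions differ far less than the comparison tolerance.

## Uncertainty: the unscented transform

Confidence intervals for occupancy functionals propagate the coefficient
covariance Σ (dimension p = 52) through the simulation with a symmetric
2p-point unscented transform: points `θ ± sqrt(p) L_i` with `L Lᵀ = Σ`
(eigen factorization; eigenvalues below −1e-8 relative are an error, small
negatives are clipped with a warning), equal weights `1/(2p)`. The point
estimate is the centre run; the variance is the weighted mean squared
deviation of the sigma-run functionals around their weighted mean; the
interval is normal-theory `estimate ± z(level)·SD`. This costs ~2p
simulation runs — the reason this scheme is preferred over a bootstrap here
— and is exact for affine functionals of θ (verified to 1e-8 in tests).
All sigma runs share one seed; with inverse-CDF sampling this makes them
common-random-number coupled, so the spread measures coefficient
uncertainty, not Monte-Carlo noise. The residual Monte-Carlo error of the
centre run is reported separately as a binomial standard error. Contrast
intervals evaluate both profiles under the same sigma point and seed so
between-profile noise cancels; identical profiles give an exactly
degenerate interval.

The general scaled-UT (α, β, κ) family, percentile intervals, and bootstrap
propagation are out of scope.

## The synthetic generator

`synthgen` exists because the registry data this methodology targets cannot
be redistributed. `default_truth()` fixes a complete generating law:

* Arm shares 7544 : 9959 : 2734 (AS/RP/RT ≈ 37/49/14%), per-arm age normals
  (means 65.4/61.7/64.8, SDs 6.0/5.9/5.7), and per-arm baseline-CCI
  categoricals over 0/1/2/3 (83–90% at 0) — the shape of a three-arm
  low-risk prostate-cancer cohort at diagnosis.
* Transition coefficients chosen once to give realistic per-four-week
  magnitudes at age 65 and CCI 0: death ≈ 0.11%/step (≈1.5%/year), change
  ≈ 0.4%/step on surveillance with a several-fold transient elevation in
  the first months after RP/RT (via the procedure clocks, emulating the
  post-hospitalization recording surge seen in discharge-based registries),
  mean transformed size ≈ 0.25, and ≈7% of changes ≥ 6.
* Entry dates uniform over a ten-year window; administrative censoring at a
  130-step (10-year) horizon; procedures dated at entry for their arms.

Generation runs the same transition law forward and then *decomposes* each
per-step jump greedily (largest first) into weight-valued events in
{6, 3, 2, 1}, each dated at an independent uniform day within its interval.
This reproduces the structure of real inputs (per-disease dated events) and
exercises interval pooling: decomposed and co-occurring events land in the
same interval at realistic rates. Deaths are dated uniformly within their
step (via the conditional uniform of the accepted death draw).

What the generator does **not** emulate: ICD coding and imperfect register
capture, treatment switching (procedures only at entry), seasonality,
calendar-period trends, subject-level frailty beyond the modelled
covariates, and loss to follow-up before the administrative horizon.
Passing tests therefore demonstrate the *internal* correctness of the
pipeline (discretization, estimation, simulation, uncertainty) under the
assumed law — not that the law describes any particular real cohort.

## Verification strategy and problem sizes

* Parameter recovery: 20 replicate cohorts of 50,000 subjects over the
  130-step horizon; at least 95% of the 52 true coefficients must lie
  within 3 reported SEs of their estimates (nominal 3-SE coverage is
  99.7%).
* Simulator vs oracle: 200,000 subjects, 20 steps, oracle capped at CCI 3
  (mass above the cap compared against the oracle's overflow state),
  agreement within 3 binomial SEs per state per step.
* Kaplan-Meier self-consistency: 100,000 subjects generated at a fixed
  profile (age 65, baseline CCI 1, single arm); sup-norm between the KM
  curve (lifelines) and the closed-form model curve below 0.02 over 10
  years. The KM curve is evaluated at `kΔ − 1` days so that
  `S_KM = P(T ≥ kΔ)` aligns with the model's step grid.
* UT: affine exactness to 1e-8; agreement with a central finite-difference
  delta method within 10% on the reduced configuration with the exact
  evaluator and SD 0.05 on the four intercepts.
* Smaller versions of these checks run in the unit suite; stochastic
  assertions are seeded and, where a check multiplies ~100 comparisons, use
  a 4-SE rather than 3-SE bound to leave a multiplicity margin.

## Numerical choices

* Linear predictors are clipped to ±30 before exponentiation/expit;
  IRLS working weights are floored at 1e-12. "Probability zero" scenarios
  built from ±30 intercepts are therefore zero only to ~1e-13, and
  degenerate assertions use 1e-9 absolute tolerance.
* Deviance convergence tolerance 1e-8 (relative); covariance symmetrized
  and checked to 1e-10.
* `poisson.ppf(u, mu)` defines the size draw; ties/edge `u` values follow
  scipy's inverse-CDF convention.
* Occupancy normalization is asserted to 1e-9 at every step in both
  engines; the death mass must be non-decreasing.
* Seeds: every stochastic entry point takes an explicit seed;
  `generate_cohort` derives separate streams for trajectories and event-day
  placement from one `SeedSequence`, so same seed ⇒ byte-identical output.

## Known limitations

* The block-diagonal covariance ignores cross-model dependence; the UT
  interval inherits this approximation.
* The normal-theory interval can leave [0, 1] for functionals near the
  boundary; it is not clipped.
* One month ≡ one four-week step in all clock categories; calendar-month
  arithmetic is a non-goal.
* `stay_initial` is NaN once no alive mass remains.
* Mapping ICD codes to Charlson categories, registry linkage, per-transition
  Cox modelling, and cause-of-death attribution are out of scope: inputs
  are pre-weighted dated increments.
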