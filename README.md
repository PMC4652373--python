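# ccistate

Discrete-time state-transition modelling of comorbidity accumulation in a
cohort, built around the Charlson Comorbidity Index (CCI).

Comorbidity burden — as summarized by the CCI, a weighted sum over disease
categories with weights 1, 2, 3 or 6 — strongly affects treatment choice and
survival of cancer patients, and it *changes* during follow-up: multiple
times, by different amounts, never downwards. Classical time-to-event
analysis handles one transition per model and would need dozens of models to
describe this process. `ccistate` implements the alternative: treat CCI
levels plus death as states of a multi-state model in discrete four-week
steps, estimate the whole transition law with just four regressions,
microsimulate cohorts forward, and attach confidence intervals to
state-occupancy summaries with the unscented transform.

It is aimed at biostatisticians and epidemiological modellers working with
registry-style follow-up data (subject table + dated, weighted comorbidity
events).

## The model in brief

Follow-up is discretized into steps of Δ = 28 days and arranged in
person-period (long) format, age and CCI updated at each step. Per step,
for a subject alive at the step start:

1. death:   `logit P(death) = β₀ + β₁·age + β₂·CCI + β₃·age·CCI`
2. change:  `logit P(ΔCCI > 0)` on treatment, age, CCI category (0/1/2/3/4+),
   time since last CCI change, time since prostatectomy, time since
   radiotherapy (each as 1 / 2–3 / 4–6 / >6-or-never steps), and age×treatment
3. size:    `log E[Δ*] = x'γ` (Poisson), where the transformed size
   `Δ* = ΔCCI − 1`, or `ΔCCI − 6` when `ΔCCI ≥ 6`, same design as (2)
4. ≥6 flag: `logit P(ΔCCI ≥ 6)` on treatment, CCI (0/1/2+ dummies + linear),
   the change clock, and age

Simulation inverts the transform: `ΔCCI = y + 6` or `y + 1` with `y` the
Poisson draw. Confidence intervals re-run the simulation at 2p = 104
deterministically chosen sigma points of the stacked coefficient vector
(p = 4+19+19+10 = 52, block-diagonal covariance) — about twice the number of
coefficients, far cheaper than a bootstrap — with common random numbers
across runs. An exact forward-propagation oracle over the capped
(CCI × change-clock) state space verifies the simulator, and a synthetic
cohort generator with known coefficients stands in for the non-public
registry data this methodology targets. See `docs/methods.md` for details.

## Worked example

```python
import ccistate as cs

# a synthetic three-arm cohort from the default known truth
truth = cs.default_truth()                      # 130 four-week steps ~ 10 y
cohort = cs.generate_cohort(truth, 20_000, seed=1)

steps, report = cs.discretize_followup(cohort)  # person-period long format
print(f"{len(steps)} person-steps, "
      f"{100 * report.frac_events_pooled:.1f}% of events pooled")

params = cs.fit_transition_models(steps)        # the four regressions
print([m.n_coefficients for m in params.models])

# ten-year occupancy for 65-year-old men starting at CCI 0
rt = cs.Profile(treatment="RT", age_at_start=65.0, initial_cci=0)
rp = cs.Profile(treatment="RP", age_at_start=65.0, initial_cci=0)
ci = cs.ut_contrast_interval(params, rt, rp, kind="died_or_changed",
                             step=130, n_subjects=20_000, n_steps=130, seed=2)
print(f"P(died or changed CCI by 10 y), RT - RP: {100 * ci.estimate:.1f}% "
      f"(95% CI {100 * ci.lower:.1f} to {100 * ci.upper:.1f})")
```

Output:

```
2364461 person-steps, 5.8% of events pooled
[4, 19, 19, 10]
P(died or changed CCI by 10 y), RT - RP: 3.2% (95% CI 1.7 to 4.6)
```

Read: discretization lost little information (5.8% of daily events shared a
four-week interval with another); the four models carry their full 4/19/19/10
coefficient sets; and under the synthetic generating law, radiotherapy
patients of this profile are an estimated 3.2 percentage points more likely
than prostatectomy patients to have died or accumulated comorbidity within
ten years, with an unscented-transform interval reflecting the fitted
coefficient uncertainty.

The same pipeline is available from the shell:

```bash
ccistate synth --n-subjects 20000 --seed 1 \
    --out-subjects subjects.csv --out-events events.csv
ccistate discretize --subjects subjects.csv --events events.csv --out long.csv
ccistate fit --long long.csv --out params.yaml --histogram-out sizes.csv
ccistate simulate --params params.yaml --treatment RT --age 65 --cci 0 \
    --seed 2 --out occupancy.csv
ccistate ci --params params.yaml --treatment RT --age 65 --vs-treatment RP \
    --step 130 --seed 2 --out ci.csv
ccistate validate --params params.yaml --subjects subjects.csv \
    --events events.csv --treatment AS --age 65 --cci 0 --seed 3 --out val.csv
```

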