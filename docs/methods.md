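# Methods

## Model structure and assumptions

The model is a one-cycle cohort decision tree with a lifetime extrapolation
tail, evaluated analytically (expected values over leaf probabilities), not
by simulation. The compared strategies differ only in (a) screening
sensitivity/specificity and (b) the treatment time of true positives
(algorithm −3 h vs current practice 0 h, relative to current-practice
diagnosis). False negatives are treated at +3 h in both arms; the time from
detection to antibiotics is 0 h in both arms, so "time to detection" and
"time to treatment" coincide.

Key structural assumptions, all configurable:

- **Septic shock** is a continuous function of treatment time: a straight
  line through (0 h, 56.6%) and (−3 h, 40%), i.e. +5.53 percentage points
  per hour of delay, clamped to [0, 1]. A `time_dependent: false` switch
  fixes it at 56.6% regardless of timing.
- **In-hospital mortality** applies only to sepsis patients (non-sepsis ICU
  mortality is identical across arms and cancels from every increment):
  0.4281·e^(0.0272·t) with shock, max(0, 0.0052·t) without. Outputs are
  clamped to [0, 1]; the floor at 0 for negative *t* reflects the printed
  0% no-shock mortality at −3 h. Two alternative curve variants support
  scenario analysis: a linear survival decrease (7.6 pp/h anchored at 40%
  mortality at 0 h) and constant 33%/22% mortality.
- **Readmission** (20.6% in year 1) is charged to *all* in-hospital
  survivors, not only sepsis survivors. Only this accounting reproduces the
  published readmission proportions (20.0%/19.8%) and costs (€835/€826 =
  rate × survivors × €4166); a `readmission_population: sepsis_survivors`
  switch provides the narrower reading.
- **Prediction cost** is €1037 charged once per ICU patient in the
  algorithm arm. The published per-patient total (€16 436) and national
  prediction cost (€38.27M ≈ 1037 × 36 900) are only mutually consistent
  under that accounting, although the cost is labelled "per sepsis
  patient"; the €90/ICU-day pricing that motivates €1037 (= 90 × 1.62 /
  0.141) is kept as a separate worked-example operation.
- **Long-term survival**: sepsis survivors face relative risks 5.5 (years
  1–5), 3.1 (years 6–10), 1.0 (year 11+) on the general-population annual
  death probability; the 60–70 age band is the base case (cohort mean age
  60). Septic-shock survivors additionally face a 17.5% first-year
  post-discharge mortality, which replaces the projection's year-1 hazard.
  Non-sepsis patients follow general-population survival.
- **QALYs** use annual year-end discounting at 3% and a population-norm
  baseline utility of 0.80 (the source material never states the norm;
  this choice shifts absolute QALYs in both arms equally and leaves every
  cost result untouched). Utility decrements (−0.164 years 1–5, −0.124
  years 6–10, 0 thereafter) apply to sepsis survivors; utilities are
  clamped at 0 with a logged warning if a sampled decrement exceeds the
  baseline.

## Back-calculated unit costs

Three unit costs were not published as such and are recovered from the
published aggregate rows, with a cross-arm consistency check (both arms
must imply the same constant to <0.1%, which they do):

| constant | derivation | value (EUR) |
|---|---|---|
| ICU day | per-arm ICU cost ÷ per-arm expected ICU days | 6 355.38 |
| ward day | per-arm ward cost ÷ per-arm expected ward days | 626.26 |
| long-term lump per 1-year sepsis survivor | per-arm long-term cost ÷ model 1-year-survivor probability | 1 947.73 |

The long-term consequence cost is therefore a **one-time discounted lump**
per sepsis patient alive one year after discharge (its itemised
constituents — impaired kidney function 14.1%, amputation 8.5%, depression
2.8%, PTSD 9.9% — are reported descriptively only). Consequence: scenarios
that change only long-term *survival* or the *discount rate* cannot move
the cost side of the model (the lump is fixed), only QALYs. This is the one
part of the published scenario table the lump accounting cannot reproduce;
an annual-cost formulation would need the unpublished per-item costs.

## Two-step mortality-curve estimation

The procedure that produced the mortality curves is implemented and
validated on synthetic data (the original grouped source data are not
published). Step 1 solves a linear program: variables are cumulative
mortality fractions m(t) on an hourly grid; each observed group's implied
death count is n × mean(m over grid points in its interval); the objective
is the total absolute deviation from observed deaths (L1, the natural
LP-compatible choice — the original objective is unstated), subject to
0 ≤ m ≤ 1 and monotone non-decreasing m, with a 1e−9 penalty on Σm for
uniqueness. Step 2 fits a·e^{bt} by least squares on the log scale
(deterministic and closed-form; requires positive mortalities) or c·t by
the closed-form through-origin slope.

## Synthetic data

- **Life table**: Gompertz, q(x) = min(1, 5·10⁻⁵·e^{0.095x}), terminal
  q = 1 at age 105 — a plausible high-income-country table (remaining life
  expectancy ≈ 17 years at age 60) chosen once; explicitly synthetic, not
  an official national table. National absolute QALY levels therefore
  differ from any official-table run, but incremental results are driven
  by the short-term tree, where no life table enters the cost side.
- **Grouped mortality data**: binomial death counts at interval-midpoint
  probabilities from a chosen generating curve, for end-to-end recovery
  tests of the two-step procedure.
- **Microsimulation**: 2·10⁶ patients per arm routed through the tree by
  Bernoulli draws, with stays and conditional QALY expectations assigned
  per leaf/severity (optionally gamma-distributed stays). It emulates the
  tree's branching randomness only — not patient-level heterogeneity in
  risks, costs, or lifetimes — so its agreement with the analytic
  expectations (within 3 Monte-Carlo SEs on every field, a required test)
  validates the expectation algebra, not the model's external validity.

## Probabilistic sensitivity analysis

All 35 rows of the published distribution table are carried verbatim:
means and standard errors converted to beta (probabilities), gamma (days),
log-normal (relative risks/hazard ratios), or normal (hours, utility
decrements) parameters by the method of moments, with exact round-trip
identities tested. One row has SE 0 (utility decrement year 11+) and is
treated as degenerate. Each parameter owns an independent random stream
`default_rng([seed, row_index])`, so the conditioned PSA (one parameter
fixed at its mean) leaves all other draws unchanged — a common-random-
numbers design that makes variance attribution clean. The treatment-time
offsets for TP and FN are drawn as independent normals (SE 0.5 h); the
hazard-ratio rows for the <60 and >70 age bands are sampled but only the
band matching the cohort's mean age is applied. Draws that leave the
model's support (early-detection shock probability above the
current-practice one, TP time above FN time, relative risks below 1) are
clamped back and counted; >1% clamped draws logs a warning. Parameters are
sampled independently (no correlations are published). 1000 draws run in
under a second; with every SE forced to 0 the cloud collapses exactly to
the deterministic result (a required test).

## Numerical and reporting conventions

- Internal arithmetic is full precision; rounding (days to 2 dp, EUR to
  whole units, percentages to 1 dp) happens only at presentation.
- National results are per-patient increments × 36 900, exactly.
- Percent changes in the scenario table use the base-case national impact
  as denominator, so a deeper saving is a positive percentage (the
  published sign convention).
- CSV outputs are UTF-8, comma-separated, "." decimal, no thousands
  separators.

## Known limitations

- The lump-sum long-term cost cannot respond to survival or discounting
  scenarios (see above).
- The published national ward-days figure recomputes to ≈7886 from the
  published inputs rather than the printed 7916 (a 0.4% gap consistent
  with upstream input rounding); the model reports its computed value.
- The life table is synthetic; absolute QALY levels (not increments' signs
  or cost results) depend on it and on the 0.80 baseline utility.
- No correlation structure between PSA parameters; no morbidity-state
  Markov structure beyond the survivor lump — both match the modelled
  source, not a limitation relative to it.
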