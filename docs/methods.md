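# Methods

## State-transition model

The cohort engine propagates a probability distribution over six states
— living states H0..H4+ (count of prior CHF admissions) and absorbing
death — in monthly cycles. Event ordering within a cycle: the
hospitalization event is resolved first (probability
`p_hosp_by_state[H]`); death is then conditional on hospitalization
status (`p_death_hospitalized = 0.100` per admission event,
`p_death_not_hospitalized` otherwise). Survivors of an admission advance
exactly one state, capped at H4+; there are no recovery transitions. The
in-hospital death probability is treated as per admission event, not per
cycle spent in hospital — length of stay is not a state of this model.

Two hazard columns ship by default, for the NYHA II/III and NYHA III/IV
strata; the reference cohorts all use the II/III column. Hospitalization
risk is validated to be nondecreasing in prior admissions for the
built-in columns; user-supplied columns may violate this (the check is
available, not imposed).

## Telehealth efficacy

A program is a five-parameter bundle: detection sensitivity (SEN) and
specificity (SPE) plus proportional reductions in mortality,
hospitalization and length of stay (LOS). The telehealth arm's hazards
are the usual-care hazards scaled by `1 − SEN·reduction` — mortality on
both death probabilities (the underlying effect estimate is all-cause),
hospitalization on all five state hazards. Gating the reductions by SEN
encodes that a missed exacerbation (false negative) receives no early
intervention and therefore cannot have its admission averted or its
outcome improved; this detection-gated form is what reproduces the
published admission and cost increments (ungated, admission reductions
overshoot by ~25%). `adjust_hazards` applies the plain proportional
reduction unless `detection_gated=True` is passed; the pipeline passes
the `ModelOptions.detection_gated_reductions` flag, default on.

## Cost accrual

All flows are 2013 USD from a payer perspective, no inflation
adjustment, no indirect costs. Per cycle *t* (1-based), discounted by
`(1 + r)^(−t/12)` with r = 0.03/year (end-of-cycle convention):

- **admission**: expected admission events × $12,000. In the telehealth
  arm the per-admission cost is multiplied by `1 − los_reduction`
  (`los_gating="all"`); the alternative `"sen"` applies the saving only
  to the detected fraction, `SEN·(1 − los) + (1 − SEN)`.
- **outpatient / non-CHF**: patients alive at cycle start accrue the
  annual figures ($1,700 and $10,000) divided by 12 — uniform monthly
  accrual, the standard cohort-model convention.
- **TEST** (telehealth only): $220/month (install amortization $15 +
  monitoring $80 + case manager $125) per alive patient.
- **TREAT** (telehealth only): per alive patient,
  `[SEN·p_ex + (1 − SPE)(1 − p_ex)] × $187`, where `p_ex` is the
  occupancy-weighted exacerbation (hospitalization) probability. The
  trigger hazard defaults to the telehealth-adjusted one
  (`treat_trigger="adjusted"`): the monitored population's exacerbation
  frequency is its own, not the counterfactual usual-care one. The
  `"usual"` alternative is available. TREAT is charged on every positive
  test, including admissions that the program averts.

Admission costs are billed in the cycle of the event, including for
patients who die during the admission. No half-cycle correction by
default (`half_cycle` averages start/end occupancy for fixed-cost and
life-year accrual when enabled).

Life years accrue as the fraction alive at cycle **end**, divided
by 12, **discounted at the same 3% rate as costs**
(`discount_life_years=True`, `life_year_basis="end"`). Undiscounted or
start-of-cycle accrual are one flag away.

## Calibration of under-specified conventions

The published analysis leaves several mechanics unstated (discount
granularity, half-cycle correction, LOS gating, TREAT trigger, life-year
discounting). The shipped defaults were selected once by checking each
candidate convention set against *all* published outputs simultaneously
(the 27 base-case cells, the 30-cell two-way matrix, the break-even
table and the two validation figures), not per-quantity:

- monthly end-of-cycle discounting — confirmed exactly by the national
  burden figure ($36.20B computed vs $36.2B published);
- detection-gated hazard reductions and LOS saving on all telehealth
  admissions — admission deltas match within 0.01 and dollar cells
  within 7% / 4.4% (base-case / two-way tables);
- discounted, end-of-cycle life years — all 18 published LY cells match
  within 0.007, i.e. to their printed precision;
- break-even fees for the intermediate/high-risk cohorts match within
  2.6%.

Two residual discrepancies survive every consistent convention set and
are reported as computed rather than forced: the 20-year lifetime cost
comes out 7.3% below the published $114,939 (and cumulative mortality at
240 cycles is 94.6%, marginally under the stated "over 95%"), and the
low-risk cohort's base-case year-one break-even fee is a small positive
number (≈ $5/month) where the published table prints "Never" — a
boundary cell where the incremental cost at zero fee is within rounding
of zero.

## National burden accounting

The yearly national cost uses CHF-specific channels only — admissions
plus CHF outpatient care — because the published figure ($36.2B for 5M
patients, ≈ $7.2k per patient-year) is below the fixed $11.7k/year total
healthcare cost and is explicitly a *CHF* direct-cost estimate. The
`include_non_chf` flag adds the non-CHF channel (giving ≈ $82.6B).

## Break-even solving

Incremental cost is affine in the monthly TEST fee with slope equal to
the discounted alive patient-months of the telehealth arm, so the
break-even fee follows from two exact evaluations; the suite
cross-checks the closed form against root bracketing to $0.01. The fee
replaces the whole $220 TEST bundle; TREAT stays at its scheduled value.
"Never" (`None`) is returned when the program is cost-incurring even at
a zero fee.

## Microsimulation oracle

The microsimulation draws individual trajectories under the identical
event ordering and cost rules, using a counter-based Philox stream:
each patient owns a fixed contiguous block of draws (one for the initial
state, four per cycle — hospitalization, the two death channels, test
outcome), so enlarging the population appends patients without
reshuffling existing ones, and running both arms with one seed reuses
the same uniforms (common random numbers). It is the package's
brute-force check that the deterministic expectations are right — the
suite requires agreement within 3 Monte-Carlo standard errors at
n = 200,000 for every built-in cohort and both arms — and its
trajectory export is the synthetic patient-level dataset: the model's
hazards are the data-generating process, since the model is fully
parameterized by published summary tables and no patient-level records
exist. What the microsimulation does *not* emulate: between-patient
heterogeneity beyond the admission-count state (no age, sex, comorbidity
or NYHA mixing within a run), time-varying efficacy, or correlated
month-to-month exacerbation risk. Agreement between engine and
microsimulation therefore validates the implementation, not the model's
fidelity to any real population.

## Problem sizes and runtimes

Everything is desk scale: a 60-cycle cohort run is a few thousand
floating-point operations, the full test suite (including the
n = 200,000 microsimulation agreement check) runs in seconds, and the
acceptance script recomputes all headline quantities in under half a
minute on one core.

## Known limitations

- No utility weighting (life years only) and no indirect costs, by
  design of the underlying analysis.
- Constant efficacy across cycles; real programs likely decay.
- Transition probabilities are literature-derived point estimates; the
  published ranges for some cells (e.g. 0.07–0.10 in-hospital death)
  are not sampled — no probabilistic sensitivity analysis.
- The two validation figures depend on accounting choices (see
  calibration notes); the lifetime figure is reproduced to ~7%, not to
  printed precision.
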