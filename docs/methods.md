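# Methods

## Scope and model structure

`diabia` implements a deterministic, cohort-level budget-impact model for
adding a digital-plus-nurse diabetes program to standard of care for type 2
diabetes in the South African private sector, plus the patient-level
clinical outcome computations of the underlying observational study. There
is no patient-level event simulation in the economic model: each scenario
is a mean-HbA1c trajectory applied to a projected treated population.

The model compares two scenarios over 5 years. Costs per scenario-year are

* complication costs: for each of seven complications, HbA1c-adjusted
  annual incidence × treated population × 2021 unit cost per event;
* monitoring costs: per-patient annual monitoring cost × treated population.

The budget impact is the without-minus-with difference per year, its 5-year
sum, and the year-1 difference divided by the year-1 treated population.

## Risk scaling

Each complication class has a single rule: macrovascular risk grows 38% of
baseline per 1 percentage point of HbA1c above 7.0%; microvascular risk
grows 40% per point above 6.5%; below threshold risk is flat. Three
reconstruction choices were genuinely open, and the package adopts the ones
under which the reconstruction is self-consistent with the published
aggregate figures:

* **Linear-additive scaling.** The increments accumulate additively in
  0.1-point steps (3.8% / 4.0% of baseline per step), which is identical to
  the closed form `1 + β·max(0, h − T)` on the 0.1 grid. Geometric
  compounding (`1.38^excess`) is not used; under it the scenario totals are
  not internally consistent with the published aggregates.
* **Year-1 averaging.** Model year 1 is the arithmetic mean of the adjusted
  incidence at the baseline HbA1c and at the 6-month HbA1c — one half-year
  at each level. Years 2–5 hold the 6-month level (the model's explicit
  stability assumption).
* **Literature incidences as threshold-level rates.** The published annual
  incidences (MI 6%, stroke 4%, cardiovascular disease 17%, nephropathy
  25%, retinopathy 15%, foot ulcers/diabetic foot 13%, amputations 3%) are
  treated as the at-threshold baselines that each cohort's multiplier
  scales. Whether the source authors intended this anchoring is not
  documented; it is the reading under which the pipeline reproduces their
  totals.

Excess HbA1c is rounded to the nearest 0.1 before scaling (ties upward,
with a 1e-9 epsilon so decimal inputs stored just below a binary tie still
round up). The adjusted incidence is capped at 1.0; no packaged
parameterisation reaches the cap below HbA1c ≈ 14%.

## Populations and denominators

The treated population of model year *k* is **prevalence(k) +
incidence(k)** — 371,528 patients in year 1 (328,118 + 43,410). This
denominator is used both for scaling events and for the per-patient impact;
it is the only denominator under which the per-patient and market-share
results are simultaneously consistent with the scenario totals. No
discounting, mortality attrition or legacy (glycaemic-memory) effect is
applied; the source model applies none.

## Primary versus calibrated inputs

`parameter_audit()` tags every configuration value `PAPER` or `CALIBRATED`:

* **Calibrated monitoring costs.** The per-item monitoring tariffs behind
  the scenario monitoring totals are not public (national price list plus
  unpublished market research). The packaged `MonitoringProfile`s store
  per-patient annual costs back-derived from the published scenario totals
  over the year-1 treated population: 2.5e9/371,528 ≈ 6,729 ZAR (standard
  of care) and 3.6e9/371,528 ≈ 9,690 ZAR (program scenario). The program
  total appears once in the source as "3.6 million"; it is treated as a
  typo for billion, consistent with the stated 43% increase on 2.5 billion.
* **Fitted inflation series.** The unit-cost table gives source and 2021
  costs per item but not the annual medical-inflation rates used between
  them. The packaged `InflationTable` holds an annual series fitted to the
  endpoint pairs — the 2021 rate from the 2020-sourced item, the 2020 rate
  from the shared 2019-sourced factor, and a constant 2015–2019 rate from
  the 2014-sourced item — with notional source years 2014/2019/2020/2021
  assigned by cited cost source. Compounding this series maps every source
  cost to its published 2021 value within 0.002% (the configuration
  invariant requires 0.5%). The series is a reconstruction, not the
  official statistics series.

All monetary arithmetic is double precision; event counts are real numbers
internally; rounding to whole ZAR or whole events happens only in rendered
tables.

## Sensitivity analysis

The one-way DSA perturbs one input at a time by ±`variance` (default 10%)
multiplicatively, rebuilds the full model, and records the year-1 net
impact per treated patient; items are sorted by descending output range.
The default parameter set is everything scalar the model consumes: the
seven unit costs, seven baseline incidences, four cohort HbA1c levels,
year-1 prevalence and the two monitoring costs (21 inputs). HbA1c levels
are varied multiplicatively like the rest — ±10% of the level — because the
source analysis specifies a uniform 10% variance rather than per-parameter
ranges. For inputs entering linearly (costs, incidences, populations,
monitoring) the output range is symmetric about base to numerical
precision, and the unit-cost shifts admit a closed-form check used in the
tests. The exact parameter list and bar values of the source tornado figure
are not printed and are not reproduction targets.

The equal-baseline scenario sets the standard-of-care cohort to 7.8% → 7.8%
and the program cohort to 7.8% → 7.2%, isolating the program effect from
the baseline difference between the two source cohorts. The market-uptake
scenario scales each year's *deltas* (avoided events and costs, monitoring
difference) by that year's program share (2%, 3%, 4%, 5%, 6%); scaling the
deltas rather than the absolute scenario totals is what the published
uptake figure corresponds to.

## Clinical pipeline

Outcome definitions on patient-level records:

* **Timepoint matching.** A "6-month" value is the measurement of that
  parameter nearest to enrollment + 6 × 365.25/12 days, within ±6 weeks;
  ties resolve to the earlier measurement. The source study reports 3/6/9/
  12-month values without stating its matching rule; the window is
  configurable per call.
* **Target classification.** Judged on the endpoint value alone:
  reached/maintained when the endpoint satisfies the personal target (≤ for
  at-most parameters, ≥ for HDL), else improved when strictly better than
  baseline in the target direction, else not improved; missing when either
  endpoint is absent. Categories partition the paired subset exactly.
* **Adherence.** Per care-plan item, performed events over planned events
  prorated to follow-up (`planned/yr × months/12`), floored at one expected
  event (an annual test falls due at least once in any ≥6-month follow-up)
  and capped at 100% — the source reports per-item adherences of at most
  100%, implying no over-performance credit. The overall figure is the
  unweighted mean over items; zero-frequency items are excluded with a
  warning.
* **Summaries.** Mean/SD/median/IQR with pairwise deletion and explicit
  missing counts; HbA1c bands <7.0 / 7.0–7.9 / 8.0–8.9 / ≥9.0 (band edges
  configurable; the source figure's exact bands are not stated in text); a
  decrease of at least 0.4 points is flagged clinically relevant.

## Synthetic cohort generator

The generator emulates the *summary* structure of the study cohort, with
defaults fixed at the study conditions: n = 117, type 1 fraction 8/117,
baseline HbA1c truncated-normal(7.8, 1.4) on [4.5, 15], 6-month value =
baseline + normal(−0.6, 1.3) floored at 4.0, paired availability 79/117,
and eight care-plan items whose completion probabilities mirror the
reported per-item adherence pattern (labs and consultations 0.98–0.99,
dietetics 0.59, eye screening 0.57, foot screening 0.44). Subgroup
membership is Bernoulli by default; `stratified=True` pins the exact
published denominators (8 type 1, 79 paired) for tests that need exact
counts. Other cardiometabolic parameters (LDL, HDL, systolic pressure) are
sampled independently — their joint distribution is unreported — and exist
to exercise both target directions, not to be marginally realistic.

Two consequences matter for interpreting the tests. First, flooring the
follow-up value at 4.0 raises the realised mean change slightly above the
nominal −0.6 (analytically ≈ +0.04 points, computed by quadrature in the
test oracle); recovery tests therefore compare pipeline estimates against
the generator's *analytic* truncated/clipped means, and separately assert
those analytic means stay within 0.05–0.06 of the nominal values. Second,
the generator induces no correlation between adherence and HbA1c change by
default (the study reports none); a correlation knob exists purely for
stress tests. Passing recovery tests show the pipeline estimates what the
generator encodes — they say nothing about real-world effectiveness of any
program.

Problem sizes in the test suite — recovery at n = 5,000, replicate checks
pooling 300 cohorts of 117 — were chosen as the smallest sizes at which the
3-standard-error recovery bands are meaningfully narrow.

## Reproduction tolerances

The nine desk-scale reproduction checks use ±2% relative tolerance (±3% for
the equal-baseline scenario, whose published figures are more heavily
rounded, and ±10% for the nephropathy figure printed only as "about 22
billion"). The published year-1 total reduction is printed both as a
rounded headline (26 billion, from 117 − 91) and implicitly as 27.5 − 1.1 =
26.4 billion; the internally consistent 26.4 is the comparison value. These
bands absorb the source's display rounding, not model disagreement: the
computed values sit within ~1% of the printed ones except where the print
itself is coarser.

## Known limitations

* Cohort-mean model: no patient-level heterogeneity, competing risks or
  mortality in the economic module; complications recur independently each
  year at the adjusted incidence.
* The standard-of-care and program cohorts come from different source
  populations with different baselines; the equal-baseline scenario bounds,
  but does not remove, the resulting confounding.
* Monitoring costs and the inflation series are calibrated reconstructions
  (above), adequate for reproducing aggregates but not itemisable.
* The synthetic cohort reproduces summary moments and missingness only; it
  has no within-patient longitudinal dynamics, no treatment-effect
  causality, and independent parameters.
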