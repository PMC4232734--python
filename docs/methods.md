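# Methods

## Cohort model

The disease model is a discrete-time Markov cohort with a one-month
cycle and a ten-year horizon (120 cycles), matching the duration of
high-risk follow-up. States: DISEASE_FREE, RELAPSE, POST_RELAPSE,
DEAD. RELAPSE is a tunnel state — occupancy lasts exactly one cycle,
representing the month in which loco-regional relapse is detected and
salvage abdominoperineal resection (with reconstructive surgery)
takes place. POST_RELAPSE mortality equals the relapse-month
mortality: the model does not distinguish salvage from palliative
survivors, so one monthly death probability serves both. The whole
cohort starts disease free, encoding the assumption that curative
primary treatment achieves local control; relapse is possible from the
first cycle. There is no separate background-mortality stream — the
disease-free death probability is calibrated against *all-cause*
mortality and therefore absorbs it.

Mass conservation is maintained to 1e-9 over the full horizon (in
practice to machine precision, ~1e-15; the test suite asserts the
looser bound). With relapse switched off, disease-free occupancy is
exactly geometric, `(1−p_death_df)^t`, which the suite checks to 1e-12.

### Costing conventions

No half-cycle correction: cycle `t` (t = 1..120) is costed on its
start-of-cycle occupancy, with schedule month index `t−1`. This is the
natural reading of a monthly reimbursement model (a month's care is
billed for those alive in it); the convention is isolated in
`accumulate_costs` so a half-cycle variant could be added. Under this
convention a cohort that never leaves disease free accrues exactly
120 monthly payments plus the upfront cost.

Inflation (the second pricing scenario) is a constant annual rate,
default 3.2% — a CPI-level figure for 2011/12 — compounded in whole-year
steps `⌊(t−1)/12⌋`. No discounting in either scenario: the model
estimates realised payments rather than a present value. Total cost is
therefore non-decreasing in the inflation rate (asserted as a
property).

Patients presenting with advanced disease (default 5%) bypass the
curative pathway: they are costed upfront as diagnosis plus a
configurable expected duration of palliative care (default 12 months,
a survival-scale figure for advanced disease) at year-0 prices. The
curative arms (CRT vs RT) are blended by the CRT proportion.

### Follow-up schedule

The follow-up programme (appointments, MRI and CT scans over ten
years; low-risk intensity for the CRT arm, high-risk for RT-alone
patients, who are at greater relapse risk) must be spread over monthly
cycles. The reference timetable is not available, so the package
front-loads it: monthly weights `1/year_index`, uniform within each
year, normalised to conserve the programme total exactly. Only the
total is contractually fixed; the distribution affects results solely
through attrition weighting and inflation timing. Consistent with
clinical practice, most cost falls in the first year after treatment.

The post-relapse monthly cost is memory-less by construction: the
Markov property hides time-since-relapse, so the salvage fraction
accrues the *average* monthly cost of a completed high-risk programme
and the rest accrue the monthly palliative cost. Long-term colostomy
care is excluded.

## Base-case parameters

The configuration schema accepts any base-case value set. The shipped
defaults are **illustrative**: where published one-way bounds exist
the base value is the midpoint (diagnostics, chemotherapy and
radiotherapy delivery items, follow-up intensities); the
admission-dependent primary-treatment cost table uses the published
admission-type bounds as its day-case (lower) and non-elective (upper)
rows with midpoints for elective inpatients; the remaining unit costs
(follow-up appointment £130, salvage APR £8,000, reconstruction
£2,500, colostomy £3,500, palliative £1,000/month) are plausible
2010/11 tariff-scale values. Pathway proportions: 85% CRT, 5% advanced
presentation, 50% salvage on relapse, 5% pre-treatment colostomy, 25%
FNA, and an admission mix of 52% elective inpatient / 33% day case /
15% non-elective (85% elective overall). Proportion-type sensitivity
bounds are not published and ship as roughly ±50% around base.
Headline totals from this configuration are therefore indicative of
scale, not reproductions of any published base case; the structural
behaviour (scenario ordering, tornado ordering, phase structure) is
what the tests pin down.

Default monthly probabilities (0.005 relapse, 0.004 death disease
free, 0.030 death post relapse) produce ten-year cumulative all-cause
mortality ≈ 0.59 and cumulative relapse ≈ 0.37, in the range of
published long-term trial outcomes for anal cancer; they seed the
default synthetic calibration target.

## Calibration

The estimator is an iterative batch random search: 1,000 triples per
round drawn within the current ranges, scored by the summed squared
deviation of both model curves from the target at the target months
(equal weighting; every target month used), then the ranges are
re-determined around the round's best fit. Batch evaluation is
vectorised over triples, so a full calibration is milliseconds.

Two numerical refinements proved necessary. First, recentring on the
single best triple and halving the range width each round can collapse
the weakly identified post-relapse death probability around an early
wrong value, after which the truth lies outside every later range. The
new width is therefore floored at the spread of the round's best 5% of
triples: well-identified directions contract geometrically (factor
0.5/round) while weakly identified ones stay open until the rest of
the space pins them down. Second, 30% of each batch after the first is
drawn from a Gaussian around the incumbent (per-axis sd = range
width/10), which reliably refines the incumbent and prevents chance
stalls from masquerading as convergence. The stopping rule — best
objective unchanged at three significant figures — must accordingly
persist for three consecutive rounds. With batch size 1,000 and at
most ten rounds this recovers each probability of a noiseless
synthetic truth within ±0.002 on 199 of 200 seeds (the one miss is a
slow-convergence case at 0.006).

Identifiability: the mortality curve alone cannot separate the two
death probabilities (they trade off through the relapse fraction); the
joint fit with the relapse curve can. The suite demonstrates this by
fitting mortality only, with the true relapse rate excluded from the
search range: the fit is still near-perfect on mortality while the
implied relapse curve is materially wrong.

## Episode costing pipeline

Filtering keeps inpatient records with an anal cancer code in any of
the first three diagnosis positions and outpatient records in the
first two (post-treatment outpatient coding is more disease-specific).
Invasive codes take precedence over the in-situ code when both appear.
Codes failing the ICD-10 shape (letter + two digits + optional
third character) are excluded with a logged warning.

The proprietary HRG4 grouper is replaced by a transparent rule, and
outputs are flagged accordingly in the run manifest: FCEs of one
patient and provider whose half-open `[admission, discharge)` windows
overlap or touch merge into one spell; ties are broken by scanning in
admission order (earliest admission defines the spell); the spell's
core HRG is the first FCE's. Spell price = admission-type tariff price
+ `max(0, length_of_stay − trim_point)` excess bed days at the HRG per
diem; unbundled codes are priced from reference costs and tagged
chemotherapy/radiotherapy/other by code prefix (SB/SC) — a documented
simplification of the real unbundling rules. Annual summaries
stratify by year × sex × invasive/in-situ × setting; a partial
reporting year has costs, events and patient counts scaled (default
×1.33 for nine months, assuming no seasonality), which leaves cost per
patient unchanged; strata with zero patients report cost per patient
as absent, not zero. Study-period means divide mean annual cost by
mean annual patient count.

## Synthetic data

The synthetic generator emulates the *structure* of a national
episode extract and its headline descriptives — roughly three spells
per inpatient-year, four-day mean stay, 85% elective admissions of
which 33 percentage points are day cases, ~10%/3% of elective/
non-elective spells with excess bed days, ~10% in-situ diagnoses, and
unbundled chemotherapy/radiotherapy on ~11.5%/8% of spells — with no
claim of reproducing national totals. Spell and attendance counts are
Poisson and stays geometric (the simplest distributions consistent
with reported means, with closed-form expectations); when an
excess-bed-day event is drawn, the stay is set to the trim point plus
a geometric excess so recomputed excess days equal the drawn value and
ground-truth expectations stay closed-form. Spells sit in disjoint
~monthly windows so the grouper cannot spuriously merge them, and a
fraction of spells is split into two contiguous FCEs to exercise
FCE-to-spell aggregation. `count_model="fixed"` / `los_model="fixed"`
switch to deterministic counts for exact-oracle tests.

What passing tests do and do not show: agreement with the generator's
ground truth validates the pipeline's arithmetic and aggregation
logic, not its behaviour on real extracts, which feature coding
errors, missing fields, cross-provider transfers, re-admissions inside
a window, and HRG mixes far richer than the three illustrative codes
in the shipped synthetic tariff (whose prices are synthetic, not the
national tariff).

## Problem sizes and tolerances

The test suite runs the full 120-cycle model throughout; property
tests use 50 hypothesis examples or 100 random triples; calibration
tests use batches of 1,000 and ≤10 rounds; the stochastic
episode-pipeline oracle uses 10,000 patients over three study years
(~150,000 records) with a fixed seed, compared within three
cluster-robust (patient-level) standard errors. Trace row sums are
asserted to 1e-9, closed-form survival to 1e-12, oracle equivalence to
1e-9 relative, and the hand-costed fixture to the penny.

## Known limitations

- The shipped base-case values are illustrative; headline totals move
  with them. All structural conclusions asserted by the tests are
  invariant to the base values within the published bounds.
- No toxicity/adverse-event costs, no high-cost drugs (excluded from
  tariff reimbursement), no QALYs or discounting, no probabilistic
  sensitivity analysis.
- The spell grouper and unbundled-code tagging are documented
  emulations of NHS grouping software.
- The advanced-presentation branch is costed upfront rather than
  modelled as a Markov state, so its palliative duration is an
  expectation, not a survival process.
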