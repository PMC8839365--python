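# Methods

This note documents the models and procedures implemented in
`pasturewatch`, the parameters that matter, the design decisions taken
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Synthetic cow-day generator

The generator emulates a rotational grazing experiment in which paddock
allowance is restricted to 80% of the herd's requirement so that herbage
becomes scarce towards day 6 of each six-day cycle.

**Herd.** Cows are drawn with body weight ~ N(626, 64²) kg, daily milk
yield ~ N(29.1, 6.3²) kg, BCS ~ N(2.8, 0.4²) rounded to the 0.25 scoring
grid, days in milk ~ N(142, 44²), a 35% primiparous share, and a 60%
gestation share. Group assignment alternates A/B within each
grazing-experience stratum, starting each stratum with the currently
smaller group, so group sizes and experience counts are balanced within
one cow for any herd size.

**Cow-days.** Each behavioral variable is generated as

    value = base mean + cow intercept + day-curve offset + day noise,

with the cow intercept ~ N(0, cow SD) drawn once per cow and the day
noise ~ N(0, day SD) independent per cow-day. The default day curves
encode the qualitative course observed under gradual herbage decline:
bite frequency rises from ~46 to ~54.6 n/min between days 1 and 6 (48.8
on day 2), the rumination and eating variables start high on day 1 — ad
libitum hay is offered in the barn on the first cycle day — and fall
towards day 6 with the steepest steps late in the cycle (e.g. roughly
−1900 rumination chews and −26.5 min rumination time from day 4 to 5),
while rumination chews per bolus, head activity, and lying bouts drift
without a consistent direction. The hay-driven day-1 elevation can be
switched off (`hay_day1_effect=False`), which flattens day 1 onto day 2
for the eating-related variables.

**Milk and rumen fill.** Milk is generated per cow and cycle for days
1..7 as `mean yield × (1 + relative day offset + relative noise)`; the
default offsets decline to −11.5% by day 6, and the day after the cycle
continues the slope of the last two days because yield keeps falling for
about one day after a feed restriction ends. Day-to-day relative noise
defaults to 5.5%, chosen so the baseline variability is of the order of
the ~6% relative SD such herds show. Rumen fill is a latent Gaussian
(cow base ~ N(3.7, 0.4²), day noise SD 0.35, day offsets declining to
−0.8 by day 6) rounded to the 0.5-step visual scale and clamped to
[1, 5]. An optional per-cow-day dropout probability (default 0) emulates
estrus/illness/missing-data exclusions.

**Training set.** Two-class feature tables (defaults 629 sufficient /
592 scarce) are Gaussian location-shift families per variable: under
scarcity, bite frequency and head activity shift up, the rumination,
eating, and lying variables shift down, with shifts of roughly 1–1.5
within-class SDs per variable, representing a pronounced (40%-level)
restriction contrast. Rows are i.i.d.; within-cow correlation of the
real training data is *not* emulated (see Limitations).

## Paddock allocation

Calibration of the rising plate meter is an OLS line of herbage mass
(kg DM/ha) on compressed sward height (mm), fitted per month from 9–15
clipped plots. Available herbage above the 20 mm residual-sward floor is
computed by differencing the line at the pre-grazing height and at the
floor — a choice that avoids extrapolating the intercept — and clamped
at zero. The paddock area is cycle demand over net supply per hectare:

    area = allowance × requirement × n_cows × days
           / [(1 − loss) × (available HM/ha + regrowth × days)]

with defaults: allowance 0.8 (a 20% restriction), loss 0.10 for
trampling and rejected patches, regrowth 90/60/30 kg DM/ha/day for
May/July/September, requirement 11.3 kg DM/cow/day on pasture. The 10%
loss is applied to standing herbage *plus* regrowth; whether regrowth
should be included is ambiguous, so the factor placement is documented
here and both terms are configurable. The barn side of the budget is
5.7 kg DM hay + 3.1 kg DM corn pellets = 8.8 kg DM/cow/day.

## Daily feature aggregation

Hour-based rates (bite frequency, chews per bolus, head activity) are
averaged over the hours of a day with equal weights (the converter
already normalizes within the hour); counts and durations (rumination
chews, rumination time, eating bouts, lying bouts) are summed; the mean
rumination bout length is daily rumination time over the number of bouts
started. Missing hourly values are skipped in means and count as zero in
sums. Positive rumination time with zero detected bouts is an error, not
a silent zero. The day boundary is the experiment's clock midnight.
Days with less than 117 min of daily rumination time — below the
plausible minimum for lactating cows — are removed; the comparison is
strict, a day at exactly 117 min is kept. Pasture/barn splits apply the
same rules within each location subset, so sum-type variables decompose
exactly.

## Reference classification

* Day attribution: day-grazing months evaluate grazing day *d* with the
  milk of day *d* + 1; night-grazing months use same-day milk. The
  generator emits the next day's milk alongside each cow-day; externally
  supplied tables may instead carry day-7 rows, which the attribution
  handles by shifting within each cow-cycle.
* Baselines: rumen = mean score of days 1–2; milk = mean attributed
  yield of days 2–3. A missing or excluded baseline day makes the
  cow-cycle unlabelable for that indicator.
* Limits: per cow × month, the SD over the four baseline-day values
  (2 days × 2 cycles); milk SDs are expressed as percent of the
  cow-month mean. Milk relative SDs above Q3 + 3·IQR are excluded as
  outliers — a reproducible stand-in for the visual outlier screening
  such campaigns use — with the excluded count logged. The limit is
  k = 3 times the average SD; limits are global (averaged over cow-
  months), not per cow.
* Classes: on days 3–6, a decline *strictly* beyond the limit is scarce
  (class 1); a decline exactly at the limit, any increase, and the
  baseline days 1–2 are sufficient (class 0). Under the 3-SD construction
  a no-effect day is positive with probability ≈ 0.13%, which the null
  calibration test verifies at ≤ 1% on > 10,000 simulated null cow-days.
* Combination: a cow-day is combined-positive if either indicator is
  positive; a cow-day carried by only one indicator uses that indicator
  alone.

## Classifiers

The GLM is a binomial likelihood with logit link fitted by maximum
likelihood (IRLS); complete separation is flagged, not fatal. The random
forest uses 500 trees and sqrt(p) candidate variables per split — the
canonical defaults of the standard implementations — with out-of-bag
accuracy recorded and a fixed seed for determinism. Predictions use the
0.5 probability threshold; a probability of exactly 0.5 maps to the
negative class, the conservative choice for a warning system. The
reduced predictor set drops rumination chews per bolus, head activity,
and lying bouts. Models are trained once and never refitted on test
data.

## Evaluation

Confusion counts treat class 1 (scarce) as positive. Ratios with a zero
denominator are reported as explicitly undefined rather than 0 or 1.
AUC is computed as (sensitivity + specificity)/2: for a hard 0/1
predictor the ROC polygon has a single interior vertex, so its exact
area is the balanced accuracy; a probability-ranked AUC (`ranked_auc`)
exists for probabilistic predictors. Subgroup evaluation uses fixed cow
attributes (parity 1 / > 1; grazing experience; milk > 27, 20–27,
< 20 kg/day; gestation; BCS ≥ 3.25, 2.75–3.00, ≤ 2.5) with mutually
exclusive, exhaustive bands; membership is fixed per cow, and empty
subgroups are omitted with a warning.

## Day-trend model and predictor screening

Per variable, a linear mixed model is fitted by REML: fixed effect of
cycle day as a natural cubic regression spline with 5 degrees of freedom
(boundary knots pinned at days 1 and 6, internal knots at days 2–5 — on
six day levels this basis is saturated, so fixed-effect predictions are
adjusted day means), a random intercept per cow, and a random day slope
per paddock. The two crossed random factors are expressed as variance
components on a single trivial grouping; on non-convergence the model
falls back to a cow-intercept-only fit and, failing that, to OLS on the
spline basis, with the fallback recorded in the result. Paddock 1 is
excluded by default (its cows avoided rain-soiled herbage, distorting
the trend). Day-wise 95% confidence intervals come from the fixed-effect
covariance.

The relevance screen is necessarily an operationalization of a verbal
criterion: a variable is relevant iff its estimated trajectory over the
last four cycle days is monotone in one direction *and* the final
estimate lies outside the confidence interval of the first of those
days (both parts configurable). On day-mean fixtures reproducing the
qualitative trends above, the screen excludes exactly rumination chews
per bolus, head activity, and lying bouts.

## Pipeline

`run_pipeline` chains the seven stages (simulate, features, label,
train, predict, evaluate, trends), writes flat CSV artifacts and a JSON
manifest (configuration, SHA-256 configuration hash, seeds, package
version, per-stage file lists), and aborts with a stage-tagged error and
partial manifest on failure. All randomness flows from the configured
seed (herd: seed; training set: seed + 1; forest: seed + 2), so
identical configurations reproduce byte-identical CSVs.

## Problem sizes

The test suite exercises the default 720-cow-day design; the null
calibration of the reference labels uses a 10,800-cow-day no-effect
herd (300 cows); GLM parameter recovery uses n = 5000; the forest
checks use 600-record training sets with 200 trees. The acceptance
script runs the default 720-cow-day pipeline once. The full suite
completes in well under a minute on one CPU.

## Limitations

* The generator is a location-shift Gaussian model: it reproduces means,
  SDs, and the qualitative day trends, not the joint distribution,
  skewness, or autocorrelation of real sensor data. Passing tests
  demonstrate internal correctness and statistical calibration of the
  pipeline, not field performance of the classifiers.
* Training rows are i.i.d.; repeated measures per cow are not simulated,
  so standard errors of the classifier fits are optimistic relative to a
  real 40-cow campaign.
* Absolute classifier performance (Table-style sensitivity/specificity
  against the references) depends on the real training and test
  datasets, which are not bundled; the package therefore verifies the
  classifier path by oracle equivalence, parameter recovery, and null
  calibration rather than by reproducing published performance values.
* Interior knot placement follows the stated boundary-knot convention;
  with six day levels the basis is saturated and the placement is
  immaterial, but for other designs the default (integer interior days)
  is a convention, not the only choice.
* The exclusion breakdown behind real-world attrition (estrus, illness,
  sensor failure) is modelled as a single generic dropout probability.
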