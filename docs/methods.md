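# Methods

`ursactive` implements an activity-budget analysis for bears wearing GPS
collars with dual-axis tip-switch motion sensors. Each collar records, every
5 minutes, the summed number of switch closures of two perpendicular sensors
(each capped at 255, so a sample lies in 0–510 switches). The pipeline turns
those counts into active/inactive states, bouts, daily and seasonal activity
summaries, and mixed-effects tests of seasonal and thermal hypotheses. A
synthetic-data generator with full ground truth drives every test.

## State classification

The 5-minute switch-count distribution of a collared bear is bimodal: a pile
at and near 0 from resting animals and a broad mode (per-bear mean roughly
90–190 switches) from active ones. The threshold separating the modes is
derived from the data, per bear, as the minimum of the smoothed count
histogram between the two modes, then pooled across bears:

1. exact 511-bin histogram per bear;
2. centered moving-average smoothing, bandwidth 5 switch values, reflected
   at the edges — raw 511-bin histograms are noisy at per-bear sample sizes
   (tens of thousands of samples spread over 511 bins). The bandwidth is
   exposed in the API and recorded in the output metadata;
3. valley = argmin of the smoothed histogram inside the search window
   [11, 89], ties to the smallest value. The window default brackets the
   region between the inactive pile and the lowest reported active mode;
4. pooled threshold = arithmetic mean of per-bear valleys, rounded
   half-to-even.

A sample is **active iff its count strictly exceeds the threshold**; ties
count as inactive. A fixed preset of 41 (the video-calibrated Asiatic
black-bear convention: 0–41 inactive, ≥42 active) is available as a
constant for comparison. Per-bear thresholds can be used instead of the
pooled value by classifying each bear with its own valley.

## Interruption smoothing and bouts

Long bouts are often broken by 1–3 samples (5–15 min) of the apparent
opposite state — a bear shifting in its bed or pausing on a trail. The
smoothing rule flips any maximal run of ≤ 3 samples whose neighbouring
opposite-state run on at least one side holds ≥ 12 samples (1 hour); runs of
4+ samples are never altered. Design choices:

* **Fixpoint sweeps.** The rule is applied left-to-right and repeated until
  no run qualifies. Because a flip only merges runs (flanks only grow, and
  a qualifying run keeps qualifying), the qualifying set grows monotonically
  and the fixpoint is unique; the test suite verifies equality with a naive
  leftmost-first restart oracle over all 2^16 binary sequences of length 16
  (flank threshold scaled to 4 samples to make enumeration meaningful at
  that length).
* **"Before, after or both".** One qualifying flank suffices by default; a
  `require_both_flanks` flag gives the strict reading. A run touching a
  block edge qualifies on its single interior flank in either mode.
* **Gaps.** Sampling gaps (hibernation, the post-capture week, excluded
  days) split a bear's record into blocks; flanks never span a gap, since an
  unobserved hour cannot certify bout continuity.

Bouts are maximal same-state runs within a block; `duration_h` =
n_samples × 5/60, so durations tile each block exactly. Bouts abutting a
block edge are censored and flagged `truncated`; they are excluded from
mean-bout-length summaries by default (flag to include).

## Solar time

Solar events (sunrise/sunset at zenith 90.833°, civil twilight 96°, nautical
twilight 102°) are computed with the NOAA solar-position equations plus one
refinement pass at the first-pass event time, which agrees with an
independent Meeus-style altitude-bisection oracle to within 4 seconds over a
full year at the study site (50.6° N, 122.5° W). The six daily periods —
day, evening twilight, evening nautical, night, morning nautical, morning
twilight — are half-open [start, end) intervals, so the 288 daily samples
partition exactly; night wraps to the next day's nautical dawn. Pooling maps
civil twilights to day and nautical twilights to night. All timestamps are
fixed local standard time (UTC−8 by default, configurable); avoiding DST
removes 23/25-hour days. Latitudes poleward of 60° are rejected rather than
given degenerate twilight times. The daylight covariate is the span between
civil twilights in hours.

## Seasons, exclusions, bear-weeks

Three foraging seasons surround each bear's individually delineated berry
window: herb-bulb from the spring floor (22 May) to the day before
`berry_start`; berry with both boundary days inclusive; post-berry through
the autumn ceiling (22 Oct). Samples outside the guards are `excluded`.
Additional exclusions: all samples within 7 × 24 h of a capture, and every
sample of any day the bear came within 500 m of settlement (whole days, via
per-day flags). Exclusions drop rows — nothing is zero-filled, so excluded
time can never leak into an activity budget. An accounting helper asserts
retained + excluded = input.

The sampling unit of the seasonal models is the bear-week: consecutive 7-day
blocks anchored at 1 January (deterministic, calendar-aligned). A week
enters the weekly table only if *complete* — 7 days, each with all 288
samples, none excluded, all in one season — so `hours_active_per_day`
always equals 24 × the week's active fraction. Mean bout lengths per week
cover uncensored bouts starting in the week.

## Models

* **Weekly LMM** (response: hours active/day, or mean active/inactive bout
  length): fixed effects civil-daylight hours, sex, season, sex × season;
  random intercept per bear; REML. Reference levels are female and
  herb-bulb, so `season[T.berry]` is the berry-vs-herb-bulb contrast for
  females.
* **Period LMM**: response arcsin√(proportion active) per
  bear × season × period; fixed effects period, season, sex,
  period × season; random intercept per bear; reference period is day.
* **Temperature regression**: OLS of arcsin√(daily 24-h activity
  proportion) on daily maximum temperature, per bear-day.
* **Warm/hot comparison**: distinct days sorted by maximum temperature and
  split into equal halves (ties broken by date; an odd day count raises
  unless `on_odd="drop_median"`); response arcsin√(proportion active) per
  bear × day × pooled period; the term of interest is the
  category × pool interaction.

The "arcsine of the proportion" is implemented as the variance-stabilizing
arcsin√p (the standard usage for proportion data in ecology); a plain
arcsin p variant is available behind a flag since the phrase is ambiguous.
P-values are Wald normal-approximation tests from the statsmodels REML fit.
With the bear-week and bear-period sample sizes used here (hundreds of
observations, 19 groups) these are close to
denominator-degrees-of-freedom-corrected (Satterthwaite) values, and the
weekly model's coefficients are cross-checked against an independent REML
backend (lme4 via Rscript) to 10⁻³ in the test suite; exact Satterthwaite
small-sample corrections are out of scope. Singular or non-converged fits
are reported via `ModelFit.warnings`, not raised.

## Synthetic data

The generator produces bear-years whose statistical structure matches what
the pipeline assumes, with known ground truth. What it emulates:

* **Alternating renewal bouts.** Exponential durations with season × state
  mean scales. Defaults (h): active 3.9 / 6.2 / 5.0 and daytime inactive
  1.0 / 0.9 / 1.2 for herb-bulb / berry / post-berry. Active scales follow
  empirical seasonal bout means for grizzly bears; inactive scales were set
  once from the renewal identity (daytime active fraction =
  s_a/(s_a + s_i)) so realized activity lands near observed levels
  (~13–15 h/day, higher in the berry season). Exponential durations are an
  assumption — field studies report only mean bout lengths, not duration
  distributions — chosen as the simplest renewal process reproducing the
  means.
* **Diurnal modulation.** A 24-entry hour-of-day propensity acts twice: a
  proposed active bout starts with that acceptance probability (rejection
  extends the rest), and a running active bout survives each hour boundary
  with the same probability. The default profile (1.0 midday, ~0.8/0.45 in
  the dusk hours, 0.02–0.10 at night) was chosen once from the same renewal
  identity to reproduce observed period activity levels (~78% day, ~75%
  evening twilight, ~40% nautical, ~10–14% night). Males get active scales
  × 0.85 and inactive scales ÷ 0.85, making them roughly 1 h/day less
  active. A zero-propensity hour is a hard curfew: no activity can occur in
  it, by construction.
* **Emissions.** Inactive: point mass 0.60 at zero, decaying pile over
  1–10, and a thin 2% uniform tail up to a per-bear support edge. Active:
  per-bear normal, mean ~ U[90, 190], sd 12, rounded and clipped to
  [0, 510]; under the defaults < 0.1% of active samples emit ≤ 36 switches,
  so states are recoverable from counts. Each bear's ground-truth valley is
  the argmin of the bandwidth-smoothed exact mixture pmf — the same
  functional the estimator targets — and the per-bear support edges are
  drawn so valleys land at 36 ± 5.
* **Interruptions.** Each bout of ≥ 27 samples carries, with probability
  0.5, one opposite-state interruption of length 1/2/3 with probability
  0.70/0.18/0.12, placed to leave ≥ 12 consistent samples on each flank.
  This reproduces the observed prevalence in field-verified bouts (half
  interrupted; ~70% of interruptions single-sample) and guarantees the
  smoothing rule can revert every injected interruption exactly.
* **Seasons, gaps, weather.** Per-bear berry windows drawn uniformly
  (start Jul 6–Aug 25, end Sep 7–Oct 12); the first post-capture week is a
  gap of absent rows; daily maxima follow a latent AR(1) (autocorrelation
  0.6) mapped through the normal CDF into [20.4, 40.1] °C, minima 8–16 °C
  lower.

What it does **not** emulate: within-bout autocorrelation of switch counts,
emission drift with behaviour type (feeding vs travelling), GPS location
structure (settlement proximity enters only as per-day flags), collar
failure, partial days, or multi-year records. Passing tests therefore show
the pipeline recovers the structure it assumes — threshold, states, bouts,
seasonal contrasts — not that real collars satisfy those assumptions.

Two lightweight generators back the model tests at the aggregate level:
`simulate_weekly_summaries` (weekly tables with known fixed effects and a
bear random intercept) and `simulate_temperature_day_records` /
`simulate_pool_records` (bear-day proportions with or without temperature
effects). Identical config + seed give identical output everywhere,
including byte-identical fixture files.

## Problem sizes and numerical choices

The default simulated study is 19 bears (10 F, 9 M) over 1 May – 31 Oct
2006 (~0.96 M samples), which the full pipeline processes in well under a
minute. Test harnesses use: 5 bears × 70 days for end-to-end recovery
checks; 19 bears × 60 days for threshold recovery; 50 replicates of
20 bears × 30 weeks for berry-effect recovery (truth inside the 95% Wald
interval in ≥ 45/50); 1000 zero-effect replicates for the null calibration
of both temperature tests (rejection 5% ± 2% at α = 0.05); and exhaustive
enumeration of all 2^16 length-16 sequences for the smoothing oracle.

Tie-breaks and degenerate inputs: histogram valley ties go to the smallest
switch value; a histogram with no mass in the search window and mass on only
one side raises a degenerate-distribution error; warm/hot median ties are
resolved by date order; a constant response in the temperature regression
returns slope 0, r² 0, p 1 rather than 0/0.

## Known limitations

* Realized bout means in the simulator differ from the configured scales
  (dusk truncation shortens active bouts; night rejection lengthens rests);
  the scales are renewal parameters, not predictions of the realized means.
* Wald p-values are anti-conservative for very small group counts; with
  < ~10 bears, treat borderline p-values with care or refit in lmerTest.
* The hour-based diurnal profile does not track seasonal dawn/dusk
  movement, so morning-twilight activity is less sharply aligned to the sun
  than in real records.
* The solar computation targets |lat| < 60°; high-latitude persistent
  twilight is out of scope.
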