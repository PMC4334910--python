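# ursactive

Activity-budget analysis for bears collared with dual-axis tip-switch motion
sensors, for movement ecologists working with biologging actigraphy. A
collar records, every 5 minutes, the summed switch count of two
perpendicular sensors (0–510). `ursactive` turns those counts into states,
bouts and seasonal activity budgets, and fits the standard mixed-effects
tests of foraging-season and hot-weather hypotheses:

* **Threshold classification** — the count distribution is bimodal (a pile
  at 0 from resting bears, a broad mode with per-bear mean ~90–190 from
  active ones); the active/inactive cut is the data-derived valley between
  the modes, per bear, pooled across bears. Active ⇔ count > threshold.
* **Interruption smoothing & bouts** — maximal runs of ≤ 3 samples flanked
  by ≥ 1 h (12 samples) of the consistent opposite state are flipped to the
  bout that bounds them; maximal runs become bouts with exact durations.
* **Solar day-periods** — NOAA solar events split every day into day,
  morning/evening civil twilight, morning/evening nautical twilight, and
  night; civil twilight pools with day, nautical with night.
* **Seasons & bear-weeks** — herb-bulb / berry / post-berry seasons around
  per-bear berry windows inside 22 May – 22 Oct guards; capture-week and
  settlement-day exclusions; complete 7-day bear-weeks as sampling units.
* **Models** — weekly LMM (hours active/day or bout length ~ daylight +
  sex + season + sex:season, random intercept per bear, REML); period LMM
  on arcsin√ proportions; OLS of daily activity on maximum temperature; and
  a warm/hot × day/night interaction LMM.

A synthetic-data generator (`ursactive.synthetic_data`) produces bear-years
with known ground truth — states, emission parameters, berry windows,
injected interruptions, AR(1) weather — so that every stage of the pipeline
is tested against what it should recover.

## Worked example

The `analysis/` drivers run the full chain on a simulated study of 19 bears
(10 F, 9 M) over one active season:

```bash
cd analysis
python 01_simulate_dataset.py
python 02_derive_threshold.py
python 03_smooth_and_segment.py
python 04_annotate_time.py
python 05_weekly_summaries.py
python 06_seasonal_models.py
python 07_temperature_tests.py
```

Step 02 recovers the classification threshold from the count histograms:

```
per-bear valleys span 31-41 switches; largest |estimate - truth| = 0
pooled threshold: 37 switches (ground-truth mean valley 36.84)
classification error vs ground truth at that threshold: 0.0025%
```

Step 03 applies the smoothing rule and reverts every injected interruption:

```
smoothing flipped 13,700 samples: +1.20% inactive time, +1.61% active time, net +0.57% active time
injected interruptions reverted: 100.0% of 8,020
extracted 21,437 bouts (21,399 with uncensored durations)
```

Step 05 aggregates to complete bear-weeks and daily periods — bears are
most active in the berry season and strongly diurnal:

```
complete bear-weeks: 193 female, 173 male
mean hours active per day (complete weeks):
season      sex
berry       F      14.19
            M      13.58
herb_bulb   F      12.95
            M      11.88
post_berry  F      12.85
            M      11.73
grand mean proportion of time active by daily period:
day                 77.0
evening_nautical    61.8
evening_twilight    73.0
morning_nautical    21.1
morning_twilight    33.4
night               13.5
```

Step 06 fits the seasonal models (berry vs herb-bulb contrast for females,
hours active/day):

```
berry vs herb-bulb, hours active/day: beta = 1.06 (SE 0.20, p = 1.7e-07)
male vs female: beta = -1.06 (SE 0.15)
night vs day, arcsine proportion active: beta = -0.83 (SE 0.02, p = 2.3e-279)
```

and step 07 runs the hot-weather tests on a simulated open-mountainside
subset (3 bears, ~97 days, daily maxima 20.4–40.1 °C) with no built-in
temperature effect, so both tests should come out null up to the nominal
false-positive rate:

```
daily tmax vs 24-h activity (n = 97 days x 3 bears): r^2 = 0.014, p = 0.045
warm/hot x day/night interaction: beta = -0.015 (SE 0.021, p = 0.476)
```

Summary tables (weekly summaries, period proportions, mean bout lengths,
model coefficient tables) are written under `results/`; bulky intermediates
(raw simulated tables, the full bout list, cached state series) go to
`scratch/`.

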