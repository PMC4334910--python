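"""Synthetic bear-years of 5-minute tip-switch activity data.

The generator emulates the statistical structure the analysis pipeline
assumes, with fully known ground truth:

* **Two-state renewal process.**  Each bear alternates active and inactive
  bouts with exponentially distributed durations whose means depend on
  season and state (season x state scales; empirical seasonal means from
  collared grizzly bears are the defaults).  Diurnal structure comes from an
  hour-of-day propensity profile applied twice: a proposed active bout is
  accepted with the propensity at its start hour (rejection extends the
  inactive stretch), and a running active bout survives each hour boundary
  with the propensity there.  Nights therefore accumulate long rests, days
  carry most activity, and zero-propensity hours contain no activity by
  construction.
* **Bimodal switch-count emissions.**  Inactive samples draw from a
  zero-piled discrete mixture (mode at 0, decaying pile over 1-10, a thin
  uniform tail up to a per-bear support edge); active samples draw from a
  per-bear truncated normal with mean in [90, 190] and sd 12, so fewer than
  0.1% of active samples fall at or below the mid-thirties.  Each bear's
  ground-truth valley is the argmin of the bandwidth-smoothed exact mixture
  pmf — the same functional the threshold estimator targets — and the
  per-bear valley parameters are drawn so valleys land at 36 +/- 5.
* **Interruptions.**  Long bouts are interrupted by 1-3 samples of the
  opposite state (a bear shifting in its bed, pausing on a trail), always
  leaving at least 12 consistent samples on each flank so the smoothing rule
  can provably recover them.  With the default rate, half the eligible
  bouts carry an interruption, 70% of them single-sample.
* **Seasons and gaps.**  Each bear gets an individual berry window (start
  uniform on Jul 6 - Aug 25, end on Sep 7 - Oct 12).  The first week after
  capture is a sampling gap (absent rows), as are hibernation days outside
  the simulated span.
* **Weather.**  Daily maximum temperature is an AR(1) latent series mapped
  into a configured range (default 20.4-40.1 C); minima sit 8-16 C below.

Identical config + seed give identical output, including byte-identical
fixture files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as _date
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats
from .io_formats import MAX_SWITCHES, SAMPLE_MINUTES
from .state_classification import DEFAULT_BANDWIDTH, DEFAULT_WINDOW, smooth_histogram
from .temporal_stratification import SeasonCalendar, season_of_dates

SAMPLES_PER_DAY = 24 * 60 // SAMPLE_MINUTES

#: Hour-of-day activity propensity: the probability that a proposed active
#: bout starting in hour h is accepted, and the per-hour-boundary
#: continuation probability of a running active bout.  Chosen once from the
#: renewal-fraction formula so active fractions by daily period approximate
#: observed grizzly values (about 78% by day, 47% in nautical twilight, 9%
#: at night for a mid-latitude summer in local standard time).
DEFAULT_DIURNAL_PROFILE = (
    0.02, 0.02, 0.02,        # 00-02  night
    0.10,                    # 03
    0.50, 0.80,              # 04-05  dawn twilights
    0.95,                    # 06
    1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,  # 07-18 day
    0.95,                    # 19
    0.80, 0.45,              # 20-21  dusk twilights
    0.10, 0.03,              # 22-23  night
)

#: Mean bout duration (hours) by season and state for the renewal process.
#: Active scales follow empirical seasonal means; inactive scales are the
#: *daytime* renewal scales — realized inactive bouts are longer because
#: rejected and truncated nighttime activity extends them into full-night
#: rests.
DEFAULT_BOUT_SCALE_H = {
    "herb_bulb": {"active": 3.9, "inactive": 1.0},
    "berry": {"active": 6.2, "inactive": 0.9},
    "post_berry": {"active": 5.0, "inactive": 1.2},
}

INTERRUPTION_LENGTH_PROBS = {1: 0.70, 2: 0.18, 3: 0.12}
MIN_FLANK_SAMPLES = 12  # 1 hour of consistent state on each side


@dataclass(frozen=True)
class InactiveEmissionSpec:
    """Discrete inactive-count distribution: point mass at zero, a decaying
    pile over 1..pile_top, and a thin uniform tail up to ``support_max``."""

    p_zero: float = 0.60
    pile_mass: float = 0.38
    pile_decay: float = 0.72
    pile_top: int = 10
    tail_mass: float = 0.02

    def pmf(self, support_max: int) -> np.ndarray:
        """Exact pmf over 0..support_max.

        The default valley range keeps the edge at or below 38 (inactive
        support within 0-40); configured edges up to 80 are allowed but must
        stay below the active mode.
        """
        if not (self.pile_top < support_max <= 80):
            raise ValueError(f"inactive support edge {support_max} outside ({self.pile_top}, 80]")
        p = np.zeros(support_max + 1)
        p[0] = self.p_zero
        pile = self.pile_decay ** np.arange(1, self.pile_top + 1)
        p[1:self.pile_top + 1] = self.pile_mass * pile / pile.sum()
        p[self.pile_top + 1:] = self.tail_mass / (support_max - self.pile_top)
        return p / p.sum()


@dataclass(frozen=True)
class ActiveEmissionSpec:
    """Per-bear truncated-normal active counts: mean drawn uniformly from
    ``mean_range``, common sd, truncated to [0, 510]."""

    mean_range: tuple[float, float] = (90.0, 190.0)
    sd: float = 12.0

    def pmf(self, mean: float) -> np.ndarray:
        """Exact discretized pmf over 0..510 (integer counts by rounding)."""
        edges = np.arange(-0.5, MAX_SWITCHES + 1.5)
        cdf = stats.norm.cdf(edges, loc=mean, scale=self.sd)
        p = np.diff(cdf)
        p[0] = cdf[1]  # clip below 0
        p[-1] += 1.0 - cdf[-1]  # clip above 510
        return p / p.sum()


@dataclass(frozen=True)
class TemperatureSpec:
    """AR(1) daily-maximum series mapped into ``tmax_range``."""

    tmax_range: tuple[float, float] = (20.4, 40.1)
    autocorr: float = 0.6
    tmin_offset_range: tuple[float, float] = (8.0, 16.0)


@dataclass(frozen=True)
class SimConfig:
    """Everything that defines a simulated dataset."""

    n_bears: int = 19
    sex_ratio: float = 10.0 / 19.0  # proportion female
    start_date: _date = _date(2006, 5, 1)
    end_date: _date = _date(2006, 10, 31)  # exclusive
    sample_interval: int = SAMPLE_MINUTES
    inactive_emission: InactiveEmissionSpec = field(default_factory=InactiveEmissionSpec)
    active_emission: ActiveEmissionSpec = field(default_factory=ActiveEmissionSpec)
    bout_scale_by_season_state: dict = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_BOUT_SCALE_H.items()})
    male_active_scale_factor: float = 0.85
    diurnal_profile: tuple = DEFAULT_DIURNAL_PROFILE
    interruption_rate: float = 0.5
    valley_range: tuple[int, int] = (31, 41)  # target valleys 36 +/- 5
    berry_start_window: tuple[_date, _date] = (_date(2006, 7, 6), _date(2006, 8, 25))
    berry_end_window: tuple[_date, _date] = (_date(2006, 9, 7), _date(2006, 10, 12))
    temperature_spec: TemperatureSpec = field(default_factory=TemperatureSpec)
    capture_gap_days: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.end_date <= self.start_date:
            raise ValueError("date span must cover at least one day")
        if self.sample_interval != SAMPLE_MINUTES:
            raise ValueError("sample interval is fixed at 5 minutes")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        for season, scales in self.bout_scale_by_season_state.items():
            for state, scale in scales.items():
                if scale <= 0:
                    raise ValueError(f"bout scale {season}/{state} must be positive")
        if len(self.diurnal_profile) != 24:
            raise ValueError("diurnal_profile must have 24 entries")

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days


@dataclass
class BearParams:
    """Per-bear ground-truth parameters."""

    bear_id: str
    sex: str
    active_mean: float
    valley_param: int  # target valley drawn from config.valley_range
    true_valley: int  # argmin of the smoothed exact mixture pmf
    berry_start: pd.Timestamp
    berry_end: pd.Timestamp
    capture_date: pd.Timestamp


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    bears: dict[str, BearParams]
    true_states: pd.DataFrame  # bear_id, timestamp, state (pre-interruption)
    interruptions: pd.DataFrame  # bear_id, timestamp (flipped samples)
    n_gap_samples: int = 0

    @property
    def mean_true_valley(self) -> float:
        return float(np.mean([b.true_valley for b in self.bears.values()]))


def true_valley_of(config: SimConfig, support_max: int, active_mean: float,
                   mix_inactive: float = 0.5) -> int:
    """Ground-truth valley: argmin (ties smallest) of the bandwidth-smoothed
    exact mixture pmf inside the default search window."""
    pmf = np.zeros(MAX_SWITCHES + 1)
    inact = config.inactive_emission.pmf(support_max)
    pmf[:len(inact)] += mix_inactive * inact
    pmf += (1.0 - mix_inactive) * config.active_emission.pmf(active_mean)
    smoothed = smooth_histogram(pmf, DEFAULT_BANDWIDTH)
    lo, hi = DEFAULT_WINDOW
    return lo + int(np.argmin(smoothed[lo:hi + 1]))


def _draw_date(rng: np.random.Generator, window: tuple[_date, _date]) -> pd.Timestamp:
    span = (window[1] - window[0]).days
    return pd.Timestamp(window[0] + timedelta(days=int(rng.integers(0, span + 1))))


def draw_bear_params(config: SimConfig, rng: np.random.Generator) -> dict[str, BearParams]:
    """Sex, emission parameters, valley and berry window for every bear."""
    n_f = int(round(config.n_bears * config.sex_ratio))
    bears: dict[str, BearParams] = {}
    for i in range(config.n_bears):
        sex = "F" if i < n_f else "M"
        bear_id = f"{sex}{i + 1:02d}"
        valley_param = int(rng.integers(config.valley_range[0], config.valley_range[1] + 1))
        support_max = valley_param - DEFAULT_BANDWIDTH // 2 - 1
        active_mean = float(rng.uniform(*config.active_emission.mean_range))
        berry_start = _draw_date(rng, config.berry_start_window)
        berry_end = _draw_date(rng, config.berry_end_window)
        bears[bear_id] = BearParams(
            bear_id=bear_id,
            sex=sex,
            active_mean=active_mean,
            valley_param=valley_param,
            true_valley=true_valley_of(config, support_max, active_mean),
            berry_start=berry_start,
            berry_end=berry_end,
            capture_date=pd.Timestamp(config.start_date),
        )
    return bears


def _season_scales(config: SimConfig, params: BearParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-day (active, inactive) bout scales for this bear's calendar.

    Days outside the season guards reuse the nearest season's scales."""
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    berry = (dates >= params.berry_start) & (dates <= params.berry_end)
    post = dates > params.berry_end
    act = np.empty(config.n_days)
    inact = np.empty(config.n_days)
    sc = config.bout_scale_by_season_state
    male = config.male_active_scale_factor if params.sex == "M" else 1.0
    for i in range(config.n_days):
        season = "berry" if berry[i] else ("post_berry" if post[i] else "herb_bulb")
        act[i] = sc[season]["active"] * male
        inact[i] = sc[season]["inactive"] / male  # males also rest longer
    return act, inact


def simulate_state_sequence(config: SimConfig, params: BearParams,
                            seed: int | np.random.Generator) -> pd.DataFrame:
    """True 5-minute active/inactive labels for one bear over the full span.

    Alternating exponential bouts; a proposed active bout is accepted with
    the diurnal profile's probability at its start hour (rejection extends
    the inactive stretch), and a running active bout survives each hour
    boundary with the profile's probability there — so activity dies off
    after dusk and zero-propensity hours contain no activity at all.  The
    slot label is the state at the slot's midpoint.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = np.asarray(config.diurnal_profile, dtype=float)
    act_scale, inact_scale = _season_scales(config, params)
    total_h = config.n_days * 24.0

    starts = [0.0]  # bout start times (hours); states alternate starting inactive
    t = 0.0
    active = False
    while t < total_h:
        if not active:
            while True:
                day = min(int(t // 24), config.n_days - 1)
                t += rng.exponential(inact_scale[day])
                if t >= total_h:
                    break
                if rng.random() < profile[int(t % 24)]:
                    break
        else:
            day = min(int(t // 24), config.n_days - 1)
            t_end = t + rng.exponential(act_scale[day])
            # hourly survival: the bout continues past each hour boundary
            # with the profile's probability (1.0 never truncates; 0.0 is a
            # hard curfew)
            h = math.floor(t) + 1.0
            while h < t_end:
                p = profile[int(h % 24)]
                if p < 1.0 and rng.random() >= p:
                    t_end = h
                    break
                h += 1.0
            t = t_end
        if t < total_h:
            starts.append(t)
        active = not active

    starts_arr = np.asarray(starts)
    midpoints = (np.arange(config.n_days * SAMPLES_PER_DAY) + 0.5) * (SAMPLE_MINUTES / 60.0)
    bout_idx = np.searchsorted(starts_arr, midpoints, side="right") - 1
    states = np.where(bout_idx % 2 == 1, "active", "inactive")  # bout 0 is inactive

    timestamps = pd.Timestamp(config.start_date) + pd.to_timedelta(
        np.arange(config.n_days * SAMPLES_PER_DAY) * SAMPLE_MINUTES, unit="m")
    return pd.DataFrame({
        "bear_id": params.bear_id,
        "timestamp": timestamps,
        "state": states,
    })


def inject_interruptions(states: pd.DataFrame, rate: float,
                         seed: int | np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flip 1-3-sample opposite-state runs inside long bouts.

    Each maximal run of at least ``2 * 12 + 3`` samples carries, with
    probability ``rate``, exactly one interruption of length 1-3 (70/18/12%)
    placed so that at least 12 consistent samples remain on each flank.
    Returns the modified series and a table of flipped positions.
    """
    if rate < 0:
        raise ValueError("interruption rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = states.copy()
    arr = out["state"].to_numpy().copy()
    lengths = list(INTERRUPTION_LENGTH_PROBS)
    probs = np.array(list(INTERRUPTION_LENGTH_PROBS.values()))
    flipped_rows = []
    for bear, idx in out.groupby("bear_id", sort=False).indices.items():
        sub = arr[idx]
        # maximal runs of the (per-bear) sequence
        change = np.flatnonzero(sub[1:] != sub[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(sub)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            run_len = e - s
            if run_len < 2 * MIN_FLANK_SAMPLES + max(lengths):
                continue
            if rate < 1.0 and rng.random() >= rate:
                continue
            length = int(rng.choice(lengths, p=probs))
            pos = int(rng.integers(s + MIN_FLANK_SAMPLES, e - MIN_FLANK_SAMPLES - length + 1))
            opposite = "inactive" if sub[s] == "active" else "active"
            sub[pos:pos + length] = opposite
            flipped_rows.extend(idx[pos:pos + length])
        arr[idx] = sub
    out["state"] = arr
    interruptions = out.loc[flipped_rows, ["bear_id", "timestamp"]].reset_index(drop=True)
    return out, interruptions


def emit_switch_counts(states: pd.DataFrame, config: SimConfig,
                       bears: dict[str, BearParams],
                       seed: int | np.random.Generator) -> pd.DataFrame:
    """Draw integer switch counts in [0, 510] for every labelled sample."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = states.copy()
    counts = np.zeros(len(out), dtype=np.int64)
    active_mask = out["state"].to_numpy() == "active"
    for bear, idx in out.groupby("bear_id", sort=False).indices.items():
        params = bears[str(bear)]
        support_max = params.valley_param - DEFAULT_BANDWIDTH // 2 - 1
        inact_pmf = config.inactive_emission.pmf(support_max)
        is_active = active_mask[idx]
        n_act, n_inact = int(is_active.sum()), int((~is_active).sum())
        inact_draws = rng.choice(len(inact_pmf), size=n_inact, p=inact_pmf)
        act_draws = np.clip(
            np.rint(rng.normal(params.active_mean, config.active_emission.sd, size=n_act)),
            0, MAX_SWITCHES).astype(np.int64)
        sub = np.empty(len(idx), dtype=np.int64)
        sub[~is_active] = inact_draws
        sub[is_active] = act_draws
        counts[idx] = sub
    out["switches"] = counts
    return out


def simulate_temperature(config: SimConfig, seed: int | np.random.Generator) -> pd.DataFrame:
    """Daily tmax/tmin series: AR(1) latent process mapped into the
    configured range by the normal probability integral transform."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = config.temperature_spec
    n = config.n_days
    phi = spec.autocorr
    innov_sd = math.sqrt(max(1.0 - phi * phi, 1e-12))
    z = np.empty(n)
    z[0] = rng.normal()
    for i in range(1, n):
        z[i] = phi * z[i - 1] + rng.normal(scale=innov_sd)
    lo, hi = spec.tmax_range
    tmax = lo + (hi - lo) * stats.norm.cdf(z)
    tmin = tmax - rng.uniform(*spec.tmin_offset_range, size=n)
    return pd.DataFrame({
        "date": pd.date_range(config.start_date, periods=n, freq="D"),
        "tmax_c": np.round(tmax, 1),
        "tmin_c": np.round(tmin, 1),
    })


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Full synthetic activity table (post capture-gap) plus ground truth.

    The activity table has the standard columns ``bear_id, sex, timestamp,
    season, switches``; the first ``capture_gap_days`` days of each bear are
    missing rows (the post-capture exclusion), counted in
    ``GroundTruth.n_gap_samples``.
    """
    root = np.random.SeedSequence(config.seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    bears = draw_bear_params(config, param_rng)

    frames, truth_frames, intr_frames = [], [], []
    n_gap = 0
    child_seeds = root.spawn(len(bears))
    for ss, (bear_id, params) in zip(child_seeds, sorted(bears.items())):
        rng = np.random.default_rng(ss)
        truth = simulate_state_sequence(config, params, rng)
        truth_frames.append(truth)
        observed, interruptions = inject_interruptions(truth, config.interruption_rate, rng)
        observed = emit_switch_counts(observed, config, bears, rng)
        observed["sex"] = params.sex
        cal = SeasonCalendar(bear_id, params.berry_start, params.berry_end)
        observed["season"] = season_of_dates(observed["timestamp"], cal)
        gap_end = params.capture_date + pd.Timedelta(days=config.capture_gap_days)
        gap = observed["timestamp"] < gap_end
        n_gap += int(gap.sum())
        frames.append(observed[~gap])
        intr_frames.append(interruptions)

    activity = pd.concat(frames, ignore_index=True)[
        ["bear_id", "sex", "timestamp", "season", "switches", "state"]
    ].rename(columns={"state": "true_state"})
    ground_truth = GroundTruth(
        bears=bears,
        true_states=pd.concat(truth_frames, ignore_index=True),
        interruptions=pd.concat(intr_frames, ignore_index=True),
        n_gap_samples=n_gap,
    )
    return activity, ground_truth


def make_fixture_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write activity, weather and metadata tables for a simulated dataset.

    Files round-trip through the :mod:`ursactive.io_formats` readers and are
    byte-identical for a fixed config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "activity": outdir / "activity.csv",
        "weather": outdir / "weather.csv",
        "metadata": outdir / "metadata.csv",
    }
    if config.n_bears == 0:
        io_formats.write_activity_table(
            pd.DataFrame(columns=io_formats.ACTIVITY_COLUMNS), paths["activity"])
        io_formats.write_weather_table(
            simulate_temperature(config, np.random.default_rng(config.seed + 1)),
            paths["weather"])
        io_formats.write_metadata_table(
            pd.DataFrame(columns=io_formats.METADATA_COLUMNS), paths["metadata"])
        return paths

    activity, truth = simulate_dataset(config)
    io_formats.write_activity_table(activity, paths["activity"])
    io_formats.write_weather_table(
        simulate_temperature(config, np.random.default_rng(config.seed + 1)),
        paths["weather"])
    meta = pd.DataFrame([
        {"bear_id": b.bear_id, "sex": b.sex, "capture_date": b.capture_date,
         "berry_start": b.berry_start, "berry_end": b.berry_end}
        for b in truth.bears.values()
    ])
    io_formats.write_metadata_table(meta, paths["metadata"])
    return paths


# ---------------------------------------------------------------------------
# Lightweight generators for model-level recovery and null-calibration tests
# ---------------------------------------------------------------------------

def simulate_weekly_summaries(n_bears: int = 20, n_weeks: int = 30, *,
                              berry_effect: float = 2.0,
                              post_effect: float = -0.8,
                              sex_effect: float = -1.0,
                              daylight_effect: float = 0.0,
                              intercept: float = 13.0,
                              bear_sd: float = 1.0,
                              resid_sd: float = 1.5,
                              seed: int = 0) -> pd.DataFrame:
    """Weekly summary table with known fixed effects, for parameter-recovery
    checks of the weekly mixed model.

    Weeks 0-11 are herb-bulb, 12-23 berry, and the rest post-berry; the
    daylight covariate follows a season-typical curve.  The generating model
    has no sex x season interaction, so the fitted ``season[T.berry]``
    coefficient estimates ``berry_effect`` (the female contrast).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_bears):
        sex = "F" if i < (n_bears + 1) // 2 else "M"
        b = rng.normal(scale=bear_sd)
        for w in range(n_weeks):
            season = "herb_bulb" if w < 12 else ("berry" if w < 24 else "post_berry")
            daylight = 16.0 + 3.0 * math.cos((w - 8) / n_weeks * 2 * math.pi)
            mu = (intercept + b
                  + (berry_effect if season == "berry" else 0.0)
                  + (post_effect if season == "post_berry" else 0.0)
                  + (sex_effect if sex == "M" else 0.0)
                  + daylight_effect * daylight)
            rows.append({
                "bear_id": f"{sex}{i:02d}", "sex": sex, "year": 2006, "week": w,
                "season": season,
                "hours_active_per_day": float(np.clip(mu + rng.normal(scale=resid_sd), 0, 24)),
                "active_bout_h": np.nan, "inactive_bout_h": np.nan,
                "daylight_civil_hours": daylight, "n_complete_days": 7,
            })
    return pd.DataFrame(rows)


def simulate_temperature_day_records(n_days: int = 97, n_bears: int = 3, *,
                                     tmax_effect: float = 0.0,
                                     mean_proportion: float = 0.55,
                                     bear_sd: float = 0.03,
                                     resid_sd: float = 0.08,
                                     seed: int = 0) -> pd.DataFrame:
    """Bear-day 24-h activity proportions against daily maximum temperature.

    ``tmax_effect`` is the change in proportion per 10 C; zero gives null
    data for calibration checks.
    """
    rng = np.random.default_rng(seed)
    cfg = replace(SimConfig(), start_date=_date(2006, 7, 1),
                  end_date=_date(2006, 7, 1) + timedelta(days=n_days), seed=seed)
    temps = simulate_temperature(cfg, rng)
    bear_eff = rng.normal(scale=bear_sd, size=n_bears)
    rows = []
    for i in range(n_bears):
        for r in temps.itertuples():
            p = (mean_proportion + bear_eff[i]
                 + tmax_effect * (r.tmax_c - np.mean(cfg.temperature_spec.tmax_range)) / 10.0
                 + rng.normal(scale=resid_sd))
            rows.append({
                "date": r.date, "bear_id": f"F{i:02d}", "tmax_c": r.tmax_c,
                "proportion_active_24h": float(np.clip(p, 0.0, 1.0)),
            })
    return pd.DataFrame(rows)


def simulate_pool_records(n_days: int = 96, n_bears: int = 3, *,
                          interaction: float = 0.0,
                          day_mean: float = 0.75, night_mean: float = 0.12,
                          bear_sd: float = 0.03, resid_sd: float = 0.08,
                          seed: int = 0) -> pd.DataFrame:
    """Bear x day x pooled-period activity proportions with warm/hot labels.

    ``interaction`` adds to the night proportion on hot days only; zero
    gives null data.  Day categories come from the median temperature split.
    """
    rng = np.random.default_rng(seed)
    day_recs = simulate_temperature_day_records(
        n_days=n_days, n_bears=1, seed=seed)[["date", "tmax_c"]].drop_duplicates("date")
    from .summaries_models import split_warm_hot
    days = split_warm_hot(day_recs.assign(bear_id="x"),
                          on_odd="drop_median")[["date", "tmax_c", "category"]]
    bear_eff = rng.normal(scale=bear_sd, size=n_bears)
    rows = []
    for i in range(n_bears):
        for r in days.itertuples():
            for pool, mean in (("day_pooled", day_mean), ("night_pooled", night_mean)):
                mu = mean + bear_eff[i]
                if pool == "night_pooled" and r.category == "hot":
                    mu += interaction
                rows.append({
                    "date": r.date, "bear_id": f"F{i:02d}", "tmax_c": r.tmax_c,
                    "category": r.category, "pool": pool,
                    "proportion_active": float(np.clip(mu + rng.normal(scale=resid_sd), 0, 1)),
                })
    return pd.DataFrame(rows)
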