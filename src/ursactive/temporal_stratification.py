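"""Season assignment, exclusion rules, and bear-week aggregation.

The active year is split into three foraging seasons around each bear's
individually delineated berry window:

* ``herb_bulb`` — from the spring floor (22 May, after the last den
  departure) up to the day before the bear first moved to berry fields;
* ``berry`` — the bear's berry window, boundary days inclusive;
* ``post_berry`` — from the day after the berry window through the autumn
  ceiling (22 Oct, before the first pre-denning movement).

Samples outside [floor, ceiling], within the first week after a capture, or
on days the bear approached human settlement are excluded (whole days for
the settlement rule).  Exclusions remove rows; nothing is zero-filled.

The sampling unit of the seasonal analyses is the bear-week: consecutive
7-day blocks anchored at 1 January.  A week enters the weekly summary only
if it is complete — 7 fully-sampled (288 samples/day), non-excluded days —
and lies entirely within one season.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

from .io_formats import SAMPLE_MINUTES

SPRING_FLOOR = (5, 22)  # 22 May: latest den departure
AUTUMN_CEILING = (10, 22)  # 22 Oct: earliest pre-denning movement
SAMPLES_PER_DAY = 24 * 60 // SAMPLE_MINUTES  # 288
CAPTURE_EXCLUSION_DAYS = 7


@dataclass(frozen=True)
class SeasonCalendar:
    """Per-bear season boundaries for one year."""

    bear_id: str
    berry_start: pd.Timestamp
    berry_end: pd.Timestamp

    def __post_init__(self):
        if pd.Timestamp(self.berry_start) >= pd.Timestamp(self.berry_end):
            raise ValueError(
                f"bear {self.bear_id}: berry_start {self.berry_start} not before "
                f"berry_end {self.berry_end}"
            )


def calendar_from_metadata(metadata: pd.DataFrame) -> dict[str, SeasonCalendar]:
    """Build per-bear calendars from a metadata table."""
    return {
        str(r.bear_id): SeasonCalendar(
            bear_id=str(r.bear_id),
            berry_start=pd.Timestamp(r.berry_start),
            berry_end=pd.Timestamp(r.berry_end),
        )
        for r in metadata.itertuples()
    }


def season_of_dates(dates: pd.Series, cal: SeasonCalendar) -> pd.Series:
    """Vectorized season label for normalized dates of one bear."""
    year = int(pd.Timestamp(cal.berry_start).year)
    floor = pd.Timestamp(_date(year, *SPRING_FLOOR))
    ceiling = pd.Timestamp(_date(year, *AUTUMN_CEILING))
    d = pd.to_datetime(dates).dt.normalize()
    out = pd.Series("excluded", index=d.index, dtype=object)
    out[(d >= floor) & (d < cal.berry_start)] = "herb_bulb"
    out[(d >= cal.berry_start) & (d <= cal.berry_end)] = "berry"
    out[(d > cal.berry_end) & (d <= ceiling)] = "post_berry"
    return out


def assign_season(samples: pd.DataFrame, calendars: dict[str, SeasonCalendar]) -> pd.DataFrame:
    """Add/overwrite the ``season`` column from per-bear calendars.

    Raises ``KeyError`` for a bear with no calendar.
    """
    out = samples.copy()
    season = pd.Series(index=out.index, dtype=object)
    for bear, idx in out.groupby("bear_id", sort=False).indices.items():
        if str(bear) not in calendars:
            raise KeyError(f"no season calendar for bear {bear!r}")
        season.iloc[idx] = season_of_dates(
            out["timestamp"].iloc[idx], calendars[str(bear)]
        ).to_numpy()
    out["season"] = season
    return out


def exclude_capture_week(samples: pd.DataFrame, captures: pd.DataFrame) -> pd.DataFrame:
    """Drop samples within 7 x 24 h after each capture of the same bear.

    ``captures`` has columns ``bear_id, capture_date`` (one row per capture
    event; a bear may appear more than once).
    """
    if len(captures) == 0:
        return samples.copy()
    keep = np.ones(len(samples), dtype=bool)
    ts = pd.to_datetime(samples["timestamp"]).to_numpy()
    bear = samples["bear_id"].to_numpy()
    horizon = np.timedelta64(CAPTURE_EXCLUSION_DAYS * 24 * 3600, "s")
    for r in captures.itertuples():
        t0 = np.datetime64(pd.Timestamp(r.capture_date))
        keep &= ~((bear == r.bear_id) & (ts >= t0) & (ts < t0 + horizon))
    return samples[keep].copy()


def exclude_settlement_days(samples: pd.DataFrame, day_flags: pd.DataFrame) -> pd.DataFrame:
    """Drop every sample of any flagged bear-day.

    ``day_flags`` has columns ``bear_id, date``: days on which one or more
    of the bear's locations fell within 500 m of human settlement.
    """
    if len(day_flags) == 0:
        return samples.copy()
    flagged = set(
        zip(day_flags["bear_id"], pd.to_datetime(day_flags["date"]).dt.normalize())
    )
    day = pd.to_datetime(samples["timestamp"]).dt.normalize()
    mask = [
        (b, d) in flagged for b, d in zip(samples["bear_id"], day)
    ]
    return samples[~np.asarray(mask)].copy()


def week_index(dates: pd.Series) -> pd.Series:
    """Consecutive 7-day blocks anchored at 1 January: (day_of_year-1)//7."""
    d = pd.to_datetime(dates)
    return (d.dt.dayofyear - 1) // 7


def weekly_aggregate(states: pd.DataFrame, bouts: pd.DataFrame,
                     include_truncated_bouts: bool = False) -> pd.DataFrame:
    """Aggregate an annotated state series to complete bear-weeks.

    ``states`` must carry ``bear_id, sex, timestamp, season, state`` and
    (from solar annotation) ``daylight_civil_hours``; samples with season
    ``excluded`` must already have been dropped.  Only complete weeks — 7
    days each with 288 samples, all in one season — are returned.

    ``hours_active_per_day`` is 5/60 x active samples / 7, which for a
    complete week equals 24 x the week's active fraction.  Mean bout lengths
    cover bouts starting within the week, censored edge bouts excluded by
    default.
    """
    df = states.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["_date"] = ts.dt.normalize()
    df["_year"] = ts.dt.year
    df["_week"] = week_index(ts)

    if len(bouts):
        b = bouts if include_truncated_bouts else bouts[~bouts["truncated"]]
        b = b.copy()
        b["_year"] = pd.to_datetime(b["start"]).dt.year
        b["_week"] = week_index(b["start"])
        bout_means = (
            b.groupby(["bear_id", "_year", "_week", "state"])["duration_h"]
            .mean().unstack("state")
        )
    else:
        bout_means = pd.DataFrame()

    rows = []
    for (bear, year, week), grp in df.groupby(["bear_id", "_year", "_week"], sort=True):
        day_counts = grp.groupby("_date").size()
        complete = len(day_counts) == 7 and (day_counts == SAMPLES_PER_DAY).all()
        seasons = grp["season"].unique()
        if not complete or len(seasons) != 1 or seasons[0] == "excluded":
            continue
        n_active = int((grp["state"] == "active").sum())
        key = (bear, year, week)
        rows.append({
            "bear_id": bear,
            "sex": grp["sex"].iloc[0],
            "year": year,
            "week": week,
            "season": seasons[0],
            "hours_active_per_day": n_active * SAMPLE_MINUTES / 60.0 / 7.0,
            "active_bout_h": bout_means.get("active", pd.Series(dtype=float)).get(key, np.nan)
            if len(bout_means) else np.nan,
            "inactive_bout_h": bout_means.get("inactive", pd.Series(dtype=float)).get(key, np.nan)
            if len(bout_means) else np.nan,
            "daylight_civil_hours": float(grp["daylight_civil_hours"].mean()),
            "n_complete_days": 7,
        })
    return pd.DataFrame(rows, columns=[
        "bear_id", "sex", "year", "week", "season", "hours_active_per_day",
        "active_bout_h", "inactive_bout_h", "daylight_civil_hours", "n_complete_days",
    ])


def period_proportions(states: pd.DataFrame,
                       grouping: tuple[str, ...] = ("bear_id", "season", "period"),
                       ) -> pd.DataFrame:
    """Proportion of samples active per group (default bear x season x
    period).  ``states`` must carry ``state`` and the grouping columns."""
    df = states.copy()
    df["_active"] = (df["state"] == "active").astype(float)
    out = (
        df.groupby(list(grouping), observed=True)["_active"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "proportion_active", "size": "n_samples"})
        .reset_index()
    )
    keep = [c for c in df.columns if c == "sex" and "sex" not in grouping]
    if keep:
        sex_map = df.groupby("bear_id")["sex"].first()
        if "bear_id" in grouping:
            out["sex"] = out["bear_id"].map(sex_map)
    return out


def sample_accounting(samples: pd.DataFrame, retained: pd.DataFrame,
                      reasons: dict[str, int] | None = None) -> dict[str, int]:
    """Full accounting of input samples: retained + excluded = total."""
    acc = {"n_input": len(samples), "n_retained": len(retained),
           "n_excluded": len(samples) - len(retained)}
    if reasons:
        acc.update({f"excluded_{k}": v for k, v in reasons.items()})
    return acc
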