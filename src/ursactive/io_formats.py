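"""Readers and writers for the tabular artifacts of the activity pipeline.

Formats
-------
Activity table (CSV or XLSX)
    Columns ``bear_id, sex, timestamp, season, switches``: one row per
    5-minute collar record.  ``switches`` is the summed count of two
    tip-switch sensors (each capped at 255), so it lies in [0, 510].
    ``season`` is one of ``herb_bulb, berry, post_berry, excluded``.
    Sampling gaps (hibernation, the post-capture week, excluded days) are
    absent rows, never sentinel counts.
Weather table (CSV)
    Columns ``date, tmax_c, tmin_c``: one row per day of daily shade
    temperature extremes.
Metadata table (CSV)
    Columns ``bear_id, sex, capture_date, berry_start, berry_end``: per-bear
    capture date and individually delineated berry-season window.
Bout table / summary tables (CSV)
    Written by this module; round-trip losslessly.  Durations are serialized
    in hours to 4 decimals.

Deposited activity tables in the wild carry varying column headers; readers
accept a ``column_map`` renaming dict so a foreign dialect can be adapted
without code change.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SEASONS = ("herb_bulb", "berry", "post_berry")
SEASON_LABELS = SEASONS + ("excluded",)
SEXES = ("F", "M")
MAX_SWITCHES = 510
SAMPLE_MINUTES = 5

ACTIVITY_COLUMNS = ["bear_id", "sex", "timestamp", "season", "switches"]
WEATHER_COLUMNS = ["date", "tmax_c", "tmin_c"]
METADATA_COLUMNS = ["bear_id", "sex", "capture_date", "berry_start", "berry_end"]
BOUT_COLUMNS = ["bear_id", "state", "start", "end", "duration_h", "n_samples", "truncated"]


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """Rows violate the format's invariants; the message lists offenders."""


def _read_table(path: str | Path, column_map: dict[str, str] | None) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def _offender_report(mask: pd.Series, df: pd.DataFrame, reason: str, max_rows: int = 10) -> str:
    rows = df.index[mask][:max_rows].tolist()
    n = int(mask.sum())
    return f"{n} row(s) {reason} (row index {rows}{'...' if n > max_rows else ''})"


def read_activity_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate an activity table; return rows sorted by bear, time.

    Raises :class:`SchemaError` on missing columns and
    :class:`ValidationError` (with row numbers) on out-of-range switch
    counts, unknown sex/season labels, duplicate timestamps within a bear,
    or timestamps off the 5-minute grid.
    """
    df = _read_table(path, column_map)
    _require_columns(df, ACTIVITY_COLUMNS, "activity table")
    df = df[ACTIVITY_COLUMNS].copy()
    if len(df) == 0:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df["switches"] = df["switches"].astype(int)
        return df

    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    problems = []
    bad_ts = df["timestamp"].isna()
    if bad_ts.any():
        problems.append(_offender_report(bad_ts, df, "have unparseable timestamps"))
    sw = pd.to_numeric(df["switches"], errors="coerce")
    bad_sw = sw.isna() | (sw < 0) | (sw > MAX_SWITCHES) | (sw != np.floor(sw))
    if bad_sw.any():
        problems.append(_offender_report(bad_sw, df, f"have switches outside 0..{MAX_SWITCHES}"))
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        problems.append(_offender_report(bad_sex, df, f"have sex not in {SEXES}"))
    bad_season = ~df["season"].isin(SEASON_LABELS)
    if bad_season.any():
        problems.append(_offender_report(bad_season, df, f"have season not in {SEASON_LABELS}"))
    if problems:
        raise ValidationError("activity table: " + "; ".join(problems))

    df["switches"] = sw.astype(int)
    df = df.sort_values(["bear_id", "timestamp"], kind="stable").reset_index(drop=True)

    dup = df.duplicated(subset=["bear_id", "timestamp"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValidationError(
            f"activity table: {int(dup.sum())} duplicate timestamp(s) within a bear, "
            f"first at bear {first['bear_id']!r} {first['timestamp']}"
        )
    off_grid = (df["timestamp"].dt.minute % SAMPLE_MINUTES != 0) | (df["timestamp"].dt.second != 0)
    if off_grid.any():
        raise ValidationError(
            "activity table: " + _offender_report(off_grid, df, "are off the 5-minute grid")
        )
    return df


def read_weather_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a daily weather table (date, tmax_c, tmin_c)."""
    df = _read_table(path, column_map)
    _require_columns(df, WEATHER_COLUMNS, "weather table")
    df = df[WEATHER_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    if len(df) == 0:
        return df
    bad = df["tmin_c"] > df["tmax_c"]
    if bad.any():
        raise ValidationError(
            "weather table: " + _offender_report(bad, df, "have tmin_c > tmax_c")
        )
    if df["date"].duplicated().any():
        raise ValidationError("weather table: duplicate dates")
    return df.sort_values("date").reset_index(drop=True)


def read_metadata_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read per-bear metadata (sex, capture date, berry window)."""
    df = _read_table(path, column_map)
    _require_columns(df, METADATA_COLUMNS, "metadata table")
    df = df[METADATA_COLUMNS].copy()
    for col in ("capture_date", "berry_start", "berry_end"):
        df[col] = pd.to_datetime(df[col]).dt.normalize()
    if len(df) and (df["berry_start"] >= df["berry_end"]).any():
        bad = df["berry_start"] >= df["berry_end"]
        raise ValidationError(
            "metadata table: " + _offender_report(bad, df, "have berry_start >= berry_end")
        )
    return df


def write_activity_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[ACTIVITY_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_weather_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[WEATHER_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[["tmax_c", "tmin_c"]] = out[["tmax_c", "tmin_c"]].round(1)
    out.to_csv(path, index=False)


def write_metadata_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[METADATA_COLUMNS].copy()
    for col in ("capture_date", "berry_start", "berry_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_bouts(bouts: pd.DataFrame, path: str | Path) -> None:
    """Write a bout table; durations in hours to 4 decimals."""
    out = bouts[BOUT_COLUMNS].copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["duration_h"] = out["duration_h"].round(4)
    out.to_csv(path, index=False)


def read_bouts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, BOUT_COLUMNS, "bout table")
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col])
    df["truncated"] = df["truncated"].astype(bool)
    return df


def write_summaries(table: pd.DataFrame, path: str | Path) -> None:
    """Write a summary table (weekly or period) as plain CSV."""
    table.to_csv(path, index=False)
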