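"""Interruption smoothing of state series and extraction of bouts.

Long resting or foraging bouts recorded by a tip-switch collar are sometimes
broken by 1-3 samples (5-15 minutes) of the apparent opposite state — a bear
shifting position in its bed, or pausing briefly while travelling.  The
smoothing rule flips any maximal run of at most ``max_run`` samples whose
neighbouring opposite-state run on at least one side (optionally both)
contains at least ``min_flank`` samples (default 12 samples = 1 hour).  The
rule is applied to a fixpoint by repeated left-to-right sweeps, so the
result is deterministic; runs of 4 or more samples are never altered.

Sampling gaps split each bear's record into blocks.  Flanks never span a
gap — an unobserved period cannot certify bout continuity — and a short run
touching a block edge qualifies on the strength of its single interior
flank.

Bouts are maximal same-state runs within a block; a bout abutting a block
edge has a censored duration and is flagged ``truncated`` (such bouts are
excluded from mean-bout-length summaries by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import SAMPLE_MINUTES

DEFAULT_MAX_RUN = 3
DEFAULT_MIN_FLANK = 12  # samples; 1 hour at 5-minute sampling

_GAP = pd.Timedelta(minutes=SAMPLE_MINUTES)


def _runs(arr: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean array as [value, length] pairs."""
    runs: list[list[int]] = []
    for v in arr:
        if runs and runs[-1][0] == v:
            runs[-1][1] += 1
        else:
            runs.append([int(v), 1])
    return runs


def smooth_runs(runs: list[list[int]], max_run: int = DEFAULT_MAX_RUN,
                min_flank: int = DEFAULT_MIN_FLANK,
                require_both_flanks: bool = False) -> list[list[int]]:
    """Apply the interruption-flipping rule to a run-length encoding.

    Sweeps left to right flipping qualifying runs in place (merging with
    their neighbours) and repeats until a sweep makes no change.  Because a
    flip only ever lengthens the surviving runs, the qualifying set grows
    monotonically and the fixpoint is unique.
    """
    runs = [list(r) for r in runs]
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(runs):
            val, length = runs[i]
            if length <= max_run and len(runs) > 1:
                left = runs[i - 1][1] if i > 0 else None
                right = runs[i + 1][1] if i + 1 < len(runs) else None
                flanks = [f for f in (left, right) if f is not None]
                if require_both_flanks:
                    ok = all(f >= min_flank for f in flanks)
                else:
                    ok = max(flanks) >= min_flank
                if ok:
                    # flip: merge [i-1, i, i+1] into one opposite-state run
                    start = i - 1 if left is not None else i
                    stop = i + 1 if right is not None else i
                    total = sum(r[1] for r in runs[start:stop + 1])
                    runs[start:stop + 1] = [[1 - val, total]]
                    changed = True
                    i = max(start - 1, 0)
                    continue
            i += 1
    return runs


def _expand(runs: list[list[int]]) -> np.ndarray:
    return np.repeat([r[0] for r in runs], [r[1] for r in runs]).astype(bool)


def _block_ids(timestamps: pd.Series) -> np.ndarray:
    """Label contiguous 5-minute blocks; a step larger than one sample
    interval starts a new block."""
    ts = pd.to_datetime(timestamps)
    new_block = ts.diff() != _GAP
    new_block.iloc[0] = True
    return new_block.cumsum().to_numpy()


def smooth_states(series: pd.DataFrame, max_run: int = DEFAULT_MAX_RUN,
                  min_flank: int = DEFAULT_MIN_FLANK,
                  require_both_flanks: bool = False) -> pd.DataFrame:
    """Smooth a classified state series (columns bear_id, timestamp, state).

    Returns a copy with flipped samples set to the opposite state and their
    ``provenance`` set to ``'flipped'``.  Rows must be sorted by bear and
    time; gaps are respected per bear.
    """
    out = series.copy()
    state = (out["state"].to_numpy() == "active")
    new_state = state.copy()
    for _, idx in out.groupby("bear_id", sort=False).indices.items():
        blocks = _block_ids(out["timestamp"].iloc[idx])
        for b in np.unique(blocks):
            sel = idx[blocks == b]
            smoothed = _expand(
                smooth_runs(_runs(state[sel]), max_run, min_flank, require_both_flanks)
            )
            new_state[sel] = smoothed
    flipped = new_state != state
    out["state"] = np.where(new_state, "active", "inactive")
    out["provenance"] = np.where(flipped, "flipped", out.get("provenance", "raw"))
    return out


def extract_bouts(series: pd.DataFrame) -> pd.DataFrame:
    """Maximal same-state runs per bear per block.

    Returns a bout table with columns ``bear_id, state, start, end,
    duration_h, n_samples, truncated``; ``end`` is exclusive (start of the
    slot after the last sample) so ``duration_h = n_samples * 5 / 60`` and
    bout durations within a block sum exactly to the block span.  Bouts
    touching a block edge are flagged truncated.
    """
    rows = []
    for bear, grp in series.groupby("bear_id", sort=False):
        ts = pd.to_datetime(grp["timestamp"]).to_numpy()
        state = grp["state"].to_numpy()
        blocks = _block_ids(grp["timestamp"])
        for b in np.unique(blocks):
            sel = np.flatnonzero(blocks == b)
            runs = _runs(state[sel] == "active")
            pos = 0
            for k, (val, length) in enumerate(runs):
                i0, i1 = sel[pos], sel[pos + length - 1]
                rows.append({
                    "bear_id": bear,
                    "state": "active" if val else "inactive",
                    "start": ts[i0],
                    "end": ts[i1] + np.timedelta64(SAMPLE_MINUTES, "m"),
                    "duration_h": length * SAMPLE_MINUTES / 60.0,
                    "n_samples": length,
                    "truncated": k == 0 or k == len(runs) - 1,
                })
                pos += length
    return pd.DataFrame(
        rows, columns=["bear_id", "state", "start", "end", "duration_h", "n_samples", "truncated"],
    )


def smoothing_impact(raw: pd.DataFrame, smoothed: pd.DataFrame) -> dict[str, float]:
    """Percentages of time converted by smoothing, relative to the raw totals.

    ``pct_inactive_added``: active samples flipped to inactive, as a percent
    of raw inactive time; ``pct_active_added``: the reverse, as a percent of
    raw active time; ``net_activity_change_pct``: signed net change in
    active time as a percent of raw active time.
    """
    if len(raw) != len(smoothed) or not (
        raw["timestamp"].reset_index(drop=True).equals(
            smoothed["timestamp"].reset_index(drop=True))
        and raw["bear_id"].reset_index(drop=True).equals(
            smoothed["bear_id"].reset_index(drop=True))
    ):
        raise ValueError("raw and smoothed series index on different samples")
    raw_active = (raw["state"].to_numpy() == "active")
    new_active = (smoothed["state"].to_numpy() == "active")
    n_active = int(raw_active.sum())
    n_inactive = int((~raw_active).sum())
    a_to_i = int((raw_active & ~new_active).sum())
    i_to_a = int((~raw_active & new_active).sum())
    return {
        "pct_inactive_added": 100.0 * a_to_i / n_inactive if n_inactive else 0.0,
        "pct_active_added": 100.0 * i_to_a / n_active if n_active else 0.0,
        "net_activity_change_pct": 100.0 * (i_to_a - a_to_i) / n_active if n_active else 0.0,
        "n_flipped": a_to_i + i_to_a,
    }


def mean_bout_lengths(bouts: pd.DataFrame, include_truncated: bool = False) -> pd.DataFrame:
    """Mean bout duration (h) by bear and state, excluding censored edge
    bouts unless asked otherwise."""
    sel = bouts if include_truncated else bouts[~bouts["truncated"]]
    return (
        sel.groupby(["bear_id", "state"])["duration_h"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_duration_h", "count": "n_bouts"})
        .reset_index()
    )
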