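"""Interruption smoothing and bout extraction.

The smoothing rule is checked against a deliberately naive oracle:
repeatedly rescan the sequence from the left, flip the first qualifying
short run, and restart until nothing qualifies.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ursactive.bout_segmentation import (
    extract_bouts,
    mean_bout_lengths,
    smooth_runs,
    smooth_states,
    smoothing_impact,
)


def brute_force_smooth(seq, max_run=3, min_flank=12, require_both=False):
    """Leftmost-first restart oracle over a boolean tuple."""
    seq = list(seq)
    while True:
        # run-length encode from scratch each pass
        runs = []
        for v in seq:
            if runs and runs[-1][0] == v:
                runs[-1][1] += 1
            else:
                runs.append([v, 1])
        flipped = False
        pos = 0
        for i, (val, length) in enumerate(runs):
            if length <= max_run and len(runs) > 1:
                left = runs[i - 1][1] if i > 0 else None
                right = runs[i + 1][1] if i + 1 < len(runs) else None
                flanks = [f for f in (left, right) if f is not None]
                ok = (all(f >= min_flank for f in flanks) if require_both
                      else max(flanks) >= min_flank)
                if ok:
                    for j in range(pos, pos + length):
                        seq[j] = not seq[j]
                    flipped = True
                    break
            pos += length
        if not flipped:
            return tuple(seq)


def _series(states, bear="b", start="2006-06-01", gap_after=()):
    """Build a state-series frame from a boolean list; indices in
    ``gap_after`` get a 1-hour hole after them."""
    ts = []
    t = pd.Timestamp(start)
    for i in range(len(states)):
        ts.append(t)
        t += pd.Timedelta(minutes=5)
        if i in gap_after:
            t += pd.Timedelta(hours=1)
    return pd.DataFrame({
        "bear_id": bear,
        "timestamp": ts,
        "state": ["active" if s else "inactive" for s in states],
        "provenance": "raw",
    })


def _states_bool(df):
    return tuple(df["state"].to_numpy() == "active")


class TestSmoothingRule:
    def test_short_active_run_inside_hour_flanks_is_absorbed(self):
        seq = [False] * 12 + [True] * 2 + [False] * 12
        out = smooth_states(_series(seq))
        assert (out["state"] == "inactive").all()
        assert (out["provenance"] == "flipped").sum() == 2

    def test_four_sample_run_is_never_flipped(self):
        seq = [False] * 12 + [True] * 4 + [False] * 12
        out = smooth_states(_series(seq))
        assert _states_bool(out) == tuple(seq)

    def test_short_flanks_do_not_qualify(self):
        seq = [False] * 5 + [True] + [False] * 5
        out = smooth_states(_series(seq))
        assert _states_bool(out) == tuple(seq)

    def test_one_sided_hour_flank_qualifies_by_default(self):
        seq = [False] * 12 + [True] * 2 + [False] * 5
        out = smooth_states(_series(seq))
        assert (out["state"] == "inactive").all()

    def test_strict_mode_requires_both_flanks(self):
        seq = [False] * 12 + [True] * 2 + [False] * 5
        out = smooth_states(_series(seq), require_both_flanks=True)
        assert _states_bool(out) == tuple(seq)

    def test_flanks_never_span_sampling_gaps(self):
        # 12 inactive | GAP | 5 inactive, 1 active, 5 inactive: without the
        # gap the left flank would total 17 samples and the run would flip;
        # an unobserved hour cannot certify continuity, so it must survive
        seq = [False] * 12 + [False] * 5 + [True] + [False] * 5
        df = _series(seq, gap_after=(11,))
        out = smooth_states(df)
        assert _states_bool(out) == tuple(seq)
        # the same sequence without a gap is smoothed
        out2 = smooth_states(_series(seq))
        assert (out2["state"] == "inactive").all()

    def test_block_edge_run_qualifies_on_its_single_interior_flank(self):
        # GAP puts a 2-sample active run at a block start; its only interior
        # flank has 12 inactive samples, which qualifies it even in strict mode
        seq = [False] * 12 + [True] * 2 + [False] * 12
        df = _series(seq, gap_after=(11,))
        out = smooth_states(df, require_both_flanks=True)
        assert (out["state"] == "inactive").all()

    def test_smoothing_is_idempotent_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = rng.random(80) < rng.uniform(0.2, 0.8)
            once = smooth_states(_series(seq))
            twice = smooth_states(once)
            assert _states_bool(once) == _states_bool(twice)

    @given(st.integers(0, 2 ** 16 - 1))
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_matches_brute_force_oracle_at_scaled_flank(self, bits):
        seq = tuple(bool((bits >> i) & 1) for i in range(16))
        expected = brute_force_smooth(seq, max_run=3, min_flank=4)
        out = smooth_states(_series(seq), max_run=3, min_flank=4)
        assert _states_bool(out) == expected

    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_flip_count_bounded_by_short_run_count(self, seq):
        df = _series(seq)
        out = smooth_states(df, max_run=3, min_flank=4)
        arr = np.asarray(seq)
        n_runs_short = 0
        i = 0
        while i < len(arr):
            j = i
            while j < len(arr) and arr[j] == arr[i]:
                j += 1
            if j - i <= 3:
                n_runs_short += 1
            i = j
        n_flipped_runs = 0
        flips = (out["provenance"] == "flipped").to_numpy()
        n_flipped_runs = int((np.diff(np.concatenate([[0], flips.astype(int)])) == 1).sum())
        assert n_flipped_runs <= n_runs_short


class TestExtractBouts:
    def test_alternating_samples_give_five_minute_bouts(self):
        seq = [True, False] * 10
        bouts = extract_bouts(_series(seq))
        assert (bouts["duration_h"] == 5 / 60).all()
        assert len(bouts) == 20

    def test_single_full_day_is_one_24h_bout(self):
        seq = [True] * 288
        bouts = extract_bouts(_series(seq))
        assert len(bouts) == 1
        assert bouts["duration_h"].iloc[0] == 24.0
        assert bouts["truncated"].iloc[0]  # touches both record edges

    def test_durations_sum_to_block_spans_and_states_alternate(self):
        rng = np.random.default_rng(9)
        seq = rng.random(600) < 0.5
        df = _series(seq, gap_after=(99, 399))
        bouts = extract_bouts(df)
        assert bouts["duration_h"].sum() == pytest.approx(600 * 5 / 60)
        # per block: alternation
        for _, blk in bouts.groupby(bouts["start"].dt.date, sort=False):
            states = blk.sort_values("start")["state"].tolist()
            assert all(a != b for a, b in zip(states, states[1:]))

    def test_interior_bouts_are_not_truncated(self):
        seq = [True] * 20 + [False] * 20 + [True] * 20
        bouts = extract_bouts(_series(seq)).sort_values("start").reset_index(drop=True)
        assert list(bouts["truncated"]) == [True, False, True]

    def test_mean_bout_lengths_exclude_censored_edges_by_default(self):
        seq = [True] * 20 + [False] * 24 + [True] * 20
        bouts = extract_bouts(_series(seq))
        means = mean_bout_lengths(bouts)
        assert set(means["state"]) == {"inactive"}
        assert means["mean_duration_h"].iloc[0] == pytest.approx(2.0)


class TestSmoothingImpact:
    def test_no_flips_means_all_zero(self):
        seq = [True] * 30 + [False] * 30
        df = _series(seq)
        out = smooth_states(df)
        impact = smoothing_impact(df, out)
        assert impact["pct_inactive_added"] == 0.0
        assert impact["pct_active_added"] == 0.0
        assert impact["net_activity_change_pct"] == 0.0

    def test_single_active_to_inactive_flip_arithmetic(self):
        # 1000 samples, 500 active; one A->I conversion = -0.2% of active time
        raw = _series([True] * 500 + [False] * 500)
        smoothed = raw.copy()
        smoothed.loc[499, "state"] = "inactive"
        impact = smoothing_impact(raw, smoothed)
        assert impact["net_activity_change_pct"] == pytest.approx(-0.2)
        assert impact["pct_inactive_added"] == pytest.approx(100 * 1 / 500)

    def test_symmetric_flips_cancel(self):
        raw = _series([True] * 500 + [False] * 500)
        smoothed = raw.copy()
        smoothed.loc[499, "state"] = "inactive"
        smoothed.loc[500, "state"] = "active"
        assert smoothing_impact(raw, smoothed)["net_activity_change_pct"] == 0.0

    def test_mismatched_indices_rejected(self):
        raw = _series([True] * 10)
        with pytest.raises(ValueError, match="different samples"):
            smoothing_impact(raw, _series([True] * 9))


class TestInterruptionRecovery:
    def test_injected_interruptions_are_reverted_exactly(self, small_dataset):
        from ursactive.state_classification import classify, derive_threshold

        activity, truth = small_dataset
        labelled = classify(activity, derive_threshold(activity).pooled_threshold)
        smoothed = smooth_states(labelled)
        sm = smoothed.set_index(["bear_id", "timestamp"])
        true = truth.true_states.set_index(["bear_id", "timestamp"])
        idx = pd.MultiIndex.from_frame(truth.interruptions[["bear_id", "timestamp"]])
        idx = idx.intersection(sm.index)  # interruptions outside gaps
        assert len(idx) > 100
        assert (sm.loc[idx, "state"].to_numpy() == true.loc[idx, "state"].to_numpy()).all()
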