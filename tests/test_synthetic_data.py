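"""Generator behaviour: renewal structure, emissions, interruptions, weather,
determinism and conservation."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from ursactive.io_formats import read_activity_table
from ursactive.synthetic_data import (
    InactiveEmissionSpec,
    SimConfig,
    draw_bear_params,
    emit_switch_counts,
    inject_interruptions,
    make_fixture_dataset,
    simulate_dataset,
    simulate_state_sequence,
    simulate_temperature,
)

SAMPLES_PER_DAY = 288


def _uniform_config(**kw):
    """No diurnal modulation, one season's scales everywhere."""
    scales = {s: {"active": 3.0, "inactive": 3.0} for s in
              ("herb_bulb", "berry", "post_berry")}
    base = dict(
        n_bears=1, sex_ratio=1.0,
        start_date=date(2006, 6, 1), end_date=date(2006, 9, 9),  # 100 days
        bout_scale_by_season_state=scales,
        diurnal_profile=(1.0,) * 24,
        capture_gap_days=0,
        seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestStateSequence:
    def test_long_run_active_proportion_matches_renewal_expectation(self):
        # uniform profile + equal scales: active fraction -> s_a/(s_a+s_i) = 1/2;
        # 500 days keep the renewal sampling error well under the tolerance
        cfg = _uniform_config(end_date=date(2007, 10, 14))
        params = next(iter(draw_bear_params(cfg, np.random.default_rng(0)).values()))
        states = simulate_state_sequence(cfg, params, seed=123)
        frac = (states["state"] == "active").mean()
        assert abs(frac - 0.5) < 0.02

    def test_unequal_scales_shift_the_long_run_proportion(self):
        scales = {s: {"active": 6.0, "inactive": 2.0} for s in
                  ("herb_bulb", "berry", "post_berry")}
        cfg = _uniform_config(end_date=date(2007, 10, 14),
                              bout_scale_by_season_state=scales)
        params = next(iter(draw_bear_params(cfg, np.random.default_rng(0)).values()))
        states = simulate_state_sequence(cfg, params, seed=42)
        frac = (states["state"] == "active").mean()
        assert abs(frac - 0.75) < 0.02

    def test_zero_length_date_span_rejected(self):
        with pytest.raises(ValueError, match="at least one day"):
            SimConfig(start_date=date(2006, 6, 1), end_date=date(2006, 6, 1))

    def test_zero_propensity_hours_contain_no_activity(self):
        profile = tuple(0.0 if h in (22, 23, 0, 1, 2, 3) else 1.0 for h in range(24))
        cfg = _uniform_config(diurnal_profile=profile)
        params = next(iter(draw_bear_params(cfg, np.random.default_rng(0)).values()))
        states = simulate_state_sequence(cfg, params, seed=7)
        hours = pd.to_datetime(states["timestamp"]).dt.hour
        night = states[hours.isin([22, 23, 0, 1, 2, 3])]
        assert (night["state"] == "inactive").all()

    def test_states_form_alternating_runs(self):
        cfg = _uniform_config(end_date=date(2006, 6, 11))
        params = next(iter(draw_bear_params(cfg, np.random.default_rng(0)).values()))
        states = simulate_state_sequence(cfg, params, seed=1)
        s = states["state"].to_numpy()
        runs = np.flatnonzero(s[1:] != s[:-1])
        # consecutive run values alternate by construction of maximal runs
        assert len(states) == 10 * SAMPLES_PER_DAY
        assert len(runs) > 2


class TestEmissions:
    def test_point_mass_inactive_emits_all_zero(self):
        cfg = _uniform_config(
            end_date=date(2006, 6, 3),
            inactive_emission=InactiveEmissionSpec(p_zero=1.0, pile_mass=0.0, tail_mass=0.0),
        )
        bears = draw_bear_params(cfg, np.random.default_rng(0))
        params = next(iter(bears.values()))
        states = simulate_state_sequence(cfg, params, seed=2)
        states["state"] = "inactive"  # all-inactive day
        emitted = emit_switch_counts(states, cfg, bears, seed=3)
        assert (emitted["switches"] == 0).all()

    def test_counts_always_within_sensor_range(self, small_dataset):
        activity, _ = small_dataset
        assert activity["switches"].between(0, 510).all()

    def test_histogram_is_bimodal_with_valley_between_40_and_90(self, small_dataset):
        activity, _ = small_dataset
        counts = np.bincount(activity["switches"], minlength=511)
        valley_zone = counts[40:91]
        low_peak = counts[0:11].max()
        high_peak = counts[91:200].max()
        assert valley_zone.min() < 0.01 * min(low_peak, high_peak)

    def test_active_emissions_separate_from_threshold_region(self, small_dataset):
        # enables threshold recovery: almost no active sample at <= 36 switches
        activity, _ = small_dataset
        active = activity[activity["true_state"] == "active"]
        assert (active["switches"] <= 36).mean() < 0.001


class TestInterruptions:
    def _long_bout_series(self, n=5000, seed=4):
        cfg = _uniform_config(end_date=date(2006, 8, 10))
        params = next(iter(draw_bear_params(cfg, np.random.default_rng(0)).values()))
        return cfg, simulate_state_sequence(cfg, params, seed=seed)

    def test_rate_zero_is_identity(self):
        _, states = self._long_bout_series()
        out, positions = inject_interruptions(states, 0.0, seed=9)
        pd.testing.assert_frame_equal(out, states)
        assert len(positions) == 0

    def test_interruptions_leave_at_least_12_samples_on_each_flank(self):
        _, states = self._long_bout_series()
        out, positions = inject_interruptions(states, 1.0, seed=9)
        orig = states["state"].to_numpy()
        new = out["state"].to_numpy()
        flipped = np.flatnonzero(orig != new)
        assert len(flipped) > 0
        for i in flipped:
            # walk outward from the interruption run: both flanks must hold
            # >= 12 samples matching the original bout state
            run_lo, run_hi = i, i
            while run_lo > 0 and new[run_lo - 1] == new[i]:
                run_lo -= 1
            while run_hi < len(new) - 1 and new[run_hi + 1] == new[i]:
                run_hi += 1
            left = new[max(0, run_lo - 12):run_lo]
            right = new[run_hi + 1:run_hi + 13]
            assert len(left) == 12 and (left != new[i]).all()
            assert len(right) == 12 and (right != new[i]).all()

    def test_single_sample_interruption_prevalence_matches_default_rate(self):
        # with the default rate, ~35% of eligible (>= 2 h) inactive bouts
        # carry exactly one single-sample interruption
        rng = np.random.default_rng(0)
        cfg = _uniform_config(end_date=date(2006, 10, 31),
                              bout_scale_by_season_state={
                                  s: {"active": 4.0, "inactive": 4.0}
                                  for s in ("herb_bulb", "berry", "post_berry")})
        params = next(iter(draw_bear_params(cfg, rng).values()))
        states = simulate_state_sequence(cfg, params, seed=21)
        out, _ = inject_interruptions(states, 0.5, seed=22)
        orig = states["state"].to_numpy()
        new = out["state"].to_numpy()
        bounds = np.concatenate([[0], np.flatnonzero(orig[1:] != orig[:-1]) + 1, [len(orig)]])
        eligible = one_single = 0
        for s, e in zip(bounds[:-1], bounds[1:]):
            if orig[s] != "inactive" or e - s < 27:
                continue
            eligible += 1
            diff = np.flatnonzero(orig[s:e] != new[s:e])
            if len(diff) == 1:
                one_single += 1
        assert eligible > 150
        assert abs(one_single / eligible - 0.35) < 0.06


class TestTemperature:
    def test_tmax_within_bounds_and_tmin_below(self):
        cfg = _uniform_config(end_date=date(2006, 9, 9))
        temps = simulate_temperature(cfg, seed=3)
        assert temps["tmax_c"].between(20.4, 40.1).all()
        assert (temps["tmin_c"] < temps["tmax_c"]).all()

    def test_zero_autocorrelation_gives_near_zero_lag1_correlation(self):
        from ursactive.synthetic_data import TemperatureSpec
        cfg = SimConfig(start_date=date(2006, 1, 1), end_date=date(2007, 1, 1),
                        temperature_spec=TemperatureSpec(autocorr=0.0),
                        capture_gap_days=0, seed=8)
        temps = simulate_temperature(cfg, seed=8)
        t = temps["tmax_c"].to_numpy()
        r = np.corrcoef(t[:-1], t[1:])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(t))  # ~3 sd of the null sampling error

    def test_positive_autocorrelation_is_detectable(self):
        cfg = SimConfig(start_date=date(2006, 1, 1), end_date=date(2007, 1, 1),
                        capture_gap_days=0, seed=8)
        temps = simulate_temperature(cfg, seed=8)
        t = temps["tmax_c"].to_numpy()
        assert np.corrcoef(t[:-1], t[1:])[0, 1] > 0.3


class TestDatasetAssembly:
    def test_identical_config_and_seed_reproduce_identically(self, small_config):
        a1, _ = simulate_dataset(small_config)
        a2, _ = simulate_dataset(small_config)
        pd.testing.assert_frame_equal(a1, a2)

    def test_sample_conservation_with_capture_gap(self):
        cfg = SimConfig(n_bears=2, start_date=date(2006, 6, 1),
                        end_date=date(2006, 7, 1), capture_gap_days=7, seed=1)
        activity, truth = simulate_dataset(cfg)
        expected_total = 2 * 30 * SAMPLES_PER_DAY
        assert truth.n_gap_samples == 2 * 7 * SAMPLES_PER_DAY
        assert len(activity) == expected_total - truth.n_gap_samples

    def test_berry_window_ordering_for_every_bear(self, small_dataset):
        _, truth = small_dataset
        for p in truth.bears.values():
            assert p.berry_start < p.berry_end

    def test_fixture_files_round_trip(self, fixture_files, small_dataset):
        activity, _ = small_dataset
        read_back = read_activity_table(fixture_files["activity"])
        assert len(read_back) == len(activity)

    def test_fixture_files_are_byte_identical_across_runs(self, small_config, tmp_path):
        p1 = make_fixture_dataset(small_config, tmp_path / "a")
        p2 = make_fixture_dataset(small_config, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_empty_dataset_yields_valid_empty_tables(self, tmp_path):
        cfg = SimConfig(n_bears=0, start_date=date(2006, 6, 1),
                        end_date=date(2006, 6, 11), seed=0)
        paths = make_fixture_dataset(cfg, tmp_path)
        assert len(read_activity_table(paths["activity"])) == 0
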