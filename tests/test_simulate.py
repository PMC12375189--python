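"""Simulator determinism, conservation-by-construction, benchtop fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagescale import (ConfigError, SimConfig, preset, simulate_benchtop,
                       simulate_recording)


class TestRecording:
    def test_same_seed_gives_bit_identical_logs(self):
        cfg = SimConfig(duration_h=0.5)
        log1, _ = simulate_recording(cfg, seed=99)
        log2, _ = simulate_recording(cfg, seed=99)
        pd.testing.assert_frame_equal(log1.records, log2.records)

    def test_different_seed_differs(self):
        cfg = SimConfig(duration_h=0.5)
        log1, _ = simulate_recording(cfg, seed=1)
        log2, _ = simulate_recording(cfg, seed=2)
        assert not np.array_equal(log1.mass, log2.mass)

    def test_zero_bite_rate_means_zero_intake(self):
        cfg = SimConfig(duration_h=1.0, daily_intake_g=0.0,
                        transient_rate_per_h=0.0)
        log, truth = simulate_recording(cfg, seed=5)
        assert truth.n_bites == 0
        assert truth.removed_total == 0.0
        assert np.ptp(truth.true_mass) == 0.0
        # observed mass is flat up to sensor noise
        assert np.ptp(log.mass) < 0.15

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_mass_balance_exact_for_any_seed(self, seed):
        """calibration − final true mass = eaten + crumbs, to the last float."""
        cfg = SimConfig(duration_h=2.0)
        _, truth = simulate_recording(cfg, seed=seed)
        assert cfg.calibration_mass_g - truth.true_mass[-1] \
            == truth.eaten_total + truth.crumb_total

    def test_infeasible_config_rejected(self):
        cfg = SimConfig(duration_h=48.0, calibration_mass_g=1.0,
                        daily_intake_g=5.0)
        with pytest.raises(ConfigError):
            simulate_recording(cfg, seed=0)

    def test_battery_truncation_shortens_log(self):
        cfg = SimConfig(duration_h=8.0, truncate_at_h=2.0)
        log, _ = simulate_recording(cfg, seed=0)
        assert len(log) == 2 * 3600

    def test_crumb_fraction_partitions_every_bite(self):
        cfg = SimConfig(duration_h=4.0, crumb_fraction=0.05)
        _, truth = simulate_recording(cfg, seed=8)
        assert truth.crumb_total == pytest.approx(
            0.05 * truth.removed_total, rel=1e-9)

    def test_chips_injected_when_requested(self):
        cfg = SimConfig(duration_h=12.0, chip_rate_per_day=8.0)
        _, truth = simulate_recording(cfg, seed=4)
        assert len(truth.chip_intervals) > 0

    def test_presets_cover_both_light_modes(self):
        assert preset("wt_ld").light_mode == "LD"
        assert preset("cry_dd").light_mode == "DD"
        with pytest.raises(ConfigError):
            preset("nonesuch")


class TestBenchtop:
    def test_step_fixture_has_12_steps_every_30_minutes(self):
        fx = simulate_benchtop("step", seed=0)
        exp = fx.expected
        assert len(exp["pellet_masses"]) == 12
        np.testing.assert_allclose(np.diff(exp["removal_times"]), 1800.0)
        # true staircase: mass near calibration at start, near zero at end
        assert fx.log.mass[0] == pytest.approx(exp["calibration_mass"],
                                               abs=0.1)
        assert fx.log.mass[-1] == pytest.approx(0.0, abs=0.1)

    def test_drift_fixture_is_static(self):
        fx = simulate_benchtop("drift", seed=1)
        assert np.ptp(fx.log.mass) < 0.15
        assert abs(fx.log.mass.mean() - fx.expected["load"]) < 0.01

    def test_tap_fixture_returns_to_baseline(self):
        fx = simulate_benchtop("tap", seed=2)
        assert abs(fx.log.mass[-60:].mean()
                   - fx.log.mass[:60].mean()) < 0.02

    def test_combined_fixture_scripts_switches_and_lights(self):
        fx = simulate_benchtop("combined", seed=0)
        s1 = fx.log.records["switch1"].to_numpy()
        flips = fx.log.t[np.flatnonzero(np.diff(s1)) + 1]
        np.testing.assert_allclose(flips, fx.expected["switch1_flips"])
        # 12 pellets, 6 per light phase
        assert len(fx.expected["pellet_masses"]) == 12

    def test_unknown_test_rejected(self):
        with pytest.raises(ConfigError):
            simulate_benchtop("voltage")

    def test_calibration_fixture_masses_sum_to_calibration(self):
        for cal in (28.0, 55.0, 82.0):
            fx = simulate_benchtop("calibration", seed=0,
                                   calibration_mass=cal)
            assert fx.expected["pellet_masses"].sum() \
                == pytest.approx(fx.expected["calibration_mass"])
            assert abs(fx.expected["calibration_mass"] - cal) < 0.2 * cal
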