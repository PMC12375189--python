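"""Mass band-pass, plateau/chip filters, LDR smoothing, folding, binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagescale import (ConfigError, FilterConfig, PlateauSeries, chip_filter,
                       compress, crop_trace, fold_daily, ldr_smooth,
                       mass_filter, plateau_filter, recommended_buffer,
                       SimConfig, simulate_recording)


def make_sim(seed: int, **overrides):
    cfg = SimConfig(**{"duration_h": 4.0, **overrides})
    return simulate_recording(cfg, seed=seed)


class TestCrop:
    def test_full_range_is_identity(self, short_sim):
        log, _ = short_sim
        out = crop_trace(log, 0.0, log.t[-1] + 1.0)
        assert len(out) == len(log)
        np.testing.assert_array_equal(out.mass, log.mass)

    def test_48h_log_cropped_to_first_24h_has_86400_samples(self):
        log, _ = simulate_recording(
            SimConfig(duration_h=48.0, transient_rate_per_h=0.0,
                      daily_intake_g=1.0), seed=0)
        out = crop_trace(log, 0.0, 86400.0)
        assert len(out) == 86400

    def test_disjoint_window_raises(self, short_sim):
        log, _ = short_sim
        with pytest.raises(ConfigError):
            crop_trace(log, log.t[-1] + 100.0, log.t[-1] + 200.0)


class TestMassFilter:
    def test_constant_input_identity(self):
        t = np.arange(100.0)
        x = np.full(100, 42.0)
        np.testing.assert_array_equal(mass_filter(t, x, 0.1), x)

    def test_sub_buffer_jitter_flattened(self, rng):
        t = np.arange(600.0)
        x = 30.0 + rng.uniform(-0.04, 0.04, 600)
        out = mass_filter(t, x, buffer=0.1)
        assert np.all(out == out[0])
        assert abs(out[0] - 30.0) < 0.02

    def test_persistent_step_passes_through(self):
        t = np.arange(200.0)
        x = np.where(t < 100, 20.0, 19.5)
        out = mass_filter(t, x, buffer=0.1, min_duration=5.0)
        assert out[0] == 20.0
        assert out[-1] == pytest.approx(19.5)
        assert out[0] - out[-1] == pytest.approx(0.5)

    def test_empty_input(self):
        out = mass_filter(np.array([]), np.array([]), 0.1)
        assert len(out) == 0


class TestPlateauFilter:
    def test_staircase_unchanged(self, default_config):
        t = np.arange(300.0)
        x = np.select([t < 100, t < 200], [10.0, 9.0], 8.0)
        pl = plateau_filter(t, x, default_config)
        np.testing.assert_array_equal(pl.mass, x)

    def test_push_excursion_removed(self, default_config):
        """A +2 g excursion that returns to baseline leaves no trace."""
        t = np.arange(400.0)
        x = np.full(400, 15.0)
        x[100:110] += 2.0
        filtered = mass_filter(t, x, default_config.buffer,
                               default_config.plateau_min_duration)
        pl = plateau_filter(t, filtered, default_config)
        np.testing.assert_allclose(pl.mass, 15.0)

    def test_transient_pull_removed(self, default_config):
        t = np.arange(400.0)
        x = np.full(400, 15.0)
        x[100:115] -= 1.0   # pull, recovers
        filtered = mass_filter(t, x, default_config.buffer,
                               default_config.plateau_min_duration)
        pl = plateau_filter(t, filtered, default_config)
        np.testing.assert_allclose(pl.mass, 15.0)

    def test_simulator_conservation(self, short_sim, default_config):
        """Final plateau equals calibration − removed mass, within buffer."""
        log, truth = short_sim
        fc = default_config
        filtered = mass_filter(log.t, log.mass, fc.buffer,
                               fc.plateau_min_duration)
        pl = plateau_filter(log.t, filtered, fc, raw=log.mass)
        expected = log.calibration_mass - truth.removed_total
        assert abs(pl.mass[-1] - expected) <= fc.buffer

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_output_non_increasing_for_every_seed(self, seed):
        log, _ = make_sim(seed, duration_h=2.0)
        fc = FilterConfig()
        filtered = mass_filter(log.t, log.mass, fc.buffer,
                               fc.plateau_min_duration)
        pl = plateau_filter(log.t, filtered, fc, raw=log.mass)
        assert pl.is_monotone

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_filter_pair_idempotent(self, seed):
        """mass_filter∘plateau_filter applied twice equals applied once."""
        log, _ = make_sim(seed, duration_h=2.0)
        fc = FilterConfig()
        once = plateau_filter(
            log.t, mass_filter(log.t, log.mass, fc.buffer,
                               fc.plateau_min_duration), fc)
        twice = plateau_filter(
            log.t, mass_filter(log.t, once.mass, fc.buffer,
                               fc.plateau_min_duration), fc)
        np.testing.assert_allclose(twice.mass, once.mass, atol=1e-9)


class TestChipFilter:
    def _staircase(self):
        t = np.arange(1200.0)
        x = np.select([t < 400, t < 800], [20.0, 19.0], 18.0)
        return t, x

    def test_clean_staircase_untouched(self, default_config):
        t, x = self._staircase()
        pl = PlateauSeries(times=t, mass=x)
        out, report = chip_filter(pl, default_config, reference=x)
        np.testing.assert_array_equal(out.mass, x)
        assert len(report) == 0

    def test_injected_chip_attenuated_with_mass_balance(self, default_config):
        """Spike then settle 1 g below: the chip contributes no net intake."""
        fc = default_config
        t = np.arange(2000.0)
        true = np.full(2000, 20.0)
        ref = true.copy()
        ref[900:910] = 21.5           # +1.5 g spike
        plateau = true.copy()
        plateau[910:] = 19.0          # settles 1.0 g below pre-spike
        pl = PlateauSeries(times=t, mass=np.minimum.accumulate(plateau))
        out, report = chip_filter(pl, fc, reference=ref)
        assert len(report) == 1
        assert report.events[0].attenuated_mass == pytest.approx(1.0)
        assert not report.events[0].manual
        # net drop across the recording is zero after attenuation
        assert out.mass[-1] == pytest.approx(out.mass[0])
        # attenuated mass equals intake-before minus intake-after, exactly
        assert (pl.mass[0] - pl.mass[-1]) - (out.mass[0] - out.mass[-1]) \
            == pytest.approx(report.total_attenuated)

    def test_manual_interval_forces_attenuation(self, default_config):
        t, x = self._staircase()
        pl = PlateauSeries(times=t, mass=x)
        out, report = chip_filter(pl, default_config,
                                  manual_intervals=[(390.0, 420.0)])
        assert len(report) == 1
        assert report.events[0].manual
        # the genuine 1 g step at t=400 has been cancelled
        assert out.mass[-1] == pytest.approx(19.0)

    def test_overlapping_manual_intervals_rejected(self, default_config):
        t, x = self._staircase()
        pl = PlateauSeries(times=t, mass=x)
        with pytest.raises(ConfigError):
            chip_filter(pl, default_config,
                        manual_intervals=[(100.0, 300.0), (200.0, 400.0)])


class TestLdrSmooth:
    def test_window_one_identity(self, rng):
        x = rng.uniform(0, 100, 50)
        np.testing.assert_array_equal(ldr_smooth(x, 1), x)

    def test_glitch_removed(self):
        x = np.full(50, 10.0)
        x[25] = 500.0
        out = ldr_smooth(x, 3)
        np.testing.assert_array_equal(out, 10.0)

    def test_monotone_ramp_stays_monotone_and_in_range(self):
        x = np.linspace(0, 100, 200)
        out = ldr_smooth(x, 7)
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= x.min() and out.max() <= x.max()


class TestFoldCompress:
    def test_periodic_signal_folds_onto_single_day(self):
        t = np.arange(0, 48 * 3600, 60.0)
        y = np.sin(2 * np.pi * t / 86400.0) + 2.0
        centers, mean, n = fold_daily(t, y, anchor_s=0.0, bin_width_h=1.0)
        assert len(centers) == 24
        day1 = y[t < 86400].reshape(24, 60).mean(axis=1)
        np.testing.assert_allclose(mean, day1, atol=1e-9)
        assert np.all(n == 120)

    def test_fold_anchor_maps_lights_on_to_zt0(self):
        t = np.arange(0, 86400.0, 60.0)
        anchor = 7 * 3600.0
        centers, mean, _ = fold_daily(t, t.copy(), anchor, bin_width_h=0.5)
        # the sample taken at the anchor lands in the first ZT bin
        idx = int(((anchor - anchor) % 86400) // 1800)
        assert idx == 0

    def test_constant_series_constant_bins(self):
        t = np.arange(0, 3600.0)
        tb, agg = compress(t, np.full(3600, 5.0), 60.0, "mean")
        np.testing.assert_allclose(agg, 5.0)

    def test_day_at_1hz_to_60s_bins_is_1440_rows(self):
        t = np.arange(86400.0)
        tb, _ = compress(t, np.zeros(86400), 60.0, "sum")
        assert len(tb) == 1440

    @pytest.mark.parametrize("bin_width", [30.0, 60.0, 613.0, 7200.0])
    def test_binned_increments_conserve_total(self, rng, bin_width):
        t = np.arange(20000.0)
        inc = rng.choice([0.0, 0.01], 20000, p=[0.99, 0.01])
        _, agg = compress(t, inc, bin_width, "sum")
        assert agg.sum() == pytest.approx(inc.sum(), abs=1e-12)


def test_buffer_recommendation_from_drift_fluctuation():
    """Twice the ±0.045 g static fluctuation rounds to the 0.1 g default."""
    assert recommended_buffer(0.045) == pytest.approx(0.1)
    assert FilterConfig().buffer == pytest.approx(recommended_buffer(0.045))
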