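"""Spectral densities, band powers, time courses, spindle detection."""

import numpy as np
import pytest

from remcycle.eeg import (
    SpectralDensity,
    band_power,
    detect_spindles,
    event_rate,
    normalized_timecourse,
    weighted_density_average,
    welch_psd,
)
from remcycle.hypnogram import Hypnogram

FS = 1000.0


def _flat_density(value=1.0, fmax=100.0):
    f = np.arange(0, fmax + 1e-9, 1 / 3)
    return SpectralDensity(frequencies=f, power=np.full(f.size, value), n_windows=1)


class TestWelch:
    def test_tone_localized_on_third_hz_grid(self):
        t = np.arange(0, 30, 1 / FS)
        psd = welch_psd(np.sin(2 * np.pi * 10.0 * t), FS)
        assert psd.frequencies[1] - psd.frequencies[0] == pytest.approx(1 / 3)
        assert psd.frequencies[np.argmax(psd.power)] == pytest.approx(10.0)

    def test_white_noise_total_power_matches_variance(self, rng):
        x = rng.normal(0, 2.0, int(600 * FS))
        psd = welch_psd(x, FS)
        total = np.sum(psd.power) * (psd.frequencies[1] - psd.frequencies[0])
        assert total == pytest.approx(x.var(), rel=0.05)

    def test_matches_scipy_welch_on_one_segment(self, rng):
        from scipy import signal as sps

        x = rng.normal(0, 1, int(60 * FS))
        psd = welch_psd(x, FS)
        f_ref, p_ref = sps.welch(x, FS, window="hann", nperseg=3000, noverlap=1500)
        np.testing.assert_allclose(psd.frequencies, f_ref)
        np.testing.assert_allclose(psd.power, p_ref, rtol=1e-6)

    def test_pooling_two_segments_reduces_variance(self, rng):
        a = rng.normal(0, 1, int(30 * FS))
        b = rng.normal(0, 1, int(30 * FS))
        pooled = welch_psd([a, b], FS)
        single = welch_psd(a, FS)
        assert pooled.n_windows == 2 * single.n_windows
        # pooled density should be closer to the flat truth (2/fs per Hz...
        # compare dispersion around the common mean)
        assert pooled.power[10:200].std() < single.power[10:200].std()

    def test_short_segments_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), FS)


class TestBandPower:
    def test_flat_unit_density_delta_is_four(self):
        # delta band 0.5-4.5 Hz over a flat unit density: exactly 4.0
        assert band_power(_flat_density(), (0.5, 4.5)) == pytest.approx(4.0)

    def test_inverse_square_density_matches_integral(self):
        f = np.arange(0, 100, 1 / 3)
        p = np.where(f > 0, 1.0 / np.maximum(f, 1e-9) ** 2, 0.0)
        psd = SpectralDensity(frequencies=f, power=p, n_windows=1)
        # theta band 5-9.5 Hz: included cell midpoints run from 5.0 to 28/3,
        # so the covered interval is [5 - 1/6, 28/3 + 1/6]
        got = band_power(psd, (5.0, 9.5))
        exact = 1 / (5.0 - 1 / 6) - 1 / (28 / 3 + 1 / 6)
        assert got == pytest.approx(exact, rel=0.01)

    def test_zero_region_is_zero(self):
        f = np.arange(0, 50, 1 / 3)
        psd = SpectralDensity(frequencies=f, power=np.zeros(f.size), n_windows=1)
        assert band_power(psd, (20.0, 30.0)) == 0.0

    def test_additive_over_disjoint_bands(self, rng):
        f = np.arange(0, 50, 1 / 3)
        psd = SpectralDensity(frequencies=f, power=rng.random(f.size), n_windows=1)
        whole = band_power(psd, (0.0, 48.0))
        parts = band_power(psd, (0.0, 16.0)) + band_power(psd, (16.0, 32.0)) + band_power(psd, (32.0, 48.0))
        assert whole == pytest.approx(parts)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            band_power(_flat_density(), (10.0, 5.0))


class TestWeightedAverage:
    def test_one_hot_weights_return_input(self, rng):
        ds = [_flat_density(v) for v in (1.0, 2.0, 3.0)]
        out = weighted_density_average(ds, [1.0, 0.0, 0.0])
        np.testing.assert_array_equal(out.power, ds[0].power)

    def test_uniform_weights_are_mean(self, rng):
        f = np.arange(0, 30, 1 / 3)
        ds = [SpectralDensity(f, rng.random(f.size), 1) for _ in range(4)]
        out = weighted_density_average(ds, [0.25] * 4)
        np.testing.assert_allclose(out.power, np.mean([d.power for d in ds], axis=0))

    def test_random_weights_match_direct_sum(self, rng):
        f = np.arange(0, 30, 1 / 3)
        ds = [SpectralDensity(f, rng.random(f.size), 1) for _ in range(5)]
        w = rng.random(5)
        w /= w.sum()
        out = weighted_density_average(ds, w)
        np.testing.assert_allclose(out.power, sum(wi * d.power for wi, d in zip(w, ds)))

    def test_unnormalised_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            weighted_density_average([_flat_density(), _flat_density()], [0.6, 0.6])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            weighted_density_average([_flat_density(fmax=50), _flat_density(fmax=60)], [0.5, 0.5])


class TestNormalizedTimecourse:
    def test_constant_signal_constant_bins(self):
        out = normalized_timecourse(np.full(24, 3.0), boundary=8)
        np.testing.assert_allclose(out, 3.0)

    def test_linear_ramp_quartile_means(self):
        vals = np.arange(16.0)
        out = normalized_timecourse(vals, boundary=16)  # all refractory
        np.testing.assert_allclose(out[0], [1.5, 5.5, 9.5, 13.5])
        assert np.all(np.isnan(out[1]))

    def test_unequal_period_lengths(self):
        vals = np.arange(24.0)
        out = normalized_timecourse(vals, boundary=8)  # 8 vs 16 epochs
        np.testing.assert_allclose(out[0], [0.5, 2.5, 4.5, 6.5])  # 2 epochs per quartile
        np.testing.assert_allclose(out[1], [9.5, 13.5, 17.5, 21.5])  # 4 per quartile

    def test_short_period_flagged_nan(self):
        out = normalized_timecourse(np.arange(6.0), boundary=2)
        assert np.all(np.isnan(out[0]))
        assert not np.any(np.isnan(out[1]))


def _pink_noise(rng, n):
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / FS)
    spec[1:] /= np.sqrt(f[1:])
    return np.fft.irfft(spec, n) * 30.0


def _burst(fs, freq, dur, amp=8.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.hanning(t.size) * np.sin(2 * np.pi * freq * t)


class TestSpindleDetection:
    def test_single_burst_detected_once(self, rng):
        n = int(60 * FS)
        x = _pink_noise(rng, n)
        x[int(30 * FS) : int(31 * FS)] += _burst(FS, 12.0, 1.0)
        events = detect_spindles(x, FS, nrem_only=False)
        overlapping = [e for e in events if e.onset < 31.2 and e.onset + e.duration > 29.8]
        assert len(overlapping) == 1
        assert 10.0 <= overlapping[0].peak_frequency <= 16.7

    def test_close_bursts_give_one_event(self, rng):
        # two 0.5 s bursts 200 ms apart: a single event (the < 300 ms gap
        # fusion rule plus window overlap guarantee no split)
        n = int(120 * FS)
        x = _pink_noise(rng, n)
        x[int(30.0 * FS) : int(30.5 * FS)] += _burst(FS, 13.0, 0.5)
        x[int(30.7 * FS) : int(31.2 * FS)] += _burst(FS, 13.0, 0.5)
        events = [e for e in detect_spindles(x, FS, nrem_only=False) if 29.5 < e.onset < 31.5]
        assert len(events) == 1
        assert events[0].duration > 1.0

    def test_brief_weak_burst_discarded(self, rng):
        # a 150 ms burst at moderate SNR: only windows covering most of it
        # clear the threshold, and the resulting short run falls to the
        # > 200 ms duration rule
        n = int(120 * FS)
        x = _pink_noise(rng, n)
        x[int(30.0 * FS) : int(30.15 * FS)] += _burst(FS, 13.0, 0.15, amp=2.5)
        assert all(not (29.5 < e.onset < 30.7) for e in detect_spindles(x, FS, nrem_only=False))

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_spindles(np.zeros(1000), 25.0)


class TestCandidateRuns:
    def test_short_gap_fused(self):
        from remcycle.eeg import candidate_runs_to_events

        cand = [1, 1, 1, 0, 0, 1, 1, 1]  # 200 ms gap < 300 ms
        assert candidate_runs_to_events(cand, hop=0.1) == [(0, 8)]

    def test_long_gap_splits(self):
        from remcycle.eeg import candidate_runs_to_events

        cand = [1, 1, 1, 0, 0, 0, 1, 1, 1]  # 300 ms gap is not < 300 ms
        assert candidate_runs_to_events(cand, hop=0.1) == [(0, 3), (6, 9)]

    def test_short_run_discarded(self):
        from remcycle.eeg import candidate_runs_to_events

        cand = [0, 1, 1, 0, 0, 0, 0, 1, 1, 1, 0]  # 0.2 s run <= 200 ms rule
        assert candidate_runs_to_events(cand, hop=0.1) == [(7, 10)]

    def test_fusion_rescues_short_runs(self):
        from remcycle.eeg import candidate_runs_to_events

        cand = [1, 1, 0, 0, 1, 1]  # two 0.2 s runs fuse into one 0.6 s event
        assert candidate_runs_to_events(cand, hop=0.1) == [(0, 6)]


class TestEventRate:
    def test_rate_arithmetic(self):
        h = Hypnogram(("N",) * 72)  # 3 minutes of NREM
        assert event_rate([1.0, 10.0, 50.0, 100.0, 150.0, 170.0], h) == pytest.approx(2.0)

    def test_no_events_zero(self):
        h = Hypnogram(("N",) * 24)
        assert event_rate([], h) == 0.0

    def test_events_outside_state_ignored(self):
        h = Hypnogram(("W",) * 24 + ("N",) * 24)
        # all events fall in the wake half
        assert event_rate([1.0, 30.0], h) == 0.0

    def test_empty_state_rejected(self):
        h = Hypnogram(("W",) * 10)
        with pytest.raises(ValueError):
            event_rate([1.0], h)
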