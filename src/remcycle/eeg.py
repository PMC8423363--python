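"""EEG feature analysis: spectral densities, band powers, spindle detection.

Spectral densities use Welch's method (Hann window, 3 s half-overlapping
segments, 1/3 Hz resolution at 1 kHz sampling).  Band powers are midpoint
Riemann sums of the density over the analysis bands (delta 0.5-4.5 Hz,
theta 5-9.5 Hz, sigma 10-15 Hz) — note these analysis bands differ from
the coarser scoring bands used for automatic staging.

Sleep spindles are transient sigma-band (10-16.67 Hz) bursts.  The
detector works on a 600 ms / 100 ms-step spectrogram and flags bins whose
largest sigma-range spectral peak exceeds the recording-wide 96th
percentile of such peaks and also exceeds half the 0-10 Hz peak value;
flagged bins are merged, near-by events (< 300 ms gaps) fused, events
lasting <= 200 ms discarded, and events kept only when the per-bin peak
frequency lies in the sigma range for at least half of their bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from remcycle.hypnogram import MA, NREM, Hypnogram

#: analysis bands (Hz); distinct from both the staging bands and the spindle band
ANALYSIS_BANDS = {"delta": (0.5, 4.5), "theta": (5.0, 9.5), "sigma": (10.0, 15.0)}

#: spindle detection band (Hz)
SPINDLE_BAND = (10.0, 16.67)


@dataclass(frozen=True)
class SpectralDensity:
    """One-sided power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    n_windows: int

    def __post_init__(self):
        if np.any(np.asarray(self.power) < 0):
            raise ValueError("spectral power must be non-negative")


@dataclass(frozen=True)
class SpindleEvent:
    """A detected (or ground-truth) sigma-band burst."""

    onset: float  # seconds
    duration: float  # seconds
    peak_frequency: float  # Hz

    @property
    def offset(self) -> float:
        return self.onset + self.duration


def welch_psd(segments, fs: float, window_sec: float = 3.0) -> SpectralDensity:
    """Welch power spectral density pooled over signal segments.

    Each segment is cut into ``window_sec`` long, half-overlapping
    Hann-windowed intervals; the averaged periodogram is pooled over all
    windows of all segments (weighted by each segment's window count).
    With 3 s windows the frequency resolution is 1/3 Hz.
    """
    if np.ndim(segments) == 1 or isinstance(segments, np.ndarray) and segments.ndim == 1:
        segments = [segments]
    nperseg = int(round(window_sec * fs))
    step = nperseg // 2
    win = sps.get_window("hann", nperseg)
    scale = 1.0 / (fs * (win**2).sum())

    acc = None
    total = 0
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if seg.size < nperseg:
            continue
        n_win = (seg.size - nperseg) // step + 1
        idx = np.arange(nperseg)[None, :] + step * np.arange(n_win)[:, None]
        frames = seg[idx]
        frames = (frames - frames.mean(axis=1, keepdims=True)) * win  # constant detrend
        spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2 * scale
        # one-sided: double everything except DC (and Nyquist for even nperseg)
        spec[:, 1:] *= 2.0
        if nperseg % 2 == 0:
            spec[:, -1] /= 2.0
        s = spec.sum(axis=0)
        acc = s if acc is None else acc + s
        total += n_win
    if total == 0:
        raise ValueError(f"no segment is at least {window_sec} s long")
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return SpectralDensity(frequencies=freqs, power=acc / total, n_windows=total)


def band_power(psd: SpectralDensity, band) -> float:
    """Midpoint Riemann sum of the density over ``band = (lo, hi)``.

    Each grid frequency is the midpoint of a cell of width equal to the
    grid spacing; cells whose midpoints fall in [lo, hi) contribute.
    """
    lo, hi = band
    if lo >= hi:
        raise ValueError(f"band must satisfy lo < hi, got {band}")
    f = np.asarray(psd.frequencies, dtype=float)
    if lo < f[0] or hi > f[-1] + (f[1] - f[0]):
        raise ValueError(f"band {band} outside the frequency grid [{f[0]}, {f[-1]}]")
    df = float(f[1] - f[0])
    mask = (f >= lo) & (f < hi)
    return float(np.sum(psd.power[mask]) * df)


def weighted_density_average(densities: Sequence[SpectralDensity], weights) -> SpectralDensity:
    """Pointwise weighted average of spectral densities (weights sum to 1).

    This is the linear approximation used to test whether density
    differences between cycle groups are explained by their REM-duration
    composition alone.
    """
    weights = np.asarray(weights, dtype=float)
    if len(densities) != weights.size:
        raise ValueError("one weight per density required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {weights.sum()}")
    f0 = densities[0].frequencies
    for d in densities[1:]:
        if d.frequencies.shape != f0.shape or not np.array_equal(d.frequencies, f0):
            raise ValueError("frequency grids do not match")
    power = sum(w * d.power for w, d in zip(weights, densities))
    return SpectralDensity(frequencies=f0, power=power, n_windows=sum(d.n_windows for d in densities))


def normalized_timecourse(values, boundary: int, n_bins: int = 4) -> np.ndarray:
    """Quartile means of a per-epoch quantity across two normalized periods.

    ``values`` covers one inter-REM interval's epochs; ``boundary`` is the
    index of the first epoch of the second (permissive) period.  Each
    period is normalized to unit length and divided into ``n_bins`` bins
    of equal normalized duration.  Returns a (2, n_bins) array of bin
    means; a period with fewer than ``n_bins`` epochs yields NaNs.
    """
    values = np.asarray(values, dtype=float)
    if not 0 <= boundary <= values.size:
        raise ValueError("boundary outside the value range")
    out = np.full((2, n_bins), np.nan)
    for row, seg in enumerate((values[:boundary], values[boundary:])):
        m = seg.size
        if m < n_bins:
            continue
        bins = (np.arange(m) * n_bins) // m
        for b in range(n_bins):
            out[row, b] = seg[bins == b].mean()
    return out


def candidate_runs_to_events(cand, hop: float, max_gap: float = 0.3, min_duration: float = 0.2):
    """Turn a boolean per-bin candidate mask into event bin-ranges.

    Adjacent flagged bins form runs; runs separated by gaps shorter than
    ``max_gap`` seconds are fused; runs whose fused duration is at most
    ``min_duration`` seconds are discarded.  Returns half-open [start, end)
    bin index pairs.
    """
    cand = np.asarray(cand, dtype=bool)
    runs = []
    i = 0
    n = cand.size
    while i < n:
        if cand[i]:
            j = i
            while j < n and cand[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    if not runs:
        return []
    fused = [runs[0]]
    for s, e in runs[1:]:
        if (s - fused[-1][1]) * hop < max_gap:
            fused[-1][1] = e
        else:
            fused.append([s, e])
    return [(s, e) for s, e in fused if (e - s) * hop > min_duration]


def _sigma_peaks(Sxx: np.ndarray, freqs: np.ndarray, band) -> np.ndarray:
    """Per-time-bin height of the largest local spectral maximum inside ``band``.

    Bins with no local maximum in the band get NaN.
    """
    interior = np.zeros_like(Sxx, dtype=bool)
    interior[1:-1, :] = (Sxx[1:-1, :] > Sxx[:-2, :]) & (Sxx[1:-1, :] >= Sxx[2:, :])
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    masked = np.where(interior & in_band[:, None], Sxx, -np.inf)
    peaks = masked.max(axis=0)
    return np.where(np.isfinite(peaks), peaks, np.nan)


def detect_spindles(
    eeg,
    fs: float,
    hypnogram: Hypnogram | None = None,
    percentile: float = 96.0,
    peak_ratio: float = 0.5,
    max_gap: float = 0.3,
    min_duration: float = 0.2,
    band=SPINDLE_BAND,
    nrem_only: bool = True,
) -> list:
    """Detect sleep spindles in an EEG trace.

    See the module docstring for the detection rules.  With ``nrem_only``
    (the default) candidate bins are restricted to NREM (incl. MA) epochs
    of ``hypnogram`` before merging; pass ``nrem_only=False`` (or no
    hypnogram) for whole-recording detection.
    """
    eeg = np.asarray(eeg, dtype=float)
    if fs < 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for the {band} Hz band")
    nperseg = int(round(0.6 * fs))
    noverlap = int(round(0.5 * fs))
    if eeg.size < nperseg:
        raise ValueError("recording shorter than one 600 ms analysis window")
    freqs, times, Sxx = sps.spectrogram(eeg, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    hop = (nperseg - noverlap) / fs  # 100 ms
    starts = times - 0.5 * nperseg / fs  # window onset times

    peaks = _sigma_peaks(Sxx, freqs, band)
    if np.all(np.isnan(peaks)):
        return []
    thr = np.nanpercentile(peaks, percentile)
    low_mask = (freqs >= 0) & (freqs < 10.0)
    low_peak = Sxx[low_mask, :].max(axis=0)

    with np.errstate(invalid="ignore"):
        cand = (peaks > thr) & (peaks > peak_ratio * low_peak)

    if nrem_only and hypnogram is not None:
        states = hypnogram.as_array()
        epoch_idx = np.clip((times / hypnogram.epoch_len).astype(int), 0, len(states) - 1)
        cand &= np.isin(states[epoch_idx], (NREM, MA))

    fused = candidate_runs_to_events(cand, hop, max_gap=max_gap, min_duration=min_duration)

    # per-bin peak frequency: the dominant peak within the detector's range
    # (0 Hz up to the top of the sigma band); the final majority rule then
    # demands that the sigma peak actually dominates the 0-10 Hz peak in at
    # least half of an event's bins
    det_range = freqs <= band[1]
    peak_freq = freqs[det_range][Sxx[det_range, :].argmax(axis=0)]

    events = []
    for s, e in fused:
        duration = (e - s) * hop
        pf = peak_freq[s:e]
        in_band = (pf >= band[0]) & (pf <= band[1])
        if in_band.sum() * 2 < (e - s):
            continue
        events.append(
            SpindleEvent(
                onset=float(starts[s]),
                duration=float(duration),
                peak_frequency=float(np.median(pf[in_band])),
            )
        )
    return events


def event_rate(event_times, h: Hypnogram, states=(NREM, MA)) -> float:
    """Events per minute of the given state(s).

    ``event_times`` are onset times in seconds; an event counts when its
    onset epoch carries one of ``states``.
    """
    arr = h.as_array()
    state_mask = np.isin(arr, list(states))
    minutes = state_mask.sum() * h.epoch_len / 60.0
    if minutes == 0:
        raise ValueError(f"no time spent in state(s) {states}; rate undefined")
    count = 0
    for t in event_times:
        idx = int(t / h.epoch_len)
        if 0 <= idx < arr.size and state_mask[idx]:
            count += 1
    return count / minutes
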