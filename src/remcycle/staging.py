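"""Automatic brain-state classification from EEG/EMG signals.

The scoring follows threshold rules on spectrogram band powers computed in
5 s half-overlapping windows (2.5 s hypnogram resolution).  Scoring bands:
delta 0.5-4 Hz, theta 5-12 Hz, sigma 12-20 Hz, high gamma 100-150 Hz, EMG
50-500 Hz.  Each band is split at its temporal mean (mean + 1 sd for EMG
and the theta/delta ratio).  REM requires high theta/delta, low EMG and
low delta; NREM requires high delta with low theta/delta and low EMG, or
low EMG and low delta with high sigma; wake covers low delta with high
EMG, and any high-gamma state not classified as REM.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from remcycle.hypnogram import NREM, REM, WAKE, Hypnogram

#: scoring bands (Hz) — deliberately different from the analysis bands in remcycle.eeg
SCORING_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (5.0, 12.0),
    "sigma": (12.0, 20.0),
    "gamma": (100.0, 150.0),
    "emg": (50.0, 500.0),
}


@dataclass(frozen=True)
class SignalRecording:
    """Raw parietal/prefrontal EEG and EMG traces at a common sampling rate."""

    eeg_parietal: np.ndarray
    eeg_prefrontal: np.ndarray
    emg: np.ndarray
    sampling_rate: float = 1000.0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = len(self.eeg_parietal)
        if len(self.eeg_prefrontal) != n or len(self.emg) != n:
            raise ValueError("all channels must have equal length")

    @property
    def duration(self) -> float:
        return len(self.eeg_parietal) / self.sampling_rate


@dataclass(frozen=True)
class ScoringFeatures:
    """Per-2.5 s-bin band powers used by the state classifier."""

    delta: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray
    gamma: np.ndarray
    theta_delta: np.ndarray
    emg: np.ndarray
    epoch_len: float = 2.5

    def __len__(self):
        return len(self.delta)


def _band_sum(Sxx, freqs, band):
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    df = freqs[1] - freqs[0]
    return Sxx[mask, :].sum(axis=0) * df


def compute_scoring_features(rec: SignalRecording, window_sec: float = 5.0) -> ScoringFeatures:
    """Spectrogram band powers in half-overlapping ``window_sec`` windows.

    Consecutive FFTs on 5 s windows with 50% overlap give one feature row
    per 2.5 s hypnogram epoch.
    """
    fs = rec.sampling_rate
    if fs / 2 < SCORING_BANDS["gamma"][1]:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve the 100-150 Hz scoring band")
    if rec.duration < window_sec:
        raise ValueError(f"recording must be at least {window_sec} s long")
    nperseg = int(round(window_sec * fs))
    noverlap = nperseg // 2

    f_eeg, _, S_eeg = sps.spectrogram(
        np.asarray(rec.eeg_parietal, dtype=float), fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    f_emg, _, S_emg = sps.spectrogram(
        np.asarray(rec.emg, dtype=float), fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap
    )

    delta = _band_sum(S_eeg, f_eeg, SCORING_BANDS["delta"])
    theta = _band_sum(S_eeg, f_eeg, SCORING_BANDS["theta"])
    sigma = _band_sum(S_eeg, f_eeg, SCORING_BANDS["sigma"])
    gamma = _band_sum(S_eeg, f_eeg, SCORING_BANDS["gamma"])
    emg = _band_sum(S_emg, f_emg, SCORING_BANDS["emg"])
    with np.errstate(divide="ignore", invalid="ignore"):
        td = np.where(delta > 0, theta / np.maximum(delta, 1e-300), np.inf)
    return ScoringFeatures(
        delta=delta, theta=theta, sigma=sigma, gamma=gamma, theta_delta=td, emg=emg, epoch_len=window_sec / 2
    )


def classify_states(features: ScoringFeatures, phase: str = "unknown") -> Hypnogram:
    """Classify each feature bin as WAKE, NREM or REM.

    Thresholds are data-relative (mean, or mean + 1 sd for EMG and the
    theta/delta ratio), so classification is invariant to rescaling all
    channels by a positive constant.  Rule order: REM first, then the
    high-gamma wake override, then NREM, then wake; bins matching no rule
    inherit the previous bin's label (the first such bin is WAKE).
    """
    f = features
    if not all(np.all(np.isfinite(v)) for v in (f.delta, f.sigma, f.gamma, f.emg)):
        raise ValueError("non-finite feature values")

    # the tiny relative epsilon keeps a constant feature column from being
    # split by floating-point summation error in its own mean
    def _mean_thr(v):
        m = float(np.mean(v))
        return m + 1e-12 * abs(m)

    def _mean_sd_thr(v):
        sd = float(np.std(v))
        if sd == 0:
            warnings.warn("zero-variance feature; threshold degenerates to the mean")
        m = float(np.mean(v))
        return m + sd + 1e-12 * abs(m)

    thr_delta = _mean_thr(f.delta)
    thr_sigma = _mean_thr(f.sigma)
    thr_gamma = _mean_thr(f.gamma)
    td = np.where(np.isfinite(f.theta_delta), f.theta_delta, np.nanmax(np.where(np.isfinite(f.theta_delta), f.theta_delta, 0)))
    thr_td = _mean_sd_thr(td)
    thr_emg = _mean_sd_thr(f.emg)

    is_rem = (td > thr_td) & (f.emg < thr_emg) & (f.delta < thr_delta)
    gamma_wake = f.gamma > thr_gamma
    is_nrem = ((f.delta > thr_delta) & (td <= thr_td) & (f.emg < thr_emg)) | (
        (f.emg < thr_emg) & (f.delta < thr_delta) & (f.sigma > thr_sigma)
    )
    is_wake = (f.delta < thr_delta) & (f.emg > thr_emg)

    labels = []
    prev = WAKE
    for i in range(len(f)):
        if is_rem[i]:
            lab = REM
        elif gamma_wake[i]:
            lab = WAKE
        elif is_nrem[i]:
            lab = NREM
        elif is_wake[i]:
            lab = WAKE
        else:
            lab = prev
        labels.append(lab)
        prev = lab
    return Hypnogram(tuple(labels), epoch_len=f.epoch_len, phase=phase)


def score_recording(rec: SignalRecording, ma_threshold: float = 20.0, phase: str = "unknown") -> Hypnogram:
    """Full staging pipeline: features, classification, microarousal scoring."""
    from remcycle.hypnogram import score_microarousals

    h = classify_states(compute_scoring_features(rec), phase=phase)
    return score_microarousals(h, ma_threshold=ma_threshold)


def read_signals(path, sidecar=None) -> SignalRecording:
    """Read signals from CSV (+ JSON sidecar with ``sampling_rate``) or EDF.

    CSV files need columns ``eeg_parietal, eeg_prefrontal, emg``; the
    sampling rate comes from ``<path>.json`` (or an explicit sidecar path).
    EDF files are read through :mod:`mne` (channels EEG1/EEG2/EMG), when
    that package is available.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()
        names = [n.upper() for n in raw.ch_names]

        def _chan(*keys):
            for k in keys:
                if k in names:
                    return data[names.index(k)]
            raise ValueError(f"EDF is missing a channel among {keys}")

        return SignalRecording(
            eeg_parietal=_chan("EEG1", "EEG PARIETAL"),
            eeg_prefrontal=_chan("EEG2", "EEG PREFRONTAL"),
            emg=_chan("EMG"),
            sampling_rate=float(raw.info["sfreq"]),
        )
    df = pd.read_csv(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    fs = 1000.0
    if sidecar.exists():
        with open(sidecar) as fh:
            fs = float(json.load(fh)["sampling_rate"])
    return SignalRecording(
        eeg_parietal=df["eeg_parietal"].to_numpy(float),
        eeg_prefrontal=df["eeg_prefrontal"].to_numpy(float),
        emg=df["emg"].to_numpy(float),
        sampling_rate=fs,
    )


def write_signals(rec: SignalRecording, path) -> None:
    """Write signals as CSV plus a JSON sidecar with the sampling rate."""
    path = Path(path)
    pd.DataFrame(
        {
            "eeg_parietal": rec.eeg_parietal,
            "eeg_prefrontal": rec.eeg_prefrontal,
            "emg": rec.emg,
        }
    ).to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump({"sampling_rate": rec.sampling_rate}, fh)
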