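"""Synthetic mouse-sleep data with known ground truth.

The generator produces, from a declared ground-truth conditional mixture
model, (i) sleep cycles with their true component labels, (ii) whole
hypnograms on the 2.5 s epoch grid, and (iii) raw EEG/EMG signals with
state-dependent band content and embedded, annotated sleep spindles — so
that every analysis stage (cycle extraction, mixture fitting, taxonomy,
staging, spindle detection) can be tested end to end against known truth.

The default ground-truth coefficients reproduce the qualitative behaviour
of the fitted light-phase model — the long-component weight k_long rising
logarithmically and reaching 1 near REM_pre = 150 s, mu_long increasing
and sigma_long decreasing with REM_pre, and a linearly shrinking
sigma_short — but they are fixture constants of this package, not
estimates from any recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from remcycle.conditional_gmm import ConditionalGMM, ParamCurve, compute_domain_min
from remcycle.eeg import SpindleEvent
from remcycle.hypnogram import MA, NREM, REM, WAKE, Hypnogram, SleepCycle
from remcycle.staging import SignalRecording

EPOCH_LEN = 2.5

#: per-state amplitude templates for the band-limited EEG noise components
#: and the EMG channel (arbitrary units)
SIGNAL_TEMPLATES = {
    WAKE: {"delta": 1.0, "theta": 1.2, "sigma": 0.5, "gamma": 2.0, "emg": 3.0},
    MA: {"delta": 1.0, "theta": 1.2, "sigma": 0.5, "gamma": 2.0, "emg": 3.0},
    NREM: {"delta": 4.0, "theta": 1.0, "sigma": 0.8, "gamma": 0.3, "emg": 0.5},
    REM: {"delta": 0.8, "theta": 3.0, "sigma": 0.5, "gamma": 0.3, "emg": 0.2},
}

#: EEG noise component passbands (Hz)
SIGNAL_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (6.0, 9.5),
    "sigma": (10.0, 15.0),
    "gamma": (100.0, 150.0),
}


def _default_curves() -> dict:
    """Fixture parameter curves, anchored to the reported light-phase magnitudes:
    the short mode sits near ln(85 s), the long mode rises from ~ln(420 s) to
    ~ln(1100 s), k_long grows from ~0.6 at the first bin to 1 at 150 s, and
    sigma_long shrinks from ~0.5 to ~0.3 ln-units."""
    return {
        "k_long": ParamCurve("logarithmic", 0.2886, 30.0, -0.498),
        "mu_long": ParamCurve("logarithmic", 0.547, 40.0, 3.93),
        "mu_short": ParamCurve("logarithmic", -0.12, 30.0, 4.96),
        "sigma_long": ParamCurve("logarithmic", -0.185, 30.0, 1.383),
        "sigma_short": ParamCurve("linear", -0.0005, 0.42),
    }


@dataclass(frozen=True)
class GroundTruth:
    """Declared generating process for synthetic sleep data.

    Parameters
    ----------
    model : ConditionalGMM
        The conditional mixture that generates ln(|N|) given REM_pre.
    rem_shape, rem_scale : float
        Gamma law of REM episode durations (seconds), truncated to
        [rem_min, rem_max); the near-exponential default (shape 1.3,
        scale 65) has a ~85 s mean, typical for mouse light-phase REM
        episodes, and populates all 30 s REM_pre bins well enough for
        reliable per-bin mixture estimation.
    wake_p_zero : float
        Probability that an inter-REM interval contains no wake episode
        (0.43 by default, mirroring the share of uninterrupted cycles).
    wake_geom_p : float
        Success probability of the geometric law for the wake-episode
        count when nonzero.
    wake_mu, wake_sigma : float
        Lognormal parameters of wake-episode durations (seconds),
        truncated below at ``wake_min`` so wake episodes stay above the
        default microarousal threshold.
    ma_rate : float
        Microarousal bouts per minute of NREM (carved out of |N|).
    spindle_rate : float
        Embedded spindle bursts per minute of NREM.
    spindle_amp : float
        Burst amplitude; the default puts the burst's sigma-band envelope
        well above both the NREM sigma background and half the delta peak,
        i.e. bursts are unambiguous, as in a hand-annotated reference set.
    """

    model: ConditionalGMM
    rem_shape: float = 1.3
    rem_scale: float = 65.0
    rem_min: float = 2.5
    rem_max: float = 240.0
    wake_p_zero: float = 0.43
    wake_geom_p: float = 0.55
    wake_mu: float = 4.0  # ln-seconds: median ~55 s
    wake_sigma: float = 0.7
    wake_min: float = 22.5
    ma_rate: float = 0.5
    spindle_rate: float = 2.0
    spindle_amp: float = 8.0
    sampling_rate: float = 1000.0


def default_ground_truth(phase: str = "light") -> GroundTruth:
    """The standard synthetic fixture used throughout the test-suite."""
    curves = _default_curves()
    model = ConditionalGMM(
        curves=curves,
        domain_min=compute_domain_min(curves),
        phase=phase,
    )
    return GroundTruth(model=model)


def dark_like_ground_truth() -> GroundTruth:
    """A second fixture with a shifted long component (dark-phase-like):
    larger k_long (fewer sequential cycles), larger mu_long and sigma_long."""
    curves = _default_curves()
    curves["mu_long"] = ParamCurve("logarithmic", 0.547, 40.0, 4.23)
    curves["sigma_long"] = ParamCurve("logarithmic", -0.185, 30.0, 1.46)
    curves["k_long"] = ParamCurve("logarithmic", 0.2886, 30.0, -0.398)
    model = ConditionalGMM(curves=curves, domain_min=compute_domain_min(curves), phase="dark")
    return GroundTruth(model=model)


def _quantize(seconds, epoch_len=EPOCH_LEN):
    """Round a duration to the epoch grid, at least one epoch."""
    return max(1, int(round(seconds / epoch_len))) * epoch_len


def _draw_rem_pre(gt: GroundTruth, rng: np.random.Generator) -> float:
    """One REM episode duration: truncated gamma, quantized to the epoch grid."""
    while True:
        x = rng.gamma(gt.rem_shape, gt.rem_scale)
        if gt.rem_min <= x < gt.rem_max:
            return _quantize(x)


def _draw_wake_structure(gt: GroundTruth, rng: np.random.Generator):
    """Wake-episode durations for one inter-REM interval (possibly empty)."""
    if rng.random() < gt.wake_p_zero:
        return ()
    count = int(rng.geometric(gt.wake_geom_p))
    durs = []
    for _ in range(count):
        while True:
            d = float(np.exp(rng.normal(gt.wake_mu, gt.wake_sigma)))
            if d >= gt.wake_min:
                durs.append(_quantize(d))
                break
    return tuple(durs)


def generate_cycles(gt: GroundTruth, n: int, rng: np.random.Generator):
    """Draw ``n`` independent sleep cycles plus their true component labels.

    Returns a list of (SleepCycle, label) with label "long" or "short".
    REM_pre follows the ground-truth REM law; the component is Bernoulli
    in k_long(REM_pre); ln(|N|) is drawn from that component; the wake
    structure follows the wake law.  All durations are quantized to the
    2.5 s epoch grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = gt.model
    out = []
    for _ in range(n):
        rem_pre = _draw_rem_pre(gt, rng)
        p = m.parameters(max(rem_pre, m.domain_min))
        is_long = rng.random() < p.k_long
        ln_n = rng.normal(p.mu_long, p.sigma_long) if is_long else rng.normal(p.mu_short, p.sigma_short)
        n_total = _quantize(float(np.exp(ln_n)))
        wake = _draw_wake_structure(gt, rng)
        cyc = SleepCycle(
            rem_pre=rem_pre,
            n_total=n_total,
            w_total=float(sum(wake)),
            wake_episode_durations=wake,
            rem_post=_draw_rem_pre(gt, rng),
            start_index=-1,
        )
        out.append((cyc, "long" if is_long else "short"))
    return out


def _inter_rem_epochs(cycle: SleepCycle, gt: GroundTruth, rng: np.random.Generator):
    """Epoch labels of one inter-REM interval: NREM with MAs and wake inserts."""
    n_ep = int(round(cycle.n_total / EPOCH_LEN))
    labels = [NREM] * n_ep

    # microarousal bouts carved out of the NREM epochs (they count into |N|)
    n_ma = rng.poisson(gt.ma_rate * cycle.n_total / 60.0)
    placed = 0
    attempts = 0
    taken = np.zeros(n_ep, dtype=bool)
    while placed < n_ma and attempts < 10 * n_ma + 10:
        attempts += 1
        ma_len = int(rng.integers(1, 9))  # 2.5-20 s
        if n_ep - 2 <= ma_len:
            break
        start = int(rng.integers(1, n_ep - ma_len - 1))
        # keep one NREM epoch on each side so MAs never touch wake inserts or REM
        lo, hi = max(0, start - 1), min(n_ep, start + ma_len + 1)
        if taken[lo:hi].any():
            continue
        for j in range(start, start + ma_len):
            labels[j] = MA
        taken[lo:hi] = True
        placed += 1

    # wake episodes inserted at uniformly random cut positions
    cuts = sorted(rng.integers(0, n_ep + 1, size=cycle.wake_episode_count))
    out = []
    prev = 0
    for cut, dur in zip(cuts, cycle.wake_episode_durations):
        out.extend(labels[prev:cut])
        out.extend([WAKE] * int(round(dur / EPOCH_LEN)))
        prev = cut
    out.extend(labels[prev:])
    return out


def generate_hypnogram(gt: GroundTruth, total_duration: float, rng: np.random.Generator):
    """Concatenate generated cycles into a hypnogram of ~``total_duration`` s.

    Returns (Hypnogram, cycles) where the cycles carry their true epoch
    ``start_index``.  The hypnogram starts with a wake prefix and is
    truncated at ``total_duration``; only cycles whose terminating REM
    episode starts inside the truncated record are returned, so that
    :func:`remcycle.hypnogram.extract_cycles` recovers their rem_pre and
    inter_rem exactly (the last cycle's rem_post may be cut short).
    """
    n_target = int(total_duration / EPOCH_LEN)
    epochs = [WAKE] * 24  # 60 s lead-in
    cycles = []
    rem_pre = _draw_rem_pre(gt, rng)
    m = gt.model
    while len(epochs) < n_target:
        start_index = len(epochs)
        epochs.extend([REM] * int(round(rem_pre / EPOCH_LEN)))
        p = m.parameters(max(rem_pre, m.domain_min))
        is_long = rng.random() < p.k_long
        ln_n = rng.normal(p.mu_long, p.sigma_long) if is_long else rng.normal(p.mu_short, p.sigma_short)
        wake = _draw_wake_structure(gt, rng)
        rem_next = _draw_rem_pre(gt, rng)
        cyc = SleepCycle(
            rem_pre=rem_pre,
            n_total=_quantize(float(np.exp(ln_n))),
            w_total=float(sum(wake)),
            wake_episode_durations=wake,
            rem_post=rem_next,
            start_index=start_index,
        )
        epochs.extend(_inter_rem_epochs(cyc, gt, rng))
        if len(epochs) < n_target:  # terminating REM episode begins inside the record
            cycles.append(cyc)
        rem_pre = rem_next
    epochs.extend([REM] * int(round(rem_pre / EPOCH_LEN)))
    epochs = epochs[:n_target]
    # drop trailing cycles whose terminating REM start was truncated away
    cycles = [c for c in cycles if c.start_index + (c.rem_pre + c.inter_rem) / EPOCH_LEN < n_target]
    return Hypnogram(tuple(epochs), epoch_len=EPOCH_LEN, phase=m.phase), cycles


def _band_noise(n, fs, band, rng):
    """Unit-variance band-limited Gaussian noise."""
    from scipy import signal as sps

    lo, hi = band
    sos = sps.butter(4, [lo, min(hi, fs / 2 * 0.999)], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_signals(h: Hypnogram, gt: GroundTruth, rng: np.random.Generator):
    """Synthesize EEG/EMG traces consistent with a hypnogram.

    Each epoch's EEG is a sum of band-limited noise components scaled by
    the state's amplitude template; spindle bursts (10-15.5 Hz Hann-windowed
    wave packets, 0.5-1.5 s) are injected into NREM epochs of the
    prefrontal EEG at ``gt.spindle_rate`` per NREM minute and returned as
    ground-truth annotations.
    """
    if len(h) == 0:
        raise ValueError("empty hypnogram")
    fs = gt.sampling_rate
    spe = int(round(h.epoch_len * fs))  # samples per epoch
    n = len(h) * spe

    # per-sample amplitude envelopes from the state templates
    states = h.as_array()
    env = {}
    for band in list(SIGNAL_BANDS) + ["emg"]:
        amps = np.array([SIGNAL_TEMPLATES[s][band] for s in states])
        env[band] = np.repeat(amps, spe)

    def _eeg():
        sig = 0.15 * rng.standard_normal(n)  # broadband floor
        for band, rng_band in SIGNAL_BANDS.items():
            sig = sig + env[band] * _band_noise(n, fs, rng_band, rng)
        return sig

    eeg_parietal = _eeg()
    eeg_prefrontal = _eeg()
    emg = env["emg"] * _band_noise(n, fs, (50.0, 499.0), rng)

    # spindle bursts in NREM epochs of the prefrontal EEG
    nrem_minutes = float(np.isin(states, (NREM, MA)).sum()) * h.epoch_len / 60.0
    n_spindles = rng.poisson(gt.spindle_rate * nrem_minutes)
    nrem_epochs = np.flatnonzero(states == NREM)
    events = []
    occupied = np.zeros(len(h), dtype=bool)
    attempts = 0
    while len(events) < n_spindles and attempts < 20 * n_spindles + 20 and nrem_epochs.size:
        attempts += 1
        ep = int(rng.choice(nrem_epochs))
        if occupied[max(0, ep - 1): ep + 2].any():
            continue
        dur = float(rng.uniform(0.5, 1.5))
        onset = ep * h.epoch_len + float(rng.uniform(0, max(h.epoch_len - dur, 0.01)))
        freq = float(rng.uniform(10.0, 15.5))
        i0 = int(onset * fs)
        i1 = min(i0 + int(dur * fs), n)
        if i1 - i0 < int(0.4 * fs):
            continue
        t = np.arange(i1 - i0) / fs
        packet = gt.spindle_amp * np.hanning(i1 - i0) * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        eeg_prefrontal[i0:i1] += packet
        occupied[max(0, ep - 1): ep + 2] = True
        events.append(SpindleEvent(onset=onset, duration=(i1 - i0) / fs, peak_frequency=freq))

    events.sort(key=lambda e: e.onset)
    rec = SignalRecording(
        eeg_parietal=eeg_parietal, eeg_prefrontal=eeg_prefrontal, emg=emg, sampling_rate=fs
    )
    return rec, events
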