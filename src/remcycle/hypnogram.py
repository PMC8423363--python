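"""Hypnogram I/O, microarousal scoring and sleep-cycle segmentation.

A hypnogram is a sequence of brain-state labels on a fixed epoch grid
(2.5 s by default).  States are WAKE ("W"), NREM ("N"), REM ("R") and,
after microarousal scoring, MA ("M") for brief wake bouts embedded in
NREM sleep.  A sleep cycle comprises one REM episode and the following
inter-REM interval; the interval is split into its total NREM content
|N| (microarousals included) and total wake content |W|.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WAKE = "W"
NREM = "N"
REM = "R"
MA = "M"

STATES = (WAKE, NREM, REM, MA)

#: states whose time counts into |N| of an inter-REM interval
_NREM_LIKE = frozenset({NREM, MA})


class HypnogramFormatError(ValueError):
    """Raised when a hypnogram file cannot be parsed."""


@dataclass(frozen=True)
class Hypnogram:
    """Epoch-label time series.

    Parameters
    ----------
    epochs : tuple of str
        State label per epoch, each one of ``"W"``, ``"N"``, ``"R"``, ``"M"``.
    epoch_len : float
        Epoch duration in seconds (default 2.5).
    phase : str
        ``"light"``, ``"dark"`` or ``"unknown"``.
    """

    epochs: tuple
    epoch_len: float = 2.5
    phase: str = "unknown"

    def __post_init__(self):
        if self.epoch_len <= 0:
            raise ValueError(f"epoch_len must be positive, got {self.epoch_len}")
        bad = set(self.epochs) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        object.__setattr__(self, "epochs", tuple(self.epochs))

    def __len__(self):
        return len(self.epochs)

    @property
    def duration(self) -> float:
        """Total recording duration in seconds."""
        return len(self.epochs) * self.epoch_len

    def as_array(self) -> np.ndarray:
        return np.asarray(self.epochs, dtype="U1")


@dataclass(frozen=True)
class SleepCycle:
    """One REM episode plus the following inter-REM interval.

    Durations are in seconds and always integer multiples of the epoch
    length.  ``n_total`` (|N|) counts NREM *and* microarousal epochs;
    ``w_total`` (|W|) counts wake epochs only.
    """

    rem_pre: float
    n_total: float
    w_total: float
    wake_episode_durations: tuple
    rem_post: float
    start_index: int

    @property
    def inter_rem(self) -> float:
        return self.n_total + self.w_total

    @property
    def wake_episode_count(self) -> int:
        return len(self.wake_episode_durations)


def _runs(labels: Sequence[str]):
    """Yield (label, start, length) for maximal runs of equal labels."""
    labels = list(labels)
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        yield labels[i], i, j - i
        i = j


def read_hypnogram(path, epoch_len: float | None = None, phase: str = "unknown") -> Hypnogram:
    """Read a hypnogram from CSV with columns ``time_s,state``.

    The epoch length is inferred from the time deltas unless given
    explicitly.  Unknown state labels raise :class:`HypnogramFormatError`
    naming the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise HypnogramFormatError(f"{path}: empty hypnogram file") from None
    if df.empty:
        raise HypnogramFormatError(f"{path}: empty hypnogram file")
    if "state" not in df.columns:
        raise HypnogramFormatError(f"{path}: missing 'state' column")
    states = df["state"].astype(str).str.strip().tolist()
    for i, s in enumerate(states):
        if s not in STATES:
            raise HypnogramFormatError(f"{path}: unknown state label {s!r} at row {i}")
    if epoch_len is None:
        if "time_s" in df.columns and len(df) > 1:
            deltas = np.diff(df["time_s"].to_numpy(dtype=float))
            epoch_len = float(np.median(deltas))
        else:
            epoch_len = 2.5
    return Hypnogram(tuple(states), epoch_len=epoch_len, phase=phase)


def write_hypnogram(h: Hypnogram, path) -> None:
    """Write a hypnogram as CSV with columns ``time_s,state``."""
    t = np.arange(len(h)) * h.epoch_len
    pd.DataFrame({"time_s": t, "state": list(h.epochs)}).to_csv(path, index=False)


def score_microarousals(h: Hypnogram, ma_threshold: float = 20.0) -> Hypnogram:
    """Relabel brief wake bouts as microarousals.

    Every maximal run of WAKE epochs whose total duration is less than or
    equal to ``ma_threshold`` seconds is relabeled MA.  With a threshold of
    0 s no epoch is relabeled.  The operation is idempotent.
    """
    if ma_threshold < 0:
        raise ValueError(f"ma_threshold must be non-negative, got {ma_threshold}")
    labels = list(h.epochs)
    for lab, start, length in _runs(labels):
        if lab == WAKE and length * h.epoch_len <= ma_threshold:
            labels[start:start + length] = [MA] * length
    return replace(h, epochs=tuple(labels))


def extract_cycles(h: Hypnogram) -> list:
    """Segment a hypnogram into sleep cycles.

    A cycle requires a leading and a terminating REM episode, so a
    hypnogram with fewer than two REM episodes yields an empty list.
    Material before the first and after the last REM episode is dropped.
    Microarousal epochs count into ``n_total``, not ``w_total``.
    """
    runs = list(_runs(h.epochs))
    rem_runs = [(start, length) for lab, start, length in runs if lab == REM]
    cycles = []
    for (s0, l0), (s1, l1) in zip(rem_runs, rem_runs[1:]):
        gap_start, gap_end = s0 + l0, s1
        n_epochs = 0
        wake_durs = []
        for lab, start, length in _runs(h.epochs[gap_start:gap_end]):
            if lab in _NREM_LIKE:
                n_epochs += length
            elif lab == WAKE:
                wake_durs.append(length * h.epoch_len)
        cycles.append(
            SleepCycle(
                rem_pre=l0 * h.epoch_len,
                n_total=n_epochs * h.epoch_len,
                w_total=float(sum(wake_durs)),
                wake_episode_durations=tuple(wake_durs),
                rem_post=l1 * h.epoch_len,
                start_index=s0,
            )
        )
    return cycles


def cycles_to_frame(cycles: Iterable[SleepCycle]) -> pd.DataFrame:
    """Tabulate cycles, one row per cycle."""
    rows = [
        {
            "rem_pre": c.rem_pre,
            "inter_rem": c.inter_rem,
            "n_total": c.n_total,
            "w_total": c.w_total,
            "wake_episode_count": c.wake_episode_count,
            "rem_post": c.rem_post,
            "start_index": c.start_index,
        }
        for c in cycles
    ]
    return pd.DataFrame(rows)


def frame_to_cycles(df: pd.DataFrame) -> list:
    """Inverse of :func:`cycles_to_frame` (wake episode structure reduced to totals)."""
    out = []
    for _, r in df.iterrows():
        k = int(r.get("wake_episode_count", 0))
        w = float(r["w_total"])
        durs = tuple([w / k] * k) if k else ()
        out.append(
            SleepCycle(
                rem_pre=float(r["rem_pre"]),
                n_total=float(r["n_total"]),
                w_total=w,
                wake_episode_durations=durs,
                rem_post=float(r["rem_post"]),
                start_index=int(r.get("start_index", -1)),
            )
        )
    return out
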