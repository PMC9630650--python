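"""Raw-stream preprocessing: band-pass + notch filtering, trigger
detection, MVC normalization, and trial segmentation.

All filtering is zero-phase (forward-backward): the analysis is
offline, and zero-phase application preserves the temporal alignment
between the EMG envelope and the force channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import (
    CHANNELS,
    MOVEMENTS,
    TRIAL_SECONDS,
    SessionRecording,
)

#: Trial phase boundaries (s) of a classification trial: rest, reach,
#: force ramp, hold.
PHASES = {
    "rest": (0.0, 7.0),
    "reach": (7.0, 7.5),
    "ramp": (7.5, 9.0),
    "hold": (9.0, 13.0),
}

#: Analysis window used for classification (s).  The hold phase is
#: nominally 9-13 s, but analysis is restricted to 10-13 s where the
#: force has fully settled; configurable wherever it is used.
ANALYSIS_WINDOW = (10.0, 13.0)


@dataclass(frozen=True)
class FilterSpec:
    """EMG filter design: 6th-order Butterworth band-pass 10-500 Hz
    plus a 50 Hz notch, applied zero-phase."""

    band: tuple[float, float] = (10.0, 500.0)
    order: int = 6
    notch_freq: float = 50.0
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.order < 2 or self.order % 2:
            raise ValueError("filter order must be even and >= 2")


def design_filters(spec: FilterSpec, fs: float):
    """Return (band-pass sos, notch (b, a)) for sampling rate ``fs``."""
    low, high = spec.band
    if high >= fs / 2:
        raise ValueError(f"band edge {high} Hz >= Nyquist ({fs / 2} Hz)")
    # scipy's band-pass order doubles: order//2 gives a filter of the
    # requested overall order.
    sos = signal.butter(spec.order // 2, spec.band, btype="bandpass", fs=fs, output="sos")
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    return sos, (b, a)


def bandpass_notch(
    emg: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase band-pass + notch filter along the last axis.

    Accepts a single channel (1-D) or a channels x samples array.
    """
    sos, (b, a) = design_filters(spec, fs)
    x = signal.sosfiltfilt(sos, emg, axis=-1)
    return signal.filtfilt(b, a, x, axis=-1)


def detect_triggers(
    trigger: np.ndarray,
    threshold: float = 0.5,
    fs: float = 2000.0,
    merge_s: float = 0.1,
) -> np.ndarray:
    """Leading-edge samples of supra-threshold trigger pulses.

    Edges closer than ``merge_s`` are merged into the earliest one.
    An empty result is returned with a warning, never silently.
    """
    above = np.asarray(trigger) >= threshold
    edges = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if edges.size == 0:
        warnings.warn("no trigger pulses found", stacklevel=2)
        return edges
    merged = [int(edges[0])]
    gap = merge_s * fs
    for e in edges[1:]:
        if e - merged[-1] >= gap:
            merged.append(int(e))
    return np.array(merged, dtype=int)


@dataclass(frozen=True)
class MvcReference:
    """Maximum-voluntary-contraction reference for one movement: the
    mean of three recorded maxima."""

    movement: str
    value: float
    source_maxima: tuple[float, float, float]


def compute_mvc(maxima, movement: str = "palmar") -> MvcReference:
    """MVC reference = arithmetic mean of three trial maxima (N)."""
    maxima = tuple(float(m) for m in maxima)
    if len(maxima) != 3:
        raise ValueError("exactly three MVC maxima are required")
    if any(m <= 0 for m in maxima):
        raise ValueError("MVC maxima must be positive")
    return MvcReference(movement, float(np.mean(maxima)), maxima)


@dataclass
class Trial:
    """One filtered, MVC-normalized 13 s trial."""

    emg: np.ndarray  # (8, M), filtered, arbitrary volts
    force: np.ndarray  # (M,), %MVC
    movement: str
    condition: str  # "L20"/"L50"/"L80" or profile kind
    fs: float
    trial_id: int = 0

    def __post_init__(self) -> None:
        if self.emg.shape[1] != len(self.force):
            raise ValueError("EMG and force must be the same length")
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement {self.movement!r}")

    @property
    def duration(self) -> float:
        return len(self.force) / self.fs

    @property
    def level(self) -> float | None:
        """Force level in %MVC for classification trials, else None."""
        if self.condition.startswith("L"):
            return float(self.condition[1:])
        return None


def cut_trials(
    session: SessionRecording,
    onsets,
    mvc: dict[str, MvcReference],
    spec: FilterSpec = FilterSpec(),
    tolerance_samples: int = 40,
) -> list[Trial]:
    """Filter the session's EMG and cut 13 s trials at trigger onsets.

    Each onset is matched to the nearest annotation (within
    ``tolerance_samples``) to obtain its movement/condition label and
    MVC reference; force is normalized to %MVC.  Trials running past
    the stream end are dropped with a warning.
    """
    emg_f = bandpass_notch(session.emg, session.fs, spec)
    n_trial = int(round(TRIAL_SECONDS * session.fs))
    ann_onsets = np.array([a.onset_sample for a in session.annotations])
    trials = []
    for onset in np.atleast_1d(np.asarray(onsets, dtype=int)):
        j = int(np.argmin(np.abs(ann_onsets - onset)))
        if abs(int(ann_onsets[j]) - int(onset)) > tolerance_samples:
            warnings.warn(f"onset {onset} matches no annotation; skipped", stacklevel=2)
            continue
        if onset + n_trial > session.n_samples:
            warnings.warn(f"trial at {onset} extends past stream end; dropped", stacklevel=2)
            continue
        ann = session.annotations[j]
        ref = mvc[ann.movement]
        trials.append(
            Trial(
                emg=emg_f[:, onset : onset + n_trial],
                force=session.force[onset : onset + n_trial] / ref.value * 100.0,
                movement=ann.movement,
                condition=ann.condition,
                fs=session.fs,
                trial_id=ann.index,
            )
        )
    return trials


def mvc_from_annotations(session: SessionRecording) -> dict[str, MvcReference]:
    """Convenience MVC references for simulated sessions: the known
    simulator MVC constants wrapped as three identical maxima."""
    from .simulate import MVC_NEWTONS

    return {
        m: compute_mvc((MVC_NEWTONS[m],) * 3, m)
        for m in {a.movement for a in session.annotations}
    }


def extract_phase(
    trial: Trial, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Slice (emg, force) for a ``(start_s, end_s)`` window of a trial."""
    start, end = window
    if not 0 <= start < end <= trial.duration + 1e-9:
        raise ValueError(f"invalid phase window {window}")
    i0 = int(round(start * trial.fs))
    i1 = int(round(end * trial.fs))
    return trial.emg[:, i0:i1], trial.force[i0:i1]
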