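"""Sliding-window segmentation and the five time-domain EMG features.

Features (per window ``x`` of N samples):

- MAV, mean absolute value: ``(1/N) sum |x_i|``
- RMS, root mean square: ``sqrt((1/N) sum x_i^2)``
- VAR, sample variance: ``(1/(N-1)) sum (x_i - mean)^2`` — defined with
  mean subtraction and the N-1 denominator; EMG is near zero-mean so
  the choice is benign, but it is stated because parts of the EMG
  literature omit the mean.
- WAMP, Willison amplitude: count of consecutive-sample differences
  with ``|x_{i+1} - x_i| >= threshold``
- WL, waveform length: ``sum |x_{i+1} - x_i}|`` (total variation)

The WAMP threshold defaults to an adaptive per-channel value, twice
the median absolute deviation of the trial's rest-phase signal, which
makes the feature scale-free across simulator gain settings; a fixed
value can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .preprocessing import ANALYSIS_WINDOW, Trial, extract_phase
from .simulate import CHANNELS

FEATURE_NAMES = ("mav", "rms", "var", "wamp", "wl")

#: Rest window (s) used to calibrate the adaptive WAMP threshold;
#: force is zero over [0, 4] s for every profile used here.
WAMP_REST_WINDOW = (0.0, 4.0)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width/step in ms at sampling rate fs."""

    width_ms: float
    step_ms: float
    fs: float = 2000.0

    def __post_init__(self) -> None:
        if not self.width_ms >= self.step_ms > 0:
            raise ValueError("need width >= step > 0")
        for ms in (self.width_ms, self.step_ms):
            if abs(ms * self.fs / 1000.0 - round(ms * self.fs / 1000.0)) > 1e-9:
                raise ValueError(f"{ms} ms is not a whole number of samples at {self.fs} Hz")

    @property
    def width(self) -> int:
        return int(round(self.width_ms * self.fs / 1000.0))

    @property
    def step(self) -> int:
        return int(round(self.step_ms * self.fs / 1000.0))


#: The two window settings used by the two analyses.
CLASSIFICATION_WINDOW = WindowSpec(175.0, 20.0)
REGRESSION_WINDOW = WindowSpec(200.0, 80.0)


def window_indices(length: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open (start, end) sample ranges of all full windows.

    Count = floor((length - W) / S) + 1; trailing partial windows are
    discarded.  Returns [] with a warning when the signal is shorter
    than one window.
    """
    w, s = spec.width, spec.step
    if length < w:
        warnings.warn(f"signal of {length} samples shorter than one {w}-sample window",
                      stacklevel=2)
        return []
    count = (length - w) // s + 1
    return [(i * s, i * s + w) for i in range(count)]


def _check_window(x: np.ndarray, min_len: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < min_len:
        raise ValueError(f"need a 1-D window of at least {min_len} samples")
    return x


def mav(x) -> float:
    x = _check_window(x)
    return float(np.mean(np.abs(x)))


def rms(x) -> float:
    x = _check_window(x)
    return float(np.sqrt(np.mean(x**2)))


def var(x) -> float:
    x = _check_window(x, min_len=2)
    return float(np.var(x, ddof=1))


def wamp(x, threshold: float) -> int:
    x = _check_window(x, min_len=2)
    if threshold < 0:
        raise ValueError("WAMP threshold must be nonnegative")
    return int(np.count_nonzero(np.abs(np.diff(x)) >= threshold))


def wl(x) -> float:
    x = _check_window(x, min_len=2)
    return float(np.sum(np.abs(np.diff(x))))


def adaptive_wamp_threshold(rest: np.ndarray) -> float:
    """2 x median absolute deviation of the rest-phase signal."""
    rest = np.asarray(rest, dtype=float)
    return float(2.0 * np.median(np.abs(rest - np.median(rest))))


def _window_features(
    windows: np.ndarray, features: tuple[str, ...], wamp_thr: float
) -> np.ndarray:
    """Feature columns for a (n_windows, W) stack of one channel."""
    out = np.empty((windows.shape[0], len(features)))
    diffs = np.abs(np.diff(windows, axis=1))
    for j, name in enumerate(features):
        if name == "mav":
            out[:, j] = np.mean(np.abs(windows), axis=1)
        elif name == "rms":
            out[:, j] = np.sqrt(np.mean(windows**2, axis=1))
        elif name == "var":
            out[:, j] = np.var(windows, axis=1, ddof=1)
        elif name == "wamp":
            out[:, j] = np.count_nonzero(diffs >= wamp_thr, axis=1)
        elif name == "wl":
            out[:, j] = np.sum(diffs, axis=1)
        else:
            raise ValueError(f"unknown feature {name!r}")
    return out


@dataclass
class FeatureMatrix:
    """Windows x (channels x features) matrix with aligned targets.

    Columns are channel-major ("C1_mav", "C1_rms", ..., "C2_mav", ...);
    each row is one window of one trial.  ``y_force`` is the window-mean
    force in %MVC; class labels are derived downstream from the
    per-row movement/condition metadata.
    """

    X: np.ndarray
    columns: list[str]
    trial_ids: np.ndarray
    movements: np.ndarray
    conditions: np.ndarray
    y_force: np.ndarray
    channels: tuple[str, ...]
    features: tuple[str, ...] = FEATURE_NAMES
    window_times: np.ndarray = field(default=None, repr=False)

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def select_channels(self, channels) -> "FeatureMatrix":
        """Column-block view restricted to a channel subset (order of
        ``channels`` defines the new block order)."""
        channels = tuple(channels)
        nf = len(self.features)
        idx = []
        for ch in channels:
            i = self.channels.index(ch)
            idx.extend(range(i * nf, (i + 1) * nf))
        return FeatureMatrix(
            X=self.X[:, idx],
            columns=[self.columns[i] for i in idx],
            trial_ids=self.trial_ids,
            movements=self.movements,
            conditions=self.conditions,
            y_force=self.y_force,
            channels=channels,
            features=self.features,
            window_times=self.window_times,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "trial_id", self.trial_ids)
        df.insert(1, "movement", self.movements)
        df.insert(2, "condition", self.conditions)
        df["y_force"] = self.y_force
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c not in ("trial_id", "movement", "condition", "y_force")]
        channels = tuple(dict.fromkeys(c.split("_")[0] for c in cols))
        features = tuple(dict.fromkeys(c.split("_", 1)[1] for c in cols))
        return cls(
            X=df[cols].to_numpy(),
            columns=cols,
            trial_ids=df["trial_id"].to_numpy(),
            movements=df["movement"].to_numpy(),
            conditions=df["condition"].to_numpy(),
            y_force=df["y_force"].to_numpy(),
            channels=channels,
            features=features,
        )


def featurize(
    trials: list[Trial],
    spec: WindowSpec,
    channels: tuple[str, ...] = CHANNELS,
    features: tuple[str, ...] = FEATURE_NAMES,
    phase: tuple[float, float] = ANALYSIS_WINDOW,
    wamp_threshold: float | None = None,
) -> FeatureMatrix:
    """Windowed feature extraction over a phase of each trial.

    ``wamp_threshold=None`` selects the adaptive per-trial, per-channel
    rest-phase threshold; a float fixes it globally.
    """
    if not channels or not features:
        raise ValueError("need at least one channel and one feature")
    phase_len = int(round((phase[1] - phase[0]) * spec.fs))
    if phase_len < spec.width:
        raise ValueError("phase shorter than one window")

    ch_idx = [CHANNELS.index(c) for c in channels]
    blocks, tids, movs, conds, yf, wt = [], [], [], [], [], []
    for trial in trials:
        emg, force = extract_phase(trial, phase)
        idx = window_indices(emg.shape[1], spec)
        if not idx:
            continue
        starts = np.array([a for a, _ in idx])
        fwin = sliding_window_view(force, spec.width)[starts]
        cols = []
        for ci, ch in zip(ch_idx, channels):
            x = emg[ci]
            if wamp_threshold is None:
                rest, _ = extract_phase(trial, WAMP_REST_WINDOW)
                thr = adaptive_wamp_threshold(rest[ci])
            else:
                thr = float(wamp_threshold)
            wins = sliding_window_view(x, spec.width)[starts]
            cols.append(_window_features(wins, tuple(features), thr))
        blocks.append(np.hstack(cols))
        tids.append(np.full(len(idx), trial.trial_id))
        movs.append(np.full(len(idx), trial.movement, dtype=object))
        conds.append(np.full(len(idx), trial.condition, dtype=object))
        yf.append(fwin.mean(axis=1))
        wt.append(phase[0] + starts / spec.fs)

    if not blocks:
        raise ValueError("no windows produced from the given trials")
    columns = [f"{ch}_{f}" for ch in channels for f in features]
    return FeatureMatrix(
        X=np.vstack(blocks),
        columns=columns,
        trial_ids=np.concatenate(tids),
        movements=np.concatenate(movs),
        conditions=np.concatenate(conds),
        y_force=np.concatenate(yf),
        channels=tuple(channels),
        features=tuple(features),
        window_times=np.concatenate(wt),
    )
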