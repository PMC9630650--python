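"""Continuous grasp-force estimation from windowed EMG features.

A small feed-forward network (back-propagation-trained multilayer
perceptron) maps each window's feature vector to the window-mean force
in %MVC.  Evaluation is by the coefficient of determination

    R^2 = 1 - sum (y - yhat)^2 / sum (y - mean(y))^2

over held-out trials (trial-wise splits; windows of one trial never
straddle the train/test boundary).  The module also provides the
window/step sweep, the channel-force correlation table, per-movement
channel selection and the channel-subset scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .features import (
    REGRESSION_WINDOW,
    FeatureMatrix,
    WindowSpec,
    featurize,
    window_indices,
)
from .preprocessing import Trial, extract_phase
from .simulate import CHANNELS, MOVEMENTS

#: Fixed per-movement channel quartets for force estimation, as chosen
#: from the correlation analysis of the original study conditions.
PRESET_CHANNELS: dict[str, tuple[str, ...]] = {
    "pinch": ("C1", "C2", "C3", "C5"),
    "palmar": ("C2", "C4", "C5", "C6"),
    "twist": ("C1", "C2", "C3", "C4"),
    "plug": ("C2", "C4", "C5", "C7"),
}


@dataclass(frozen=True)
class RegressorConfig:
    """Feed-forward network settings.

    One hidden layer of 20 logistic units by default; trained with
    Adam, early stopping on a held-out fifth of the training windows.
    """

    hidden_layout: tuple[int, ...] = (20,)
    activation: str = "logistic"
    max_epochs: int = 3000
    learning_rate: float = 0.003
    early_stopping: bool = True
    validation_fraction: float = 0.2
    n_iter_no_change: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layout or any(w <= 0 for w in self.hidden_layout):
            raise ValueError("need >= 1 hidden layer, all widths > 0")


class ForceRegressor:
    """Standardized-input MLP mapping feature vectors to %MVC force.

    The target is internally scaled to [0, ~1] (divided by 100) for
    optimizer stability and rescaled on prediction.
    """

    def __init__(self, cfg: RegressorConfig):
        self.cfg = cfg
        self.scaler = StandardScaler()
        self.net = MLPRegressor(
            hidden_layer_sizes=cfg.hidden_layout,
            activation=cfg.activation,
            solver="adam",
            learning_rate_init=cfg.learning_rate,
            max_iter=cfg.max_epochs,
            early_stopping=cfg.early_stopping,
            validation_fraction=cfg.validation_fraction,
            n_iter_no_change=cfg.n_iter_no_change,
            random_state=cfg.seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ForceRegressor":
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in features or targets")
        if np.ptp(y) == 0:
            warnings.warn("constant force target: training R^2 is undefined",
                          stacklevel=2)
        Xs = self.scaler.fit_transform(X)
        self.net.fit(Xs, np.asarray(y, dtype=float) / 100.0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(self.scaler.transform(X)) * 100.0

    def predict_clipped(self, X: np.ndarray) -> np.ndarray:
        """Predictions clipped to [0, 120] %MVC for reporting."""
        return np.clip(self.predict(X), 0.0, 120.0)

    @property
    def loss_curve(self) -> list[float]:
        return list(self.net.loss_curve_)


def train_regressor(fm: FeatureMatrix, cfg: RegressorConfig) -> ForceRegressor:
    """Fit the force regressor on a feature matrix's windows."""
    return ForceRegressor(cfg).fit(fm.X, fm.y_force)


def r_squared(reference, predictions) -> float:
    """Coefficient of determination 1 - SSE/SST; NaN (with a warning)
    for a constant reference."""
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predictions, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1 or len(ref) < 2:
        raise ValueError("reference and predictions must be equal-length 1-D, n >= 2")
    sst = float(np.sum((ref - ref.mean()) ** 2))
    if sst == 0:
        warnings.warn("constant reference: R^2 undefined", stacklevel=2)
        return float("nan")
    return 1.0 - float(np.sum((ref - pred) ** 2)) / sst


@dataclass
class RegressionResult:
    """One held-out evaluation: predictions vs reference force."""

    r2: float
    predictions: np.ndarray
    reference: np.ndarray
    movement: str
    profile: str
    channels: tuple[str, ...]
    window_times: np.ndarray | None = field(default=None, repr=False)


def split_trials(
    trial_ids: np.ndarray, test_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-wise train/test row masks (test_frac of trials held out)."""
    uniq = np.unique(trial_ids)
    n_test = max(1, int(round(test_frac * len(uniq))))
    test_trials = rng.choice(uniq, size=n_test, replace=False)
    te = np.isin(trial_ids, test_trials)
    return ~te, te


def evaluate_regression(
    fm: FeatureMatrix,
    cfg: RegressorConfig,
    test_frac: float = 0.25,
    n_repeats: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, RegressionResult]:
    """Repeated trial-wise hold-out evaluation.

    Returns the array of held-out R^2 over repeats and the last
    repeat's full result (for prediction-vs-reference plots).
    """
    rng = np.random.default_rng(seed)
    r2s, last = [], None
    for rep in range(n_repeats):
        tr, te = split_trials(fm.trial_ids, test_frac, rng)
        model = ForceRegressor(
            RegressorConfig(**{**cfg.__dict__, "seed": cfg.seed + rep})
        ).fit(fm.X[tr], fm.y_force[tr])
        pred = model.predict_clipped(fm.X[te])
        r2 = r_squared(fm.y_force[te], pred)
        r2s.append(r2)
        last = RegressionResult(
            r2=r2,
            predictions=pred,
            reference=fm.y_force[te],
            movement=str(fm.movements[0]) if len(set(fm.movements)) == 1 else "mixed",
            profile=str(fm.conditions[0]) if len(set(fm.conditions)) == 1 else "mixed",
            channels=fm.channels,
            window_times=None if fm.window_times is None else fm.window_times[te],
        )
    return np.array(r2s), last


def _group_by_movement(trials: list[Trial]) -> dict[str, list[Trial]]:
    groups: dict[str, list[Trial]] = {}
    for t in trials:
        groups.setdefault(t.movement, []).append(t)
    return groups


def _active_phase(trials: list[Trial], margin_s: float = 0.25) -> tuple[float, float]:
    """Time window covering the force-active part of a set of trials,
    found from where the smoothed normalized force first exceeds
    2 %MVC (100 ms moving average suppresses measurement noise)."""
    onsets = []
    for t in trials:
        win = max(1, int(round(0.1 * t.fs)))
        smooth = np.convolve(t.force, np.ones(win) / win, mode="same")
        onsets.append(
            float(np.argmax(smooth > 2.0)) / t.fs if np.any(smooth > 2.0) else 0.0
        )
    return max(0.0, min(onsets) - margin_s), trials[0].duration


def sweep_windows(
    trials: list[Trial],
    steps_ms=(40.0, 80.0, 120.0, 160.0),
    widths_ms=(100.0, 150.0, 200.0, 250.0, 300.0),
    fixed_width_ms: float = 300.0,
    cfg: RegressorConfig = RegressorConfig(),
    seed: int = 0,
    n_repeats: int = 2,
    channels: tuple[str, ...] = CHANNELS,
) -> tuple[pd.DataFrame, float, float]:
    """Two-stage sliding-window parameter sweep.

    Stage 1 fixes the width at 300 ms (about the feedback delay an
    operator can perceive) and sweeps the step; stage 2 fixes the best
    step and sweeps the width.  Per-movement held-out R^2 and the
    4-movement mean are reported; returns (table, best_step, best_width).
    """
    groups = _group_by_movement(trials)
    rows = []

    def eval_spec(stage: str, param: str, value: float, wspec: WindowSpec):
        means = []
        for movement, mtrials in sorted(groups.items()):
            fm = featurize(mtrials, wspec, channels=channels,
                           phase=_active_phase(mtrials))
            r2s, _ = evaluate_regression(fm, cfg, n_repeats=n_repeats, seed=seed)
            rows.append({"stage": stage, "parameter": param, "value_ms": value,
                         "movement": movement, "r2": float(np.mean(r2s))})
            means.append(float(np.mean(r2s)))
        rows.append({"stage": stage, "parameter": param, "value_ms": value,
                     "movement": "mean", "r2": float(np.mean(means))})
        return float(np.mean(means))

    step_scores = {}
    for s in steps_ms:
        if fixed_width_ms < s:
            warnings.warn(f"step {s} ms exceeds width {fixed_width_ms} ms; skipped",
                          stacklevel=2)
            continue
        step_scores[s] = eval_spec("step", "step_ms", s,
                                   WindowSpec(fixed_width_ms, s, trials[0].fs))
    best_step = max(step_scores, key=step_scores.get)

    width_scores = {}
    for w in widths_ms:
        if w < best_step:
            warnings.warn(f"width {w} ms below step {best_step} ms; skipped",
                          stacklevel=2)
            continue
        width_scores[w] = eval_spec("width", "width_ms", w,
                                    WindowSpec(w, best_step, trials[0].fs))
    best_width = max(width_scores, key=width_scores.get)
    return pd.DataFrame(rows), float(best_step), float(best_width)


@dataclass
class CorrelationTable:
    """Channel-force correlation, |Pearson r| x 100, mean +/- std over
    trials, per movement x channel.

    The statistic is the absolute Pearson correlation between a
    channel's windowed RMS envelope and the window-mean force over the
    force-active phase of each trial — an interpretation choice, since
    "correlation" admits several definitions; it is stated here so the
    table is reproducible.
    """

    mean: pd.DataFrame  # movements x C1..C8, percent
    std: pd.DataFrame
    n_trials: pd.Series


def channel_correlation(
    trials: list[Trial],
    spec: WindowSpec = REGRESSION_WINDOW,
) -> CorrelationTable:
    """Per-movement, per-channel correlation between EMG envelope and
    force (percent).  Zero-variance envelopes yield NaN entries that
    are excluded from the mean with a warning."""
    groups = _group_by_movement(trials)
    mean_rows, std_rows, counts = {}, {}, {}
    for movement, mtrials in groups.items():
        if len(mtrials) < 2:
            raise ValueError(f"movement {movement!r} needs >= 2 trials")
        per_trial = np.full((len(mtrials), len(CHANNELS)), np.nan)
        for i, trial in enumerate(mtrials):
            emg, force = extract_phase(trial, _active_phase([trial]))
            idx = window_indices(emg.shape[1], spec)
            if not idx:
                continue
            fwin = np.array([force[a:b].mean() for a, b in idx])
            for c in range(len(CHANNELS)):
                env = np.array([np.sqrt(np.mean(emg[c, a:b] ** 2)) for a, b in idx])
                if env.std() == 0 or fwin.std() == 0:
                    warnings.warn(
                        f"zero-variance envelope ({trial.trial_id}, C{c + 1}); "
                        "entry excluded", stacklevel=2)
                    continue
                r, _ = stats.pearsonr(env, fwin)
                per_trial[i, c] = abs(r) * 100.0
        mean_rows[movement] = np.nanmean(per_trial, axis=0)
        std_rows[movement] = np.nanstd(per_trial, axis=0, ddof=1)
        counts[movement] = len(mtrials)
    order = [m for m in MOVEMENTS if m in mean_rows] + [
        m for m in mean_rows if m not in MOVEMENTS
    ]
    mean = pd.DataFrame(mean_rows, index=list(CHANNELS)).T.loc[order]
    std = pd.DataFrame(std_rows, index=list(CHANNELS)).T.loc[order]
    return CorrelationTable(mean, std, pd.Series(counts).loc[order])


def select_channels(
    table: CorrelationTable | None,
    movement: str,
    k: int = 4,
    mode: str = "top_k",
) -> tuple[str, ...]:
    """Channel subset for force estimation of one movement.

    ``top_k`` picks the k channels with the highest mean correlation
    (ties broken toward the lower channel index); ``preset``
    returns the fixed study quartets.
    """
    if k > len(CHANNELS):
        raise ValueError(f"k={k} exceeds the {len(CHANNELS)} available channels")
    if mode == "preset":
        return PRESET_CHANNELS[movement][:k]
    if mode == "top_k":
        if table is None:
            raise ValueError("top_k selection needs a correlation table")
        vals = table.mean.loc[movement].to_numpy()
        order = np.argsort(-vals, kind="stable")  # stable: ties keep low index
        chosen = sorted(order[:k])
        return tuple(CHANNELS[i] for i in chosen)
    raise ValueError(f"unknown selection mode {mode!r}")


def regression_scan(
    trials: list[Trial],
    sizes=range(1, 9),
    cfg: RegressorConfig = RegressorConfig(),
    seed: int = 0,
    budget: int | None = None,
    spec: WindowSpec = REGRESSION_WINDOW,
    n_repeats: int = 2,
) -> pd.DataFrame:
    """Held-out R^2 over channel subsets of each size, per movement.

    Budgeted mode evaluates a seeded random sample of at most
    ``budget`` subsets per size; with budget >= C(8, n) it coincides
    with the full scan.  Returns a tidy table with per-subset rows and
    mean/min/max summaries per (movement, size).
    """
    groups = _group_by_movement(trials)
    rng = np.random.default_rng(seed)
    rows = []
    fms = {
        m: featurize(mt, spec, channels=CHANNELS, phase=_active_phase(mt))
        for m, mt in sorted(groups.items())
    }
    for n in sizes:
        subsets = list(combinations(CHANNELS, n))
        if budget is not None and len(subsets) > budget:
            pick = rng.choice(len(subsets), size=budget, replace=False)
            subsets = [subsets[i] for i in sorted(pick)]
        for movement, fm in fms.items():
            for sub in subsets:
                r2s, _ = evaluate_regression(
                    fm.select_channels(sub), cfg, n_repeats=n_repeats, seed=seed
                )
                rows.append({"movement": movement, "n_channels": n,
                             "channels": "+".join(sub), "r2": float(np.mean(r2s))})
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["movement", "n_channels"])["r2"]
        .agg(["mean", "min", "max"])
        .reset_index()
    )
    return df.merge(summary, on=["movement", "n_channels"], suffixes=("", "_size"))


def estimate_by_profile(
    trials: list[Trial],
    channels_by_movement: dict[str, tuple[str, ...]],
    cfg: RegressorConfig = RegressorConfig(),
    spec: WindowSpec = REGRESSION_WINDOW,
    n_repeats: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], RegressionResult]]:
    """Per-movement, per-profile R^2 table (percent, mean +/- std over
    repeated trial-wise splits) with AVE rows per movement, plus the
    last held-out predictions for each cell."""
    rows, results = [], {}
    by_mov = _group_by_movement(trials)
    for movement in [m for m in MOVEMENTS if m in by_mov]:
        profiles = sorted({t.condition for t in by_mov[movement]})
        cell_means = []
        for profile in profiles:
            ptrials = [t for t in by_mov[movement] if t.condition == profile]
            fm = featurize(
                ptrials, spec,
                channels=channels_by_movement[movement],
                phase=_active_phase(ptrials),
            )
            r2s, res = evaluate_regression(fm, cfg, n_repeats=n_repeats, seed=seed)
            rows.append({"movement": movement, "profile": profile,
                         "r2_mean_pct": 100 * float(np.mean(r2s)),
                         "r2_std_pct": 100 * float(np.std(r2s, ddof=1)) if len(r2s) > 1 else 0.0})
            results[(movement, profile)] = res
            cell_means.append(100 * float(np.mean(r2s)))
        rows.append({"movement": movement, "profile": "AVE",
                     "r2_mean_pct": float(np.mean(cell_means)),
                     "r2_std_pct": float(np.std(cell_means, ddof=1)) if len(cell_means) > 1 else 0.0})
    return pd.DataFrame(rows), results
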