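"""Grasp-type classification: labeling schemes, trial-wise k-fold SVM
accuracy, exhaustive channel-subset scanning and the increase-of-rate
(IR) analysis.

Five labeling schemes combine the four movements with the three force
levels (20/50/80 %MVC):

- SCH1: 4 classes — movement only, levels pooled
- SCH2: 8 classes — movement x {20, 50}
- SCH3: 8 classes — movement x {50, 80}
- SCH4: 8 classes — movement x {20, 80}
- SCH5: 12 classes — movement x {20, 50, 80}

Cross-validation folds are always split by TRIAL, never by window:
adjacent windows of one trial overlap heavily (175/20 ms), so
window-level folds would leak test information into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix, WindowSpec, featurize
from .preprocessing import ANALYSIS_WINDOW, Trial
from .simulate import CHANNELS


@dataclass(frozen=True)
class SchemeSpec:
    """One labeling scheme: which force levels participate and whether
    levels are pooled into the movement label."""

    id: str
    levels_used: tuple[float, ...]
    pooled: bool

    @property
    def n_classes(self) -> int:
        return 4 if self.pooled else 4 * len(self.levels_used)


SCHEMES: dict[str, SchemeSpec] = {
    "SCH1": SchemeSpec("SCH1", (20.0, 50.0, 80.0), pooled=True),
    "SCH2": SchemeSpec("SCH2", (20.0, 50.0), pooled=False),
    "SCH3": SchemeSpec("SCH3", (50.0, 80.0), pooled=False),
    "SCH4": SchemeSpec("SCH4", (20.0, 80.0), pooled=False),
    "SCH5": SchemeSpec("SCH5", (20.0, 50.0, 80.0), pooled=False),
}


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM settings: RBF kernel, C=1, gamma scaled by feature count."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"

    def build(self):
        return make_pipeline(
            StandardScaler(), SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)
        )


def build_labels(fm: FeatureMatrix, scheme: SchemeSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Per-window class labels under a scheme.

    Returns ``(fm_used, labels)`` where ``fm_used`` retains only the
    windows whose force level participates in the scheme.  Labels are
    the movement name (SCH1) or ``"<movement>_L<level>"`` strings,
    which sort deterministically.
    """
    levels = np.empty(fm.n_windows)
    for i, cond in enumerate(fm.conditions):
        cond = str(cond)
        if not cond.startswith("L"):
            raise ValueError(
                f"window {i} has condition {cond!r}: schemes need level-annotated "
                "classification trials"
            )
        levels[i] = float(cond[1:])
    keep = np.isin(levels, scheme.levels_used)
    kept = _subset_rows(fm, keep)
    if scheme.pooled:
        labels = kept.movements.astype(str)
    else:
        labels = np.array(
            [f"{m}_L{int(lv)}" for m, lv in zip(kept.movements, levels[keep])]
        )
    return kept, labels


def _subset_rows(fm: FeatureMatrix, mask: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        X=fm.X[mask],
        columns=fm.columns,
        trial_ids=fm.trial_ids[mask],
        movements=fm.movements[mask],
        conditions=fm.conditions[mask],
        y_force=fm.y_force[mask],
        channels=fm.channels,
        features=fm.features,
        window_times=None if fm.window_times is None else fm.window_times[mask],
    )


def trial_folds(
    trial_ids: np.ndarray, labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold assignment at the trial level, mapped back to
    window rows.  No trial contributes windows to both sides of a fold."""
    uniq, first = np.unique(trial_ids, return_index=True)
    trial_labels = labels[first]
    counts = pd.Series(trial_labels).value_counts()
    if (counts < k).any():
        bad = counts[counts < k].index.tolist()
        raise ValueError(
            f"classes {bad} have fewer than k={k} trials; cannot build "
            "trial-wise stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(uniq, trial_labels):
        tr_mask = np.isin(trial_ids, uniq[tr])
        te_mask = np.isin(trial_ids, uniq[te])
        folds.append((np.flatnonzero(tr_mask), np.flatnonzero(te_mask)))
    return folds


def crossval_accuracy(
    fm: FeatureMatrix,
    labels: np.ndarray,
    k: int = 5,
    clf: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Trial-wise k-fold cross-validated window accuracy, in percent.

    Feature standardization is fit on the training folds only (inside
    the pipeline).  A degenerate single-class problem is reported as
    100 % with a warning.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) == 1:
        warnings.warn("single-class problem: accuracy is trivially 100 %", stacklevel=2)
        return 100.0, np.full(k, 100.0)
    accs = []
    for tr, te in trial_folds(fm.trial_ids, labels, k, seed):
        model = clf.build()
        model.fit(fm.X[tr], labels[tr])
        accs.append(100.0 * float(np.mean(model.predict(fm.X[te]) == labels[te])))
    accs = np.array(accs)
    return float(accs.mean()), accs


@dataclass
class ChannelScanResult:
    """Accuracy over channel subsets, aggregated by subset size.

    ``per_subset`` maps a channel tuple to (mean accuracy %, std over
    folds); ``per_size[n]`` is the mean accuracy over all evaluated
    subsets of size n; ``ir[n] = per_size[n] - per_size[n-1]``, the
    increase of rate when the channel count grows by one.
    """

    scheme: str
    per_subset: dict[tuple[str, ...], tuple[float, float]]
    budget: int | None = None

    @property
    def sizes(self) -> list[int]:
        return sorted({len(s) for s in self.per_subset})

    @property
    def per_size(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for n in self.sizes:
            vals = [m for s, (m, _) in self.per_subset.items() if len(s) == n]
            out[n] = float(np.mean(vals))
        return out

    @property
    def ir(self) -> dict[int, float]:
        ps = self.per_size
        sizes = sorted(ps)
        return {n: ps[n] - ps[p] for p, n in zip(sizes, sizes[1:])}


def channel_scan(
    trials: list[Trial],
    scheme: SchemeSpec,
    spec: WindowSpec,
    sizes=range(1, 9),
    clf: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
    k: int = 5,
    budget: int | None = None,
    phase: tuple[float, float] = ANALYSIS_WINDOW,
    channels: tuple[str, ...] = CHANNELS,
) -> ChannelScanResult:
    """Cross-validated accuracy for channel subsets of each size.

    Evaluates every subset of each requested size, or — in budgeted
    mode — a seeded random sample of at most ``budget`` subsets per
    size (the full scan remains the reference mode).  Features are
    extracted once over all channels and column-sliced per subset.
    """
    fm_all = featurize(trials, spec, channels=channels, phase=phase)
    fm_used, labels = build_labels(fm_all, scheme)
    rng = np.random.default_rng(seed)
    per_subset: dict[tuple[str, ...], tuple[float, float]] = {}
    for n in sizes:
        subsets = list(combinations(channels, n))
        if budget is not None and len(subsets) > budget:
            pick = rng.choice(len(subsets), size=budget, replace=False)
            subsets = [subsets[i] for i in sorted(pick)]
        for sub in subsets:
            mean, folds = crossval_accuracy(
                fm_used.select_channels(sub), labels, k=k, clf=clf, seed=seed
            )
            per_subset[sub] = (mean, float(folds.std()))
    return ChannelScanResult(scheme.id, per_subset, budget=budget)


def scheme_report(
    results: dict[str, ChannelScanResult],
    fixed_size: int = 4,
) -> dict[str, pd.DataFrame]:
    """Publication-style tables from per-scheme scan results.

    Returns ``curves`` (accuracy vs channel count, one column per
    scheme), ``ir`` (IR2..IR8 per scheme plus an AVE row) and
    ``fixed_size`` (per-scheme accuracy at the chosen channel count).
    """
    schemes = list(results)
    curves = pd.DataFrame(
        {sid: pd.Series(results[sid].per_size) for sid in schemes}
    ).sort_index()
    curves.index.name = "n_channels"

    ir_rows = {}
    for sid in schemes:
        ir_rows[sid] = {f"IR{n}": v for n, v in results[sid].ir.items()}
    ir = pd.DataFrame(ir_rows).T
    ir.loc["AVE"] = ir.mean(axis=0)
    ir.index.name = "scheme"

    fixed = pd.DataFrame(
        {
            "scheme": schemes,
            "n_channels": fixed_size,
            "accuracy_pct": [results[s].per_size.get(fixed_size, np.nan) for s in schemes],
        }
    ).set_index("scheme")
    return {"curves": curves, "ir": ir, "fixed_size": fixed}
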