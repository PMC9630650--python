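"""End-to-end experiment runners and their configuration.

A :class:`RunConfig` plus a seed fully determines a run; both runners
write canonical CSV outputs (and a JSON copy of the config) so any
report bundle can be regenerated identically.  Plots are left to the
analysis scripts — CSVs are the canonical outputs.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, regression
from .features import WindowSpec
from .preprocessing import ANALYSIS_WINDOW, cut_trials, detect_triggers, mvc_from_annotations
from .simulate import (
    CHANNELS,
    ExperimentDesign,
    NoiseConfig,
    make_gain_matrix,
    simulate_session,
)

log = logging.getLogger("graspemg")

_CSV_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Single source of truth for one reproducible run."""

    seed: int = 0
    gains_preset: str = "typical"
    baseline_amplitude: float = 0.02
    trials_per_condition_1: int = 50
    trials_per_condition_2: int = 20
    lead_in_s: float = 30.0
    movements: tuple[str, ...] = ("pinch", "palmar", "twist", "plug")
    # classification
    class_window_ms: tuple[float, float] = (175.0, 20.0)
    schemes: tuple[str, ...] = ("SCH1", "SCH2", "SCH3", "SCH4", "SCH5")
    scan_sizes: tuple[int, ...] = tuple(range(1, 9))
    scan_budget: int | None = 8
    folds: int = 5
    fixed_size: int = 4
    # regression
    reg_window_ms: tuple[float, float] = (200.0, 80.0)
    sweep_steps_ms: tuple[float, ...] = (40.0, 80.0, 120.0, 160.0)
    sweep_widths_ms: tuple[float, ...] = (100.0, 150.0, 200.0, 250.0, 300.0)
    reg_repeats: int = 5
    selection_mode: str = "top_k"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("movements", "class_window_ms", "schemes", "scan_sizes",
                    "reg_window_ms", "sweep_steps_ms", "sweep_widths_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def _stage(name: str, t0: float, seed: int) -> float:
    t1 = time.perf_counter()
    log.info("stage=%s seed=%d duration=%.2fs", name, seed, t1 - t0)
    return t1


def _simulate_and_cut(cfg: RunConfig, kind: int):
    gains = make_gain_matrix(cfg.gains_preset, seed=cfg.seed)
    noise = NoiseConfig(baseline_amplitude=cfg.baseline_amplitude)
    if kind == 1:
        design = ExperimentDesign.experiment_1(
            movements=cfg.movements,
            trials_per_condition=cfg.trials_per_condition_1,
            lead_in_s=cfg.lead_in_s,
        )
    else:
        design = ExperimentDesign.experiment_2(
            movements=cfg.movements,
            trials_per_condition=cfg.trials_per_condition_2,
            lead_in_s=cfg.lead_in_s,
        )
    session = simulate_session(design, gains, seed=cfg.seed, noise=noise)
    onsets = detect_triggers(session.trigger, fs=session.fs)
    trials = cut_trials(session, onsets, mvc_from_annotations(session))
    return trials


def run_experiment_1(cfg: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Classification study: simulate -> preprocess -> featurize ->
    channel scan per scheme -> curves, IR table, fixed-size table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    trials = _simulate_and_cut(cfg, kind=1)
    t0 = _stage("simulate+preprocess", t0, cfg.seed)

    wspec = WindowSpec(*cfg.class_window_ms)
    results = {}
    for sid in cfg.schemes:
        results[sid] = decoding.channel_scan(
            trials, decoding.SCHEMES[sid], wspec,
            sizes=cfg.scan_sizes, seed=cfg.seed, k=cfg.folds,
            budget=cfg.scan_budget, phase=ANALYSIS_WINDOW,
        )
        t0 = _stage(f"scan:{sid}", t0, cfg.seed)

    tables = decoding.scheme_report(results, fixed_size=cfg.fixed_size)
    paths = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, float_format=_CSV_FMT)
        paths[name] = p
    per_subset = pd.DataFrame(
        [
            {"scheme": sid, "channels": "+".join(sub), "n_channels": len(sub),
             "accuracy_pct": m, "fold_std": s}
            for sid, res in results.items()
            for sub, (m, s) in res.per_subset.items()
        ]
    )
    p = out / "per_subset.csv"
    per_subset.to_csv(p, index=False, float_format=_CSV_FMT)
    paths["per_subset"] = p
    cfg.to_json(out / "config.json")
    return paths


def run_experiment_2(cfg: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Force-estimation study: simulate -> preprocess -> window sweep
    -> correlation table -> channel selection -> per-movement,
    per-profile regression with prediction traces."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    trials = _simulate_and_cut(cfg, kind=2)
    t0 = _stage("simulate+preprocess", t0, cfg.seed)

    cfgreg = regression.RegressorConfig(seed=cfg.seed)
    step_trials = [t for t in trials if t.condition == "step_climbing"] or trials
    sweep, best_step, best_width = regression.sweep_windows(
        step_trials, steps_ms=cfg.sweep_steps_ms, widths_ms=cfg.sweep_widths_ms,
        cfg=cfgreg, seed=cfg.seed,
    )
    t0 = _stage("window-sweep", t0, cfg.seed)

    table = regression.channel_correlation(trials)
    t0 = _stage("correlation", t0, cfg.seed)

    movements = sorted({t.movement for t in trials})
    channels_by_movement = {
        m: regression.select_channels(table, m, k=4, mode=cfg.selection_mode)
        for m in movements
    }
    wspec = WindowSpec(*cfg.reg_window_ms)
    table4, results = regression.estimate_by_profile(
        trials, channels_by_movement, cfg=cfgreg, spec=wspec,
        n_repeats=cfg.reg_repeats, seed=cfg.seed,
    )
    # AVE column analogue: overall mean across movements
    t0 = _stage("regression", t0, cfg.seed)

    paths = {}
    sweep_p = out / "window_sweep.csv"
    sweep.to_csv(sweep_p, index=False, float_format=_CSV_FMT)
    paths["window_sweep"] = sweep_p
    corr_p = out / "correlation_mean.csv"
    table.mean.to_csv(corr_p, float_format=_CSV_FMT)
    table.std.to_csv(out / "correlation_std.csv", float_format=_CSV_FMT)
    paths["correlation_mean"] = corr_p
    sel = pd.DataFrame(
        {"movement": list(channels_by_movement),
         "channels": ["+".join(v) for v in channels_by_movement.values()]}
    )
    sel_p = out / "selected_channels.csv"
    sel.to_csv(sel_p, index=False)
    paths["selected_channels"] = sel_p
    t4_p = out / "r2_by_profile.csv"
    table4.to_csv(t4_p, index=False, float_format=_CSV_FMT)
    paths["r2_by_profile"] = t4_p
    for (movement, profile), res in results.items():
        p = out / f"predictions_{movement}_{profile}.csv"
        pd.DataFrame(
            {"window_time_s": res.window_times,
             "reference_pct_mvc": res.reference,
             "predicted_pct_mvc": res.predictions}
        ).to_csv(p, index=False, float_format=_CSV_FMT)
        paths[f"predictions_{movement}_{profile}"] = p
    meta = {"best_step_ms": best_step, "best_width_ms": best_width}
    (out / "sweep_choice.json").write_text(json.dumps(meta, indent=2))
    cfg.to_json(out / "config.json")
    return paths
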