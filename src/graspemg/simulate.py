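"""Synthetic EMG/force/trigger session generator.

Generates multichannel surface-EMG recordings with the statistical
structure the downstream analysis assumes: amplitude-modulated
band-limited Gaussian noise per channel, a channel x movement gain
matrix controlling how strongly each electrode site couples to each
grasp type, a force channel tracking a target profile in newtons, and
a trigger pulse train marking trial onsets.

The surrogate signal model for channel ``c`` during movement ``m`` is::

    emg_c(t) = g[c, m] * (f(t)/100)**alpha * n_c(t) + b * w_c(t)

where ``f(t)`` is the target force in %MVC, ``n_c`` and ``w_c`` are
independent unit-variance Gaussian processes band-limited to the EMG
band, ``alpha`` is the amplitude-force exponent (default 1) and ``b``
the baseline-noise amplitude.  Amplitude-modulated band-limited noise
is the standard sEMG surrogate; no motor-unit physiology is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .profiles import FORCE_LEVELS, TargetProfile, make_target_profile

MOVEMENTS = ("pinch", "palmar", "twist", "plug")
CHANNELS = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8")

#: Electrode sites, in channel order.
CHANNEL_MUSCLES = {
    "C1": "flexor carpi radialis",
    "C2": "extensor digitorum",
    "C3": "palmaris longus",
    "C4": "brachioradialis",
    "C5": "extensor carpi radialis",
    "C6": "extensor carpi ulnaris",
    "C7": "biceps brachii",
    "C8": "triceps brachii",
}

#: Maximum voluntary contraction per movement, newtons (torque-type
#: grasps mapped to an equivalent handle force).  Arbitrary constants:
#: only %MVC matters downstream.
MVC_NEWTONS = {"pinch": 30.0, "palmar": 100.0, "twist": 40.0, "plug": 40.0}

TRIAL_SECONDS = 13.0
DEFAULT_FS = 2000.0

# Relative channel-coupling strengths per movement (columns), encoding
# the ordinal structure observed between electrode sites and grasp
# types: e.g. biceps (C7) nearly silent in pinch but dominant in plug,
# triceps (C8) weakly coupled overall, forearm sites strong throughout.
_TYPICAL_GAINS = np.array(
    [
        # pinch palmar twist  plug
        [0.82, 0.73, 0.85, 0.59],  # C1
        [0.79, 0.76, 0.80, 0.78],  # C2
        [0.70, 0.72, 0.80, 0.76],  # C3
        [0.70, 0.81, 0.87, 0.90],  # C4
        [0.84, 0.83, 0.80, 0.87],  # C5
        [0.65, 0.74, 0.80, 0.30],  # C6
        [0.11, 0.27, 0.68, 0.89],  # C7
        [0.26, 0.21, 0.39, 0.50],  # C8
    ]
)


@dataclass(frozen=True)
class GainMatrix:
    """Channel x movement EMG amplitude gains (8 channels x 4 movements).

    ``gains[c, m]`` is the EMG amplitude (arbitrary volts) channel ``c``
    produces at 100 %MVC of movement ``m``.
    """

    gains: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        if g.shape != (len(CHANNELS), len(MOVEMENTS)):
            raise ValueError(f"gain matrix must be {len(CHANNELS)}x{len(MOVEMENTS)}")
        if np.any(g < 0):
            raise ValueError("gains must be nonnegative")
        if np.any(g.max(axis=0) <= 0):
            raise ValueError("each movement needs at least one informative channel")
        object.__setattr__(self, "gains", g)

    def gain(self, channel: str, movement: str) -> float:
        return float(self.gains[CHANNELS.index(channel), MOVEMENTS.index(movement)])

    def column(self, movement: str) -> np.ndarray:
        return self.gains[:, MOVEMENTS.index(movement)]


def make_gain_matrix(
    preset: str = "typical",
    seed: int | None = None,
    n_informative: int = 4,
) -> GainMatrix:
    """Build a gain matrix.

    ``"typical"`` encodes the ordinal channel-movement coupling
    structure above.  ``"random"`` (seeded) draws, per movement,
    ``n_informative`` informative channels with gains in U(0.5, 1.5)
    and leaves the remaining channels at zero gain.
    """
    if preset == "typical":
        return GainMatrix(_TYPICAL_GAINS.copy())
    if preset == "random":
        if seed is None:
            raise ValueError("random gain matrices require a seed")
        rng = np.random.default_rng(seed)
        g = np.zeros((len(CHANNELS), len(MOVEMENTS)))
        for m in range(len(MOVEMENTS)):
            idx = rng.choice(len(CHANNELS), size=n_informative, replace=False)
            g[idx, m] = rng.uniform(0.5, 1.5, size=n_informative)
        return GainMatrix(g)
    raise ValueError(f"unknown preset {preset!r}")


@dataclass(frozen=True)
class NoiseConfig:
    """Noise settings of the simulator.

    Parameters
    ----------
    baseline_amplitude
        Standard deviation of the additive baseline EMG noise,
        same arbitrary-volt scale as the gains (default 0.02).
    force_sigma_pct
        Force measurement noise, %MVC (default 0.5).
    emg_band
        Band limits (Hz) of the EMG surrogate noise.
    force_lag_s
        Electromechanical time constant (s): the measured force is a
        first-order low-pass of the neural drive the EMG follows, so
        fast force transitions produce a transient EMG/force mismatch
        (default 0.1 s; 0 disables the dynamics).
    """

    baseline_amplitude: float = 0.02
    force_sigma_pct: float = 0.5
    emg_band: tuple[float, float] = (20.0, 450.0)
    force_lag_s: float = 0.1


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    return x / x.std()


def simulate_trial(
    movement: str,
    profile: TargetProfile,
    gains: GainMatrix,
    noise: NoiseConfig = NoiseConfig(),
    fs: float = DEFAULT_FS,
    seed: int | None = None,
    alpha: float = 1.0,
    trial_s: float = TRIAL_SECONDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one 13 s trial.

    The profile is placed at the end of the trial; everything before
    its onset (rest and reach) is at zero force.  Returns
    ``(emg, force)`` with ``emg`` of shape (8, N) in arbitrary volts
    and ``force`` of length N in newtons.
    """
    if movement not in MOVEMENTS:
        raise ValueError(f"unknown movement {movement!r}")
    if fs <= 2 * noise.emg_band[1]:
        raise ValueError(
            f"fs={fs} too low for EMG band limit {noise.emg_band[1]} Hz"
        )
    if profile.duration > trial_s:
        raise ValueError("profile longer than the trial")
    rng = np.random.default_rng(seed)
    n = int(round(trial_s * fs))
    t = np.arange(n) / fs
    t0 = trial_s - profile.duration
    pct = np.where(t >= t0, profile(t - t0), 0.0)

    # measured force follows the neural drive through first-order
    # electromechanical dynamics; EMG amplitude follows the drive itself
    if noise.force_lag_s > 0:
        a = 1.0 / (fs * noise.force_lag_s)
        force_pct = signal.lfilter([a], [1.0, a - 1.0], pct)
    else:
        force_pct = pct
    mvc = MVC_NEWTONS[movement]
    force = mvc * force_pct / 100.0 + rng.normal(
        0.0, noise.force_sigma_pct / 100.0 * mvc, size=n
    )

    envelope = (pct / 100.0) ** alpha
    emg = np.empty((len(CHANNELS), n))
    col = gains.column(movement)
    for c in range(len(CHANNELS)):
        carrier = _bandlimited_noise(n, fs, noise.emg_band, rng)
        baseline = _bandlimited_noise(n, fs, noise.emg_band, rng)
        emg[c] = col[c] * envelope * carrier + noise.baseline_amplitude * baseline
    return emg, force


@dataclass(frozen=True)
class TrialAnnotation:
    """Ground-truth record of one simulated trial."""

    index: int
    movement: str
    condition: str  # "L20"/"L50"/"L80" or a profile kind
    onset_sample: int


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a session: which trials, in which order.

    ``kind`` 1 is the classification experiment (ramp-and-hold at the
    three force levels); ``kind`` 2 the force-estimation experiment
    (four target profiles).
    """

    kind: int
    movements: tuple[str, ...] = MOVEMENTS
    levels: tuple[float, ...] = FORCE_LEVELS
    profiles: tuple[str, ...] = ("rectangular", "triangle", "step_climbing", "random")
    trials_per_condition: int = 50
    lead_in_s: float = 30.0
    trigger_width_s: float = 0.05
    trigger_amplitude: float = 1.0
    shuffle: bool = True

    def conditions(self) -> list[str]:
        if self.kind == 1:
            return [f"L{int(lv)}" for lv in self.levels]
        if self.kind == 2:
            return list(self.profiles)
        raise ValueError("experiment kind must be 1 or 2")

    @classmethod
    def experiment_1(cls, **kw) -> "ExperimentDesign":
        kw.setdefault("trials_per_condition", 50)
        return cls(kind=1, **kw)

    @classmethod
    def experiment_2(cls, **kw) -> "ExperimentDesign":
        kw.setdefault("trials_per_condition", 20)
        return cls(kind=2, **kw)


@dataclass
class SessionRecording:
    """Raw simulated session: EMG, force and trigger streams plus
    ground-truth annotations."""

    emg: np.ndarray  # (8, N) arbitrary volts
    force: np.ndarray  # (N,) newtons
    trigger: np.ndarray  # (N,) pulse train
    fs: float
    annotations: list[TrialAnnotation]

    def __post_init__(self) -> None:
        n = self.emg.shape[1]
        if not (len(self.force) == len(self.trigger) == n):
            raise ValueError("all streams must share the same length")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    def save(self, directory: str | Path) -> None:
        """Write the session to a directory: ``.npy`` arrays, a JSON
        sidecar, and CSV exports of force and annotations."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "emg.npy", self.emg)
        np.save(d / "force.npy", self.force)
        np.save(d / "trigger.npy", self.trigger)
        meta = {
            "fs": self.fs,
            "channels": [f"{c} ({CHANNEL_MUSCLES[c]})" for c in CHANNELS],
            "annotations": [
                {
                    "index": a.index,
                    "movement": a.movement,
                    "condition": a.condition,
                    "onset_sample": a.onset_sample,
                }
                for a in self.annotations
            ],
        }
        (d / "session.json").write_text(json.dumps(meta, indent=2))
        with open(d / "force.csv", "w") as fh:
            fh.write("sample,force_newtons\n")
            for i, v in enumerate(self.force):
                fh.write(f"{i},{v:.6f}\n")
        with open(d / "annotations.csv", "w") as fh:
            fh.write("index,movement,condition,onset_sample\n")
            for a in self.annotations:
                fh.write(f"{a.index},{a.movement},{a.condition},{a.onset_sample}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "SessionRecording":
        d = Path(directory)
        meta = json.loads((d / "session.json").read_text())
        anns = [
            TrialAnnotation(
                a["index"], a["movement"], a["condition"], a["onset_sample"]
            )
            for a in meta["annotations"]
        ]
        return cls(
            emg=np.load(d / "emg.npy"),
            force=np.load(d / "force.npy"),
            trigger=np.load(d / "trigger.npy"),
            fs=meta["fs"],
            annotations=anns,
        )


def _condition_profile(
    design: ExperimentDesign, condition: str, seed: int
) -> TargetProfile:
    if design.kind == 1:
        level = float(condition[1:])
        return make_target_profile("ramp_hold", level=level)
    if condition == "random":
        return make_target_profile("random", seed=seed)
    return make_target_profile(condition)


def simulate_session(
    design: ExperimentDesign,
    gains: GainMatrix,
    seed: int,
    noise: NoiseConfig = NoiseConfig(),
    fs: float = DEFAULT_FS,
    alpha: float = 1.0,
) -> SessionRecording:
    """Simulate a full annotated session.

    Trials for every (movement, condition, repetition) are generated
    with per-trial seeds spawned from ``seed``, optionally shuffled,
    and concatenated after a lead-in rest.  A trigger pulse marks each
    trial's onset; annotations record the ground truth.
    """
    rng = np.random.default_rng(seed)
    plan = [
        (m, cond)
        for m in design.movements
        for cond in design.conditions()
        for _ in range(design.trials_per_condition)
    ]
    if design.shuffle:
        order = rng.permutation(len(plan))
        plan = [plan[i] for i in order]

    n_trial = int(round(TRIAL_SECONDS * fs))
    n_lead = int(round(design.lead_in_s * fs))
    n_total = n_lead + len(plan) * n_trial
    emg = np.empty((len(CHANNELS), n_total))
    force = np.empty(n_total)
    trigger = np.zeros(n_total)

    # lead-in rest: baseline EMG noise and force measurement noise only
    lead_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    for c in range(len(CHANNELS)):
        emg[c, :n_lead] = noise.baseline_amplitude * _bandlimited_noise(
            max(n_lead, 64), fs, noise.emg_band, lead_rng
        )[:n_lead]
    force[:n_lead] = lead_rng.normal(0.0, noise.force_sigma_pct, size=n_lead)

    annotations = []
    pulse = int(round(design.trigger_width_s * fs))
    for i, (movement, condition) in enumerate(plan):
        trial_seed = int(rng.integers(0, 2**31 - 1))
        profile = _condition_profile(design, condition, trial_seed)
        e, f = simulate_trial(
            movement, profile, gains, noise=noise, fs=fs, seed=trial_seed, alpha=alpha
        )
        start = n_lead + i * n_trial
        emg[:, start : start + n_trial] = e
        force[start : start + n_trial] = f
        trigger[start : start + pulse] = design.trigger_amplitude
        annotations.append(TrialAnnotation(i, movement, condition, start))

    return SessionRecording(emg, force, trigger, float(fs), annotations)
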