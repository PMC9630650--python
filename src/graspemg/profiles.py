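"""Target force-trajectory profiles, expressed in %MVC.

A profile is the on-screen force trajectory a subject tracks during the
active part of a trial: piecewise linear, starting from rest (0 %MVC),
bounded by 100 %MVC.  Five kinds are supported:

``rectangular``
    three plateaus at 20/50/80 %MVC, 2 s each, joined by short ramps.
``triangle``
    a symmetric 0 -> 80 -> 0 %MVC ramp over 5 s.
``step_climbing``
    a monotone staircase, four steps of 20/40/60/80 %MVC joined by
    0.5 s ramps, 8.5 s total.
``random``
    a seeded piecewise-linear path over 5 s, never exceeding 80 %MVC.
``ramp_hold``
    the grasp-classification condition: rise to a target level in 1.5 s,
    hold it for 4 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

PROFILE_KINDS = ("rectangular", "triangle", "step_climbing", "random", "ramp_hold")

#: Force levels (classification experiment), %MVC.
FORCE_LEVELS = (20.0, 50.0, 80.0)


@dataclass(frozen=True)
class TargetProfile:
    """Piecewise-linear %MVC force trajectory.

    Parameters
    ----------
    kind
        One of :data:`PROFILE_KINDS`.
    breakpoints
        Sequence of ``(time_s, force_pct)`` knots with strictly
        increasing times and forces in ``[0, 100]``.
    """

    kind: str
    breakpoints: tuple[tuple[float, float], ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        times = np.array([t for t, _ in self.breakpoints], dtype=float)
        forces = np.array([f for _, f in self.breakpoints], dtype=float)
        if len(times) < 2:
            raise ValueError("a profile needs at least two breakpoints")
        if not np.all(np.diff(times) > 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if forces.min() < 0 or forces.max() > 100:
            raise ValueError("force breakpoints must lie in [0, 100] %MVC")

    @property
    def duration(self) -> float:
        """Total profile duration in seconds."""
        return self.breakpoints[-1][0] - self.breakpoints[0][0]

    def __call__(self, t) -> np.ndarray:
        """Evaluate the profile (in %MVC) at time(s) ``t`` seconds."""
        times = [p[0] for p in self.breakpoints]
        forces = [p[1] for p in self.breakpoints]
        return np.interp(t, times, forces, left=forces[0], right=forces[-1])


def make_target_profile(
    kind: str,
    *,
    level: float | None = None,
    seed: int | None = None,
    plateau_s: float = 2.0,
    ramp_s: float = 0.5,
    peak_pct: float = 80.0,
    n_knots: int = 6,
) -> TargetProfile:
    """Construct one of the supported target profiles.

    Parameters
    ----------
    kind
        Profile kind, one of :data:`PROFILE_KINDS`.
    level
        Hold level in %MVC; required for ``ramp_hold``.  Levels outside
        the studied 20/50/80 set are allowed but flagged with a warning.
    seed
        RNG seed; required for ``random``.
    plateau_s, ramp_s
        Plateau width and inter-plateau ramp time of the rectangular
        profile (and the step ramps of the staircase).
    peak_pct
        Peak force of the triangle / staircase / random bound.
    n_knots
        Number of knots of the random profile.
    """
    if kind == "rectangular":
        bps: list[tuple[float, float]] = [(0.0, 0.0)]
        t = 0.0
        for lv in FORCE_LEVELS:
            t += ramp_s
            bps.append((t, lv))
            t += plateau_s
            bps.append((t, lv))
        t += ramp_s
        bps.append((t, 0.0))
        return TargetProfile(kind, tuple(bps))

    if kind == "triangle":
        return TargetProfile(kind, ((0.0, 0.0), (2.5, peak_pct), (5.0, 0.0)))

    if kind == "step_climbing":
        steps = np.linspace(peak_pct / 4, peak_pct, 4)
        total = 8.5
        hold = (total - 4 * ramp_s) / 4
        bps = [(0.0, 0.0)]
        t = 0.0
        for lv in steps:
            t += ramp_s
            bps.append((t, float(lv)))
            t += hold
            bps.append((t, float(lv)))
        return TargetProfile(kind, tuple(bps))

    if kind == "random":
        if seed is None:
            raise ValueError("random profiles require a seed")
        rng = np.random.default_rng(seed)
        times = np.linspace(0.0, 5.0, n_knots)
        forces = rng.uniform(0.0, peak_pct, size=n_knots)
        forces[0] = 0.0
        return TargetProfile(kind, tuple(zip(times.tolist(), forces.tolist())))

    if kind == "ramp_hold":
        if level is None:
            raise ValueError("ramp_hold profiles require a level")
        if level not in FORCE_LEVELS:
            warnings.warn(
                f"hold level {level} %MVC is outside the studied 20/50/80 set",
                stacklevel=2,
            )
        if not 0 < level <= 100:
            raise ValueError("hold level must be in (0, 100] %MVC")
        return TargetProfile(
            kind, ((0.0, 0.0), (1.5, float(level)), (5.5, float(level)))
        )

    raise ValueError(f"unknown profile kind {kind!r}")
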