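# Methods

This note documents the models and procedures implemented in
`graspemg`, the choices made where the design was genuinely open, and
what the synthetic data can and cannot establish.

## Signal model of the synthetic generator

Each EMG channel is the standard surface-EMG surrogate —
amplitude-modulated, band-limited Gaussian noise:

    emg_c(t) = g[c, m] · (f(t)/100)^α · n_c(t) + b · w_c(t)

- `g` — an 8×4 **gain matrix** (channels × movements), the EMG
  amplitude of channel *c* at 100 %MVC of movement *m* (arbitrary
  volts).  The `"typical"` preset encodes the ordinal structure of
  channel-movement coupling observed in this experimental paradigm
  (biceps nearly silent in pinch but dominant in plug grasp, triceps
  weakly coupled throughout, forearm sites strong for all movements).
  The `"random"` preset draws, per movement, four informative channels
  with gains in U(0.5, 1.5) and leaves four at exactly zero — an
  unambiguous ground truth for channel-selection experiments.
- `f(t)` — the target force profile in %MVC (the *neural drive*).
- `α` — amplitude–force exponent, default 1 (linear EMG-amplitude vs
  force, adequate over the 0–80 %MVC range used here).
- `n_c`, `w_c` — independent unit-variance Gaussian processes
  band-limited to 20–450 Hz (4th-order Butterworth, zero-phase,
  renormalized), sampled at 2000 Hz.
- `b` — baseline noise amplitude, default 0.02 (≈ 2.5 % of a typical
  gain): rest-phase EMG variance equals b².

The **measured force** is not the drive itself: it passes through
first-order electromechanical dynamics with a 100 ms time constant
(`NoiseConfig.force_lag_s`; 0 disables), then MVC scaling and additive
Gaussian measurement noise of 0.5 %MVC.  The lag reflects the known
excitation–contraction delay between EMG and force; it is what makes
fast force transitions (rectangular profiles) intrinsically harder to
regress than slow ones (triangle profiles), since windows during a
transition see an EMG envelope that leads the measured force.  Without
it, EMG and force would be driven by the same instantaneous signal and
profile shape would not matter.

MVC constants (100 N palmar, 30 N pinch, 40 N twist/plug equivalent)
are arbitrary: everything downstream uses %MVC.

**Trial structure.** Trials last 13 s.  For classification trials the
profile is a ramp-and-hold (rise to the level in 1.5 s, hold 4 s) after
7 s rest and 0.5 s reach.  Force-estimation profiles are placed at the
end of the trial, so the rest period shrinks to 13 s minus the profile
duration — the 8.5 s step-climbing profile leaves 4.5 s of rest.  (A
fixed 7 s rest cannot accommodate all four stated profile durations
inside a 13 s trial; keeping the trial length and the profile durations
and letting rest absorb the difference was the consistent resolution.)
Profile geometries not fully pinned by the paradigm were fixed once:
rectangular = 2 s plateaus at 20/50/80 %MVC joined by 0.5 s ramps
(8 s total); step-climbing = four steps 20/40/60/80 %MVC with 0.5 s
ramps over 8.5 s; random = a seeded 6-knot piecewise-linear path over
5 s bounded by 80 %MVC.  A 50 ms trigger pulse of amplitude 1 marks
each trial onset (detection threshold 0.5; edges within 100 ms merged).

## Preprocessing

Sixth-order Butterworth band-pass 10–500 Hz plus a 50 Hz notch
(Q = 30), both applied **zero-phase** (forward–backward): the analysis
is offline and zero-phase filtering preserves EMG-envelope/force
alignment.  Measured contracts: ≥ 20 dB attenuation at 50 Hz and at
2 Hz, 100 Hz passed within 10 %.  Trials are cut at trigger leading
edges and force is normalized by the movement's MVC reference (mean of
three maxima).  The classification analysis window defaults to
10–13 s — the hold phase nominally starts at 9 s, but the first second
is left out so the force has fully settled; it is configurable.

## Features and windowing

Five time-domain features per channel and window (MAV, RMS, VAR, WAMP,
WL), columns ordered channel-major.  Window counts follow
⌊(N−W)/S⌋+1 with trailing partial windows discarded: a 3 s phase at
2000 Hz yields 142 windows at 175/20 ms and 36 at 200/80 ms.  Open
choices, fixed as follows:

- **WAMP threshold** (never stated in this literature consistently):
  adaptive per trial and channel, 2× the median absolute deviation of
  the rest-phase signal, making the feature scale-free across gain
  settings; a fixed override is available.
- **VAR** uses mean subtraction and the N−1 denominator; EMG is near
  zero-mean so this is benign, noted because some EMG work omits the
  mean.
- **Standardization** (z-scoring, fit on training folds only) precedes
  both learners.

## Classification

RBF-kernel SVM, C = 1, gamma scaled by feature count (all exposed in
`ClassifierConfig`).  Cross-validation is **stratified by trial**:
adjacent 175/20 ms windows overlap by 89 %, so window-level folds would
leak test windows into training; trial-level folds are imposed even
though simpler protocols are common.  Accuracy is the fraction of
correctly classified windows, in percent.  The channel scan evaluates
every subset of each size (C(8,n) subsets), or a seeded random sample
of at most `budget` subsets per size in budgeted mode; the IR table and
accuracy curves aggregate subset means per size.

## Force regression

`MLPRegressor` (one hidden layer of 20 logistic units, Adam,
learning rate 3·10⁻³, early stopping on a validation fifth of the
training windows, targets internally scaled by 1/100) maps window
features to window-mean force; reported predictions are clipped to
[0, 120] %MVC, raw values retained.  Evaluation: trial-wise 75/25
splits repeated 5 times (mean ± std across repeats fills the
per-movement × per-profile table).  The window sweep first fixes a
300 ms width (≈ the perceptible feedback delay) and sweeps the step,
then fixes the best step and sweeps the width; the 200 ms / 80 ms
setting sits in the default grids.

**Correlation table.** The channel-force "correlation" statistic is
implemented as |Pearson r| × 100 between a channel's windowed RMS
envelope and the window-mean force over the force-active phase of each
trial, averaged across trials (± std).  This is an interpretation — the
statistic is not otherwise pinned down — and is stated prominently so
the table is reproducible.  Top-k channel selection takes the k
channels with the highest mean correlation (ties broken toward the
lower channel index); the fixed per-movement quartets (e.g. plug =
{C2, C4, C5, C7}) are available as `preset`.

## Problem sizes

Defaults match the study design (50 trials per level in experiment 1,
20 per profile in experiment 2, 30 s lead-in).  The test suite, the
analysis drivers and `scripts/acceptance.py` run the same pipeline at
reduced sizes chosen as the package's own desk-scale working points —
3–8 trials per condition, a coarser window step where no specific
setting is under test, budgeted channel scans (4–8 subsets per size) —
which keep every recovery property measurable in minutes on one CPU.

## What the simulator does and does not establish

The generator reproduces the *structure* the analysis relies on:
channel-specific force-dependent amplitudes, band-limited spectra,
trial/trigger layout, force-level separation, electromechanical lag.
It does **not** model motor-unit recruitment or firing statistics,
electrode crosstalk, fatigue, impedance drift, movement artifacts, or
between-subject variability.  Consequences worth noting:

- Window-RMS estimation noise is far smaller than in real EMG, so
  classification accuracies and R² values at default noise sit near
  their ceilings; passing recovery tests shows the pipeline is
  correct and unbiased, not that real-data accuracy would be this high.
- The channel-force correlation of *any* channel with nonzero gain
  saturates near 100 %; graded correlation magnitudes like those seen
  in real data emerge only when a channel's gain is comparable to or
  below the baseline noise (e.g. the zero-gain channels of the random
  preset, which score ≈ 13 %).  The typical preset therefore yields
  a much flatter correlation table than a real session would.
- The amplitude–force relation is exactly the configured power law;
  regression quality degrades with baseline noise and force-transition
  speed, but not with the physiological nonlinearities a real arm
  contributes.

## Numerical and degenerate-input conventions

Zero-phase filtering doubles the effective filter order's attenuation;
band edges at or above Nyquist are rejected.  Empty trigger streams
return an explicit empty result with a warning.  Single-class
classification problems report 100 % with a warning; constant
regression references yield NaN R² with a warning; zero-variance
envelopes are excluded from correlation means with a warning.  All
stochastic stages (simulation, fold shuffling, subset sampling, network
initialization) are seeded, and both experiment runners regenerate
byte-identical CSVs from (config, seed).
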