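# graspemg

Offline analysis of surface electromyography (sEMG) for **natural grasp
decoding** and **continuous grasp-force estimation**, built around a
synthetic session generator so the entire pipeline is runnable and
testable without recorded human data.

The study design the package implements asks two questions of
eight-channel forearm/upper-arm sEMG (2000 Hz) recorded while a subject
performs four natural grasping movements — pinch, palmar grasp, twist,
plug grasp — against a force sensor:

1. **Classification.** Can the movement (and the force level at which it
   is performed — 20, 50 or 80 % of maximum voluntary contraction, MVC)
   be decoded from windowed time-domain EMG features?  Five labeling
   schemes (SCH1–SCH5) combine movement and level into 4-, 8- or
   12-class problems; an exhaustive electrode-subset scan measures how
   accuracy grows with the number of channels, summarized by the
   *increase of rate* IRₙ = acc(n) − acc(n−1).
2. **Force estimation.** Can the instantaneous grasp force (in %MVC) be
   regressed from the same features while the subject tracks rectangular,
   triangular, step-climbing and random target force profiles?
   Performance is the coefficient of determination
   R² = 1 − Σ(y−ŷ)²⁄Σ(y−ȳ)² on held-out trials.

## Method

Each 13 s trial (rest → reach → force ramp → hold or profile tracking)
is band-pass filtered (6th-order Butterworth, 10–500 Hz, plus a 50 Hz
notch, applied zero-phase), synchronized to a trigger pulse, normalized
to %MVC (MVC = mean of three recorded maxima), and segmented with a
sliding window — 175 ms / 20 ms step for classification (analysis window
10–13 s), 200 ms / 80 ms for regression.  Five time-domain features per
channel and window:

| feature | definition |
|---|---|
| MAV | (1/N) Σ \|xᵢ\| |
| RMS | √((1/N) Σ xᵢ²) |
| VAR | (1/(N−1)) Σ (xᵢ−x̄)² |
| WAMP | #{i : \|xᵢ₊₁−xᵢ\| ≥ ε} |
| WL | Σ \|xᵢ₊₁−xᵢ\| |

Classification uses an RBF-kernel SVM with trial-wise stratified 5-fold
cross-validation (windows of one trial never straddle a fold boundary);
force regression uses a back-propagation-trained feed-forward network
(one hidden layer of 20 logistic units) on window features, targeting
the window-mean force.

The synthetic generator produces each EMG channel as amplitude-modulated
band-limited (20–450 Hz) Gaussian noise, `g[c,m] · (f(t)/100)^α · n_c(t)
+ b·w_c(t)`, where the 8×4 gain matrix `g` encodes how strongly each
electrode site couples to each movement, and the measured force follows
the neural drive through a 100 ms first-order electromechanical lag.
See `docs/methods.md` for the model, its parameters and its limits.

## Worked example

```python
import graspemg as g
from graspemg.preprocessing import mvc_from_annotations

design = g.ExperimentDesign.experiment_1(trials_per_condition=5, lead_in_s=1.0)
session = g.simulate_session(design, g.make_gain_matrix("typical"), seed=1)
onsets = g.detect_triggers(session.trigger, fs=session.fs)
trials = g.cut_trials(session, onsets, mvc_from_annotations(session))

fm = g.featurize(trials, g.CLASSIFICATION_WINDOW, channels=("C2", "C4", "C6", "C7"))
for sid in ("SCH1", "SCH5"):
    kept, labels = g.build_labels(fm, g.SCHEMES[sid])
    acc, _ = g.crossval_accuracy(kept, labels, k=5, seed=1)
    print(sid, round(acc, 2))
```

prints

```
SCH1 100.0
SCH5 100.0
```

i.e. with four informative channels both the 4-class movement problem
and the 12-class movement × force-level problem are fully separable at
the simulator's default noise level.  The same pipeline at scale is
driven by the numbered scripts:

```bash
python analysis/01_simulate_sessions.py    # raw sessions under scratch/
python analysis/02_classification_scan.py  # results/experiment1/: curves, IR table
python analysis/03_force_estimation.py     # results/experiment2/: sweep, correlation,
                                           # channel selection, R^2 tables, traces
```

The classification scan (seed 1, 5 trials/condition, 8 subsets/size)
shows the accuracy curves saturating at four channels — average IR of
22.6 points at 2 channels falling to 0.4 by 5 channels, SCH1 reaching
97.2 % at 4 channels — and the regression run reaches held-out R²
between 95.4 % and 99.2 % per movement × profile, with the triangle
profile beating the rectangular one (97.8 vs 97.5 % mean), the
slow-vs-fast force-application effect.

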