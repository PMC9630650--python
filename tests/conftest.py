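import numpy as np
import pytest

import graspemg as g
from graspemg.preprocessing import mvc_from_annotations


@pytest.fixture(scope="session")
def typical_gains():
    return g.make_gain_matrix("typical")


@pytest.fixture(scope="session")
def exp1_session_1mov(typical_gains):
    """Classification session, one movement, 3 levels x 50 trials."""
    design = g.ExperimentDesign.experiment_1(
        movements=("palmar",), trials_per_condition=50, lead_in_s=2.0
    )
    return g.simulate_session(design, typical_gains, seed=101)


@pytest.fixture(scope="session")
def exp1_trials_small(typical_gains):
    """Small 4-movement classification session, cut into trials."""
    design = g.ExperimentDesign.experiment_1(
        trials_per_condition=3, lead_in_s=1.0
    )
    session = g.simulate_session(design, typical_gains, seed=7)
    onsets = g.detect_triggers(session.trigger, fs=session.fs)
    return g.cut_trials(session, onsets, mvc_from_annotations(session))


@pytest.fixture(scope="session")
def exp2_trials_small(typical_gains):
    """Two-movement, two-profile force-estimation session, cut."""
    design = g.ExperimentDesign.experiment_2(
        movements=("pinch", "plug"),
        profiles=("triangle", "rectangular"),
        trials_per_condition=4,
        lead_in_s=1.0,
    )
    session = g.simulate_session(design, typical_gains, seed=13)
    onsets = g.detect_triggers(session.trigger, fs=session.fs)
    return g.cut_trials(session, onsets, mvc_from_annotations(session))


def make_trial(emg, force, movement="palmar", condition="L50", fs=2000.0, trial_id=0):
    """Hand-built Trial for unit tests."""
    return g.Trial(
        emg=np.asarray(emg, dtype=float),
        force=np.asarray(force, dtype=float),
        movement=movement,
        condition=condition,
        fs=fs,
        trial_id=trial_id,
    )
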