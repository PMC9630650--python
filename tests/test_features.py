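"""Time-domain EMG features and sliding-window segmentation.

Each feature is checked against an independently coded naive-loop
oracle and against hand-computed examples; windowing is checked
against brute-force enumeration.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graspemg as g
from graspemg.features import adaptive_wamp_threshold
from tests.conftest import make_trial


# ---- independent naive oracles (deliberately loop-based) -------------

def oracle_mav(x):
    return sum(abs(v) for v in x) / len(x)


def oracle_rms(x):
    return (sum(v * v for v in x) / len(x)) ** 0.5


def oracle_var(x):
    m = sum(x) / len(x)
    return sum((v - m) ** 2 for v in x) / (len(x) - 1)


def oracle_wamp(x, thr):
    return sum(1 for a, b in zip(x[:-1], x[1:]) if abs(b - a) >= thr)


def oracle_wl(x):
    return sum(abs(b - a) for a, b in zip(x[:-1], x[1:]))


def oracle_window_count(length, w, s):
    count = 0
    start = 0
    while start + w <= length:
        count += 1
        start += s
    return count


finite_windows = st.lists(
    st.floats(-10, 10, allow_nan=False, allow_infinity=False),
    min_size=2, max_size=50,
)


class TestFeatureExamples:
    def test_mav_hand_examples(self):
        assert g.mav([1, -1, 2, -2]) == pytest.approx(1.5)
        assert g.mav(np.zeros(10)) == 0.0
        assert g.mav(np.full(7, -3.2)) == pytest.approx(3.2)

    def test_rms_hand_examples(self):
        assert g.rms([3, 4]) == pytest.approx(np.sqrt(12.5))
        assert g.rms(np.full(5, -2.0)) == pytest.approx(2.0)

    def test_rms_of_unit_gaussian_approaches_one(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert g.rms(x) == pytest.approx(1.0, rel=0.01)

    def test_var_hand_examples(self):
        assert g.var([1, -1, 1, -1]) == pytest.approx(4 / 3)
        assert g.var(np.full(9, 2.5)) == 0.0

    def test_wamp_hand_examples(self):
        assert g.wamp([0, 0.1, 0.1, 0.5], 0.2) == 1
        x = [0.0, 1.0, 1.0, 2.5, 2.5, 2.5]
        # threshold 0: N-1 minus exactly-equal neighbor pairs
        assert g.wamp(x, 0.0) == len(x) - 1

    def test_wamp_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            g.wamp([0, 1], -0.5)

    def test_wl_hand_examples(self):
        assert g.wl([0, 1, 3]) == pytest.approx(3.0)
        assert g.wl(np.full(6, 1.7)) == 0.0
        mono = np.array([0.0, 0.5, 1.1, 4.0])
        assert g.wl(mono) == pytest.approx(mono[-1] - mono[0])

    def test_empty_or_short_windows_rejected(self):
        with pytest.raises(ValueError):
            g.mav([])
        with pytest.raises(ValueError):
            g.var([1.0])
        with pytest.raises(ValueError):
            g.wl([1.0])


class TestFeatureOracles:
    @settings(derandomize=True, max_examples=50)
    @given(finite_windows)
    def test_scalar_features_match_naive_loops(self, x):
        assert g.mav(x) == pytest.approx(oracle_mav(x), rel=1e-12, abs=1e-12)
        assert g.rms(x) == pytest.approx(oracle_rms(x), rel=1e-12, abs=1e-12)
        assert g.var(x) == pytest.approx(oracle_var(x), rel=1e-9, abs=1e-12)
        assert g.wl(x) == pytest.approx(oracle_wl(x), rel=1e-12, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(finite_windows, st.floats(0, 5))
    def test_wamp_matches_naive_loop_exactly(self, x, thr):
        assert g.wamp(x, thr) == oracle_wamp(x, thr)

    def test_translation_covariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        shifted = x + 5.0
        # WL and WAMP are difference-based: invariant to a constant shift
        assert g.wl(shifted) == pytest.approx(g.wl(x))
        assert g.wamp(shifted, 0.5) == g.wamp(x, 0.5)
        # MAV and RMS are amplitude-based: not invariant
        assert g.mav(shifted) != pytest.approx(g.mav(x))
        assert g.rms(shifted) != pytest.approx(g.rms(x))


class TestWindowing:
    @pytest.mark.parametrize(
        "length,width_ms,step_ms,expected",
        [(6000, 175.0, 20.0, 142), (6000, 200.0, 80.0, 36), (350, 175.0, 175.0, 1)],
    )
    def test_window_counts(self, length, width_ms, step_ms, expected):
        spec = g.WindowSpec(width_ms, step_ms)
        idx = g.window_indices(length, spec)
        assert len(idx) == expected
        assert all(0 <= a < b <= length for a, b in idx)

    def test_count_formula_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            w = int(rng.integers(2, 500))
            s = int(rng.integers(1, w + 1))
            length = int(rng.integers(w, 5000))
            spec = g.WindowSpec(w / 2, s / 2)  # ms at 2000 Hz
            assert len(g.window_indices(length, spec)) == oracle_window_count(
                length, w, s
            )

    def test_signal_shorter_than_window_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert g.window_indices(100, g.WindowSpec(175.0, 20.0)) == []

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            g.WindowSpec(20.0, 175.0)  # step > width
        with pytest.raises(ValueError):
            g.WindowSpec(175.3, 20.0)  # non-integral sample count


class TestFeaturize:
    def _trial(self, fill=None, seed=0):
        rng = np.random.default_rng(seed)
        emg = rng.standard_normal((8, 26000)) if fill is None else np.full(
            (8, 26000), fill
        )
        force = np.linspace(0, 80, 26000)
        return make_trial(emg, force)

    def test_shape_is_windows_by_channels_times_features(self):
        fm = g.featurize(
            [self._trial()], g.CLASSIFICATION_WINDOW,
            channels=("C1", "C2", "C3", "C4"),
        )
        assert fm.X.shape == (142, 20)
        assert fm.columns[:6] == [
            "C1_mav", "C1_rms", "C1_var", "C1_wamp", "C1_wl", "C2_mav"
        ]

    def test_constant_unit_signal_gives_unit_rms(self):
        fm = g.featurize(
            [self._trial(fill=1.0)], g.CLASSIFICATION_WINDOW,
            channels=("C1",), features=("rms",),
        )
        assert np.allclose(fm.X, 1.0)

    def test_permuting_channels_permutes_column_blocks(self):
        trial = self._trial(seed=5)
        a = g.featurize([trial], g.CLASSIFICATION_WINDOW, channels=("C1", "C2"))
        b = g.featurize([trial], g.CLASSIFICATION_WINDOW, channels=("C2", "C1"))
        nf = len(g.FEATURE_NAMES)
        assert np.array_equal(a.X[:, :nf], b.X[:, nf:])
        assert np.array_equal(a.X[:, nf:], b.X[:, :nf])

    def test_select_channels_matches_refeaturize(self):
        trial = self._trial(seed=6)
        full = g.featurize([trial], g.CLASSIFICATION_WINDOW)
        sub = full.select_channels(("C3", "C7"))
        direct = g.featurize([trial], g.CLASSIFICATION_WINDOW, channels=("C3", "C7"))
        assert np.array_equal(sub.X, direct.X)
        assert sub.columns == direct.columns

    def test_y_force_is_window_mean(self):
        trial = self._trial()
        fm = g.featurize([trial], g.CLASSIFICATION_WINDOW, channels=("C1",))
        _, force = g.extract_phase(trial, (10.0, 13.0))
        idx = g.window_indices(6000, g.CLASSIFICATION_WINDOW)
        expected = np.array([force[a:b].mean() for a, b in idx])
        assert np.allclose(fm.y_force, expected)

    def test_vectorized_features_match_scalar_functions(self):
        trial = self._trial(seed=9)
        fm = g.featurize(
            [trial], g.REGRESSION_WINDOW, channels=("C2",), wamp_threshold=0.4
        )
        emg, _ = g.extract_phase(trial, (10.0, 13.0))
        idx = g.window_indices(emg.shape[1], g.REGRESSION_WINDOW)
        for row, (a, b) in zip(fm.X, idx):
            win = emg[1, a:b]
            expected = [g.mav(win), g.rms(win), g.var(win),
                        g.wamp(win, 0.4), g.wl(win)]
            assert np.allclose(row, expected, rtol=1e-12)

    def test_adaptive_wamp_threshold_is_twice_rest_mad(self):
        rest = np.array([0.0, 1.0, -1.0, 2.0, -2.0])
        med = np.median(rest)
        mad = np.median(np.abs(rest - med))
        assert adaptive_wamp_threshold(rest) == pytest.approx(2 * mad)

    def test_phase_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="phase shorter"):
            g.featurize([self._trial()], g.WindowSpec(400.0, 100.0),
                        phase=(10.0, 10.1))

    def test_csv_roundtrip(self, tmp_path):
        fm = g.featurize([self._trial(seed=2)], g.REGRESSION_WINDOW,
                         channels=("C1", "C5"))
        p = tmp_path / "fm.csv"
        fm.to_csv(p)
        back = g.FeatureMatrix.from_csv(p)
        assert back.columns == fm.columns
        assert np.allclose(back.X, fm.X)
        assert np.allclose(back.y_force, fm.y_force)
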