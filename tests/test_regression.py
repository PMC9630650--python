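"""Force regression: R^2, the feed-forward regressor, window sweeps,
channel-force correlation and channel selection."""

import numpy as np
import pandas as pd
import pytest

import graspemg as g
from graspemg.features import FeatureMatrix
from graspemg.regression import _active_phase


def _reg_fm(n_trials=12, windows_per_trial=40, seed=0, noise=0.0):
    """Feature matrix whose single feature is linear in the force."""
    rng = np.random.default_rng(seed)
    rows = n_trials * windows_per_trial
    y = rng.uniform(0, 80, size=rows)
    X = np.column_stack([y * 0.01 + noise * rng.standard_normal(rows)])
    return FeatureMatrix(
        X=X, columns=["C1_rms"],
        trial_ids=np.repeat(np.arange(n_trials), windows_per_trial),
        movements=np.full(rows, "palmar", dtype=object),
        conditions=np.full(rows, "triangle", dtype=object),
        y_force=y, channels=("C1",), features=("rms",),
    )


class TestRSquared:
    def test_perfect_prediction_gives_one(self):
        y = np.array([1.0, 2.0, 5.0])
        assert g.r_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert g.r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_example(self):
        assert g.r_squared([0, 1, 2], [0, 0, 2]) == pytest.approx(0.5)

    def test_constant_reference_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant reference"):
            assert np.isnan(g.r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            g.r_squared([1, 2, 3], [1, 2])

    def test_matches_two_pass_brute_force(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(0, 80, 200)
        p = y + rng.standard_normal(200)
        mean = sum(y) / len(y)
        sst = sum((v - mean) ** 2 for v in y)
        sse = sum((a - b) ** 2 for a, b in zip(y, p))
        assert g.r_squared(y, p) == pytest.approx(1 - sse / sst, rel=1e-12)


class TestTrainRegressor:
    def test_linear_target_recovered(self):
        fm = _reg_fm(noise=0.0)
        r2s, _ = g.evaluate_regression(fm, g.RegressorConfig(seed=0),
                                       n_repeats=2, seed=0)
        assert np.all(r2s >= 0.99)

    def test_same_seed_identical_predictions(self):
        fm = _reg_fm(noise=0.02)
        a = g.train_regressor(fm, g.RegressorConfig(seed=3)).predict(fm.X)
        b = g.train_regressor(fm, g.RegressorConfig(seed=3)).predict(fm.X)
        assert np.array_equal(a, b)

    def test_constant_target_warns(self):
        fm = _reg_fm()
        fm.y_force = np.full(fm.n_windows, 40.0)
        with pytest.warns(UserWarning, match="constant force target"):
            g.train_regressor(fm, g.RegressorConfig(seed=0, max_epochs=50))

    def test_non_finite_features_rejected(self):
        fm = _reg_fm()
        fm.X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            g.train_regressor(fm, g.RegressorConfig(seed=0))

    def test_predictions_clipped_for_reporting(self):
        fm = _reg_fm()
        model = g.train_regressor(fm, g.RegressorConfig(seed=0, max_epochs=200))
        clipped = model.predict_clipped(fm.X)
        assert clipped.min() >= 0.0 and clipped.max() <= 120.0

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            g.RegressorConfig(hidden_layout=())


class TestSelectChannels:
    def test_preset_plug(self):
        assert g.select_channels(None, "plug", mode="preset") == (
            "C2", "C4", "C5", "C7"
        )

    @pytest.mark.parametrize("movement,expected", [
        ("pinch", ("C1", "C2", "C3", "C5")),
        ("palmar", ("C2", "C4", "C5", "C6")),
        ("twist", ("C1", "C2", "C3", "C4")),
    ])
    def test_presets_all_movements(self, movement, expected):
        assert g.select_channels(None, movement, mode="preset") == expected

    def _table(self, row):
        mean = pd.DataFrame([row], index=["pinch"],
                            columns=[f"C{i + 1}" for i in range(8)])
        return g.CorrelationTable(mean, mean * 0, pd.Series({"pinch": 3}))

    def test_top_k_picks_nonzero_channels(self):
        table = self._table([0, 80, 0, 75, 0, 60, 0, 90])
        assert g.select_channels(table, "pinch") == ("C2", "C4", "C6", "C8")

    def test_top_k_breaks_ties_toward_lower_index(self):
        table = self._table([50.0] * 8)
        assert g.select_channels(table, "pinch") == ("C1", "C2", "C3", "C4")

    def test_k_above_8_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            g.select_channels(None, "plug", k=9, mode="preset")


class TestChannelCorrelation:
    def test_entries_bounded_and_shaped(self, exp2_trials_small):
        table = g.channel_correlation(exp2_trials_small)
        assert list(table.mean.columns) == list(g.CHANNELS)
        assert set(table.mean.index) == {"pinch", "plug"}
        vals = table.mean.to_numpy()
        assert np.all((vals >= 0) & (vals <= 100))

    def test_force_correlated_with_itself_is_100(self):
        # degenerate check of the statistic itself
        from scipy import stats
        f = np.linspace(0, 80, 50)
        r, _ = stats.pearsonr(f, f)
        assert abs(r) * 100 == pytest.approx(100.0)

    def test_single_trial_per_movement_rejected(self, exp2_trials_small):
        one = [t for t in exp2_trials_small if t.movement == "pinch"][:1]
        with pytest.raises(ValueError, match=">= 2 trials"):
            g.channel_correlation(one)


class TestSweepWindows:
    def test_sweep_layout_and_choice(self, exp2_trials_small):
        tri = [t for t in exp2_trials_small if t.condition == "triangle"]
        cfg = g.RegressorConfig(seed=0, max_epochs=300)
        table, best_step, best_width = g.sweep_windows(
            tri, steps_ms=(80.0, 160.0), widths_ms=(200.0, 300.0),
            cfg=cfg, seed=0, n_repeats=1,
        )
        # one row per (stage, value, movement) plus a mean row
        stage1 = table[table.stage == "step"]
        assert set(stage1.value_ms) == {80.0, 160.0}
        for v in (80.0, 160.0):
            rows = stage1[stage1.value_ms == v]
            assert set(rows.movement) == {"pinch", "plug", "mean"}
        mean_row = stage1[(stage1.value_ms == 80.0) & (stage1.movement == "mean")]
        others = stage1[(stage1.value_ms == 80.0) & (stage1.movement != "mean")]
        assert mean_row.r2.iloc[0] == pytest.approx(others.r2.mean())
        assert best_step in (80.0, 160.0)
        assert best_width in (200.0, 300.0)
        # the default stage-2 grid includes the 200 ms setting
        assert 200.0 in g.RunConfig().sweep_widths_ms

    def test_width_below_step_skipped_with_warning(self, exp2_trials_small):
        tri = [t for t in exp2_trials_small if t.condition == "triangle"
               and t.movement == "pinch"]
        cfg = g.RegressorConfig(seed=0, max_epochs=200)
        with pytest.warns(UserWarning, match="below step"):
            table, _, _ = g.sweep_windows(
                tri, steps_ms=(160.0,), widths_ms=(100.0, 200.0),
                cfg=cfg, seed=0, n_repeats=1,
            )
        assert 100.0 not in set(table[table.stage == "width"].value_ms)


class TestEstimateByProfile:
    def test_ave_rows_equal_profile_means(self, exp2_trials_small):
        cfg = g.RegressorConfig(seed=0, max_epochs=400)
        channels = {m: g.select_channels(None, m, mode="preset")
                    for m in ("pinch", "plug")}
        table, results = g.estimate_by_profile(
            exp2_trials_small, channels, cfg=cfg, n_repeats=2, seed=0
        )
        for movement in ("pinch", "plug"):
            rows = table[table.movement == movement]
            ave = rows[rows.profile == "AVE"].r2_mean_pct.iloc[0]
            body = rows[rows.profile != "AVE"].r2_mean_pct
            assert ave == pytest.approx(body.mean())
        assert ("pinch", "triangle") in results
        res = results[("pinch", "triangle")]
        assert len(res.predictions) == len(res.reference)


class TestActivePhase:
    def test_active_phase_starts_near_profile_onset(self, exp2_trials_small):
        tri = [t for t in exp2_trials_small if t.condition == "triangle"]
        start, end = _active_phase(tri)
        # triangle lasts 5 s at the end of a 13 s trial: onset ~8 s
        assert 7.0 <= start <= 8.1
        assert end == pytest.approx(13.0)
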