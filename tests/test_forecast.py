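"""Windowing, baseline forecasters, the recurrent model, and error metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquatwin import forecast as fc
from aquatwin.nnet import LSTMRegressor
from tests.conftest import build_series


def five_min_series(n, **channels):
    return build_series(n=n, cadence_min=5, provenance="aggregated", **channels)


class TestMakeWindows:
    def test_boundary_single_window(self):
        ws = fc.make_windows(five_min_series(25))
        assert len(ws) == 1

    def test_window_count(self):
        ws = fc.make_windows(five_min_series(100))
        assert len(ws) == 76

    def test_window_shape_and_feature_order(self):
        ws = fc.make_windows(five_min_series(30))
        assert ws.X.shape[1:] == (24, 8)
        assert fc.FEATURES[:2] == ("DO", "NH3")

    def test_too_short_rejected(self):
        with pytest.raises(fc.InsufficientDataError):
            fc.make_windows(five_min_series(24))

    def test_target_is_step_after_window(self):
        do = np.linspace(4.0, 8.0, 30)
        ws = fc.make_windows(five_min_series(30, DO=do))
        # normalized target of window 0 should denormalize to do[24]
        assert ws.spec.invert_value("DO", ws.y[0, 0]) == pytest.approx(do[24])


class TestBaselines:
    def test_constant_window_both_methods(self):
        w = np.full((24, 8), 0.5)
        for method in ("persistence", "linear_trend"):
            r = fc.predict_baseline(w, method)
            assert r.DO == pytest.approx(0.5)
            assert r.NH3 == pytest.approx(0.5)

    def test_linear_trend_extrapolates_one_step(self):
        w = np.zeros((24, 8))
        w[:, 0] = 6.0 + 0.01 * np.arange(24)
        r = fc.predict_baseline(w, "linear_trend")
        assert r.DO == pytest.approx(w[-1, 0] + 0.01, abs=1e-9)

    def test_persistence_returns_last_row(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (24, 8))
        r = fc.predict_baseline(w, "persistence")
        assert r.DO == w[-1, 0] and r.NH3 == w[-1, 1]

    def test_denormalized_prediction_clamped_nonnegative(self):
        from aquatwin.series import NormalizationSpec

        spec = NormalizationSpec(
            minima={f: -1.0 for f in fc.NORMALIZED_FEATURES},
            maxima={f: 1.0 for f in fc.NORMALIZED_FEATURES},
        )
        w = np.zeros((24, 8))  # normalized 0 -> physical -1
        r = fc.predict_baseline(w, "persistence", spec=spec)
        assert r.DO == 0.0 and r.NH3 == 0.0


class TestMetrics:
    def test_perfect_forecast(self):
        assert fc.evaluate_forecast([1, 2], [1, 2]) == (0.0, 0.0)

    def test_unit_bias(self):
        assert fc.evaluate_forecast([0, 0], [1, 1]) == (1.0, 1.0)

    def test_hand_values(self):
        rmse, mae = fc.evaluate_forecast([0, 0, 3], [0, 0, 0])
        assert rmse == pytest.approx(np.sqrt(3.0))
        assert mae == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fc.evaluate_forecast([1, 2], [1])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rmse_dominates_mae(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=20)
        yhat = rng.normal(size=20)
        rmse, mae = fc.evaluate_forecast(y, yhat)
        assert rmse >= mae - 1e-12


class TestLSTM:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m = LSTMRegressor(3, hidden=4, n_layers=2, n_outputs=2, dropout=0.0, seed=0)
        X = rng.normal(size=(4, 5, 3))
        y = rng.normal(size=(4, 2))
        _, grads = m.loss_and_grads(X, y, train=False)
        eps = 1e-6
        for p, g in zip(m.parameters(), grads):
            for _ in range(3):
                ix = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                lp, _ = m.loss_and_grads(X, y, train=False)
                p[ix] = orig - eps
                lm, _ = m.loss_and_grads(X, y, train=False)
                p[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[ix], rel=1e-3, abs=1e-7)

    def _toy_windows(self, n=160, seed=0):
        # a learnable AR signal in the DO/NH3 columns
        rng = np.random.default_rng(seed)
        t = np.arange(n + 24)
        do = 0.5 + 0.3 * np.sin(2 * np.pi * t / 40) + rng.normal(0, 0.02, n + 24)
        X = np.zeros((n, 24, 8))
        y = np.zeros((n, 2))
        for k in range(n):
            X[k, :, 0] = do[k:k + 24]
            X[k, :, 1] = do[k:k + 24] / 2
            y[k] = do[k + 24], do[k + 24] / 2
        return X, y

    def test_training_reduces_loss(self):
        X, y = self._toy_windows()
        m = LSTMRegressor(8, hidden=8, n_layers=1, dropout=0.0, seed=1)
        before = m.evaluate(X, y)
        m.fit(X[:120], y[:120], X[120:], y[120:], max_epochs=5, patience=5, seed=1)
        assert m.evaluate(X, y) < before

    def test_early_stopping_triggers(self):
        # 2 training windows cannot generalise; validation loss stalls fast
        X, y = self._toy_windows(n=40)
        m = LSTMRegressor(8, hidden=4, n_layers=1, dropout=0.0, seed=2)
        hist = m.fit(X[:2], y[:2], X[20:], y[20:], max_epochs=200, patience=3,
                     learning_rate=0.05, seed=2)
        assert hist.stopped_epoch < 200

    def test_save_load_roundtrip(self, tmp_path):
        X, y = self._toy_windows(n=10)
        m = LSTMRegressor(8, hidden=4, n_layers=2, dropout=0.2, seed=3)
        path = tmp_path / "model.npz"
        m.save(path)
        back = LSTMRegressor.load(path)
        assert np.allclose(m.predict(X), back.predict(X))


class TestTrainReference:
    def test_split_is_deterministic_per_seed(self):
        a = fc.split_indices(200, 0.2, 0.15, seed=42)
        b = fc.split_indices(200, 0.2, 0.15, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        assert len(a[2]) == 40  # 20% holdout reserved first
        # partition: no overlap, full coverage
        assert len(np.union1d(np.union1d(a[0], a[1]), a[2])) == 200

    def test_too_few_windows_rejected(self):
        ws = fc.make_windows(five_min_series(30))
        with pytest.raises(fc.InsufficientDataError):
            fc.train_reference_model(ws)

    def test_reference_beats_persistence_on_noisy_scenario(self):
        # majority over 3 seeds: holdout RMSE of the trained model <= the
        # persistence baseline on the same windows (noise both sides favours
        # a smoothing learner)
        from aquatwin import scenario as sc
        from aquatwin import series as ser

        wins = 0
        for seed in (0, 1, 2):
            cfg = sc.ScenarioConfig(duration_days=3, seed=seed, dropout_prob=0.0)
            obs = sc.observe(sc.generate(cfg, "realistic"), cfg)
            s5 = ser.resample_to_5min(
                ser.preprocess(obs, window=3)
            )
            ws = fc.make_windows(s5)
            config = fc.TrainingConfig(hidden=12, n_layers=1, dropout=0.0,
                                       max_epochs=25, patience=5,
                                       learning_rate=5e-3, seed=seed)
            trained = fc.train_reference_model(ws, config)
            model_err = fc.holdout_errors(trained, ws)
            idx = trained.holdout_idx
            pers_rmse = {}
            for j, ch in enumerate(fc.TARGETS):
                y = np.array([ws.spec.invert_value(ch, v) for v in ws.y[idx, j]])
                p = np.array([ws.spec.invert_value(ch, ws.X[i, -1, j]) for i in idx])
                pers_rmse[ch], _ = fc.evaluate_forecast(y, p)
            if all(model_err[ch][0] <= pers_rmse[ch] for ch in fc.TARGETS):
                wins += 1
        assert wins >= 2
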