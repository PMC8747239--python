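"""Window construction, weighted loss, LSTM training and prediction."""

import numpy as np
import pytest

from gaitlstm import (Cycle, Hyperparams, LstmModel, WindowBatch,
                      build_windows, weighted_mse, train, predict)
from gaitlstm.lstm import loss_and_grads, _init_model, TrainingDiverged


def _cycle(n=24, n_feat=9, seed=0, sid=0, cid=0):
    rng = np.random.default_rng(seed)
    return Cycle(subject_id=sid, cycle_id=cid,
                 features=rng.normal(size=(n, n_feat)),
                 labels=rng.normal(size=(n, 3)) * 20)


class TestBuildWindows:
    def test_one_window_per_sample_with_replicate_padding(self):
        c = _cycle(24)
        wb = build_windows(c, seq_len=5)
        assert wb.X.shape == (24, 5, 9)
        assert np.array_equal(wb.X[0], np.tile(c.features[0], (5, 1)))
        assert np.array_equal(wb.y, c.labels)

    def test_seq_len_one_degenerates_to_per_sample(self):
        c = _cycle(10)
        wb = build_windows(c, seq_len=1)
        assert wb.X.shape == (10, 1, 9)
        assert np.array_equal(wb.X[:, 0], c.features)

    def test_last_row_of_each_window_is_current_sample(self):
        c = _cycle(30, seed=3)
        wb = build_windows(c, seq_len=5)
        for t in range(30):  # brute-force index oracle
            assert np.array_equal(wb.X[t, -1], c.features[t])
            for lag in range(1, 5):
                src = max(t - lag, 0)
                assert np.array_equal(wb.X[t, -1 - lag], c.features[src])

    def test_invalid_seq_len_rejected(self):
        with pytest.raises(ValueError):
            build_windows(_cycle(), seq_len=0)


class TestWeightedMse:
    def test_zero_for_perfect_prediction(self):
        y = np.random.default_rng(0).normal(size=(50, 3))
        assert weighted_mse(y, y) == 0.0

    def test_equal_joint_mse_sums_weights(self):
        y = np.zeros((4, 3))
        yhat = np.ones((4, 3))  # per-joint MSE = 1
        assert weighted_mse(y, yhat, (3, 1, 4)) == pytest.approx(8.0)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(1)
        y, yhat = rng.normal(size=(100, 3)), rng.normal(size=(100, 3))
        w = (3.0, 1.0, 4.0)
        expected = sum(w[j] * np.mean((yhat[:, j] - y[:, j]) ** 2)
                       for j in range(3))
        assert weighted_mse(y, yhat, w) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("j", [0, 1, 2])
    def test_single_joint_weight_reduces_to_plain_mse(self, j):
        rng = np.random.default_rng(2)
        y, yhat = rng.normal(size=(30, 3)), rng.normal(size=(30, 3))
        w = [0.0, 0.0, 0.0]
        w[j] = 1.0
        assert weighted_mse(y, yhat, w) == pytest.approx(
            np.mean((yhat[:, j] - y[:, j]) ** 2), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_mse(np.zeros((3, 3)), np.zeros((4, 3)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic BPTT gradients vs central finite differences."""
        rng = np.random.default_rng(0)
        hp = Hyperparams(hidden_size=4, seq_len=3, epochs=1)
        model = _init_model(2, hp, np.zeros(3), np.ones(3), rng, ())
        X = rng.normal(size=(5, 3, 2))
        y = rng.normal(size=(5, 3))
        w = (3.0, 1.0, 4.0)
        _, grads = loss_and_grads(model, X, y, w)
        eps = 1e-6
        for name, p in model.param_dict().items():
            flat = p.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = loss_and_grads(model, X, y, w)
                flat[idx] = orig - eps
                lm, _ = loss_and_grads(model, X, y, w)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[idx] == pytest.approx(
                    num, rel=1e-4, abs=1e-7), f"{name}[{idx}]"


def _windows_from(cycles, seq_len=5):
    return WindowBatch.concat([build_windows(c, seq_len) for c in cycles])


class TestTraining:
    def test_constant_labels_learned_immediately(self):
        c = _cycle(40, seed=4)
        c.labels[:] = [10.0, 20.0, 30.0]
        wb = _windows_from([c])
        hp = Hyperparams(hidden_size=8, epochs=50, batch_size=16, seed=0)
        model, hist = train(wb, hp)
        assert hist[-1] < 1e-3
        pred = predict(model, wb)
        assert np.allclose(pred, [10.0, 20.0, 30.0], atol=0.05)

    def test_training_deterministic(self):
        cycles = [_cycle(24, seed=i, cid=i) for i in range(4)]
        wb = _windows_from(cycles)
        hp = Hyperparams(hidden_size=10, epochs=5, batch_size=32, seed=123)
        m1, h1 = train(wb, hp)
        m2, h2 = train(wb, hp)
        assert np.array_equal(h1, h2)
        for k, v in m1.param_dict().items():
            assert np.array_equal(v, m2.param_dict()[k]), k

    def test_loss_decreases_on_smooth_target(self):
        rng = np.random.default_rng(7)
        cycles = []
        for cid in range(8):
            t = np.linspace(0, 1, 24, endpoint=False)
            F = np.column_stack([np.sin(2 * np.pi * t + p)
                                 for p in np.linspace(0, 2, 9)])
            F += 0.01 * rng.normal(size=F.shape)
            y = np.column_stack([30 * np.sin(2 * np.pi * t),
                                 20 * np.cos(2 * np.pi * t),
                                 10 * np.sin(4 * np.pi * t)])
            cycles.append(Cycle(0, cid, F, y))
        wb = _windows_from(cycles)
        hp = Hyperparams(hidden_size=20, epochs=60, batch_size=64, seed=1)
        _, hist = train(wb, hp)
        # smoothed over 10-epoch windows, descent holds in >= 90 % of steps
        sm = np.convolve(hist, np.ones(10) / 10, mode="valid")
        frac_down = np.mean(np.diff(sm) <= 1e-9)
        assert frac_down >= 0.9
        assert sm[-1] < sm[0]

    def test_nan_inputs_abort_with_diagnostics(self):
        c = _cycle(30, seed=9)
        c.features[3, 2] = np.nan
        wb = _windows_from([c])
        hp = Hyperparams(hidden_size=4, epochs=2, batch_size=8)
        with pytest.raises(TrainingDiverged):
            train(wb, hp)


class TestPredict:
    def test_bias_only_model_outputs_bias(self):
        hp = Hyperparams(hidden_size=6, seq_len=5)
        rng = np.random.default_rng(0)
        model = _init_model(9, hp, np.zeros(3), np.ones(3), rng, ())
        model.Wy[:] = 0.0
        model.by[:] = [10.0, 20.0, 30.0]
        wb = _windows_from([_cycle(12)])
        assert np.allclose(predict(model, wb), [10.0, 20.0, 30.0])

    def test_batch_split_equals_concatenation(self):
        hp = Hyperparams(hidden_size=6)
        rng = np.random.default_rng(1)
        model = _init_model(9, hp, np.zeros(3), np.ones(3), rng, ())
        wb = _windows_from([_cycle(20, seed=2)])
        full = predict(model, wb)
        half1 = predict(model, WindowBatch(wb.X[:10], wb.y[:10], wb.keys[:10]))
        half2 = predict(model, WindowBatch(wb.X[10:], wb.y[10:], wb.keys[10:]))
        assert np.allclose(full, np.vstack([half1, half2]), atol=1e-12)

    def test_window_permutation_invariance(self):
        hp = Hyperparams(hidden_size=6)
        rng = np.random.default_rng(3)
        model = _init_model(9, hp, np.zeros(3), np.ones(3), rng, ())
        wb = _windows_from([_cycle(20, seed=4)])
        perm = rng.permutation(len(wb))
        shuffled = WindowBatch(wb.X[perm], wb.y[perm], wb.keys[perm])
        out = predict(model, shuffled)
        restored = out[np.argsort(perm)]
        assert np.allclose(restored, predict(model, wb), atol=1e-12)

    def test_feature_count_mismatch_rejected(self):
        hp = Hyperparams(hidden_size=6)
        rng = np.random.default_rng(5)
        model = _init_model(4, hp, np.zeros(3), np.ones(3), rng, ())
        with pytest.raises(ValueError):
            predict(model, _windows_from([_cycle(10)]))


class TestCheckpoint:
    def test_save_load_roundtrip_bit_exact(self, tmp_path):
        c = _cycle(24, seed=6)
        wb = _windows_from([c])
        hp = Hyperparams(hidden_size=5, epochs=3, batch_size=8, seed=2)
        model, _ = train(wb, hp, feature_names=("a",) * 9)
        path = tmp_path / "model.ckpt"
        model.save(path)
        loaded = LstmModel.load(path)
        for k, v in model.param_dict().items():
            assert np.array_equal(v, loaded.param_dict()[k])
        assert np.allclose(predict(loaded, wb), predict(model, wb))
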