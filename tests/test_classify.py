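"""LSTM cell equations, BiLSTM forward pass, gradients and training."""

import math

import numpy as np
import pytest

from p300id import (
    BiLSTMModel, LSTMParams, LSTMState, TrainConfig, bilstm_forward, lstm_step,
    predict_proba, train_bilstm, train_svm_baseline,
)
from p300id.classify import init_params, loss_and_gradients


def _zero_params(hidden, inputs):
    z = lambda: np.zeros((hidden, hidden + inputs))
    b = lambda: np.zeros(hidden)
    return LSTMParams(W_f=z(), W_i=z(), W_C=z(), W_O=z(),
                      b_f=b(), b_i=b(), b_C=b(), b_O=b())


def _scalar_step(p, h_prev, C_prev, x):
    """Literal scalar-by-scalar transcription of the gate equations."""
    H = len(h_prev)
    z = list(h_prev) + list(x)
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h_new, C_new = [], []
    for j in range(H):
        af = sum(p.W_f[j][k] * z[k] for k in range(len(z))) + p.b_f[j]
        ai = sum(p.W_i[j][k] * z[k] for k in range(len(z))) + p.b_i[j]
        ac = sum(p.W_C[j][k] * z[k] for k in range(len(z))) + p.b_C[j]
        ao = sum(p.W_O[j][k] * z[k] for k in range(len(z))) + p.b_O[j]
        C = sig(af) * C_prev[j] + sig(ai) * math.tanh(ac)
        C_new.append(C)
        h_new.append(sig(ao) * math.tanh(C))
    return np.array(h_new), np.array(C_new)


class TestLSTMStep:
    def test_zero_parameters_halve_memory(self):
        p = _zero_params(3, 2)
        prev = LSTMState(h=np.zeros(3), C=np.array([1.0, -2.0, 0.5]))
        s = lstm_step(p, prev, np.array([4.0, -7.0]))
        assert np.allclose(s.f, 0.5) and np.allclose(s.i, 0.5) and np.allclose(s.o, 0.5)
        assert np.allclose(s.C_tilde, 0.0)
        assert np.allclose(s.C, 0.5 * prev.C)
        assert np.allclose(s.h, 0.5 * np.tanh(0.5 * prev.C))

    def test_matches_scalar_transcription(self):
        rng = np.random.default_rng(0)
        p = LSTMParams(
            W_f=rng.normal(size=(2, 5)), W_i=rng.normal(size=(2, 5)),
            W_C=rng.normal(size=(2, 5)), W_O=rng.normal(size=(2, 5)),
            b_f=rng.normal(size=2), b_i=rng.normal(size=2),
            b_C=rng.normal(size=2), b_O=rng.normal(size=2),
        )
        prev = LSTMState(h=rng.normal(size=2), C=rng.normal(size=2))
        x = rng.normal(size=3)
        s = lstm_step(p, prev, x)
        h_ref, C_ref = _scalar_step(p, prev.h, prev.C, x)
        assert np.allclose(s.h, h_ref, atol=1e-12)
        assert np.allclose(s.C, C_ref, atol=1e-12)

    def test_gate_ranges(self):
        rng = np.random.default_rng(1)
        p = init_params(4, TrainConfig(hidden_size=3, seed=0), rng)
        s = lstm_step(p, LSTMState.zeros(3), rng.normal(size=4))
        for g in (s.f, s.i, s.o):
            assert np.all((g > 0) & (g < 1))
        assert np.all((s.C_tilde > -1) & (s.C_tilde < 1))

    def test_saturated_forget_gate_preserves_memory(self):
        p = _zero_params(2, 2)
        p.b_f[:] = 20.0
        prev = LSTMState(h=np.zeros(2), C=np.array([3.0, -1.0]))
        s = lstm_step(p, prev, np.ones(2))
        assert np.allclose(s.f, 1.0, atol=1e-8)
        assert np.allclose(s.C, prev.C + s.i * s.C_tilde, atol=1e-8)

    def test_shape_mismatch_rejected(self):
        p = _zero_params(2, 3)
        with pytest.raises(ValueError, match="input shape"):
            lstm_step(p, LSTMState.zeros(2), np.ones(5))


class TestBiLSTMForward:
    def test_palindrome_with_shared_cells_is_symmetric(self):
        rng = np.random.default_rng(2)
        cell = init_params(3, TrainConfig(hidden_size=4, seed=1), rng)
        m = BiLSTMModel(forward_cell=cell, backward_cell=cell,
                        readout_w=rng.normal(size=8), readout_b=0.0)
        seq = rng.normal(size=(5, 3))
        pal = np.vstack([seq, seq[-2::-1]])  # palindromic sequence
        hf = LSTMState.zeros(4)
        for t in range(len(pal)):
            hf = lstm_step(cell, hf, pal[t])
        hb = LSTMState.zeros(4)
        for t in range(len(pal) - 1, -1, -1):
            hb = lstm_step(cell, hb, pal[t])
        assert np.allclose(hf.h, hb.h, atol=1e-12)

    def test_zero_readout_gives_half(self):
        rng = np.random.default_rng(3)
        m = BiLSTMModel(
            forward_cell=init_params(2, TrainConfig(hidden_size=3, seed=2), rng),
            backward_cell=init_params(2, TrainConfig(hidden_size=3, seed=3), rng),
            readout_w=np.zeros(6), readout_b=0.0,
        )
        assert bilstm_forward(m, rng.normal(size=(4, 2))) == pytest.approx(0.5)

    def test_single_and_batched_paths_agree(self):
        rng = np.random.default_rng(4)
        m = BiLSTMModel(
            forward_cell=init_params(3, TrainConfig(hidden_size=4, seed=4), rng),
            backward_cell=init_params(3, TrainConfig(hidden_size=4, seed=5), rng),
            readout_w=rng.normal(size=8), readout_b=0.3,
        )
        X = rng.normal(size=(6, 5, 3))
        batched = predict_proba(m, X)
        single = np.array([bilstm_forward(m, X[i]) for i in range(6)])
        assert np.allclose(batched, single, atol=1e-12)

    def test_empty_sequence_rejected(self):
        rng = np.random.default_rng(5)
        m = BiLSTMModel(
            forward_cell=init_params(2, TrainConfig(hidden_size=2, seed=0), rng),
            backward_cell=init_params(2, TrainConfig(hidden_size=2, seed=0), rng),
            readout_w=np.zeros(4), readout_b=0.0,
        )
        with pytest.raises(ValueError, match="nonempty"):
            bilstm_forward(m, np.zeros((0, 2)))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        cfg = TrainConfig(hidden_size=3, seed=0)
        m = BiLSTMModel(
            forward_cell=init_params(2, cfg, rng),
            backward_cell=init_params(2, cfg, rng),
            readout_w=rng.normal(size=6) * 0.5, readout_b=0.1,
        )
        X = rng.normal(size=(2, 3, 2))
        y = np.array([1.0, 0.0])
        _, grads = loss_and_gradients(m, X, y, l2=0.0)
        eps = 1e-6

        def num_grad(arr, analytic):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = loss_and_gradients(m, X, y)
                arr[idx] = orig - eps
                lm, _ = loss_and_gradients(m, X, y)
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                ref = analytic[idx]
                assert num == pytest.approx(ref, rel=1e-5, abs=1e-7)

        for cell, g in ((m.forward_cell, grads["fwd"]), (m.backward_cell, grads["bwd"])):
            for k in ("W_f", "W_i", "W_C", "W_O", "b_f", "b_i", "b_C", "b_O"):
                num_grad(getattr(cell, k), g[k])
        num_grad(m.readout_w, grads["readout_w"])


class TestTraining:
    def test_separable_toy_set_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(7)
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 3, 2)) * 0.1
        X[y == 1, :, 0] += 2.0  # feature 0 separates the classes
        cfg = TrainConfig(hidden_size=8, max_epochs=60, batch_size=16, seed=0)
        m = train_bilstm(X, y, cfg=cfg)
        pred = (predict_proba(m, X) >= 0.5).astype(int)
        assert np.all(pred == y)

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3, 2))
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        cfg = TrainConfig(hidden_size=4, max_epochs=10, seed=5)
        m1 = train_bilstm(X, y, cfg=cfg)
        m2 = train_bilstm(X, y, cfg=cfg)
        assert np.array_equal(m1.readout_w, m2.readout_w)
        assert np.array_equal(m1.forward_cell.W_C, m2.forward_cell.W_C)
        assert m1.train_log == m2.train_log

    def test_permuted_labels_give_chance_validation_accuracy(self):
        # null Monte-Carlo: mean validation BVA over 10 seeds ~ 50%
        rng = np.random.default_rng(9)
        bvas = []
        for seed in range(10):
            X = rng.normal(size=(60, 2, 3))
            y = np.array([0, 1] * 30)
            perm = rng.permutation(60)
            cfg = TrainConfig(hidden_size=4, max_epochs=15, patience=15, seed=seed)
            m = train_bilstm(X[perm[:40]], y[perm[:40]], X[perm[40:]], y[perm[40:]], cfg)
            pred = (predict_proba(m, X[perm[40:]]) >= 0.5).astype(int)
            truth = y[perm[40:]]
            sen = np.mean(pred[truth == 1])
            spe = np.mean(1 - pred[truth == 0])
            bvas.append(50.0 * (sen + spe))
        assert 40.0 <= np.mean(bvas) <= 60.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_bilstm(np.zeros((4, 2, 2)), np.zeros(4))

    def test_nonfinite_loss_raises_with_diagnostics(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 2, 2))
        X[0, 0, 0] = np.nan  # poisons the loss on the first batch
        y = np.array([0, 1] * 5)
        cfg = TrainConfig(hidden_size=4, batch_size=10, max_epochs=5, seed=0)
        with pytest.raises(FloatingPointError, match="diverged"):
            train_bilstm(X, y, cfg=cfg)


class TestSVMBaseline:
    def test_separable_toy_set_perfect(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 4)) * 0.05
        y = np.array([0, 1] * 20)
        X[y == 1, 0] += 3.0
        clf = train_svm_baseline(X, y, kernel="linear", C=10.0)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_sigmoid_kernel_runs(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 4))
        y = np.array([0, 1] * 15)
        X[y == 1] += 1.5
        clf = train_svm_baseline(X, y)  # default sigmoid kernel
        assert clf.kernel == "sigmoid"
        assert set(np.unique(clf.predict(X))) <= {0, 1}

    def test_vanishing_c_collapses_to_majority(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 3))
        y = np.array([1] * 25 + [0] * 15)
        X[y == 1, 0] += 1.0
        clf = train_svm_baseline(X, y, C=1e-6)
        pred = clf.predict(rng.normal(size=(50, 3)))
        assert np.mean(pred == 1) > 0.9  # majority class dominates

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 4))
        y = np.array([0, 1] * 15)
        a = train_svm_baseline(X, y).predict(X)
        b = train_svm_baseline(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_svm_baseline(np.zeros((4, 2)), np.ones(4))
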