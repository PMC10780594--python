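"""CNN/LSTM architecture contracts, gate-equation oracle and training."""

import numpy as np
import pytest

from gaitenc import (
    CNNConfig, CNNModel, LSTMConfig, LSTMModel, build_cnn, build_lstm,
    lstm_cell_step, predict_classes, train_deep,
)
from gaitenc.deep import _xent_and_grad, softmax

from oracles import lstm_step_bf


class TestCNNArchitecture:
    def test_shape_report_for_128x9_input(self):
        model = build_cnn(CNNConfig(input_shape=(128, 9, 1), n_classes=6))
        shapes = {name: shape for name, shape, _ in model.shape_report}
        # time axis: 128 -conv(3)-> 126 -pool-> 63 -conv(2)-> 62 -pool-> 31
        # -conv(2)-> 30; channel axis: 9 -conv(2)-> 8 (then kernels of 1)
        assert shapes["conv1"] == (126, 8, 32)
        assert shapes["pool1"] == (63, 8, 32)
        assert shapes["conv2"] == (62, 8, 64)
        assert shapes["pool2"] == (31, 8, 64)
        assert shapes["conv3"] == (30, 8, 128)
        assert shapes["flatten"] == (30 * 8 * 128,)
        assert shapes["dense"] == (6,)

    def test_parameter_count_matches_closed_form(self):
        model = build_cnn(CNNConfig(input_shape=(128, 9, 1), n_classes=6))
        expected = (
            (3 * 2 * 1) * 32 + 32          # conv1
            + (2 * 1 * 32) * 64 + 64       # conv2
            + (2 * 1 * 64) * 128 + 128     # conv3
            + 30 * 8 * 128 * 6 + 6         # dense
        )
        assert model.n_params == expected
        assert sum(p.size for p in model.parameters()) == expected

    def test_softmax_rows_sum_to_one(self, rng):
        model = CNNModel(CNNConfig(input_shape=(16, 4, 1), n_classes=3,
                                   conv_filters=(4, 4, 4), seed=0))
        p = model.predict_proba(rng.standard_normal((7, 16, 4, 1)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert p.shape == (7, 3)

    def test_too_small_input_names_failing_layer(self):
        with pytest.raises(ValueError, match="conv1"):
            CNNModel(CNNConfig(input_shape=(2, 1, 1), n_classes=2))

    def test_backward_matches_finite_differences(self, rng):
        model = CNNModel(CNNConfig(input_shape=(12, 4, 1), n_classes=3,
                                   conv_filters=(2, 3, 4), seed=1))
        X = rng.standard_normal((3, 12, 4, 1))
        y = np.array([0, 1, 2])
        # nudge biases off zero so no ReLU preactivation sits exactly at
        # its kink (the subgradient there is one-sided)
        for p in model.parameters():
            p += 0.01 * rng.standard_normal(p.shape)
        _, dl = _xent_and_grad(model.forward(X), y)
        grads = model.backward(dl)
        eps = 1e-6
        for p, g in zip(model.parameters(), grads):
            flat_idx = rng.integers(0, p.size, size=min(4, p.size))
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                old = p[idx]
                p[idx] = old + eps
                l1, _ = _xent_and_grad(model.forward(X), y)
                p[idx] = old - eps
                l2, _ = _xent_and_grad(model.forward(X), y)
                p[idx] = old
                num = (l1 - l2) / (2 * eps)
                assert g[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)


class TestLSTMCell:
    def _random_cell(self, rng, n_in=4, H=3):
        W = rng.standard_normal((n_in + H, 4 * H))
        b = rng.standard_normal(4 * H)
        return W, b

    def test_matches_straight_line_oracle(self, rng):
        for _ in range(10):
            W, b = self._random_cell(rng)
            x = rng.standard_normal((1, 4))
            h = rng.standard_normal((1, 3))
            c = rng.standard_normal((1, 3))
            h2, c2, _ = lstm_cell_step(x, h, c, W, b, forget_bias=1.0)
            h_bf, c_bf = lstm_step_bf(x[0], h[0], c[0], W, b, 1.0)
            np.testing.assert_allclose(h2[0], h_bf, atol=1e-8)
            np.testing.assert_allclose(c2[0], c_bf, atol=1e-8)

    def test_zero_weights_fixed_point(self):
        H = 5
        W = np.zeros((3 + H, 4 * H))
        b = np.zeros(4 * H)
        h = np.zeros((2, H))
        c = np.zeros((2, H))
        for _ in range(4):
            h, c, _ = lstm_cell_step(np.ones((2, 3)), h, c, W, b,
                                     forget_bias=0.0)
        assert np.allclose(h, 0.0)
        assert np.allclose(c, 0.0)

    def test_open_forget_closed_input_preserves_cell(self, rng):
        """Forcing f=1, i=0 (via saturated gate biases) keeps C_t = C_0."""
        H = 4
        W = np.zeros((2 + H, 4 * H))
        b = np.zeros(4 * H)
        b[:H] = 50.0                       # forget gate ~ 1
        b[H:2 * H] = -50.0                 # input gate ~ 0
        c0 = rng.standard_normal((1, H))
        h, c = np.zeros((1, H)), c0.copy()
        for _ in range(6):
            h, c, _ = lstm_cell_step(rng.standard_normal((1, 2)), h, c,
                                     W, b, forget_bias=0.0)
        np.testing.assert_allclose(c, c0, atol=1e-12)

    def test_hand_evaluated_scalar_cell(self):
        """Single unit, scalar weights, length-3 input, evaluated by hand.

        With every weight 0.5, bias 0, forget_bias 0, x = (1, -1, 2),
        h_0 = c_0 = 0, one unit:
          step maps (h, c, x) via z = 0.5 * (h + x) shared by all gates.
        """
        W = np.full((2, 4), 0.5)
        b = np.zeros(4)
        sig = lambda v: 1 / (1 + np.exp(-v))
        h = c = 0.0
        for x in (1.0, -1.0, 2.0):
            z = 0.5 * (h + x)
            f, i, g, o = sig(z), sig(z), np.tanh(z), sig(z)
            c = f * c + i * g
            h = o * np.tanh(c)
        hv = np.zeros((1, 1))
        cv = np.zeros((1, 1))
        for x in (1.0, -1.0, 2.0):
            hv, cv, _ = lstm_cell_step(np.array([[x]]), hv, cv, W, b,
                                       forget_bias=0.0)
        assert hv[0, 0] == pytest.approx(h, abs=1e-10)
        assert cv[0, 0] == pytest.approx(c, abs=1e-10)

    def test_model_backward_matches_finite_differences(self, rng):
        model = LSTMModel(LSTMConfig(segment_time_size=6, n_features=3,
                                     n_classes=3, hidden_size=4, seed=2))
        X = rng.standard_normal((4, 6, 3))
        y = np.array([0, 1, 2, 0])
        _, dl = _xent_and_grad(model.forward(X), y)
        grads = model.backward(dl)
        eps = 1e-6
        for p, g in zip(model.parameters(), grads):
            for fi in rng.integers(0, p.size, size=min(4, p.size)):
                idx = np.unravel_index(fi, p.shape)
                old = p[idx]
                p[idx] = old + eps
                l1, _ = _xent_and_grad(model.forward(X), y)
                p[idx] = old - eps
                l2, _ = _xent_and_grad(model.forward(X), y)
                p[idx] = old
                assert g[idx] == pytest.approx((l1 - l2) / (2 * eps),
                                               abs=1e-6, rel=1e-4)

    def test_stacked_architecture(self):
        model = build_lstm(LSTMConfig(n_layers=2, hidden_size=50,
                                      n_features=3, n_classes=6))
        assert len(model.cells) == 2
        assert model.cells[0].W.shape == (100, 200)
        assert model.cells[1].W.shape == (100, 200)
        assert model.Wo.shape == (50, 6)


class TestTraining:
    def _separable(self, rng, n=80, T=16, F=3):
        X = rng.standard_normal((n, T, F)) * 0.1
        y = rng.integers(0, 2, size=n)
        X[y == 1] += 2.0
        return X, y

    def test_lstm_learns_separable_data(self, rng):
        X, y = self._separable(rng)
        model = LSTMModel(LSTMConfig(segment_time_size=16, n_features=3,
                                     n_classes=2, hidden_size=8, seed=0,
                                     epochs=27, batch_size=8))
        hist = train_deep(model, X, y, seed=0)
        assert len(hist.train_loss) <= 27
        pred = predict_classes(model, X)
        assert np.mean(pred == y) >= 0.90

    def test_cnn_learns_separable_data(self, rng):
        X = rng.standard_normal((80, 16, 4, 1)) * 0.1
        y = rng.integers(0, 2, size=80)
        X[y == 1, :, :2] += 2.0
        model = CNNModel(CNNConfig(input_shape=(16, 4, 1), n_classes=2,
                                   conv_filters=(4, 8, 8), epochs=27,
                                   batch_size=8, seed=0))
        hist = train_deep(model, X, y, seed=0)
        assert len(hist.train_loss) <= 27
        assert np.mean(predict_classes(model, X) == y) >= 0.95

    def test_early_stopping_restores_best_weights(self, rng):
        X, y = self._separable(rng, n=40)
        model = LSTMModel(LSTMConfig(segment_time_size=16, n_features=3,
                                     n_classes=2, hidden_size=4, seed=1,
                                     epochs=27, batch_size=8))
        hist = train_deep(model, X, y, seed=1, patience=2)
        assert hist.best_epoch <= len(hist.val_loss) - 1
        assert max(hist.val_accuracy) == hist.val_accuracy[hist.best_epoch]
        hist_l = train_deep(model, X, y, seed=1, patience=2,
                            monitor="val_loss")
        assert min(hist_l.val_loss) == hist_l.val_loss[hist_l.best_epoch]

    def test_single_class_training_warns(self, rng, caplog):
        X = rng.standard_normal((20, 8, 3))
        y = np.zeros(20, dtype=int)
        model = LSTMModel(LSTMConfig(segment_time_size=8, n_features=3,
                                     n_classes=2, hidden_size=3, seed=0,
                                     epochs=2, batch_size=4))
        import logging
        with caplog.at_level(logging.WARNING):
            train_deep(model, X, y, seed=0)
        assert any("single class" in r.message for r in caplog.records)


def test_softmax_is_shift_invariant_and_normalized(rng):
    z = rng.standard_normal((5, 4)) * 30
    p = softmax(z)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(softmax(z + 100.0), p, atol=1e-12)
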