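"""Network blocks against straight-line oracles and finite differences."""

import numpy as np
import pytest

from ssirisk import _nn
from ssirisk.risk_models import attention_forward, cnn_forward, weighted_loss

from _oracles import attention_oracle, cnn_oracle, gelu_scalar


def make_cnn(rng, d=4, n_struct=2, windows=(2, 3), channels=3, n_pad=6):
    emb = np.zeros((1, d), dtype=np.float32)  # replaced by cnn_forward
    net = _nn.CNNNet(emb, n_struct, windows=windows, channels=channels,
                     dense_units=4, dropout_conv=0, dropout_dense=0,
                     seed=int(rng.integers(2**31)))
    return net


def random_instance(rng, n=6, d=4, n_struct=2, min_len=2):
    length = int(rng.integers(min_len, n + 1))
    padded = np.zeros((n, d))
    padded[n - length:] = rng.normal(0, 1, (length, d))
    structured = rng.normal(0, 1, n_struct)
    return padded, structured, length


class TestCNNForward:
    def test_hand_computed_single_channel(self):
        """Window 2, weights [1,0,0,1]: conv outputs GELU(5), GELU(3)."""
        rng = np.random.default_rng(0)
        net = make_cnn(rng, d=2, n_struct=1, windows=(2,), channels=1, n_pad=3)
        net.params["Wc2"] = np.array([[1.0], [0.0], [0.0], [1.0]], dtype=np.float32)
        net.params["bc2"] = np.zeros(1, dtype=np.float32)
        padded = np.array([[1.0, 2.0], [3.0, 4.0], [-1.0, 0.0]])
        prob, maps = cnn_forward(padded, [0.0], net, length=3)
        fmap = maps[0][:, 0]
        assert fmap[0] == pytest.approx(gelu_scalar(5.0), abs=1e-6)
        assert fmap[1] == pytest.approx(gelu_scalar(3.0), abs=1e-6)
        assert max(fmap) == pytest.approx(4.9999985, abs=1e-4)
        assert 0 < prob < 1

    def test_zero_weights_give_half(self):
        rng = np.random.default_rng(1)
        net = make_cnn(rng)
        for k, v in net.params.items():
            net.params[k] = np.zeros_like(v)
        padded, structured, length = random_instance(rng)
        prob, _ = cnn_forward(padded, structured, net, length)
        assert prob == pytest.approx(0.5)

    def test_output_strictly_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            net = make_cnn(rng)
            padded, structured, length = random_instance(rng)
            prob, _ = cnn_forward(padded, structured, net, length)
            assert 0.0 < prob < 1.0

    def test_matches_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            net = make_cnn(rng)
            padded, structured, length = random_instance(rng)
            prob, _ = cnn_forward(padded, structured, net, length)
            conv_w = {h: np.asarray(net.params[f"Wc{h}"], dtype=float)
                      .reshape(h, net.d, net.channels) for h in net.windows}
            conv_b = {h: np.asarray(net.params[f"bc{h}"], dtype=float)
                      for h in net.windows}
            expected, _ = cnn_oracle(
                padded, structured, length, net.windows, conv_w, conv_b,
                np.asarray(net.params["W1"], dtype=float),
                np.asarray(net.params["b1"], dtype=float),
                np.asarray(net.params["w2"], dtype=float),
                float(net.params["b2"][0]))
            assert prob == pytest.approx(expected, abs=1e-6)

    def test_window_larger_than_padding_rejected(self):
        rng = np.random.default_rng(4)
        net = make_cnn(rng, windows=(5,), n_pad=3)
        with pytest.raises(ValueError):
            cnn_forward(np.zeros((3, 4)), np.zeros(2), net, length=3)


def make_attn(rng, d=4, n_struct=2, m=3, d1=4, d2=2):
    emb = np.zeros((1, d), dtype=np.float32)
    return _nn.AttnNet(emb, n_struct, m=m, d1=d1, d2=d2, dense_units=4,
                       dropout_emb=0, dropout_lstm=0, dropout_dense=0,
                       seed=int(rng.integers(2**31)))


class TestAttentionForward:
    def test_constant_scores_give_uniform_attention(self):
        rng = np.random.default_rng(5)
        net = make_attn(rng)
        net.params["W1"] = np.zeros_like(net.params["W1"])  # pre-softmax constant 0
        padded, structured, length = random_instance(rng, min_len=3)
        _, A = attention_forward(padded, structured, net, length)
        real = A[:, A.shape[1] - length:]
        assert np.allclose(real, 1.0 / length, atol=1e-6)
        assert np.allclose(A[:, :A.shape[1] - length], 0.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            net = make_attn(rng)
            padded, structured, length = random_instance(rng, min_len=1)
            _, A = attention_forward(padded, structured, net, length)
            assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_matches_loop_oracle_on_tiny_instance(self):
        rng = np.random.default_rng(7)
        net = make_attn(rng, m=1, d1=2, d2=1)
        padded, structured, length = random_instance(rng, n=3, min_len=3)
        p = {k: np.asarray(v, dtype=float) for k, v in net.params.items()}
        prob, A = attention_forward(padded, structured, net, length)
        expected, A_exp = attention_oracle(
            padded, structured, length,
            p["Wx_f"], p["Wh_f"], p["b_f"], p["Wx_b"], p["Wh_b"], p["b_b"],
            p["W2"], p["W1"], p["Wd"], p["bd"], p["w_out"], float(p["b_out"][0]))
        assert prob == pytest.approx(expected, abs=1e-6)
        assert np.allclose(A, A_exp, atol=1e-6)

    def test_matches_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            net = make_attn(rng)
            padded, structured, length = random_instance(rng)
            p = {k: np.asarray(v, dtype=float) for k, v in net.params.items()}
            prob, _ = attention_forward(padded, structured, net, length)
            expected, _ = attention_oracle(
                padded, structured, length,
                p["Wx_f"], p["Wh_f"], p["b_f"], p["Wx_b"], p["Wh_b"], p["b_b"],
                p["W2"], p["W1"], p["Wd"], p["bd"], p["w_out"],
                float(p["b_out"][0]))
            assert prob == pytest.approx(expected, abs=1e-6)


class TestGradients:
    """Analytic backprop against central finite differences."""

    def _directional_check(self, net, forward, tol):
        rng = np.random.default_rng(11)
        for k in net.params:
            net.params[k] = net.params[k].astype(np.float64)
        B, n = 3, 6
        V = net.params["E"].shape[0] - 1
        ids = rng.integers(0, max(V, 1), (B, n))
        ids[0, :2] = V
        lengths = np.array([4, 6, 6])
        Xs = rng.normal(0, 1, (B, 2))
        y = np.array([1.0, 0.0, 1.0])

        def loss():
            res = forward(ids, lengths, Xs)
            return _nn.weighted_bce_grad(res[0], y, 2.0)[0]

        res = forward(ids, lengths, Xs)
        _, dlogit = _nn.weighted_bce_grad(res[0], y, 2.0)
        grads = net.backward(res[1], dlogit)
        dirs = {k: rng.normal(0, 1, v.shape) for k, v in net.params.items()}
        dirs["E"][net.pad_id] = 0.0  # pad row pinned to zero
        analytic = sum((grads[k] * dirs[k]).sum() for k in net.params)
        eps = 1e-5
        for k in net.params:
            net.params[k] += eps * dirs[k]
        f1 = loss()
        for k in net.params:
            net.params[k] -= 2 * eps * dirs[k]
        f2 = loss()
        fd = (f1 - f2) / (2 * eps)
        assert abs(fd - analytic) / (abs(analytic) + 1e-12) < tol

    def test_cnn_gradients(self):
        rng = np.random.default_rng(12)
        emb = rng.normal(0, 0.5, (6, 4))
        emb[5] = 0
        net = _nn.CNNNet(emb.astype(np.float32), 2, windows=(2, 3), channels=3,
                         dense_units=4, dropout_conv=0, dropout_dense=0, seed=1)
        self._directional_check(net, lambda i, l, x: net.forward(i, l, x), 1e-5)

    def test_attention_gradients(self):
        rng = np.random.default_rng(13)
        emb = rng.normal(0, 0.5, (6, 4))
        emb[5] = 0
        net = _nn.AttnNet(emb.astype(np.float32), 2, m=3, d1=4, d2=2,
                          dense_units=4, dropout_emb=0, dropout_lstm=0,
                          dropout_dense=0, seed=1)
        self._directional_check(net, lambda i, l, x: net.forward(i, l, x), 1e-4)


class TestWeightedLoss:
    def test_hand_computed_value(self):
        assert weighted_loss([0.5], [1], 3.0) == pytest.approx(3 * np.log(2))

    def test_unit_weight_is_plain_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, 20)
        y = rng.integers(0, 2, 20)
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert weighted_loss(p, y, 1.0) == pytest.approx(expected)

    def test_perfect_predictions_near_zero(self):
        assert weighted_loss([1 - 1e-9, 1e-9], [1, 0], 5.0) < 1e-5

    def test_degenerate_probabilities_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            val = weighted_loss([1.0, 0.0], [1, 0], 2.0)
        assert np.isfinite(val)

    def test_class_weighting_balances_gradient_mass(self):
        """With w+ = N-/N+ and balanced scores, the two classes pull equally."""
        y = np.array([1] * 5 + [0] * 45, dtype=float)
        logits = np.zeros(50)  # p = 0.5 everywhere
        _, dlogit = _nn.weighted_bce_grad(logits, y, pos_weight=45 / 5)
        pos_mass = np.abs(dlogit[y == 1]).sum()
        neg_mass = np.abs(dlogit[y == 0]).sum()
        assert pos_mass == pytest.approx(neg_mass)
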