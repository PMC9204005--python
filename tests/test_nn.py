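"""Network-layer semantics: LSTM cell equations, attention, dense head,
BCE loss, convolution geometry, and gradient correctness."""

import math

import numpy as np
import pytest

from deeparc import _nn
from deeparc._nn import (
    Adam,
    Attention,
    Conv1d,
    Dropout,
    Linear,
    LSTM,
    LSTMParams,
    LSTMState,
    bce_loss,
    lstm_step,
)
from deeparc.network import (
    AttentionOutput,
    ConfigurationError,
    ContractError,
    DeepARCNetwork,
    ModelSpec,
    attention_forward,
)


def scalar_lstm_reference(x, h_prev, c_prev, p: LSTMParams):
    """Independent pure-Python scalar implementation of the LSTM update."""
    H = p.hidden_size
    F = len(x)

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    def affine(Wx, Wh, b, j):
        return (sum(x[a] * Wx[a][j] for a in range(F))
                + sum(h_prev[a] * Wh[a][j] for a in range(H)) + b[j])

    c, h = [], []
    for j in range(H):
        f = sig(affine(p.W_xf, p.W_hf, p.b_f, j))
        i = sig(affine(p.W_xi, p.W_hi, p.b_i, j))
        g = math.tanh(affine(p.W_xc, p.W_hc, p.b_c, j))
        o = sig(affine(p.W_xo, p.W_ho, p.b_o, j))
        cj = f * c_prev[j] + i * g
        c.append(cj)
        h.append(o * math.tanh(cj))
    return c, h


def random_lstm_params(rng, input_size, hidden):
    mats = {f"W_x{g}": rng.standard_normal((input_size, hidden)) for g in "fico"}
    mats |= {f"W_h{g}": rng.standard_normal((hidden, hidden)) for g in "fico"}
    mats |= {f"b_{g}": rng.standard_normal(hidden) for g in "fico"}
    return LSTMParams(**mats)


class TestLstmStep:
    def test_zero_parameters_half_gates(self):
        zeros = {f"W_x{g}": np.zeros((2, 3)) for g in "fico"}
        zeros |= {f"W_h{g}": np.zeros((3, 3)) for g in "fico"}
        zeros |= {f"b_{g}": np.zeros(3) for g in "fico"}
        p = LSTMParams(**zeros)
        v = np.array([0.4, -0.2, 1.0])
        out = lstm_step(np.array([1.0, -1.0]), LSTMState(c=v, h=np.zeros(3)), p)
        np.testing.assert_allclose(out.c, 0.5 * v)
        np.testing.assert_allclose(out.h, 0.5 * np.tanh(0.5 * v))

    def test_saturated_gates_pure_memory(self):
        rng = np.random.default_rng(0)
        p = random_lstm_params(rng, 2, 3)
        p.b_f[:] = 50.0   # forget gate ~1
        p.b_i[:] = -50.0  # input gate ~0
        for m in (p.W_xf, p.W_hf, p.W_xi, p.W_hi):
            m[...] = 0
        c_prev = np.array([0.3, -0.7, 1.2])
        out = lstm_step(rng.standard_normal(2), LSTMState(c=c_prev, h=np.zeros(3)), p)
        np.testing.assert_allclose(out.c, c_prev, atol=1e-12)

    def test_single_unit_scalar_oracle(self):
        # W_xi = W_xc = 1, everything else 0, x=1, c_prev=0:
        # c = sigmoid(1) * tanh(1) = 0.7311 * 0.7616 = 0.5568
        z = np.zeros((1, 1))
        p = LSTMParams(W_xf=z.copy(), W_hf=z.copy(), W_xi=np.ones((1, 1)),
                       W_hi=z.copy(), W_xc=np.ones((1, 1)), W_hc=z.copy(),
                       W_xo=z.copy(), W_ho=z.copy(), b_f=np.zeros(1),
                       b_i=np.zeros(1), b_c=np.zeros(1), b_o=np.zeros(1))
        out = lstm_step(np.ones(1), LSTMState(c=np.zeros(1), h=np.zeros(1)), p)
        assert out.c[0] == pytest.approx(0.5568, abs=1e-4)

    @pytest.mark.parametrize("case", range(100))
    def test_matches_scalar_reference(self, case):
        rng = np.random.default_rng(1000 + case)
        hidden = int(rng.integers(1, 5))
        input_size = int(rng.integers(1, 4))
        p = random_lstm_params(rng, input_size, hidden)
        x = rng.standard_normal(input_size)
        c_prev = rng.standard_normal(hidden)
        h_prev = rng.uniform(-0.9, 0.9, hidden)
        out = lstm_step(x, LSTMState(c=c_prev, h=h_prev), p)
        c_ref, h_ref = scalar_lstm_reference(x, h_prev, c_prev, p)
        np.testing.assert_allclose(out.c, c_ref, atol=1e-6)
        np.testing.assert_allclose(out.h, h_ref, atol=1e-6)

    def test_batched_lstm_agrees_with_step(self):
        rng = np.random.default_rng(2)
        layer = LSTM(3, 4, rng, dtype=np.float64)
        x = rng.standard_normal((2, 6, 3))
        h_seq, final = layer.forward(x)
        state = LSTMState(c=np.zeros(4), h=np.zeros(4))
        for t in range(6):
            state = lstm_step(x[1, t], state, layer.params)
        np.testing.assert_allclose(h_seq[1, -1], state.h, atol=1e-10)
        np.testing.assert_allclose(final.h[1], state.h, atol=1e-10)


class TestBiLstm:
    def test_sum_merge(self):
        from deeparc._nn import BiLSTM
        rng = np.random.default_rng(3)
        bi = BiLSTM(2, 3, rng, merge="sum", dtype=np.float64)
        x = rng.standard_normal((1, 5, 2))
        hf, _ = bi.fwd.forward(x)
        hb_rev, _ = bi.bwd.forward(x[:, ::-1].copy())
        merged, _ = bi.forward(x)
        np.testing.assert_allclose(merged, hf + hb_rev[:, ::-1], atol=1e-12)

    def test_palindromic_input_shared_params_symmetric(self):
        from deeparc._nn import BiLSTM
        rng = np.random.default_rng(4)
        bi = BiLSTM(2, 3, rng, merge="sum", dtype=np.float64)
        for pf, pb in zip(bi.fwd.parameters(), bi.bwd.parameters()):
            pb.value[...] = pf.value
        half = rng.standard_normal((1, 4, 2))
        x = np.concatenate([half, half[:, ::-1]], axis=1)  # palindrome
        merged, _ = bi.forward(x)
        np.testing.assert_allclose(merged[0], merged[0, ::-1], atol=1e-10)

    def test_concat_doubles_output(self):
        from deeparc._nn import BiLSTM
        rng = np.random.default_rng(5)
        bi = BiLSTM(2, 3, rng, merge="concat", dtype=np.float64)
        merged, hn = bi.forward(rng.standard_normal((2, 5, 2)))
        assert merged.shape == (2, 5, 6) and hn.shape == (2, 6)


class TestConv:
    @pytest.mark.parametrize("T", [1, 2, 5, 99, 150])
    def test_length_preserved_kernel5_pad2(self, T):
        rng = np.random.default_rng(6)
        conv = Conv1d(8, 4, kernel_size=5, padding=2, rng=rng, dtype=np.float64)
        out = conv.forward(rng.standard_normal((2, T, 8)))
        assert out.shape == (2, T, 4)

    def test_zero_weights_zero_output_and_relu(self):
        rng = np.random.default_rng(7)
        conv = Conv1d(3, 2, 5, 2, rng, dtype=np.float64)
        conv.W.value[...] = 0
        conv.b.value[...] = 0
        out = conv.forward(rng.standard_normal((1, 10, 3)))
        np.testing.assert_array_equal(out, 0)

    def test_relu_applied_in_network_cnn(self):
        rng = np.random.default_rng(8)
        spec = ModelSpec(cnn_channels=6, bilstm_hidden=4, attention_dim=4,
                         dense_neurons=4, dropout=0.0)
        net = DeepARCNetwork(spec, "onehot_base", 4, rng=rng, dtype=np.float64)
        x = rng.random((2, 12, 4))
        for layer in net.cnn:
            x = layer.forward(x)
        assert (x >= 0).all()


class TestAttention:
    def test_constant_columns_uniform_alpha(self):
        att = Attention(3, np.random.default_rng(9), dtype=np.float64)
        H = np.tile(np.array([[0.5, -0.2, 0.1]]), (7, 1))[None]  # (1, 7, 3)
        _, alpha = att.forward(H)
        np.testing.assert_allclose(alpha[0], np.full(7, 1 / 7), atol=1e-12)

    def test_single_position_degenerate(self):
        att = Attention(3, np.random.default_rng(10), dtype=np.float64)
        col = np.array([0.4, -0.8, 0.2])
        h_star, alpha = att.forward(col[None, None, :])
        np.testing.assert_allclose(alpha, [[1.0]])
        np.testing.assert_allclose(h_star[0], np.tanh(col))

    def test_scalar_softmax_worked_example(self):
        # H = [[10, 0], [0, 0]], omega = [1, 0]:
        # scores = [tanh(10), 0] ~ [1, 0]; alpha ~ softmax([1, 0])
        att = Attention(2, np.random.default_rng(11), dtype=np.float64)
        att.omega.value[...] = [1.0, 0.0]
        H = np.array([[10.0, 0.0], [0.0, 0.0]])
        out = attention_forward(H, att)
        assert isinstance(out, AttentionOutput)
        np.testing.assert_allclose(out.alpha, [0.7311, 0.2689], atol=1e-4)

    def test_context_is_alpha_weighted_columns(self):
        rng = np.random.default_rng(12)
        att = Attention(4, rng, dtype=np.float64)
        H = rng.standard_normal((4, 9))
        out = attention_forward(H, att)
        np.testing.assert_allclose(out.context, np.tanh(H @ out.alpha), atol=1e-12)
        assert out.alpha.sum() == pytest.approx(1.0, abs=1e-6)
        assert (np.abs(out.context) < 1).all()

    def test_wrong_orientation_rejected(self):
        att = Attention(4, np.random.default_rng(13))
        with pytest.raises(ConfigurationError):
            attention_forward(np.zeros((5, 4)).T.copy()[:3], att)


class TestDenseAndLoss:
    def _net(self, dropout=0.2):
        rng = np.random.default_rng(14)
        spec = ModelSpec(architecture="bilstm_att", bilstm_hidden=4,
                         attention_dim=4, dense_neurons=4, dropout=dropout)
        return DeepARCNetwork(spec, "onehot_base", 4, rng=rng, dtype=np.float64)

    def test_zero_dense_params_give_half(self):
        net = self._net(dropout=0.0)
        for p in net.dense1.parameters() + net.dense2.parameters():
            p.value[...] = 0
        x = np.random.default_rng(15).random((3, 8, 4))
        probs, _ = net.forward(x)
        np.testing.assert_allclose(probs, 0.5)

    def test_eval_mode_deterministic_despite_dropout(self):
        net = self._net(dropout=0.5)
        x = np.random.default_rng(16).random((3, 8, 4))
        p1, _ = net.forward(x, training=False)
        p2, _ = net.forward(x, training=False)
        np.testing.assert_array_equal(p1, p2)

    def test_training_dropout_changes_output(self):
        net = self._net(dropout=0.5)
        x = np.random.default_rng(17).random((3, 8, 4))
        rng = np.random.default_rng(18)
        p1, _ = net.forward(x, training=True, rng=rng)
        p2, _ = net.forward(x, training=True, rng=rng)
        assert not np.array_equal(p1, p2)

    def test_output_monotone_in_final_bias(self):
        net = self._net(dropout=0.0)
        x = np.random.default_rng(19).random((2, 8, 4))
        p_lo, _ = net.forward(x)
        net.dense2.b.value += 1.0
        p_hi, _ = net.forward(x)
        assert (p_hi > p_lo).all()

    def test_bce_worked_examples(self):
        assert bce_loss([0.5], [1]) == pytest.approx(0.6931, abs=1e-4)
        assert bce_loss([0.9, 0.1], [1, 0]) == pytest.approx(0.10536, abs=1e-5)
        assert bce_loss([1.0, 0.0], [1, 0]) <= 1.2e-7
        assert bce_loss([0.0], [1]) > 10  # clipped, finite


class TestModelForward:
    @pytest.mark.parametrize("arch", ["cnn_bilstm_att", "cnn_bilstm", "bilstm_att"])
    def test_probability_range_all_architectures(self, arch):
        rng = np.random.default_rng(20)
        spec = ModelSpec(architecture=arch, cnn_channels=8,
                         bilstm_hidden=4, attention_dim=4, dense_neurons=4)
        net = DeepARCNetwork(spec, "onehot_base", 4, rng=rng, dtype=np.float64)
        probs, alpha = net.forward(rng.random((5, 20, 4)))
        assert ((probs > 0) & (probs < 1)).all()
        if spec.has_attention:
            assert alpha.shape == (5, 20)
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        else:
            assert alpha is None

    def test_alpha_length_99_for_101bp_k3(self):
        rng = np.random.default_rng(21)
        net = DeepARCNetwork(ModelSpec(cnn_channels=8, bilstm_hidden=4,
                                       attention_dim=4, dense_neurons=4),
                             "onehot_kmer", 64, k=3, rng=rng)
        _, alpha = net.forward(rng.random((2, 99, 64)).astype(np.float32))
        assert alpha.shape == (2, 99)

    def test_eval_determinism_bit_identical(self):
        rng = np.random.default_rng(22)
        net = DeepARCNetwork(ModelSpec(cnn_channels=8, bilstm_hidden=4,
                                       attention_dim=4, dense_neurons=4),
                             "onehot_base", 4, rng=rng, dtype=np.float64)
        x = rng.random((3, 15, 4))
        np.testing.assert_array_equal(net.forward(x)[0], net.forward(x)[0])

    def test_attention_request_from_plain_cnn_bilstm_rejected(self):
        rng = np.random.default_rng(23)
        net = DeepARCNetwork(ModelSpec(architecture="cnn_bilstm", cnn_channels=8,
                                       bilstm_hidden=4, dense_neurons=4),
                             "onehot_base", 4, rng=rng)
        with pytest.raises(ContractError):
            net.attention_weights_required()

    def test_attention_dim_must_match_bilstm_output(self):
        with pytest.raises(ConfigurationError, match="attention_dim"):
            DeepARCNetwork(ModelSpec(bilstm_hidden=8, attention_dim=4),
                           "onehot_base", 4)


class TestGradients:
    def test_finite_difference_omega_and_dense(self):
        """Analytic BCE gradients w.r.t. the attention vector and dense-layer
        parameters match central differences to < 1e-4 relative error."""
        rng = np.random.default_rng(24)
        spec = ModelSpec(architecture="bilstm_att", bilstm_hidden=3,
                         attention_dim=3, dense_neurons=4, dropout=0.0)
        net = DeepARCNetwork(spec, "onehot_base", 4, rng=rng, dtype=np.float64)
        x = rng.random((4, 9, 4))
        y = np.array([1.0, 0.0, 1.0, 0.0])

        probs, _ = net.forward(x)
        for p in net.parameters():
            p.grad[...] = 0
        net.backward(_nn.bce_grad_wrt_logits(probs, y))

        eps = 1e-5
        checked = (net.attention.parameters() + net.dense1.parameters()
                   + net.dense2.parameters())
        for par in checked:
            flat, gflat = par.value.ravel(), par.grad.ravel()
            for i in range(flat.size):
                old = flat[i]
                flat[i] = old + eps
                lp = bce_loss(net.forward(x)[0], y)
                flat[i] = old - eps
                lm = bce_loss(net.forward(x)[0], y)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num) + abs(gflat[i]), 1e-8)
                assert abs(num - gflat[i]) / denom < 1e-4, par.name

    def test_adam_reduces_loss_on_toy_problem(self):
        rng = np.random.default_rng(25)
        lin = Linear(3, 1, rng, dtype=np.float64)
        opt = Adam(lin.parameters(), learning_rate=0.05)
        x = rng.standard_normal((32, 3))
        y = (x[:, 0] > 0).astype(float)
        first = None
        for _ in range(200):
            logits = lin.forward(x)[:, 0]
            probs = _nn.sigmoid(logits)
            loss = bce_loss(probs, y)
            first = first if first is not None else loss
            opt.zero_grad()
            lin.backward(_nn.bce_grad_wrt_logits(probs, y)[:, None])
            opt.step()
        assert loss < first / 3
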