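"""Autodiff and attention-block correctness: numerical gradient checks and
the analytic forward identities of the gating mechanisms."""

import numpy as np
import pytest

from msifusion import nn
from msifusion.nn import autodiff as ad


def numerical_gradient(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def assert_grads_match(make_loss, params, tol=1e-6):
    for p in params:
        p.data = p.data.astype(np.float64)
    loss = make_loss()
    for p in params:
        p.zero_grad()
    loss.backward()
    for p in params:
        ng = numerical_gradient(lambda: make_loss().data, p.data)
        err = np.abs(ng - p.grad).max()
        assert err < tol * (1.0 + np.abs(ng).max()), \
            f"gradient mismatch for shape {p.data.shape}: {err}"


class TestGradients:
    """Finite-difference checks of every layer family used by the model."""

    def test_conv1d_batchnorm_relu_chain(self):
        rng = np.random.default_rng(0)
        x = ad.Tensor(rng.standard_normal((2, 3, 11)), requires_grad=True)
        conv = nn.Conv1d(3, 4, 3, rng, stride=2, pad=1)
        bn = nn.BatchNorm(4)
        w = np.random.default_rng(1).standard_normal((2, 4, 6))

        def loss():
            return ad.reduce_sum(nn.ReLU()(bn(conv(x))) * ad.Tensor(w))

        assert_grads_match(loss, [x, conv.weight, conv.bias, bn.gamma,
                                  bn.beta], tol=1e-5)

    def test_conv2d_depthwise_maxpool_chain(self):
        rng = np.random.default_rng(2)
        x = ad.Tensor(rng.standard_normal((2, 3, 9, 9)), requires_grad=True)
        conv = nn.Conv2d(3, 4, 3, rng, stride=2, pad=1)
        dw = nn.DepthwiseConv2d(4, 3, rng, stride=1, pad=1)
        pool = nn.MaxPool2d(2, 2)
        w = np.random.default_rng(3).standard_normal((2, 4, 2, 2))

        def loss():
            return ad.reduce_sum(pool(dw(conv(x))) * ad.Tensor(w))

        assert_grads_match(loss, [x, conv.weight, dw.weight], tol=1e-5)

    def test_channel_attention(self):
        rng = np.random.default_rng(4)
        x = ad.Tensor(rng.standard_normal((3, 8, 5)), requires_grad=True)
        att = nn.ChannelAttention1d(8, rng, reduction=4)
        w = np.random.default_rng(5).standard_normal((3, 8, 5))

        def loss():
            return ad.reduce_sum(att(x) * ad.Tensor(w))

        assert_grads_match(loss, [x, att.fc1.weight, att.fc2.weight], tol=1e-5)

    def test_cross_modal_attention(self):
        rng = np.random.default_rng(6)
        fi = ad.Tensor(rng.standard_normal((4, 16)) * 0.5, requires_grad=True)
        fs = ad.Tensor(rng.standard_normal((4, 16)) * 0.5, requires_grad=True)
        cma = nn.CrossModalAttention(16, rng)
        w = np.random.default_rng(7).standard_normal((4, 16))

        def loss():
            return ad.reduce_sum(cma(fi, fs) * ad.Tensor(w))

        assert_grads_match(loss, [fi, fs, cma.q_proj.weight, cma.k_proj.weight,
                                  cma.v_proj.weight, cma.out_proj.weight,
                                  cma.bn.gamma], tol=5e-5)

    def test_cross_entropy_through_linear(self):
        rng = np.random.default_rng(8)
        x = ad.Tensor(rng.standard_normal((6, 10)), requires_grad=True)
        lin = nn.Linear(10, 4, rng)
        y = np.array([0, 1, 2, 3, 0, 1])

        def loss():
            return nn.cross_entropy(lin(x), y)

        assert_grads_match(loss, [x, lin.weight, lin.bias], tol=1e-5)


class TestChannelAttention:
    def test_identical_channels_get_equal_weights(self):
        rng = np.random.default_rng(0)
        att = nn.ChannelAttention1d(8, rng, reduction=4)
        x = ad.Tensor(np.tile(np.linspace(0, 1, 5), (2, 8, 1)))
        w = att.weights(x).data
        assert np.allclose(w, w[:, :1], atol=1e-6)

    def test_zero_mlp_gives_half_gates(self):
        rng = np.random.default_rng(0)
        att = nn.ChannelAttention1d(8, rng, reduction=4)
        for p in (att.fc1.weight, att.fc1.bias, att.fc2.weight, att.fc2.bias):
            p.data = np.zeros_like(p.data)
        x = ad.Tensor(np.random.default_rng(1).standard_normal((3, 8, 6)))
        out = att(x)
        assert np.allclose(out.data, 0.5 * x.data, atol=1e-6)

    def test_gates_in_unit_interval(self):
        rng = np.random.default_rng(0)
        att = nn.ChannelAttention1d(16, rng, reduction=8)
        trials = np.random.default_rng(2).standard_normal((1000, 16, 4)) * 3
        w = att.weights(ad.Tensor(trials)).data
        assert ((w > 0) & (w < 1)).all()

    def test_channel_mismatch_rejected(self):
        att = nn.ChannelAttention1d(8, np.random.default_rng(0), reduction=4)
        with pytest.raises(ValueError, match="channels"):
            att(ad.Tensor(np.zeros((1, 4, 5))))


class TestSEBlock:
    def test_zero_weights_scale_input_by_half(self):
        rng = np.random.default_rng(0)
        se = nn.SEBlock(8, rng, reduction=4)
        for p in (se.fc1.weight, se.fc1.bias, se.fc2.weight, se.fc2.bias):
            p.data = np.zeros_like(p.data)
        x = ad.Tensor(np.random.default_rng(1).standard_normal((2, 8, 3, 3)))
        assert np.allclose(se(x).data, 0.5 * x.data, atol=1e-6)

    def test_hand_computed_single_channel_toy(self):
        # C=1, r=1, 1x1 weights set by hand: z = mean(x) = 2,
        # s = sigmoid(w2 * relu(w1 * z)) = sigmoid(0.5 * relu(1 * 2))
        rng = np.random.default_rng(0)
        se = nn.SEBlock(1, rng, reduction=1)
        se.fc1.weight.data = np.array([[1.0]], np.float32)
        se.fc1.bias.data = np.zeros(1, np.float32)
        se.fc2.weight.data = np.array([[0.5]], np.float32)
        se.fc2.bias.data = np.zeros(1, np.float32)
        x = ad.Tensor(np.full((1, 1, 2, 2), 2.0))
        expected = 2.0 / (1.0 + np.exp(-1.0))
        assert np.allclose(se(x).data, expected, atol=1e-6)

    def test_gate_never_amplifies(self):
        rng = np.random.default_rng(3)
        se = nn.SEBlock(8, rng, reduction=4)
        x = np.random.default_rng(4).standard_normal((5, 8, 3, 3))
        out = se(ad.Tensor(x)).data
        # s in (0,1), so each channel's norm shrinks
        assert (np.abs(out) <= np.abs(x) + 1e-9).all()

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            nn.SEBlock(6, np.random.default_rng(0), reduction=4)


class TestCrossModalAttention:
    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        cma = nn.CrossModalAttention(16, rng)
        fi = ad.Tensor(rng.standard_normal((5, 16)))
        fs = ad.Tensor(rng.standard_normal((5, 16)))
        A = cma.attention_matrix(fi, fs).data
        assert np.allclose(A.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_output_projection_is_residual_identity(self):
        rng = np.random.default_rng(1)
        cma = nn.CrossModalAttention(16, rng, post_norm=False)
        cma.out_proj.weight.data = np.zeros_like(cma.out_proj.weight.data)
        cma.out_proj.bias.data = np.zeros_like(cma.out_proj.bias.data)
        fi = ad.Tensor(rng.standard_normal((4, 16)))
        fs = ad.Tensor(rng.standard_normal((4, 16)))
        assert np.array_equal(cma(fi, fs).data, fi.data)

    def test_constant_query_and_key_give_uniform_attention(self):
        # equal logits -> softmax = 1/dim everywhere; Z = mean of projected V
        rng = np.random.default_rng(2)
        cma = nn.CrossModalAttention(16, rng, post_norm=False)
        for proj in (cma.q_proj, cma.k_proj):
            proj.weight.data = np.zeros_like(proj.weight.data)
            proj.bias.data = np.ones_like(proj.bias.data)
        fi = ad.Tensor(rng.standard_normal((3, 16)))
        fs = ad.Tensor(rng.standard_normal((3, 16)))
        A = cma.attention_matrix(fi, fs).data
        assert np.allclose(A, 1.0 / 16, atol=1e-7)
        v = cma.v_proj(fs).data
        z = cma(fi, fs).data - fi.data
        expected = cma.out_proj(ad.Tensor(
            np.tile(v.mean(axis=1, keepdims=True), (1, 16)))).data
        assert np.allclose(z, expected, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        cma = nn.CrossModalAttention(16, np.random.default_rng(0))
        with pytest.raises(ValueError, match="64|16"):
            cma(ad.Tensor(np.zeros((2, 8))), ad.Tensor(np.zeros((2, 16))))

    def test_invalid_scale_mode_rejected(self):
        with pytest.raises(ValueError, match="sqrt"):
            nn.CrossModalAttention(16, np.random.default_rng(0), scale="bad")


class TestSoftmax:
    def test_rows_sum_to_one_and_shift_invariant(self):
        x = np.random.default_rng(0).standard_normal((10, 7)) * 5
        p = nn.softmax(ad.Tensor(x), axis=1).data
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-7)
        p2 = nn.softmax(ad.Tensor(x + 123.0), axis=1).data
        assert np.allclose(p, p2, atol=1e-6)


class TestChannelShuffle:
    def test_shuffle_interleaves_groups(self):
        x = np.arange(8, dtype=np.float32).reshape(1, 8, 1, 1)
        out = nn.ChannelShuffle(2)(ad.Tensor(x)).data.reshape(-1)
        assert out.tolist() == [0, 4, 1, 5, 2, 6, 3, 7]
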