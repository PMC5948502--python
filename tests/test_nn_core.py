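import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litenet import nn_core as nc

# ---------------------------------------------------------------------------
# naive loop references (independent oracles for the vectorized kernels)


def naive_conv_same(x, W, b, stride):
    B, C, L = x.shape
    k, _, O = W.shape
    pad_l = k // 2  # even kernels pad the extra zero on the left
    xp = np.zeros((B, C, L + k - 1))
    xp[:, :, pad_l : pad_l + L] = x
    L_out = -(-L // stride)
    y = np.zeros((B, O, L_out))
    for bi in range(B):
        for o in range(O):
            for t in range(L_out):
                acc = b[o]
                for c in range(C):
                    for j in range(k):
                        acc += xp[bi, c, t * stride + j] * W[j, c, o]
                y[bi, o, t] = acc
    return y


def naive_depthwise_same(x, W, b, stride):
    B, C, L = x.shape
    k, _ = W.shape
    pad_l = k // 2
    xp = np.zeros((B, C, L + k - 1))
    xp[:, :, pad_l : pad_l + L] = x
    L_out = -(-L // stride)
    y = np.zeros((B, C, L_out))
    for bi in range(B):
        for c in range(C):
            for t in range(L_out):
                acc = b[c]
                for j in range(k):
                    acc += xp[bi, c, t * stride + j] * W[j, c]
                y[bi, c, t] = acc
    return y


# ---------------------------------------------------------------------------
# full (flip-and-slide) convolution


class TestConv1dFull:
    def test_worked_example(self):
        y = nc.conv1d_full([1, 2, 3], [4, 5, 6])
        assert len(y) == 5
        assert np.array_equal(y, [4, 13, 28, 27, 18])

    def test_identity_kernel(self, rng):
        x = rng.normal(size=17)
        assert np.allclose(nc.conv1d_full(x, [1.0]), x)

    @settings(deadline=None, derandomize=True)
    @given(m=st.integers(1, 30), k=st.integers(1, 10), seed=st.integers(0, 50))
    def test_matches_numpy_convolve(self, m, k, seed):
        r = np.random.default_rng(seed)
        x, h = r.normal(size=m), r.normal(size=k)
        assert np.allclose(nc.conv1d_full(x, h), np.convolve(x, h, mode="full"),
                           atol=1e-12)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            nc.conv1d_full([], [1.0])


# ---------------------------------------------------------------------------
# layer convolutions ("same" cross-correlation)


class TestConvLayer:
    @pytest.mark.parametrize("k,c_in,c_out,stride", [
        (1, 1, 1, 1), (2, 1, 3, 1), (3, 2, 4, 1), (5, 3, 2, 2), (4, 2, 2, 3),
    ])
    def test_matches_naive_reference(self, k, c_in, c_out, stride, rng):
        x = rng.normal(size=(2, c_in, 11))
        W = rng.normal(size=(k, c_in, c_out))
        b = rng.normal(size=c_out)
        got = nc.conv_forward(x, W, b, stride)
        want = naive_conv_same(x, W, b, stride)
        assert got.shape == want.shape
        assert np.max(np.abs(got - want)) < 1e-12

    def test_same_padding_stride1_preserves_length(self, rng):
        for k in (1, 2, 3, 5):
            x = rng.normal(size=(1, 2, 23))
            y = nc.conv_forward(x, rng.normal(size=(k, 2, 4)), np.zeros(4), 1)
            assert y.shape == (1, 4, 23)

    def test_zero_weights_give_constant_bias_map(self, rng):
        x = rng.normal(size=(2, 3, 9))
        y = nc.conv_forward(x, np.zeros((3, 3, 2)), np.array([1.5, -2.0]), 1)
        assert np.allclose(y[:, 0], 1.5) and np.allclose(y[:, 1], -2.0)

    def test_even_kernel_padding_rule(self):
        # k=2 pads its single extra zero on the left, so with kernel [1,1]
        # the input [1,2,3] maps to [1,3,5]
        x = np.array([[[1.0, 2.0, 3.0]]])
        W = np.ones((2, 1, 1))
        y = nc.conv_forward(x, W, np.zeros(1), 1)
        assert np.allclose(y[0, 0], [1.0, 3.0, 5.0])

    def test_shape_mismatch_error(self, rng):
        with pytest.raises(ValueError, match="channels"):
            nc.conv_forward(rng.normal(size=(1, 2, 5)), rng.normal(size=(3, 3, 1)),
                            np.zeros(1), 1)


class TestDepthwisePointwise:
    def test_depthwise_matches_naive(self, rng):
        x = rng.normal(size=(2, 4, 9))
        W = rng.normal(size=(3, 4))
        b = rng.normal(size=4)
        assert np.max(np.abs(
            nc.depthwise_forward(x, W, b, 1) - naive_depthwise_same(x, W, b, 1)
        )) < 1e-12

    def test_depthwise_channel_separability(self, rng):
        x = rng.normal(size=(1, 3, 12))
        W, b = rng.normal(size=(3, 3)), rng.normal(size=3)
        y0 = nc.depthwise_forward(x, W, b, 1)
        x2 = x.copy()
        x2[:, 1, :] += rng.normal(size=12)
        y1 = nc.depthwise_forward(x2, W, b, 1)
        assert np.allclose(y0[:, 0], y1[:, 0]) and np.allclose(y0[:, 2], y1[:, 2])
        assert not np.allclose(y0[:, 1], y1[:, 1])

    def test_depthwise_k1_identity(self, rng):
        x = rng.normal(size=(2, 3, 7))
        y = nc.depthwise_forward(x, np.ones((1, 3)), np.zeros(3), 1)
        assert np.allclose(y, x)

    def test_depthwise_equals_blockdiagonal_standard_conv(self, rng):
        """Oracle: depthwise == standard conv with channel-masked weights."""
        k, C = 3, 4
        x = rng.normal(size=(2, C, 10))
        W = rng.normal(size=(k, C))
        b = rng.normal(size=C)
        W_block = np.zeros((k, C, C))
        for c in range(C):
            W_block[:, c, c] = W[:, c]
        got = nc.depthwise_forward(x, W, b, 1)
        want = nc.conv_forward(x, W_block, b, 1)
        assert np.max(np.abs(got - want)) < 1e-12

    def test_pointwise_equals_k1_conv_and_per_sample_dense(self, rng):
        C_in, C_out, L = 3, 5, 8
        x = rng.normal(size=(2, C_in, L))
        W = rng.normal(size=(1, C_in, C_out))
        b = rng.normal(size=C_out)
        y = nc.conv_forward(x, W, b, 1)
        # dense map applied independently at each time index
        for t in range(L):
            want = x[:, :, t] @ W[0] + b
            assert np.max(np.abs(y[:, :, t] - want)) < 1e-12

    def test_pointwise_identity_channel_matrix(self, rng):
        x = rng.normal(size=(1, 3, 6))
        W = np.eye(3)[None, :, :]
        assert np.allclose(nc.conv_forward(x, W, np.zeros(3), 1), x)

    def test_separable_mac_saving(self):
        # k=3, 10->10 channels: 130 vs 300 MACs per position, at least 2x less
        sep = nc.separable_conv_macs(3, 10, 10)
        std = nc.standard_conv_macs(3, 10, 10)
        assert sep == 130 and std == 300
        assert sep / std <= 0.5


class TestPooling:
    def test_worked_example(self):
        x = np.array([[[3.0, 1.0, 4.0, 1.0, 5.0, 9.0]]])
        y, _ = nc.maxpool_forward(x, 2)
        assert np.array_equal(y[0, 0], [3, 4, 9])

    @pytest.mark.parametrize("L,expected", [(360, 180), (720, 360), (7, 3)])
    def test_floor_rule(self, L, expected, rng):
        y, _ = nc.maxpool_forward(rng.normal(size=(1, 2, L)), 2)
        assert y.shape == (1, 2, expected)

    def test_constant_channel_preserved(self):
        x = np.full((1, 1, 10), 2.5)
        y, _ = nc.maxpool_forward(x, 2)
        assert np.allclose(y, 2.5)

    def test_backward_routes_to_argmax(self):
        x = np.array([[[1.0, 5.0, 2.0, 3.0]]])
        y, idx = nc.maxpool_forward(x, 2)
        gx = nc.maxpool_backward(x.shape, 2, idx, np.ones_like(y))
        assert np.array_equal(gx[0, 0], [0, 1, 0, 1])


class TestActivationsDropout:
    def test_leaky_relu_values(self):
        assert nc.leaky_relu(np.array(5.0)) == 5.0
        assert nc.leaky_relu(np.array(-10.0), 0.01) == pytest.approx(-0.1)

    def test_leaky_relu_gradient_finite_differences(self, rng):
        x = rng.normal(size=50) * 2
        x = x[np.abs(x) > 1e-3]  # keep away from the kink
        alpha, eps = 0.01, 1e-6
        num = (nc.leaky_relu(x + eps, alpha) - nc.leaky_relu(x - eps, alpha)) / (2 * eps)
        ana = nc.leaky_relu_backward(x, alpha, np.ones_like(x))
        assert np.allclose(num, ana, atol=1e-6)
        assert np.allclose(ana[x > 0], 1.0) and np.allclose(ana[x < 0], alpha)

    def test_dropout_rate0_and_eval_identity(self, rng):
        x = rng.normal(size=(4, 10))
        y, mask = nc.dropout_forward(x, 0.0, rng, train=True)
        assert y is x and mask is None
        y, mask = nc.dropout_forward(x, 0.5, rng, train=False)
        assert y is x and mask is None

    def test_dropout_inverted_scaling(self, rng):
        x = np.ones((200, 50))
        y, mask = nc.dropout_forward(x, 0.3, rng, train=True)
        kept = y[y != 0]
        assert np.allclose(kept, 1.0 / 0.7)
        # unbiased in expectation
        assert abs(y.mean() - 1.0) < 0.05


class TestSoftmaxCrossEntropy:
    def test_uniform_on_equal_logits(self):
        assert np.allclose(nc.softmax(np.zeros(5)), 0.2)

    def test_closed_form(self):
        p = nc.softmax(np.array([0, 0, 0, 0, np.log(4)]))
        assert np.allclose(p, [0.125, 0.125, 0.125, 0.125, 0.5])

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100), shift=st.floats(-50, 50))
    def test_normalization_and_shift_invariance(self, seed, shift):
        z = np.random.default_rng(seed).normal(size=(3, 5)) * 10
        p = nc.softmax(z)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(p, nc.softmax(z + shift), atol=1e-12)
        assert np.array_equal(p.argmax(axis=1), z.argmax(axis=1))

    def test_overflow_safe(self):
        p = nc.softmax(np.array([1000.0, 0.0, 0.0, 0.0, 0.0]))
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)

    def test_cross_entropy_values(self):
        one_hot = np.array([1.0, 0, 0])
        assert nc.cross_entropy(one_hot, one_hot) == pytest.approx(0.0, abs=1e-9)
        assert nc.cross_entropy(one_hot, np.array([0.5, 0.25, 0.25])) == pytest.approx(
            np.log(2), rel=1e-12
        )
        # uniform prediction over 5 classes: H = ln 5 regardless of the labels
        p = np.eye(5)
        q = np.full((5, 5), 0.2)
        assert nc.cross_entropy(p, q) == pytest.approx(np.log(5), rel=1e-12)

    def test_cross_entropy_ordering(self):
        # predictions closer to the one-hot target give strictly lower loss
        p = np.array([1.0, 0, 0])
        q_far = np.array([0.4, 0.3, 0.3])
        q_close = np.array([0.7, 0.15, 0.15])
        assert nc.cross_entropy(p, q_close) < nc.cross_entropy(p, q_far)

    def test_cross_entropy_validates_expected_distribution(self):
        with pytest.raises(ValueError, match="sum to 1"):
            nc.cross_entropy(np.array([0.5, 0.2, 0.2]), np.full(3, 1 / 3))
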