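"""Layer operations against independent nested-loop oracles and hand values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prostseg.pssnet import (
    avg_pool,
    batch_norm,
    conv_forward,
    cross_entropy_loss,
    deconv_upsample,
    pixel_softmax,
    predict_labels,
    relu,
    relu_grad,
)

RNG = np.random.default_rng(20240917)


# --------------------------------------------------------------------------
# brute-force oracles, written independently of the implementation
# --------------------------------------------------------------------------

def conv_oracle(x, w, b, stride=1):
    """Nested-loop cross-correlation, valid padding."""
    n_s, c_in, h, wd = x.shape
    p_out, _, kh, kw = w.shape
    oh = (h - kh) // stride + 1
    ow = (wd - kw) // stride + 1
    out = np.zeros((n_s, p_out, oh, ow))
    for n in range(n_s):
        for p in range(p_out):
            for i in range(oh):
                for j in range(ow):
                    acc = 0.0
                    for c in range(c_in):
                        for u in range(kh):
                            for v in range(kw):
                                acc += w[p, c, u, v] * x[n, c, i * stride + u, j * stride + v]
                    out[n, p, i, j] = acc + b[p]
    return out


def pool_oracle(x, k):
    n_s, c_in, h, w = x.shape
    out = np.zeros((n_s, c_in, h // k, w // k))
    for n in range(n_s):
        for c in range(c_in):
            for i in range(h // k):
                for j in range(w // k):
                    out[n, c, i, j] = x[n, c, i * k : (i + 1) * k, j * k : (j + 1) * k].mean()
    return out


def softmax_oracle(scores):
    out = np.zeros_like(scores)
    n_s, u, h, w = scores.shape
    for n in range(n_s):
        for i in range(h):
            for j in range(w):
                e = np.exp(scores[n, :, i, j] - scores[n, :, i, j].max())
                out[n, :, i, j] = e / e.sum()
    return out


def ce_oracle(probs, targets):
    n_s, u, h, w = probs.shape
    total = 0.0
    for n in range(n_s):
        for i in range(h):
            for j in range(w):
                for c in range(u):
                    if targets[n, c, i, j]:
                        total -= targets[n, c, i, j] * np.log(probs[n, c, i, j])
    return total / (n_s * h * w)


# --------------------------------------------------------------------------
# convolution
# --------------------------------------------------------------------------

class TestConv:
    def test_identity_kernel(self):
        x = RNG.normal(size=(1, 1, 5, 5))
        out = conv_forward(x, np.ones((1, 1, 1, 1)), 0.0, padding="valid")
        assert np.allclose(out, x)

    def test_hand_example_2x2_ones(self):
        out = conv_forward(
            np.array([[[[1.0, 2.0], [3.0, 4.0]]]]), np.ones((1, 1, 2, 2)),
            0.0, padding="valid",
        )
        assert out.shape == (1, 1, 1, 1)
        assert out[0, 0, 0, 0] == pytest.approx(10.0)

    def test_zero_kernels_give_bias(self):
        x = RNG.normal(size=(2, 3, 4, 4))
        out = conv_forward(x, np.zeros((2, 3, 3, 3)), np.array([7.0, 7.0]))
        assert np.allclose(out, 7.0)

    @pytest.mark.parametrize("shape,kshape", [
        ((1, 1, 5, 5), (1, 1, 3, 3)),
        ((2, 3, 8, 8), (4, 3, 3, 3)),
        ((3, 2, 6, 7), (2, 2, 2, 4)),
    ])
    def test_matches_nested_loop_oracle(self, shape, kshape):
        x = RNG.normal(size=shape)
        w = RNG.normal(size=kshape)
        b = RNG.normal(size=kshape[0])
        out = conv_forward(x, w, b, padding="valid")
        assert np.allclose(out, conv_oracle(x, w, b), atol=1e-6)

    def test_same_padding_preserves_dims(self):
        x = RNG.normal(size=(1, 2, 7, 7))
        out = conv_forward(x, RNG.normal(size=(3, 2, 3, 3)), 0.0, padding="same")
        assert out.shape == (1, 3, 7, 7)

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="channels"):
            conv_forward(RNG.normal(size=(1, 2, 4, 4)), np.ones((1, 3, 3, 3)))


# --------------------------------------------------------------------------
# activation
# --------------------------------------------------------------------------

class TestReLU:
    def test_branches(self):
        assert relu(np.array(-3.0)) == 0.0
        assert relu(np.array(5.0)) == 5.0

    def test_gradient_values(self):
        assert np.array_equal(relu_grad(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 1.0])

    def test_gradient_matches_finite_differences(self):
        xs = np.array([-2.0, -0.5, 0.5, 3.0])
        eps = 1e-6
        fd = (relu(xs + eps) - relu(xs - eps)) / (2 * eps)
        assert np.allclose(relu_grad(xs), fd, atol=1e-5)


# --------------------------------------------------------------------------
# batch normalization
# --------------------------------------------------------------------------

class TestBatchNorm:
    def test_hand_example_three_values(self):
        x = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        out = batch_norm(x, epsilon=1e-12)
        expected = np.array([-1.2247449, 0.0, 1.2247449]).reshape(3, 1, 1, 1)
        assert np.allclose(out, expected, atol=1e-5)

    def test_constant_batch_maps_to_zero(self):
        x = np.full((4, 2, 3, 3), 3.7)
        assert np.allclose(batch_norm(x, epsilon=1e-3), 0.0)

    def test_identity_recovery(self):
        x = RNG.normal(2.0, 3.0, size=(6, 4, 5, 5))
        eps = 1e-5
        var = x.var(axis=(0, 2, 3))
        mean = x.mean(axis=(0, 2, 3))
        out = batch_norm(x, scale=np.sqrt(var + eps), shift=mean, epsilon=eps)
        assert np.allclose(out, x, atol=1e-6)

    def test_standardizes_per_channel(self):
        x = RNG.normal(5.0, 2.0, size=(8, 3, 6, 6))
        out = batch_norm(x, epsilon=1e-10)
        assert np.allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-5)
        assert np.allclose(out.var(axis=(0, 2, 3)), 1.0, atol=1e-4)

    def test_single_sample_training_batch_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            batch_norm(RNG.normal(size=(1, 2, 3, 3)), training=True)

    def test_inference_uses_running_statistics(self):
        x = RNG.normal(size=(1, 2, 3, 3))
        out = batch_norm(
            x, training=False, running_mean=np.zeros(2), running_var=np.ones(2),
            epsilon=1e-12,
        )
        assert np.allclose(out, x, atol=1e-5)


# --------------------------------------------------------------------------
# pooling
# --------------------------------------------------------------------------

class TestAvgPool:
    def test_hand_example(self):
        out = avg_pool(np.array([[[[1.0, 2.0], [3.0, 4.0]]]]), 2)
        assert out.shape == (1, 1, 1, 1)
        assert out[0, 0, 0, 0] == pytest.approx(2.5)

    def test_window_one_is_identity(self):
        x = RNG.normal(size=(2, 3, 4, 4))
        assert np.array_equal(avg_pool(x, 1), x)

    def test_constant_image_stays_constant(self):
        out = avg_pool(np.full((1, 1, 6, 6), 4.2), 3)
        assert out.shape == (1, 1, 2, 2)
        assert np.allclose(out, 4.2)

    def test_matches_window_mean_oracle(self):
        x = RNG.normal(size=(2, 3, 8, 12))
        assert np.allclose(avg_pool(x, 2), pool_oracle(x, 2), atol=1e-6)
        assert np.allclose(avg_pool(x, 4), pool_oracle(x, 4), atol=1e-6)

    def test_non_divisible_dims_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            avg_pool(RNG.normal(size=(1, 1, 5, 6)), 2)


# --------------------------------------------------------------------------
# softmax / prediction / loss
# --------------------------------------------------------------------------

class TestSoftmax:
    def test_uniform_scores(self):
        probs = pixel_softmax(np.zeros((3, 2, 2)))
        assert np.allclose(probs, 1.0 / 3.0)

    def test_hand_example(self):
        probs = pixel_softmax(np.array([1.0, 0.0, 0.0]).reshape(3, 1, 1))
        assert np.allclose(probs[:, 0, 0], [0.57612, 0.21194, 0.21194], atol=5e-6)

    def test_overflow_safe(self):
        probs = pixel_softmax(np.array([1000.0, 0.0, -1000.0]).reshape(3, 1, 1))
        assert np.isfinite(probs).all()
        assert probs[0, 0, 0] == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_normalizes_per_pixel(self, scores):
        probs = pixel_softmax(np.array(scores).reshape(3, 1, 1))
        assert probs.min() >= 0
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_per_pixel_oracle(self):
        scores = RNG.normal(size=(2, 3, 4, 4))
        assert np.allclose(pixel_softmax(scores), softmax_oracle(scores), atol=1e-6)


class TestPredictLabels:
    def test_simple_argmax(self):
        assert predict_labels(np.array([0.1, 0.7, 0.2]).reshape(3, 1, 1))[0, 0] == 1

    def test_tie_breaks_to_lowest_index(self):
        assert predict_labels(np.array([0.5, 0.5, 0.0]).reshape(3, 1, 1))[0, 0] == 0

    def test_matches_exhaustive_scan(self):
        probs = pixel_softmax(RNG.normal(size=(2, 3, 5, 5)))
        labels = predict_labels(probs)
        for n in range(2):
            for i in range(5):
                for j in range(5):
                    best = max(range(3), key=lambda c: (probs[n, c, i, j], -c))
                    assert labels[n, i, j] == best


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        targets = np.zeros((3, 2, 2))
        targets[1] = 1.0
        assert cross_entropy_loss(targets.copy(), targets) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_probs_give_log3(self):
        probs = np.full((3, 4, 4), 1.0 / 3.0)
        targets = np.zeros((3, 4, 4))
        targets[0] = 1.0
        assert cross_entropy_loss(probs, targets) == pytest.approx(np.log(3.0), abs=1e-9)

    def test_loss_increases_as_true_prob_drops(self):
        targets = np.zeros((3, 1, 1))
        targets[0] = 1.0
        losses = [
            cross_entropy_loss(np.array([p, (1 - p) / 2, (1 - p) / 2]).reshape(3, 1, 1), targets)
            for p in (0.9, 0.6, 0.3)
        ]
        assert losses[0] < losses[1] < losses[2]

    def test_matches_loop_oracle(self):
        probs = pixel_softmax(RNG.normal(size=(2, 3, 4, 4)))
        masks = RNG.integers(0, 3, size=(2, 4, 4))
        targets = np.zeros_like(probs)
        for n in range(2):
            for i in range(4):
                for j in range(4):
                    targets[n, masks[n, i, j], i, j] = 1.0
        assert cross_entropy_loss(probs, targets) == pytest.approx(
            ce_oracle(probs, targets), abs=1e-8
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy_loss(np.zeros((3, 2, 2)), np.zeros((3, 3, 3)))


# --------------------------------------------------------------------------
# transposed convolution
# --------------------------------------------------------------------------

class TestDeconv:
    def test_single_pixel_broadcast(self):
        out = deconv_upsample(
            np.array([[[[3.0]]]]), np.ones((1, 1, 2, 2)), 0.0, stride=2
        )
        assert out.shape == (1, 1, 2, 2)
        assert np.allclose(out, 3.0)

    def test_zero_input_zero_output(self):
        out = deconv_upsample(np.zeros((1, 2, 3, 3)), RNG.normal(size=(2, 4, 2, 2)))
        assert np.allclose(out, 0.0)

    def test_upsamples_by_stride(self):
        out = deconv_upsample(
            RNG.normal(size=(2, 3, 4, 4)), RNG.normal(size=(3, 5, 2, 2)), stride=2
        )
        assert out.shape == (2, 5, 8, 8)

    def test_adjoint_of_strided_convolution(self):
        # <conv(y; K, stride), x> == <y, deconv(x; K, stride)>
        k = RNG.normal(size=(2, 5, 2, 2))  # (in, out) for deconv; (out, in) for conv
        x = RNG.normal(size=(1, 2, 3, 3))
        y = RNG.normal(size=(1, 5, 6, 6))
        conv_y = conv_forward(y, k, 0.0, stride=2, padding="valid")
        deconv_x = deconv_upsample(x, k, 0.0, stride=2)
        assert (conv_y * x).sum() == pytest.approx((y * deconv_x).sum(), abs=1e-6)

    def test_scatter_matches_explicit_loop(self):
        x = RNG.normal(size=(1, 2, 3, 3))
        k = RNG.normal(size=(2, 3, 2, 2))
        out = deconv_upsample(x, k, 0.0, stride=2)
        ref = np.zeros((1, 3, 6, 6))
        for b in range(2):
            for p in range(3):
                for i in range(3):
                    for j in range(3):
                        for u in range(2):
                            for v in range(2):
                                ref[0, p, 2 * i + u, 2 * j + v] += x[0, b, i, j] * k[b, p, u, v]
        assert np.allclose(out, ref, atol=1e-6)
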