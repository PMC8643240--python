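"""Encoder-decoder segmentation network built from first principles in NumPy.

The network segments a single-channel T2WI-like slice into three tissue
classes (surrounding tissue, central gland, marginal gland).  Every layer is
implemented directly from its defining equation:

* convolution — cross-correlation of the input stack with a 4D kernel bank
  plus a per-output-channel bias;
* ReLU activation ``f(x) = max(0, x)`` with derivative 1 for ``x > 0``;
* batch normalization — per-channel standardization by batch mean and
  variance (stabilized by an epsilon under the square root) followed by a
  learnable affine scale/shift, with running statistics for inference;
* average pooling — the window mean, i.e. ``1/k_p^2`` times correlation with
  an all-ones ``k_p x k_p`` matrix;
* transposed convolution (deconvolution) for learnable upsampling in the
  decoder;
* a per-pixel softmax producing a 3-vector of class probabilities, trained
  with the mean per-pixel cross-entropy ``L = -(1/cd) sum_n sum_j y_nj ln p_nj``.

Backpropagation is hand-derived per layer; optimization uses Adam.  The
implementation is CPU-oriented and sized to train on phantom data in well
under a minute; it is deliberately dependency-free beyond NumPy so that each
layer can be checked against brute-force oracles.

Tensors follow the (sample, channel, row, col) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NetworkConfig",
    "PSSNet",
    "conv_forward",
    "relu",
    "relu_grad",
    "batch_norm",
    "avg_pool",
    "pixel_softmax",
    "predict_labels",
    "cross_entropy_loss",
    "deconv_upsample",
    "build_pssnet",
    "train_pssnet",
    "segment",
    "save_model",
    "load_model",
]

_LOG_CLIP = 1e-12  # probability floor before taking logarithms


# ---------------------------------------------------------------------------
# functional layer operations
# ---------------------------------------------------------------------------

def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Promote (C,H,W) to (1,C,H,W); report whether promotion happened."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        return x[None], True
    if x.ndim != 4:
        raise ValueError(f"expected a 3D or 4D tensor, got shape {x.shape}")
    return x, False


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int = 1) -> np.ndarray:
    """View x (N,C,H,W) as sliding windows (N,C,oh,ow,kh,kw)."""
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    shape = (n, c, oh, ow, kh, kw)
    strides = (s0, s1, s2 * stride, s3 * stride, s2, s3)
    return np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)


def _col2im(
    dwin: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int, stride: int = 1
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add window gradients back."""
    n, c, h, w = x_shape
    oh, ow = dwin.shape[2], dwin.shape[3]
    dx = np.zeros(x_shape, dtype=np.float64)
    for u in range(kh):
        for v in range(kw):
            dx[:, :, u : u + stride * oh : stride, v : v + stride * ow : stride] += (
                dwin[:, :, :, :, u, v]
            )
    return dx


def conv_forward(
    x: np.ndarray,
    kernels: np.ndarray,
    bias: np.ndarray | float = 0.0,
    stride: int = 1,
    padding: str | int = "same",
) -> np.ndarray:
    """Multi-channel 2D convolution (cross-correlation convention).

    Each output channel ``p`` is the sum over input channels ``b`` of the
    cross-correlation of input map ``b`` with kernel slab ``(p, b)``, plus a
    per-output-channel bias.  ``kernels`` has shape
    ``(out_channels, in_channels, kh, kw)``.  ``padding`` is ``'same'``
    (stride 1, odd kernels: spatial dims preserved), ``'valid'``, or an
    explicit integer pad width.
    """
    x, squeeze = _as_batch(x)
    kernels = np.asarray(kernels, dtype=np.float64)
    if kernels.ndim != 4:
        raise ValueError("kernels must be 4D (out, in, kh, kw)")
    p_out, b_in, kh, kw = kernels.shape
    if x.shape[1] != b_in:
        raise ValueError(
            f"input has {x.shape[1]} channels but kernels expect {b_in}"
        )
    if padding == "same":
        if stride != 1:
            raise ValueError("'same' padding requires stride 1")
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
    elif padding == "valid":
        ph = pw = 0
    else:
        ph = pw = int(padding)
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = _im2col(x, kh, kw, stride)
    out = np.einsum("ncohuv,pcuv->npoh", win, kernels, optimize=True)
    bias = np.asarray(bias, dtype=np.float64)
    out = out + np.broadcast_to(bias, (p_out,))[None, :, None, None]
    return out[0] if squeeze else out


def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear activation, ``max(0, x)`` elementwise."""
    return np.maximum(0.0, np.asarray(x, dtype=np.float64))


def relu_grad(x: np.ndarray) -> np.ndarray:
    """Derivative of :func:`relu`: 1 where ``x > 0``, else 0."""
    return (np.asarray(x, dtype=np.float64) > 0).astype(np.float64)


def avg_pool(x: np.ndarray, window: int) -> np.ndarray:
    """Non-overlapping average pooling with a ``window x window`` kernel.

    Each output pixel is the arithmetic mean of its window (correlation with
    an all-ones matrix scaled by ``1/window**2``).  Spatial dims must be
    divisible by ``window``.
    """
    if window < 1:
        raise ValueError("pooling window must be >= 1")
    x, squeeze = _as_batch(x)
    n, c, h, w = x.shape
    if h % window or w % window:
        raise ValueError(
            f"spatial dims ({h}, {w}) not divisible by pooling window {window}"
        )
    out = x.reshape(n, c, h // window, window, w // window, window).mean(axis=(3, 5))
    return out[0] if squeeze else out


def pixel_softmax(scores: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the class axis.

    ``scores`` is (U,H,W) or (N,U,H,W); each pixel's class scores are mapped
    to probabilities ``exp(v_j) / sum_k exp(v_k)`` with max-shift
    stabilization, so the result sums to 1 per pixel for any finite input.
    """
    scores, squeeze = _as_batch(scores)
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs[0] if squeeze else probs


def predict_labels(probs: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class label; ties break to the lowest class index."""
    probs, squeeze = _as_batch(probs)
    labels = probs.argmax(axis=1).astype(np.uint8)
    return labels[0] if squeeze else labels


def cross_entropy_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean per-pixel cross-entropy between probabilities and one-hot targets.

    Both arguments share the (U,H,W) or (N,U,H,W) layout; the loss is the
    negative log-probability at the true class, averaged over all pixels (and
    samples).  Probabilities are floored away from zero before the log.
    """
    probs, _ = _as_batch(probs)
    targets, _ = _as_batch(targets)
    if probs.shape != targets.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs targets {targets.shape}")
    logp = np.log(np.clip(probs, _LOG_CLIP, None))
    n_pixels = probs.shape[0] * probs.shape[2] * probs.shape[3]
    return float(-(targets * logp).sum() / n_pixels)


def deconv_upsample(
    x: np.ndarray,
    kernels: np.ndarray,
    bias: np.ndarray | float = 0.0,
    stride: int = 2,
) -> np.ndarray:
    """Transposed convolution: learnable upsampling by ``stride``.

    ``kernels`` has shape ``(in_channels, out_channels, kh, kw)`` with
    ``kh == kw == stride`` (non-overlapping windows), so output spatial dims
    are exactly ``stride`` times the input's.  This is the adjoint of a
    stride-``stride``, valid-padding convolution with the same kernels:
    ``<conv(x), y> == <x, deconv(y)>``.
    """
    x, squeeze = _as_batch(x)
    kernels = np.asarray(kernels, dtype=np.float64)
    b_in, p_out, kh, kw = kernels.shape
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if kh != stride or kw != stride:
        raise ValueError("deconv kernels must be stride x stride (non-overlapping)")
    if x.shape[1] != b_in:
        raise ValueError(f"input has {x.shape[1]} channels but kernels expect {b_in}")
    n, _, h, w = x.shape
    # out[n,p,i*s+u, j*s+v] = sum_b x[n,b,i,j] * K[b,p,u,v]; windows disjoint
    out = np.einsum("nbij,bpuv->npiujv", x, kernels, optimize=True)
    out = out.reshape(n, p_out, h * stride, w * stride)
    bias = np.asarray(bias, dtype=np.float64)
    out = out + np.broadcast_to(bias, (p_out,))[None, :, None, None]
    return out[0] if squeeze else out


def batch_norm(
    x: np.ndarray,
    scale: np.ndarray | float = 1.0,
    shift: np.ndarray | float = 0.0,
    epsilon: float = 1e-5,
    training: bool = True,
    running_mean: np.ndarray | None = None,
    running_var: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel batch normalization with learnable affine parameters.

    Training mode standardizes each channel by its batch mean and population
    variance (stabilized by ``epsilon`` under the square root), then applies
    the affine transform ``scale * x_hat + shift``.  Inference mode uses the
    provided running statistics instead.  A single-sample training batch is
    rejected: its variance carries no information.
    """
    x, squeeze = _as_batch(x)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if training:
        if x.shape[0] < 2:
            raise ValueError("batch normalization needs >= 2 samples in training mode")
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
    else:
        if running_mean is None or running_var is None:
            raise ValueError("inference mode requires running statistics")
        mean = np.asarray(running_mean, dtype=np.float64)
        var = np.asarray(running_var, dtype=np.float64)
    x_hat = (x - mean[None, :, None, None]) / np.sqrt(var + epsilon)[None, :, None, None]
    c = x.shape[1]
    scale = np.broadcast_to(np.asarray(scale, dtype=np.float64), (c,))
    shift = np.broadcast_to(np.asarray(shift, dtype=np.float64), (c,))
    out = scale[None, :, None, None] * x_hat + shift[None, :, None, None]
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# trainable layer objects (forward caches + hand-derived backward)
# ---------------------------------------------------------------------------


class _Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv(_Layer):
    """Same-padding stride-1 convolution with He-initialized kernels."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        fan_in = c_in * k * k
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, training):
        ph = (self.k - 1) // 2
        self._x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (ph, ph))) if ph else x
        self._xp_shape = xp.shape
        self._win = _im2col(xp, self.k, self.k)
        return (
            np.einsum("ncohuv,pcuv->npoh", self._win, self.params["W"], optimize=True)
            + self.params["b"][None, :, None, None]
        )

    def backward(self, dout):
        self.grads["W"] = np.einsum(
            "npoh,ncohuv->pcuv", dout, self._win, optimize=True
        )
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dwin = np.einsum("npoh,pcuv->ncohuv", dout, self.params["W"], optimize=True)
        dxp = _col2im(dwin, self._xp_shape, self.k, self.k)
        ph = (self.k - 1) // 2
        if ph:
            return dxp[:, :, ph:-ph, ph:-ph]
        return dxp


class _Deconv(_Layer):
    """Stride-s transposed convolution with s x s kernels (exact upsampling)."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.s = stride
        fan_in = c_in
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, stride, stride)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, training):
        self._x = x
        return deconv_upsample(x, self.params["W"], self.params["b"], stride=self.s)

    def backward(self, dout):
        n, p, hs, ws = dout.shape
        s = self.s
        dwin = dout.reshape(n, p, hs // s, s, ws // s, s)
        self.grads["W"] = np.einsum(
            "nbij,npiujv->bpuv", self._x, dwin, optimize=True
        )
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        return np.einsum("npiujv,bpuv->nbij", dwin, self.params["W"], optimize=True)


class _BatchNorm(_Layer):
    """Batch normalization with running statistics for inference."""

    def __init__(self, channels: int, epsilon: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = epsilon
        self.momentum = momentum
        self.params = {"scale": np.ones(channels), "shift": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training):
        if training:
            # statistics pool over batch AND spatial positions, so even a
            # single image provides H*W samples per channel
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._x_hat = (x - mean[None, :, None, None]) * self._inv_std[None, :, None, None]
        return (
            self.params["scale"][None, :, None, None] * self._x_hat
            + self.params["shift"][None, :, None, None]
        )

    def backward(self, dout):
        n, c, h, w = dout.shape
        m = n * h * w
        self.grads["scale"] = (dout * self._x_hat).sum(axis=(0, 2, 3))
        self.grads["shift"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["scale"][None, :, None, None]
        # standard BN input gradient (batch statistics depend on x)
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * self._x_hat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (
            self._inv_std[None, :, None, None]
            / m
            * (m * dxhat - sum_dxhat - self._x_hat * sum_dxhat_xhat)
        )


class _ReLU(_Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class _AvgPool(_Layer):
    def __init__(self, window: int):
        super().__init__()
        self.k = window

    def forward(self, x, training):
        self._x_shape = x.shape
        return avg_pool(x, self.k)

    def backward(self, dout):
        k = self.k
        return np.repeat(np.repeat(dout, k, axis=2), k, axis=3) / (k * k)


# ---------------------------------------------------------------------------
# network assembly, training, inference
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    The encoder is one conv-BN-ReLU block per entry of ``encoder_channels``,
    with ``pool_window`` average pooling after every block except the last;
    the decoder mirrors the pooling with as many stride-``pool_window``
    deconv-BN-ReLU stages, followed by a 1x1 convolution to ``n_classes``
    scores and a per-pixel softmax.  ``input_size`` must be divisible by
    ``pool_window`` raised to the number of pooling stages so the decoder
    restores the input grid exactly.
    """

    encoder_channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    pool_window: int = 2
    n_classes: int = 3
    input_size: int = 64
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    seed: int = 0
    optimizer: str = "adam"
    bn_epsilon: float = 1e-5
    class_weights: tuple[float, ...] | None = None
    intensity_scale: float = 255.0  # divisor mapping 8-bit-like input to ~[0,1]

    def validate(self) -> None:
        if not self.encoder_channels:
            raise ValueError("encoder_channels must be non-empty")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd ('same' padding)")
        n_pools = len(self.encoder_channels) - 1
        if self.input_size % (self.pool_window**n_pools):
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"pool_window^{n_pools}; decoder cannot restore input dims"
            )
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.class_weights is not None and len(self.class_weights) != self.n_classes:
            raise ValueError("class_weights length must equal n_classes")


class PSSNet:
    """The assembled encoder-decoder model (see :class:`NetworkConfig`)."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        layers: list[_Layer] = []
        c_prev = 1
        chans = config.encoder_channels
        for i, c in enumerate(chans):
            layers += [_Conv(c_prev, c, k, rng), _BatchNorm(c, config.bn_epsilon), _ReLU()]
            if i < len(chans) - 1:
                layers.append(_AvgPool(config.pool_window))
            c_prev = c
        for c in reversed(chans[:-1]):
            layers += [
                _Deconv(c_prev, c, config.pool_window, rng),
                _BatchNorm(c, config.bn_epsilon),
                _ReLU(),
            ]
            c_prev = c
        layers.append(_Conv(c_prev, config.n_classes, 1, rng))
        self.layers = layers

    # -- inference ---------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class scores (N, U, H, W) for an input batch (N, 1, H, W)."""
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def predict_proba(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return pixel_softmax(self.forward(x, training))

    def backward(self, dscores: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dscores = layer.backward(dscores)

    def parameters(self) -> Iterable[tuple[_Layer, str]]:
        for layer in self.layers:
            for name in layer.params:
                yield layer, name


class _Adam:
    def __init__(self, model: PSSNet, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots = list(model.parameters())
        self.m = [np.zeros_like(l.params[n]) for l, n in self.slots]
        self.v = [np.zeros_like(l.params[n]) for l, n in self.slots]

    def step(self, model: PSSNet) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, model: PSSNet, lr: float):
        self.lr = lr

    def step(self, model: PSSNet) -> None:
        for layer, name in model.parameters():
            layer.params[name] -= self.lr * layer.grads[name]


def build_pssnet(config: NetworkConfig | None = None) -> PSSNet:
    """Construct a seeded, untrained model from a configuration."""
    return PSSNet(config if config is not None else NetworkConfig())


def _one_hot(masks: np.ndarray, n_classes: int) -> np.ndarray:
    """(N,H,W) integer masks -> (N,U,H,W) one-hot float targets."""
    n, h, w = masks.shape
    out = np.zeros((n, n_classes, h, w), dtype=np.float64)
    idx = np.arange(n)[:, None, None]
    rows = np.arange(h)[None, :, None]
    cols = np.arange(w)[None, None, :]
    out[idx, masks, rows, cols] = 1.0
    return out


def _prepare_images(images: Sequence[np.ndarray], scale: float) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    return (arr / scale)[:, None, :, :]


def train_pssnet(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: NetworkConfig | None = None,
    model: PSSNet | None = None,
) -> tuple[PSSNet, list[float]]:
    """Train the network on (image, mask) pairs by mini-batch gradient descent.

    Minimizes the mean per-pixel cross-entropy; returns the trained model and
    the per-epoch mean training loss.  Fully reproducible under
    ``config.seed`` (parameter init, shuffling and batching all derive from
    it).
    """
    if config is None:
        config = NetworkConfig()
    config.validate()
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    images = _prepare_images([d[0] for d in dataset], config.intensity_scale)
    masks = np.stack([np.asarray(d[1]) for d in dataset]).astype(np.int64)
    if images.shape[2] != images.shape[3] or images.shape[2] != config.input_size:
        raise ValueError(
            f"images are {images.shape[2]}x{images.shape[3]} but the "
            f"configuration expects {config.input_size}x{config.input_size}"
        )
    targets = _one_hot(masks, config.n_classes)

    if model is None:
        model = build_pssnet(config)
    opt = _Adam(model, config.learning_rate) if config.optimizer == "adam" else _SGD(
        model, config.learning_rate
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E5]))
    weights = (
        np.asarray(config.class_weights, dtype=np.float64)
        if config.class_weights is not None
        else None
    )

    n = len(dataset)
    bs = min(max(2, config.batch_size), n) if n >= 2 else 1
    log: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = images[idx], targets[idx]
            scores = model.forward(xb, training=True)
            probs = pixel_softmax(scores)
            if weights is None:
                losses.append(cross_entropy_loss(probs, yb))
                dscores = (probs - yb) / (xb.shape[0] * xb.shape[2] * xb.shape[3])
            else:
                wmap = (weights[None, :, None, None] * yb).sum(axis=1, keepdims=True)
                logp = np.log(np.clip(probs, _LOG_CLIP, None))
                denom = xb.shape[0] * xb.shape[2] * xb.shape[3]
                losses.append(float(-(wmap * yb * logp).sum() / denom))
                dscores = wmap * (probs - yb) / denom
            model.backward(dscores)
            opt.step(model)
        log.append(float(np.mean(losses)))
    return model, log


def segment(model: PSSNet, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Segment a single slice: returns (label mask, probability map).

    Inference uses the stored running batch-norm statistics, so repeated
    calls with the same model and image give identical masks.  The
    probability map has shape (U, H, W) and sums to 1 per pixel.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    if image.shape[0] != model.config.input_size or image.shape[1] != model.config.input_size:
        raise ValueError(
            f"image is {image.shape[0]}x{image.shape[1]} but the model "
            f"expects {model.config.input_size}x{model.config.input_size}"
        )
    x = image[None, None] / model.config.intensity_scale
    probs = model.predict_proba(x, training=False)[0]
    return predict_labels(probs), probs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: PSSNet, path) -> None:
    """Write a single-file checkpoint: config + parameters + BN statistics."""
    import json

    blobs: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers):
        for name, value in layer.params.items():
            blobs[f"layer{i}.{name}"] = value
        if isinstance(layer, _BatchNorm):
            blobs[f"layer{i}.running_mean"] = layer.running_mean
            blobs[f"layer{i}.running_var"] = layer.running_var
    cfg = asdict(model.config)
    cfg["encoder_channels"] = list(cfg["encoder_channels"])
    if cfg["class_weights"] is not None:
        cfg["class_weights"] = list(cfg["class_weights"])
    blobs["config_json"] = np.frombuffer(
        json.dumps(cfg).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **blobs)


def load_model(path) -> PSSNet:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import json

    with np.load(path) as data:
        cfg = json.loads(bytes(data["config_json"].tobytes()).decode("utf-8"))
        cfg["encoder_channels"] = tuple(cfg["encoder_channels"])
        if cfg.get("class_weights") is not None:
            cfg["class_weights"] = tuple(cfg["class_weights"])
        model = PSSNet(NetworkConfig(**cfg))
        for i, layer in enumerate(model.layers):
            for name in layer.params:
                layer.params[name] = data[f"layer{i}.{name}"].copy()
            if isinstance(layer, _BatchNorm):
                layer.running_mean = data[f"layer{i}.running_mean"].copy()
                layer.running_var = data[f"layer{i}.running_var"].copy()
    return model
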