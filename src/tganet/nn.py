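"""Minimal CPU neural-network toolkit used by the segmentation and classification models.

Layers operate on float32 NCHW arrays and implement explicit forward/backward
passes (no autodiff tape): each layer caches what its backward pass needs during
``forward`` and consumes the cache in ``backward``.  Convolution is lowered to a
matrix product via im2col; the input gradient is itself a convolution with the
channel-transposed, spatially flipped kernel, so no scatter-add is needed.
Bilinear resizing is expressed as a pair of 1-D interpolation matrices, making
its adjoint (the backward pass) exact.

The toolkit is deliberately small: stride-1 "same" 2-D convolution, 2x2 max
pooling, nearest 2x upsampling, bilinear resize, ReLU/sigmoid, a linear layer,
softmax cross-entropy and sigmoid binary cross-entropy losses, Kaiming-normal
initialization and Adam — exactly what an encoder-decoder segmenter and a
VGG-style attention classifier require.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He/Kaiming normal init: std = sqrt(2 / fan_in), suited to ReLU layers."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(F32)


# ---------------------------------------------------------------------------
# parameters and optimizer
# ---------------------------------------------------------------------------

class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Lower NCHW input to a (N*H*W, C*k*k) matrix for stride-1 same conv."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # n,c,h,w,k,k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _conv_raw(x: np.ndarray, weight: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 convolution of NCHW x with (Cout,Cin,k,k) weight, no bias."""
    n, _, h, w = x.shape
    cout, cin, k, _ = weight.shape
    cols = _im2col(x, k, pad)
    y = cols @ weight.reshape(cout, cin * k * k).T
    return y.reshape(n, h, w, cout).transpose(0, 3, 1, 2)


class Conv2d:
    """Stride-1 'same'-padded 2-D convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("only odd kernels supported (same padding)")
        fan_in = in_ch * kernel * kernel
        self.weight = Param(kaiming_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Param(np.zeros(out_ch, dtype=F32))
        self.kernel = kernel
        self.pad = kernel // 2
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cout, cin, k, _ = self.weight.value.shape
        cols = _im2col(x, k, self.pad)
        y = cols @ self.weight.value.reshape(cout, cin * k * k).T
        y += self.bias.value
        if cache:
            self._cache = (cols, x.shape)
        return y.reshape(n, h, w, cout).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        self._cache = None
        n, c, h, w = xshape
        cout, cin, k, _ = self.weight.value.shape
        gyf = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(n * h * w, cout)
        self.weight.grad += (gyf.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += gyf.sum(axis=0)
        # input gradient = conv of gy with channel-transposed, 180deg-flipped kernel
        wt = self.weight.value.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        return _conv_raw(gy, np.ascontiguousarray(wt), self.pad)


class Linear:
    """Fully connected layer on (N, D) inputs."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Param(kaiming_normal(rng, (out_dim, in_dim), in_dim))
        self.bias = Param(np.zeros(out_dim, dtype=F32))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        self._x = None
        return gy @ self.weight.value


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

class MaxPool2x2:
    """2x2 max pooling, stride 2. Input H, W must be even."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial size, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if cache:
            self._cache = (idx, x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        self._cache = None
        n, c, h, w = xshape
        g4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g4, idx[..., None], gy[..., None], axis=-1)
        g = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(g).reshape(n, c, h, w)


class Upsample2x:
    """Nearest-neighbour 2x upsampling; backward is 2x2 block summation."""

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel centres, edges clamped)."""
    m = np.zeros((n_out, n_in), dtype=F32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (src - i0).astype(F32)
    m[np.arange(n_out), i0] += 1.0 - w1
    m[np.arange(n_out), i1] += w1
    return m


_BILIN_CACHE: dict[tuple[int, int], np.ndarray] = {}


def bilinear_resize(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of NCHW (or HxW) input to ``out_hw``.

    Implemented as two separable 1-D interpolation matrix products, so that
    ``bilinear_resize_backward`` can apply the exact adjoint.
    """
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None, None]
    _, _, h, w = x.shape
    ho, wo = out_hw
    mr = _BILIN_CACHE.setdefault((ho, h), _bilinear_matrix(ho, h))
    mc = _BILIN_CACHE.setdefault((wo, w), _bilinear_matrix(wo, w))
    y = np.matmul(mr, np.matmul(x, mc.T))
    return y[0, 0] if squeeze else y


def bilinear_resize_backward(gy: np.ndarray, in_hw: tuple[int, int]) -> np.ndarray:
    """Adjoint of :func:`bilinear_resize` mapping output grads to input grads."""
    _, _, ho, wo = gy.shape
    h, w = in_hw
    mr = _BILIN_CACHE.setdefault((ho, h), _bilinear_matrix(ho, h))
    mc = _BILIN_CACHE.setdefault((wo, w), _bilinear_matrix(wo, w))
    return np.matmul(mr.T, np.matmul(gy, mc))


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        mask = x > 0
        if cache:
            self._mask = mask
        return np.where(mask, x, 0.0).astype(x.dtype, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._mask
        self._mask = None
        return g


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over a batch; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dl = p
    dl[np.arange(n), labels] -= 1.0
    return float(loss), (dl / n).astype(F32)


def sigmoid_bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean pixel-wise binary cross-entropy on raw logits; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - t) / z.size
    return float(loss.mean()), dz.astype(F32)
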