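"""Minimal NumPy layer framework with explicit forward/backward passes.

All layers operate on float32 arrays in (N, C, H, W) layout.  Each layer
caches what it needs during ``forward`` and releases gradients through
``backward``; parameters are :class:`Param` objects holding a value and an
accumulated gradient.  Initialisation is He-uniform for convolution and
dense weights, zeros for biases.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor: value ``v`` and gradient ``g``."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)

    @property
    def size(self) -> int:
        return self.v.size

    def zero_grad(self) -> None:
        self.g[...] = 0.0


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base class; subclasses implement forward/backward and list params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# convolution primitives (im2col based)
# ---------------------------------------------------------------------------

try:  # optional numba acceleration for the gather/scatter hot loops
    from numba import njit as _njit

    @_njit(cache=True)
    def _gather_cols(xt, cols, kh, kw, stride, oh, ow):
        n, _, _, c = xt.shape
        for b in range(n):
            for y in range(oh):
                for x in range(ow):
                    for i in range(kh):
                        for j in range(kw):
                            for ch in range(c):
                                cols[b, y, x, i, j, ch] = xt[b, y * stride + i, x * stride + j, ch]

    @_njit(cache=True)
    def _scatter_cols(d6, dxt, kh, kw, stride, oh, ow):
        n, _, _, c = dxt.shape
        for b in range(n):
            for y in range(oh):
                for x in range(ow):
                    for i in range(kh):
                        for j in range(kw):
                            for ch in range(c):
                                dxt[b, y * stride + i, x * stride + j, ch] += d6[b, y, x, i, j, ch]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return (cols, out_h, out_w) where cols is (N*OH*OW, kh*kw*C).

    Works in channels-last scratch layout; the gather is a jitted loop when
    numba is importable and a slice-copy loop otherwise.
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # (N, H, W, C)
    cols = np.empty((n, oh, ow, kh, kw, c), dtype=x.dtype)
    if _HAVE_NUMBA:
        _gather_cols(xt, cols, kh, kw, stride, oh, ow)
    else:  # pragma: no cover
        for i in range(kh):
            for j in range(kw):
                cols[:, :, :, i, j, :] = xt[:, i:i + stride * oh:stride,
                                            j:j + stride * ow:stride, :]
    return cols.reshape(n * oh * ow, kh * kw * c), oh, ow


def _weight_mat(w: np.ndarray) -> np.ndarray:
    """(O, C, kh, kw) weights as an (O, kh*kw*C) matrix matching _im2col."""
    o = w.shape[0]
    return np.ascontiguousarray(w.transpose(0, 2, 3, 1)).reshape(o, -1)


def _weight_unmat(m: np.ndarray, w_shape) -> np.ndarray:
    o, c, kh, kw = w_shape
    return m.reshape(o, kh, kw, c).transpose(0, 3, 1, 2)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add column gradients back to input layout."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    d6 = np.ascontiguousarray(dcols).reshape(n, oh, ow, kh, kw, c)
    dxt = np.zeros((n, hp, wp, c), dtype=dcols.dtype)
    if _HAVE_NUMBA:
        _scatter_cols(d6, dxt, kh, kw, stride, oh, ow)
    else:  # pragma: no cover
        for i in range(kh):
            for j in range(kw):
                dxt[:, i:i + stride * oh:stride, j:j + stride * ow:stride, :] += d6[:, :, :, i, j, :]
    dxp = dxt.transpose(0, 3, 1, 2)
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return np.ascontiguousarray(dxp)


class Conv2d(Layer):
    """2-D convolution, 'same' padding by default (odd kernels, stride 1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, bias: bool = True):
        if kernel % 2 == 0:
            raise ValueError(f"even kernel size {kernel} is not supported")
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        self.w = Param(he_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.b = Param(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self._cache = None

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]

    def forward(self, x, train=False):
        if x.shape[2] == 0 or x.shape[3] == 0:
            raise ValueError("empty spatial dimensions")
        n = x.shape[0]
        o, c, kh, kw = self.w.v.shape
        cols, oh, ow = _im2col(x, kh, kw, self.stride, self.pad)
        y = cols @ _weight_mat(self.w.v).T
        if self.b is not None:
            y += self.b.v
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(y.reshape(n, oh, ow, o).transpose(0, 3, 1, 2))

    def backward(self, dy):
        cols, x_shape = self._cache
        o = self.w.v.shape[0]
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, o)
        self.w.g += _weight_unmat(dy_flat.T @ cols, self.w.v.shape)
        if self.b is not None:
            self.b.g += dy_flat.sum(axis=0)
        dcols = dy_flat @ _weight_mat(self.w.v)
        kh = kw = self.kernel
        return _col2im(dcols, x_shape, kh, kw, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Stride-2 3x3 transposed convolution that exactly doubles H and W.

    Forward is the data-gradient of a stride-2 conv (pad 1, output padding 1),
    so composing with a 2x2 down-sampling restores even spatial sizes.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        self.kernel = kernel
        self.stride = 2
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        # stored in conv orientation: (in_ch, out_ch, kh, kw)
        self.w = Param(he_uniform(rng, (in_ch, out_ch, kernel, kernel), fan_in))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        n, ci, h, w = x.shape
        co = self.w.v.shape[1]
        oh, ow = 2 * h, 2 * w
        x_flat = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, ci)
        dcols = x_flat @ _weight_mat(self.w.v)
        y = _col2im(dcols, (n, co, oh, ow), self.kernel, self.kernel, self.stride, self.pad)
        y += self.b.v[None, :, None, None]
        self._cache = (x_flat, (n, ci, h, w), (oh, ow))
        return y

    def backward(self, dy):
        x_flat, x_shape, _ = self._cache
        n, ci, h, w = x_shape
        cols, oh2, ow2 = _im2col(dy, self.kernel, self.kernel, self.stride, self.pad)
        assert (oh2, ow2) == (h, w)
        self.w.g += _weight_unmat(x_flat.T @ cols, self.w.v.shape)
        self.b.g += dy.sum(axis=(0, 2, 3))
        dx = cols @ _weight_mat(self.w.v).T
        return np.ascontiguousarray(dx.reshape(n, h, w, ci).transpose(0, 3, 1, 2))


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch, dtype=np.float32))
        self.beta = Param(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, dy):
        xhat, inv, train, shape = self._cache
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dy.sum(axis=(0, 2, 3))
        g = self.gamma.v[None, :, None, None] * inv[None, :, None, None]
        if not train:
            return dy * g
        m = shape[0] * shape[2] * shape[3]
        dxhat = dy * self.gamma.v[None, :, None, None]
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return term * inv[None, :, None, None]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._cache = None

    def forward(self, x, train=False):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._cache = (x > 0, y)
        return y

    def backward(self, dy):
        pos, y = self._cache
        return dy * np.where(pos, 1.0, y + self.alpha)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape, dtype=np.float32) >= self.p).astype(x.dtype) \
            / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h < 2 or w < 2:
            raise ValueError(f"spatial size {h}x{w} too small for 2x2 pooling")
        h2, w2 = h - h % 2, w - w % 2
        xc = x[:, :, :h2, :w2].reshape(n, c, h2 // 2, 2, w2 // 2, 2)
        y = xc.max(axis=(3, 5))
        self._cache = (x.shape, xc == y[:, :, :, None, :, None])
        return y

    def backward(self, dy):
        (n, c, h, w), mask = self._cache
        h2, w2 = h - h % 2, w - w % 2
        dx = np.zeros((n, c, h, w), dtype=dy.dtype)
        spread = mask * dy[:, :, :, None, :, None]
        dx[:, :, :h2, :w2] = spread.reshape(n, c, h2, w2)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, bias: bool = True):
        self.w = Param(he_uniform(rng, (in_f, out_f), in_f))
        self.b = Param(np.zeros(out_f, dtype=np.float32)) if bias else None

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.w.v
        if self.b is not None:
            y += self.b.v
        return y

    def backward(self, dy):
        self.w.g += self._x.T @ dy
        if self.b is not None:
            self.b.g += dy.sum(axis=0)
        return dy @ self.w.v.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
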