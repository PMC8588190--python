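"""Minimal CNN layer kernels (numpy, NCHW, float32).

Convolution and the fully-connected layers reduce to BLAS matrix
products through im2col; max-pooling and local response normalization
are vectorized elementwise/window ops.  Each layer caches what its
backward pass needs.  The first convolution skips its input gradient
(nothing below it wants one), which removes the most expensive col2im
scatter.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Forward/backward unit; ``params()`` yields (name, value, grad) triples."""

    trainable = False

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return in_shape

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        raise NotImplementedError


def _conv_out(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> (N*Ho*Wo, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols, dtype=np.float32), ho, wo


class Conv2D(Layer):
    trainable = True

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 pad: int, weight_sd: float | None = None, input_grad: bool = True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.weight_sd = weight_sd
        self.input_grad = input_grad
        self.w = np.zeros((out_ch, in_ch, kernel, kernel), dtype=np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._scatter_idx = None

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        return (self.out_ch,
                _conv_out(h, self.kernel, self.stride, self.pad),
                _conv_out(w, self.kernel, self.stride, self.pad))

    def initialize(self, rng):
        # He initialization (scaled for ReLU fan-in) unless a fixed sd is given
        sd = self.weight_sd
        if sd is None:
            sd = float(np.sqrt(2.0 / (self.in_ch * self.kernel * self.kernel)))
        self.w = rng.normal(0.0, sd, self.w.shape).astype(np.float32)
        self.b = np.zeros(self.out_ch, dtype=np.float32)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, train):
        self._in_shape = x.shape
        cols, ho, wo = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        self._cols = cols if train else None
        self._ho, self._wo = ho, wo
        wmat = self.w.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b
        n = x.shape[0]
        return y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, _, ho, wo = dy.shape
        dy2 = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        dy2 = np.ascontiguousarray(dy2, dtype=np.float32)
        self.dw[...] = (dy2.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dy2.sum(axis=0)
        if not self.input_grad:
            self._cols = None
            return None
        wmat = self.w.reshape(self.out_ch, -1)
        dcols = dy2 @ wmat  # (N*Ho*Wo, C*kh*kw)
        dx = self._col2im(dcols, n)
        self._cols = None
        return dx

    def _col2im(self, dcols, n):
        _, c, h, w = self._in_shape
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        if self._scatter_idx is None:
            # flat index into a (C, Hp, Wp) volume for every (position, patch-elem)
            k, s = self.kernel, self.stride
            ho, wo = self._ho, self._wo
            ci, ki, kj = np.meshgrid(np.arange(c), np.arange(k), np.arange(k),
                                     indexing="ij")
            patch = (ci * hp * wp + ki * wp + kj).ravel()          # (C*k*k,)
            oi, oj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
            origin = (oi * s * wp + oj * s).ravel()                # (Ho*Wo,)
            self._scatter_idx = (origin[:, None] + patch[None, :]).ravel()
        dxp = np.zeros((n, c * hp * wp), dtype=np.float32)
        per = self._ho * self._wo * c * self.kernel * self.kernel
        for i in range(n):  # scatter per sample keeps the index table small
            np.add.at(dxp[i], self._scatter_idx, dcols[i * self._ho * self._wo:
                                                       (i + 1) * self._ho * self._wo].ravel())
        dxp = dxp.reshape(n, c, hp, wp)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class CrossChannelLRN(Layer):
    """Local response normalization across channels (AlexNet constants)."""

    def __init__(self, window: int = 5, alpha: float = 1e-4,
                 beta: float = 0.75, k: float = 2.0):
        self.window, self.alpha, self.beta, self.k = window, alpha, beta, k

    def _window_sum(self, a: np.ndarray) -> np.ndarray:
        c = a.shape[1]
        half = self.window // 2
        ap = np.pad(a, ((0, 0), (half, half)) + ((0, 0),) * (a.ndim - 2))
        out = ap[:, :c].copy()
        for j in range(1, self.window):
            out += ap[:, j:j + c]
        return out

    def forward(self, x, train):
        s = self.k + self.alpha * self._window_sum(x * x)
        sb = s ** (-self.beta)
        self._x, self._s, self._sb = x, s, sb
        return x * sb

    def backward(self, dy):
        t = dy * self._x * (self._sb / self._s)
        return dy * self._sb - (2.0 * self.alpha * self.beta) * self._x * self._window_sum(t)


class MaxPool(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c,
                _conv_out(h, self.kernel, self.stride, self.pad),
                _conv_out(w, self.kernel, self.stride, self.pad))

    def _views(self, x, ho, wo):
        for ki in range(self.kernel):
            for kj in range(self.kernel):
                yield x[:, :, ki:ki + self.stride * ho:self.stride,
                        kj:kj + self.stride * wo:self.stride]

    def forward(self, x, train):
        self._in_shape = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad),
                           (self.pad, self.pad)), constant_values=-np.inf)
        hp, wp = x.shape[2], x.shape[3]
        ho = (hp - self.kernel) // self.stride + 1
        wo = (wp - self.kernel) // self.stride + 1
        self._ho, self._wo = ho, wo
        # running max over kernel offsets; the window tensor is never built
        best = np.maximum.reduce(list(self._views(x, ho, wo)))
        self._xp = x if train else None
        self._best = best if train else None
        return best

    def backward(self, dy):
        # route each output's gradient to the first window element that
        # attained the max (argmax tie rule), accumulating overlaps
        n, c, h, w = self._in_shape
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        out = np.zeros((n, c, hp, wp), dtype=np.float32)
        unused = np.ones(dy.shape, dtype=bool)
        for view, oview in zip(self._views(self._xp, self._ho, self._wo),
                               self._views(out, self._ho, self._wo)):
            m = (view == self._best) & unused
            unused &= ~m
            oview += dy * m
        self._xp = self._best = None
        if self.pad:
            return out[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return out


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_units: int, out_units: int, weight_sd: float | None = None):
        self.in_units, self.out_units = in_units, out_units
        self.weight_sd = weight_sd
        self.w = np.zeros((in_units, out_units), dtype=np.float32)
        self.b = np.zeros(out_units, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def out_shape(self, in_shape):
        if int(np.prod(in_shape)) != self.in_units:
            raise ValueError(
                f"expected {self.in_units} input units, got {int(np.prod(in_shape))}"
            )
        return (self.out_units,)

    def initialize(self, rng):
        sd = self.weight_sd
        if sd is None:
            sd = float(np.sqrt(2.0 / self.in_units))
        self.w = rng.normal(0.0, sd, self.w.shape).astype(np.float32)
        self.b = np.zeros(self.out_units, dtype=np.float32)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, dy):
        dy = dy.astype(np.float32, copy=False)
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


class Dropout(Layer):
    def __init__(self, rate: float = 0.5):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = probs.shape[0]
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())


def softmax_ce_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = probs.shape[0]
    g = probs.copy()
    g[np.arange(n), labels] -= 1.0
    return (g / n).astype(np.float32)
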