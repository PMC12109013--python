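"""Minimal numpy neural-network layer library with manual backpropagation.

Implements exactly the pieces the conditional generator, discriminator and
Ki67 regressor need: equalized-learning-rate dense and convolution layers,
leaky ReLU, second-moment (pixel) normalisation, nearest-neighbour
upsampling, per-sample channel modulation, sigmoid, and Adam.

Conventions: feature maps are ``(N, H, W, C)`` float32 (channels last, so
im2col gathers are contiguous along channels); every layer caches its
forward inputs on ``self`` and must be driven forward-then-backward in
strictly paired order.  ``backward(dy, accumulate=False)`` propagates the
input gradient without touching parameter gradients, which the R1-penalty
machinery uses to obtain image gradients cleanly.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def params(self) -> list[Param]:
        return []


class Dense(Layer):
    """Fully connected layer with equalized learning rate (weights stored
    unit-variance, rescaled by 1/sqrt(fan_in) at run time)."""

    def __init__(self, nin: int, nout: int, rng: np.random.Generator,
                 bias_init: float = 0.0):
        self.w = Param(rng.standard_normal((nout, nin)))
        self.b = Param(np.full(nout, bias_init, dtype=F32))
        self.scale = F32(1.0 / np.sqrt(nin))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ (self.w.data.T * self.scale) + self.b.data

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        if accumulate:
            self.w.grad += (dy.T @ self._x) * self.scale
            self.b.grad += dy.sum(0)
        return dy @ (self.w.data * self.scale)


class Conv2d(Layer):
    """k x k convolution via channels-last im2col, optional stride and padding.

    Patch columns are gathered as k*k contiguous channel slabs, so the
    weight matrix is laid out ``(cout, k*k*cin)`` with the (i, j, c) index
    flattened in that order.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        self.w = Param(rng.standard_normal((cout, cin * k * k)))
        self.b = Param(np.zeros(cout, dtype=F32))
        self.scale = F32(1.0 / np.sqrt(cin * k * k))
        self.cin, self.cout = cin, cout
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, s, p = self.k, self.stride, self.pad
        self._xshape = x.shape
        ho, wo = self._out_hw(h, w)
        if k == 1 and s == 1 and p == 0:
            cols = x.reshape(n, h, w, c)
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            cols = np.concatenate(
                [xp[:, i:i + s * ho:s, j:j + s * wo:s, :]
                 for i in range(k) for j in range(k)], axis=3)
        self._cols = cols
        return cols @ (self.w.data.T * self.scale) + self.b.data

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        n, h, w, c = self._xshape
        k, s, p = self.k, self.stride, self.pad
        ho, wo = dy.shape[1], dy.shape[2]
        if accumulate:
            self.w.grad += np.tensordot(dy, self._cols,
                                        axes=([0, 1, 2], [0, 1, 2])) * self.scale
            self.b.grad += dy.sum(axis=(0, 1, 2))
        dcols = dy @ (self.w.data * self.scale)  # N,Ho,Wo,k*k*C
        if k == 1 and s == 1 and p == 0:
            return dcols
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=F32)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            dxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += \
                dcols[:, :, :, idx * c:(idx + 1) * c]
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = F32(slope)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class PixelNorm(Layer):
    """Second-moment normalisation along axis 1: x / sqrt(mean(x^2) + eps)."""

    def __init__(self, eps: float = 1e-8):
        self.eps = F32(eps)
        self._x = None
        self._r = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        m = np.mean(np.square(x), axis=1, keepdims=True)
        self._r = 1.0 / np.sqrt(m + self.eps)
        self._x = x
        return (x * self._r).astype(F32)

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        x, r = self._x, self._r
        d = x.shape[1]
        xdy = np.sum(x * dy, axis=1, keepdims=True)
        return (dy * r - x * (r ** 3) * xdy / d).astype(F32)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0), dtype=F32))
        return self._y

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Upsample2x(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class AvgPool2x(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        n, h, w, c = self._shape
        return (np.broadcast_to(dy[:, :, None, :, None, :] / 4.0,
                                (n, h // 2, 2, w // 2, 2, c))
                .reshape(n, h, w, c).astype(F32))


class Modulate(Layer):
    """Per-sample channel gain on channels-last maps: y[n,:,:,c] = x[n,:,:,c] * (1 + s[n,c]).

    The style vector ``s`` comes from an affine map of w; the +1 keeps a
    zero-initialised affine neutral at the start of training.
    """

    def forward(self, x: np.ndarray, s: np.ndarray) -> np.ndarray:
        self._x, self._g = x, (1.0 + s)[:, None, None, :].astype(F32)
        return x * self._g

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dx = dy * self._g
        ds = np.sum(dy * self._x, axis=(1, 2))
        return dx, ds


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x).astype(F32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return (1.0 / (1.0 + np.exp(-x))).astype(F32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-3,
                 beta1: float = 0.0, beta2: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (np.square(g) - v)
            p.data -= (self.lr * (m / b1t) /
                       (np.sqrt(v / b2t) + self.eps)).astype(F32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def collect(params: list[Param]) -> list[np.ndarray]:
    """Snapshot parameter gradients (copies)."""
    return [p.grad.copy() for p in params]
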