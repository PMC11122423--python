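"""Minimal NumPy CNN framework (float32, NHWC) with manual backprop.

Provides exactly the pieces the two reconstruction networks need:
3x3/1x1 'same' convolutions, 2x2 max pooling, 2x2 stride-2 transposed
convolutions, ELU/ReLU, and an Adam optimizer.  Convolutions are
evaluated as k*k shifted GEMMs on channels-last arrays, which is the
fastest formulation for small channel counts on a single CPU core.
All layers implement ``forward`` and ``backward`` and keep whatever
intermediates the backward pass needs.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """k x k 'same' zero-padded convolution (k odd; 1 or 3 in practice).

    Weight layout: (k, k, cin, cout); input/output (N, H, W, C).
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        self.w = Param(_he_init(rng, (k, k, cin, cout), cin * k * k))
        self.b = Param(np.zeros(cout, dtype=DTYPE))
        self._xp = None
        self._x_shape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, h, w, c = x.shape
        self._x_shape = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            self._xp = x
            return x @ self.w.value[0, 0] + self.b.value
        xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=DTYPE)
        xp[:, p:p + h, p:p + w] = x
        self._xp = xp
        y = np.empty((n, h, w, self.cout), dtype=DTYPE)
        y[:] = self.b.value
        for a in range(k):
            for b in range(k):
                np.add(y, xp[:, a:a + h, b:b + w] @ self.w.value[a, b], out=y)
        return y

    def backward(self, dy):
        n, h, w, c = self._x_shape
        k, p = self.k, self.k // 2
        self.b.grad += dy.sum(axis=(0, 1, 2))
        if k == 1:
            self.w.grad[0, 0] += np.tensordot(self._xp, dy,
                                              axes=([0, 1, 2], [0, 1, 2]))
            return dy @ self.w.value[0, 0].T
        dxp = np.zeros_like(self._xp)
        for a in range(k):
            for b in range(k):
                self.w.grad[a, b] += np.tensordot(
                    self._xp[:, a:a + h, b:b + w], dy,
                    axes=([0, 1, 2], [0, 1, 2]))
                np.add(dxp[:, a:a + h, b:b + w], dy @ self.w.value[a, b].T,
                       out=dxp[:, a:a + h, b:b + w])
        return dxp[:, p:p + h, p:p + w]


class TransposedConv2x2(Layer):
    """2x2 stride-2 transposed convolution: doubles H and W."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.w = Param(_he_init(rng, (cin, 4 * cout), cin))
        self.b = Param(np.zeros(cout, dtype=DTYPE))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, h, w, c = x.shape
        self._x = x
        y = x @ self.w.value  # (N, H, W, 4*cout)
        y = y.reshape(n, h, w, 2, 2, self.cout)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.cout)
        return y + self.b.value

    def backward(self, dy):
        n, h, w, c = self._x.shape
        self.b.grad += dy.sum(axis=(0, 1, 2))
        d = dy.reshape(n, h, 2, w, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        d = np.ascontiguousarray(d).reshape(n, h, w, 4 * self.cout)
        self.w.grad += np.tensordot(self._x, d, axes=([0, 1, 2], [0, 1, 2]))
        return d @ self.w.value.T


class MaxPool2x2(Layer):
    def __init__(self):
        self._idx = None
        self._x_shape = None

    def forward(self, x):
        n, h, w, c = x.shape
        self._x_shape = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._x_shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dxr).reshape(n, h, w, c)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._neg = None
        self._y_neg = None

    def forward(self, x):
        # expm1 only on the negative entries; much cheaper than a full pass
        neg = x < 0
        y = x.copy()
        y_neg = self.alpha * np.expm1(x[neg])
        y[neg] = y_neg
        self._neg, self._y_neg = neg, y_neg
        return y

    def backward(self, dy):
        dx = dy.copy()
        dx[self._neg] = dy[self._neg] * (self._y_neg + self.alpha)
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_state(net: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in net.params()]


def set_state(net: Layer, state: list[np.ndarray]) -> None:
    for p, s in zip(net.params(), state):
        p.value[...] = s


def gaussian_kernel2d(sigma: float, radius: int | None = None) -> np.ndarray:
    """Unit-sum 2-D Gaussian kernel used by the localization loss."""
    if radius is None:
        radius = max(1, int(np.ceil(3 * sigma)))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    g1 = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    g = np.outer(g1, g1)
    return (g / g.sum()).astype(DTYPE)


class FixedConv:
    """Non-learnable 'same' convolution with a fixed separable symmetric
    kernel (outer product of a 1-D profile with itself).

    Being symmetric, the operator is self-adjoint, which the localization
    loss gradient relies on.
    """

    def __init__(self, kernel: np.ndarray):
        from scipy.ndimage import convolve1d  # deferred import
        k = kernel.shape[0]
        assert kernel.shape == (k, k) and k % 2 == 1
        self.k = k
        self.kernel = kernel.astype(DTYPE)
        # separable factorization kernel = outer(a, a):
        # a_j = K[c, j] / sqrt(K[c, c])
        c = (k - 1) // 2
        if kernel[c, c] <= 0:
            raise ValueError("kernel centre must be positive")
        self._g1 = (kernel[c].astype(np.float64)
                    / np.sqrt(float(kernel[c, c]))).astype(DTYPE)
        self._conv1d = convolve1d

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """x: (..., H, W) or (N, H, W, 1) -> blurred, same shape."""
        if x.ndim == 4:  # NHWC with a single channel
            y = self._conv1d(x, self._g1, axis=1, mode="constant")
            return self._conv1d(y, self._g1, axis=2, mode="constant")
        y = self._conv1d(x, self._g1, axis=-1, mode="constant")
        return self._conv1d(y, self._g1, axis=-2, mode="constant")
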