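"""Minimal CPU neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
``backward(g)`` returns the gradient with respect to its input while
accumulating parameter gradients in-place.  Convolutions use "same"
padding with output size ceil(n / stride), so a stride-2 layer maps
108 -> 54 -> 27 -> 14 -> 7 -> 4 across five stages.
"""

from __future__ import annotations

import math

import numpy as np


class Parameter:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    lo = total // 2
    return out, lo, total - lo


class Conv2d(Layer):
    """2D convolution (cross-correlation) with optional bias."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel_size: int,
        stride: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        std = math.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.k, self.stride = k, stride
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        oh, plo_h, phi_h = _same_pad(h, self.k, self.stride)
        ow, plo_w, phi_w = _same_pad(w, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (plo_h, phi_h), (plo_w, phi_w)))
        y = np.zeros((n, self.weight.data.shape[0], oh, ow), dtype=x.dtype)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                xs = xp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s]
                # (c_out, c_in) x (n, c_in, oh, ow) -> (n, c_out, oh, ow)
                y += np.moveaxis(
                    np.tensordot(self.weight.data[:, :, ki, kj], xs, axes=([1], [1])),
                    0,
                    1,
                )
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = (xp, x.shape, (plo_h, plo_w), (oh, ow))
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp, x_shape, (plo_h, plo_w), (oh, ow) = self._cache
        s = self.stride
        dxp = np.zeros_like(xp)
        for ki in range(self.k):
            for kj in range(self.k):
                xs = xp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s]
                self.weight.grad[:, :, ki, kj] += np.tensordot(
                    g, xs, axes=([0, 2, 3], [0, 2, 3])
                )
                dxs = np.moveaxis(
                    np.tensordot(self.weight.data[:, :, ki, kj].T, g, axes=([1], [1])),
                    0,
                    1,
                )
                dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dxs
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2, 3))
        _, _, h, w = x_shape
        return dxp[:, :, plo_h : plo_h + h, plo_w : plo_w + w]


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) per channel, before activation."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, training, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd, training, shape = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gam_inv = (self.gamma.data * invstd)[None, :, None, None]
        if not training:
            return g * gam_inv
        m = shape[0] * shape[2] * shape[3]
        g_sum = g.sum(axis=(0, 2, 3))[None, :, None, None]
        gx_sum = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return gam_inv * (g - g_sum / m - xhat * gx_sum / m)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class GlobalAvgPool2d(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        _, _, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / c_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ g
        self.bias.grad += g.sum(axis=0)
        return g @ self.weight.data.T


def sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
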