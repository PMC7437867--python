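"""Minimal NumPy neural-network primitives with explicit backprop.

Functional-cache style: ``forward`` returns ``(output, cache)`` and
``backward`` consumes the cache, so a single parameterized layer can be
shared across parallel pathways (each call gets its own cache while
gradients accumulate on the layer).  float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "Dense",
    "relu_forward",
    "relu_backward",
    "maxpool_forward",
    "maxpool_backward",
    "dropout_forward",
    "dropout_backward",
    "SGDMomentum",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d:
    """2-D convolution (cross-correlation), NCHW, no padding, square kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel * kernel
        self.W = _he_init(rng, (out_channels, fan_in), fan_in)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        k, s = self.kernel, self.stride
        return (h - k) // s + 1, (w - k) // s + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, c, h, w = x.shape
        oh, ow = self.out_size(h, w)
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s, :, :]                  # (n, c, oh, ow, k, k)
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
        return np.ascontiguousarray(col)

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        oh, ow = self.out_size(h, w)
        col = self._im2col(x)
        y = col @ self.W.T + self.b
        y = y.transpose(0, 2, 1).reshape(n, self.out_channels, oh, ow)
        return y, (col, x.shape)

    def backward(self, gy: np.ndarray, cache, need_dx: bool = True):
        col, x_shape = cache
        n, c, h, w = x_shape
        oh, ow = self.out_size(h, w)
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.out_channels)
        col2 = col.reshape(-1, col.shape[-1])
        self.dW += g2.T @ col2
        self.db += g2.sum(axis=0)
        if not need_dx:
            return None
        dcol = g2 @ self.W                                # (n*oh*ow, c*k*k)
        k, s = self.kernel, self.stride
        # one contiguous relayout so the scatter adds below are contiguous
        dcol = np.ascontiguousarray(
            dcol.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2))
        dx = np.zeros(x_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcol[:, :, i, j]
        return dx

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Dense:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        self.W = _he_init(rng, (out_features, in_features), in_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray):
        return x @ self.W.T + self.b, x

    def backward(self, gy: np.ndarray, cache):
        x = cache
        self.dW += gy.T @ x
        self.db += gy.sum(axis=0)
        return gy @ self.W

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(gy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return gy * mask


def maxpool_forward(x: np.ndarray, k: int):
    """Non-overlapping k x k max pooling; trailing rows/cols are cropped."""
    if k == 1:
        return x, None
    n, c, h, w = x.shape
    oh, ow = h // k, w // k
    xc = x[:, :, :oh * k, :ow * k].reshape(n, c, oh, k, ow, k)
    xc = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
    idx = xc.argmax(axis=-1)
    y = np.take_along_axis(xc, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape, k)


def maxpool_backward(gy: np.ndarray, cache) -> np.ndarray:
    if cache is None:
        return gy
    idx, x_shape, k = cache
    n, c, h, w = x_shape
    oh, ow = h // k, w // k
    dxc = np.zeros((n, c, oh, ow, k * k), dtype=np.float32)
    np.put_along_axis(dxc, idx[..., None], gy[..., None], axis=-1)
    dxc = dxc.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
    dx = np.zeros(x_shape, dtype=np.float32)
    dx[:, :, :oh * k, :ow * k] = dxc.reshape(n, c, oh * k, ow * k)
    return dx


def dropout_forward(x: np.ndarray, p: float, rng: np.random.Generator, train: bool):
    if not train or p <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * mask, mask


def dropout_backward(gy: np.ndarray, mask) -> np.ndarray:
    return gy if mask is None else gy * mask


class SGDMomentum:
    """Plain SGD with momentum, L2 weight decay, and optional global
    gradient-norm clipping (stabilizes the violent early steps of
    small-batch training)."""

    def __init__(self, layers, lr: float, momentum: float, l2: float,
                 max_grad_norm: float | None = None) -> None:
        self.layers = list(layers)
        self.lr = lr
        self.momentum = momentum
        self.l2 = l2
        self.max_grad_norm = max_grad_norm
        self.velocities = [
            [np.zeros_like(p) for p, _ in layer.params_grads()] for layer in self.layers
        ]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        scale = 1.0
        if self.max_grad_norm is not None:
            sq = 0.0
            for layer in self.layers:
                for _, g in layer.params_grads():
                    sq += float(np.sum(np.square(g, dtype=np.float64)))
            norm = np.sqrt(sq)
            if norm > self.max_grad_norm:
                scale = self.max_grad_norm / norm
        for layer, vels in zip(self.layers, self.velocities):
            for (p, g), v in zip(layer.params_grads(), vels):
                v *= self.momentum
                v -= self.lr * (scale * g + self.l2 * p)
                p += v
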