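"""Minimal NumPy neural-network engine for 2D semantic segmentation.

Implements exactly the pieces a small encoder--decoder segmentation
network needs -- same-padded convolutions, ReLU, 2x2 max pooling,
nearest-neighbour upsampling, channel concatenation and a numerically
stable sigmoid cross-entropy -- with hand-written backward passes.
Everything runs in float32 on a single CPU and is deterministic for a
fixed seed.

Convolutions are evaluated as matrix products on im2col-unrolled
patches; the backward pass scatters gradients back with a k*k-term
shifted accumulation, which is cheap for the 3x3 kernels used here.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Upsample2", "SGD", "sigmoid", "bce_with_logits"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix, zero-padded."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N, C, H, W, k, k
    n, c, h, w, _, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    cols = cols.reshape(n, c, k, k, h, w)
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


class Conv2d:
    """Same-padded 2D convolution with He-normal initialisation."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self.pad = k // 2
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        out = np.einsum("of,nfp->nop", self.w, cols, optimize=True)
        out += self.b[None, :, None]
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = grad.shape
        g = grad.reshape(n, self.out_ch, h * w)
        self.gw += np.einsum("nop,nfp->of", g, self._cols, optimize=True)
        self.gb += g.sum(axis=(0, 2))
        gcols = np.einsum("of,nop->nfp", self.w, g, optimize=True)
        self._cols = None
        return _col2im(gcols, self._xshape, self.k, self.pad)


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2 (even spatial sides required)."""

    def __init__(self):
        self._argmax = None
        self._shape = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._argmax = idx
            self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        blocks = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        for (p, g), v in zip(self.params, self._vel):
            if self.momentum:
                v *= self.momentum
                v -= self.lr * g
                p += v
            else:
                p -= self.lr * g

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, target: np.ndarray):
    """Mean pixel-wise binary cross entropy and its gradient w.r.t. logits."""
    z = logits.astype(np.float64)
    loss = np.mean(np.maximum(z, 0.0) - z * target + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(logits) - target.astype(logits.dtype)) / logits.size
    return float(loss), grad.astype(logits.dtype)
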