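"""Minimal reverse-mode neural-network engine used by the segmentation U-Net.

Implements exactly the layer set the encoder/decoder architecture needs —
3×3 same-padding convolutions, ReLU, 2×2 max pooling, 2×2 stride-2
transposed convolutions, channel concatenation, 1×1 convolutions — together
with hand-derived gradients and an Adam optimizer.  Arrays are NCHW
``float32``; convolutions run as im2col + matmul so the heavy lifting stays
inside BLAS.

Each layer instance is used at most once per forward pass, so forward
activations needed by ``backward`` are cached on the instance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "ConvTranspose2",
    "Concat",
    "Adam",
]

_F32 = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, H*W) for a same-padded k×k convolution."""
    if k == 1:
        b, c, h, w = x.shape
        return x.reshape(b, c, h * w)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # v: (B, C, H, W, k, k) -> (B, C, k, k, H*W)
    b, c, h, w = x.shape
    cols = v.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add column gradients back."""
    b, c, h, w = shape
    if k == 1:
        return dcols.reshape(b, c, h, w)
    pad = k // 2
    d = dcols.reshape(b, c, k, k, h, w)
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2D:
    """k×k same-padding convolution with bias (He-initialized)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)).astype(_F32)
        self.b = np.zeros(cout, dtype=_F32)
        self.k = k
        self.cin = cin
        self.cout = cout
        self.dW = None
        self.db = None
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols
        self._xshape = x.shape
        y = np.matmul(self.W, cols) + self.b[:, None]
        return y.reshape(b, self.cout, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h, w = dy.shape
        dyf = dy.reshape(b, self.cout, h * w)
        self.dW = np.tensordot(dyf, self._cols, axes=([0, 2], [0, 2]))
        self.db = dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, dyf)
        self._cols = None
        return _col2im(dcols, self._xshape, self.k)

    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, _F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, _F32(0.0))
        self._mask = None
        return dx


class MaxPool2:
    """2×2 max pooling with stride 2 (spatial dims must be even)."""

    def __init__(self):
        self._mask = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        # ties share the gradient; with float activations they are rare
        self._mask = xr == y[:, :, :, None, :, None]
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dxr = self._mask * dy[:, :, :, None, :, None]
        self._mask = None
        return dxr.reshape(b, c, h, w)


class ConvTranspose2:
    """2×2 stride-2 transposed convolution (learned ×2 upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout, 2, 2)).astype(_F32)
        self.b = np.zeros(cout, dtype=_F32)
        self.cin = cin
        self.cout = cout
        self.dW = None
        self.db = None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._x = x
        t = np.tensordot(x, self.W, axes=([1], [0]))  # (B, H, W, cout, 2, 2)
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(b, self.cout, 2 * h, 2 * w)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dyr = dy.reshape(b, self.cout, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        # dyr: (B, H, W, cout, 2, 2)
        self.dW = np.tensordot(self._x, dyr, axes=([0, 2, 3], [0, 1, 2]))
        self.db = dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dyr, self.W, axes=([3, 4, 5], [1, 2, 3]))
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def n_params(self) -> int:
        return self.W.size + self.b.size


class Concat:
    """Channel-axis concatenation of (skip, upsampled) pairs."""

    def __init__(self):
        self._split = None

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._split = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, dy: np.ndarray):
        s = self._split
        self._split = None
        return dy[:, :s], dy[:, s:]


class Adam:
    """Adam with decoupled learning rate so a scheduler can change it."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if hasattr(l, "W")]
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]
        self._v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for p, g, mi, vi in ((layer.W, layer.dW, m[0], v[0]),
                                 (layer.b, layer.db, m[1], v[1])):
                mi *= b1
                mi += (1 - b1) * g
                vi *= b2
                vi += (1 - b2) * np.square(g)
                p -= self.lr * (mi / bc1) / (np.sqrt(vi / bc2) + self.eps)
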