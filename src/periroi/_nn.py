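"""Minimal, fully deterministic NumPy neural-network core.

Implements exactly what the compact CNN backbones need: 2D/3D "same"
convolution (stride 1, via im2col matrix multiplies), ReLU, factor-2 average
pooling, global average pooling, a linear head, binary cross-entropy on
logits, and Adam with decoupled weight decay. Everything is float64 NumPy,
so training is bit-reproducible for a fixed seed on any platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv",
    "ReLU",
    "AvgPool2",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray, weights=None):
    """Mean weighted binary cross-entropy; returns (loss, dloss/dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=np.float64)
    loss = -(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))).mean()
    grad = w * (p - y) / p.size
    return loss, grad


class Layer:
    def params(self):
        return []

    def grads(self):
        return []


class Conv(Layer):
    """Stride-1 "same" convolution for 2D or 3D inputs.

    Input ``(N, C, *spatial)``; kernel ``k`` per spatial axis (odd). The
    backward pass reuses the im2col forward on the transposed, spatially
    flipped kernel, so no scatter-add is needed.
    """

    def __init__(self, c_in: int, c_out: int, k: int, ndim: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.ndim = c_in, c_out, k, ndim
        fan_in = c_in * k**ndim
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in) + (k,) * ndim)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._spatial = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, nd = self.k, self.ndim
        pad = k // 2
        pads = [(0, 0), (0, 0)] + [(pad, pad)] * nd
        xp = np.pad(x, pads)
        win = sliding_window_view(xp, (k,) * nd, axis=tuple(range(2, 2 + nd)))
        # win: (N, C, *spatial, *k) -> (N, *spatial, C, *k)
        win = np.moveaxis(win, 1, 1 + nd)
        n = x.shape[0]
        spatial = x.shape[2:]
        return win.reshape(n * int(np.prod(spatial)), self.c_in * k**nd)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        self._spatial = x.shape[2:]
        cols = self._im2col(x)
        self._cols = cols
        Wmat = self.W.reshape(self.c_out, -1)
        out = cols @ Wmat.T + self.b
        out = out.reshape((n,) + self._spatial + (self.c_out,))
        return np.moveaxis(out, -1, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        dmat = np.moveaxis(dout, 1, -1).reshape(-1, self.c_out)
        self.dW += (dmat.T @ self._cols).reshape(self.W.shape)
        self.db += dmat.sum(axis=0)
        # dx = conv(dout, W transposed in channels and flipped spatially)
        flip = tuple(slice(None, None, -1) for _ in range(self.ndim))
        Wt = np.swapaxes(self.W[(slice(None), slice(None)) + flip], 0, 1)
        tmp = Conv.__new__(Conv)
        tmp.c_in, tmp.c_out, tmp.k, tmp.ndim = self.c_out, self.c_in, self.k, self.ndim
        cols = Conv._im2col(tmp, dout)
        dx = cols @ Wt.reshape(self.c_in, -1).T
        dx = dx.reshape((n,) + self._spatial + (self.c_in,))
        return np.moveaxis(dx, -1, 1)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m


class AvgPool2(Layer):
    """Factor-2 average pooling along every spatial axis (sizes must be even)."""

    def forward(self, x):
        nd = x.ndim - 2
        self._shape = x.shape
        shp = list(x.shape[:2])
        for s in x.shape[2:]:
            if s % 2:
                raise ValueError(f"AvgPool2 needs even spatial sizes, got {x.shape}")
            shp += [s // 2, 2]
        xr = x.reshape(shp)
        return xr.mean(axis=tuple(range(3, 3 + 2 * nd, 2)))

    def backward(self, dout):
        nd = dout.ndim - 2
        out = dout / (2**nd)
        for ax in range(2, 2 + nd):
            out = np.repeat(out, 2, axis=ax)
        return out


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._spatial = x.shape[2:]
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dout):
        scale = 1.0 / float(np.prod(self._spatial))
        out = dout * scale
        return out.reshape(out.shape + (1,) * len(self._spatial)) * np.ones(
            out.shape + self._spatial
        )


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(1.0 / d_in), size=(d_out, d_in))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def zero_grad(self):
        for l in self.layers:
            for g in l.grads():
                g[...] = 0.0

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


class Adam:
    """Adam with decoupled weight decay (AdamW when weight_decay > 0)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            if self.wd:
                p -= self.lr * self.wd * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
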