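"""Minimal NumPy neural-network primitives with explicit backprop.

Implements exactly the pieces the conditional encoder-decoder needs:
strided 2D convolution (im2col + BLAS matmul), conditional instance
normalization, ReLU, inverted dropout, nearest-neighbour up-sampling and
the Adam optimizer.  Forward passes cache what the matching ``backward``
needs; parameter gradients accumulate in ``grads`` until the optimizer
step consumes them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ConditionalInstanceNorm",
    "ReLU",
    "Dropout",
    "upsample_nearest",
    "downsample_sum",
    "avg_pool",
    "Adam",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    return np.ascontiguousarray(cols.reshape(n, c * k * k, ho * wo)), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    x = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


class Conv2d:
    """2D convolution with He-initialized weights (optionally zero-init)."""

    def __init__(self, c_in, c_out, k=3, stride=1, pad=None, rng=None, zero_init=False):
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((c_out, c_in * k * k))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / (c_in * k * k)), (c_out, c_in * k * k))
        self.w = w.astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}
        self._cache = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("oc,ncp->nop", self.w, cols, optimize=True)
        out += self.b[None, :, None]
        self._cache = (cols, x.shape, ho, wo)
        n = x.shape[0]
        return out.reshape(n, -1, ho, wo)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        n = gout.shape[0]
        g = gout.reshape(n, -1, ho * wo)
        self.grads["w"] += np.einsum("nop,ncp->oc", g, cols, optimize=True)
        self.grads["b"] += g.sum(axis=(0, 2))
        gcols = np.einsum("oc,nop->ncp", self.w, g, optimize=True)
        return _col2im(gcols, x_shape, self.k, self.stride, self.pad)


class ConditionalInstanceNorm:
    """Instance normalization with per-condition scale/shift tables.

    ``gamma``/``beta`` hold one per-channel pair for every condition; the
    active condition selects the row, so a single set of convolutional
    features serves all reconstruction objectives.
    """

    def __init__(
        self,
        channels: int,
        n_conditions: int = 4,
        eps: float = 1e-5,
        init_spread: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        # init_spread > 0 breaks the symmetry between conditions at t = 0,
        # so the per-condition feature statistics diverge immediately
        # instead of waiting for the slow drift of identical tables
        self.gamma = np.ones((n_conditions, channels), dtype=np.float32)
        self.beta = np.zeros((n_conditions, channels), dtype=np.float32)
        if init_spread > 0:
            rng = rng or np.random.default_rng(0)
            self.gamma += rng.normal(0, init_spread, self.gamma.shape).astype(np.float32)
            self.beta += rng.normal(0, init_spread, self.beta.shape).astype(np.float32)
        self.eps = eps
        self.grads = {"gamma": np.zeros_like(self.gamma), "beta": np.zeros_like(self.beta)}
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, cond_idx: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        g = self.gamma[cond_idx][:, :, None, None]
        b = self.beta[cond_idx][:, :, None, None]
        self._cache = (xhat, inv, g, cond_idx)
        return g * xhat + b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, g, cond_idx = self._cache
        np.add.at(self.grads["gamma"], cond_idx, (gout * xhat).sum(axis=(2, 3)))
        np.add.at(self.grads["beta"], cond_idx, gout.sum(axis=(2, 3)))
        gxhat = gout * g
        m = xhat.shape[2] * xhat.shape[3]
        # standard instance-norm backward per sample/channel
        return (
            gxhat
            - gxhat.mean(axis=(2, 3), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(2, 3), keepdims=True)
        ) * inv


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Dropout:
    """Inverted dropout: ``retention`` is the keep probability."""

    def __init__(self, retention: float = 0.5):
        if not 0 < retention <= 1:
            raise ValueError("retention must be in (0, 1]")
        self.retention = retention
        self._mask = None

    def forward(self, x, rng: np.random.Generator, train: bool):
        if not train or self.retention == 1.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) < self.retention) / self.retention
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


def upsample_nearest(x: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return x
    return x.repeat(factor, axis=2).repeat(factor, axis=3)


def downsample_sum(g: np.ndarray, factor: int) -> np.ndarray:
    """Adjoint of nearest-neighbour up-sampling (sums each block)."""
    if factor == 1:
        return g
    n, c, h, w = g.shape
    return g.reshape(n, c, h // factor, factor, w // factor, factor).sum(axis=(3, 5))


def avg_pool(x: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return x
    n, c, h, w = x.shape
    return x.reshape(n, c, h // factor, factor, w // factor, factor).mean(axis=(3, 5))


class Adam:
    """Adam over a dict of named parameter arrays (shared references)."""

    def __init__(self, params: dict, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
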