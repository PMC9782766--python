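"""Minimal 3D neural-network layers with analytic backpropagation.

Everything operates on a single sample laid out channel-first, ``(C, D, H, W)``
— instance normalization makes per-sample processing equivalent to batched
processing, so batches are handled by gradient accumulation in the trainer.
Convolution is im2col + matmul; its backward pass scatters column gradients
back with strided slice-adds. All layers are gradient-checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3d", "InstanceNorm3d", "LeakyReLU", "Upsample2x", "Sigmoid"]


class Conv3d:
    """3D convolution (cross-correlation) with cubic kernel, optional stride.

    Weights are He-initialized for leaky-ReLU fan-in. ``pad`` defaults to
    ``k // 2`` so stride-1 convolutions preserve the spatial grid.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        leaky_slope: float = 0.01,
        dtype=np.float32,
    ) -> None:
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        fan_in = cin * k**3
        std = np.sqrt(2.0 / (fan_in * (1.0 + leaky_slope**2)))
        self.w = rng.normal(0.0, std, size=(cout, cin, k, k, k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::s, ::s, ::s]
        do, ho, wo = win.shape[1:4]
        # (N, cin*k^3) with N = do*ho*wo; copy made by reshape of the view
        cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(do * ho * wo, c * k**3)
        wm = self.w.reshape(self.cout, c * k**3)
        y = cols @ wm.T + self.b
        self._cache = (cols, x.shape, (do, ho, wo))
        return np.ascontiguousarray(y.T.reshape(self.cout, do, ho, wo))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, (do, ho, wo) = self._cache
        c, d, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dym = dy.reshape(self.cout, do * ho * wo).T  # (N, cout)
        # accumulate so a batch can be backpropagated case by case
        self.dw += (dym.T @ cols).reshape(self.w.shape)
        self.db += dym.sum(axis=0)
        dcols = (dym @ self.w.reshape(self.cout, -1)).reshape(
            do, ho, wo, c, k, k, k
        )
        dxp = np.zeros((c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        dcols = dcols.transpose(3, 4, 5, 6, 0, 1, 2)  # (c, k, k, k, do, ho, wo)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    dxp[
                        :,
                        kd : kd + s * do : s,
                        kh : kh + s * ho : s,
                        kw : kw + s * wo : s,
                    ] += dcols[:, kd, kh, kw]
        self._cache = None
        return dxp[:, p : p + d, p : p + h, p : p + w]


class InstanceNorm3d:
    """Per-channel normalization over the spatial grid with learnable affine.

    Statistics are computed per sample per channel, so inference is
    independent of batch composition (the reason this family of networks
    prefers it over batch normalization at batch size 1).
    """

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32) -> None:
        self.channels = channels
        self.eps = eps
        self.g = np.ones(channels, dtype=dtype)
        self.b = np.zeros(channels, dtype=dtype)
        self.dg = np.zeros_like(self.g)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    @property
    def n_params(self) -> int:
        return self.g.size + self.b.size

    def params(self):
        return [("g", self.g, self.dg), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = (1, 2, 3)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.g[:, None, None, None] * xhat + self.b[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        ax = (1, 2, 3)
        self.dg += (dy * xhat).sum(axis=ax)
        self.db += dy.sum(axis=ax)
        dxhat = dy * self.g[:, None, None, None]
        m1 = dxhat.mean(axis=ax, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=ax, keepdims=True)
        self._cache = None
        return inv_std * (dxhat - m1 - xhat * m2)


class LeakyReLU:
    """Elementwise ``max(x, slope * x)``."""

    def __init__(self, slope: float = 0.01) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    n_params = 0

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return g


class Upsample2x:
    """Nearest-neighbor upsampling by a factor of two along each spatial axis."""

    n_params = 0

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = dy.shape
        return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class Sigmoid:
    """Elementwise logistic output nonlinearity."""

    n_params = 0

    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        # clip to avoid overflow in exp at extreme logits
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        self._y = None
        return dy * y * (1.0 - y)
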