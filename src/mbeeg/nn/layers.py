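"""Plain (directly materialized) layers.

These cover everything downstream of a branch's entry block — pooling,
batch-norm, activations, the separable convolution, dropout, dense — plus
straightforward temporal/spatial convolutions.  The straightforward
convolutions serve two roles: they build the band-power-style shallow
branch (whose tensors are small after pooling), and they provide a naive
reference path against which the FFT-fused entry block of the EEGNet-style
branch is validated.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Layer, Param, glorot_uniform

__all__ = [
    "TemporalConv",
    "DepthwiseSpatialConv",
    "SpatialConv",
    "BatchNorm",
    "ELU",
    "Square",
    "LogActivation",
    "AvgPool",
    "Dropout",
    "SeparableConv",
    "Flatten",
    "Dense",
    "max_norm_constraint",
]


def max_norm_constraint(max_value: float):
    """Per-spatial-filter max-norm renormalization (optional, EEGNet lineage)."""

    def apply(w: np.ndarray) -> np.ndarray:
        # norm over the electrode axis (first axis)
        norms = np.sqrt((w**2).sum(axis=0, keepdims=True))
        return w * np.minimum(1.0, max_value / np.maximum(norms, 1e-12))

    return apply


def _same_pad(kernel: int) -> tuple[int, int]:
    left = (kernel - 1) // 2
    return left, kernel - 1 - left


class TemporalConv(Layer):
    """1 x KE convolution along time, one filter bank shared by all electrodes.

    Input ``(N, E, T)`` -> output ``(N, E, T', F)``; ``padding`` is
    ``"same"`` (T' = T) or ``"valid"`` (T' = T - KE + 1).  Bias-free.
    """

    def __init__(self, n_filters: int, kernel: int, padding: str = "same",
                 name: str = "temporal_conv", rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.padding = padding
        self.w = Param(name + "/w", glorot_uniform(rng, (kernel, n_filters), kernel, kernel * n_filters, dtype))

    def params(self):
        return [self.w]

    def forward(self, x, training=False, rng=None):
        if self.padding == "same":
            l, r = _same_pad(self.kernel)
            x = np.pad(x, ((0, 0), (0, 0), (l, r)))
        self._x = x
        win = sliding_window_view(x, self.kernel, axis=2)  # (N,E,T',KE)
        return np.einsum("netk,kf->netf", win, self.w.value, optimize=True)

    def backward(self, dy):
        win = sliding_window_view(self._x, self.kernel, axis=2)
        self.w.grad += np.einsum("netk,netf->kf", win, dy, optimize=True)
        # full correlation for dx
        n, e, tp, f = dy.shape
        dxp = np.zeros(self._x.shape, dtype=dy.dtype)
        wv = self.w.value
        for k in range(self.kernel):
            dxp[:, :, k : k + tp] += dy @ wv[k]
        if self.padding == "same":
            l, r = _same_pad(self.kernel)
            return dxp[:, :, l : dxp.shape[2] - r]
        return dxp


class DepthwiseSpatialConv(Layer):
    """E x 1 depthwise convolution across electrodes, multiplier ``D``.

    Input ``(N, E, T, F)`` -> output ``(N, T, F*D)`` (electrode axis fully
    collapsed; output feature ``f*D + d``).  Bias-free.
    """

    def __init__(self, n_channels: int, in_filters: int, depth_multiplier: int = 2,
                 max_norm: float | None = None, name: str = "depthwise_spatial", rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        shape = (n_channels, in_filters, depth_multiplier)
        constraint = max_norm_constraint(max_norm) if max_norm else None
        self.w = Param(name + "/w", glorot_uniform(rng, shape, n_channels, n_channels * depth_multiplier, dtype),
                       constraint=constraint)

    def params(self):
        return [self.w]

    def forward(self, x, training=False, rng=None):
        self._x = x
        out = np.einsum("netf,efd->ntfd", x, self.w.value, optimize=True)
        n, t = out.shape[:2]
        return out.reshape(n, t, -1)

    def backward(self, dy):
        e, f, d = self.w.value.shape
        dyr = dy.reshape(dy.shape[0], dy.shape[1], f, d)
        self.w.grad += np.einsum("netf,ntfd->efd", self._x, dyr, optimize=True)
        return np.einsum("ntfd,efd->netf", dyr, self.w.value, optimize=True)


class SpatialConv(Layer):
    """E x 1 full spatial convolution mixing all input filters.

    Input ``(N, E, T, F)`` -> output ``(N, T, G)``.  Bias-free.
    """

    def __init__(self, n_channels: int, in_filters: int, out_filters: int,
                 name: str = "spatial_conv", rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        shape = (n_channels, in_filters, out_filters)
        self.w = Param(name + "/w", glorot_uniform(rng, shape, n_channels * in_filters, out_filters, dtype))

    def params(self):
        return [self.w]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return np.einsum("netf,efg->ntg", x, self.w.value, optimize=True)

    def backward(self, dy):
        self.w.grad += np.einsum("netf,ntg->efg", self._x, dy, optimize=True)
        return np.einsum("ntg,efg->netf", dy, self.w.value, optimize=True)


class BatchNorm(Layer):
    """Batch normalization over the trailing feature axis.

    Training uses batch statistics (biased variance) and updates running
    statistics with ``momentum``; inference uses the running statistics.
    Two trainable parameters (scale, shift) per feature map.
    """

    def __init__(self, n_features: int, momentum: float = 0.99, eps: float = 1e-3,
                 name: str = "bn", dtype=np.float32):
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(name + "/gamma", np.ones(n_features, dtype))
        self.beta = Param(name + "/beta", np.zeros(n_features, dtype))
        self.running_mean = np.zeros(n_features, dtype)
        self.running_var = np.ones(n_features, dtype)

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    @staticmethod
    def _moments(x):
        # single-pass einsum reductions (faster than mean/var on big arrays)
        flat = x.reshape(-1, x.shape[-1])
        n = flat.shape[0]
        s = np.einsum("nc->c", flat, dtype=np.float64)
        s2 = np.einsum("nc,nc->c", flat, flat, dtype=np.float64)
        mu = s / n
        return mu, np.maximum(s2 / n - mu**2, 0.0)

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu, var = self._moments(x)
            mu = mu.astype(x.dtype)
            var = var.astype(x.dtype)
            self.running_mean += (1 - self.momentum) * (mu - self.running_mean)
            self.running_var += (1 - self.momentum) * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv.astype(x.dtype), training, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, training, shape = self._cache
        c = dy.shape[-1]
        dyf = dy.reshape(-1, c)
        xf = xhat.reshape(-1, c)
        dbeta = np.einsum("nc->c", dyf)
        dgamma = np.einsum("nc,nc->c", dyf, xf)
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        if not training:
            return dy * (self.gamma.value * inv)
        m = dyf.shape[0]
        return (self.gamma.value * inv) * (dy - dbeta / m - xhat * (dgamma / m))


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def forward(self, x, training=False, rng=None):
        out = x.copy()
        neg = x < 0
        out[neg] = np.expm1(x[neg])  # expm1 only where needed; it dominates otherwise
        self._out = out
        return out

    def backward(self, dy):
        return dy * np.where(self._out > 0, 1.0, self._out + 1.0)


class Square(Layer):
    def forward(self, x, training=False, rng=None):
        self._x = x
        return x * x

    def backward(self, dy):
        return 2.0 * self._x * dy


class LogActivation(Layer):
    """``log(max(x, eps))`` — safe log of pooled power."""

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def forward(self, x, training=False, rng=None):
        clipped = np.maximum(x, self.eps)
        self._mask = (x > self.eps).astype(x.dtype)
        self._clipped = clipped
        return np.log(clipped)

    def backward(self, dy):
        return dy * self._mask / self._clipped


class AvgPool(Layer):
    """Average pooling along the time axis (axis 1) of ``(N, T, C)``.

    Non-overlapping when ``stride`` is omitted (``stride = length``);
    overlapping windows (e.g. 75 with stride 15) are supported.  Trailing
    samples that do not fill a window are dropped.
    """

    def __init__(self, length: int, stride: int | None = None):
        self.length = length
        self.stride = stride if stride is not None else length

    def out_length(self, t: int) -> int:
        return (t - self.length) // self.stride + 1

    def forward(self, x, training=False, rng=None):
        n, t, c = x.shape
        tout = self.out_length(t)
        if tout < 1:
            raise ValueError(f"pool length {self.length} collapses time axis of {t}")
        self._in_shape = x.shape
        if self.stride == self.length:
            win = x[:, : tout * self.length].reshape(n, tout, self.length, c)
            return np.einsum("ntpc->ntc", win) * (1.0 / self.length)
        cs = np.concatenate([np.zeros((n, 1, c), x.dtype), np.cumsum(x, axis=1)], axis=1)
        idx = np.arange(tout) * self.stride
        return (cs[:, idx + self.length] - cs[:, idx]) / self.length

    def backward(self, dy):
        n, t, c = self._in_shape
        tout = dy.shape[1]
        dx = np.zeros((n, t, c), dy.dtype)
        if self.stride == self.length:
            dx[:, : tout * self.length] = np.repeat(dy / self.length, self.length, axis=1)
            return dx
        for j in range(tout):
            dx[:, j * self.stride : j * self.stride + self.length] += dy[:, j : j + 1] / self.length
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference or rate 0."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class SeparableConv(Layer):
    """Depthwise temporal convolution (same padding) + 1x1 pointwise mix.

    Input ``(N, T, C)`` -> ``(N, T, F2)``.  Bias-free, as in the compact
    EEGNet lineage.
    """

    def __init__(self, in_features: int, out_features: int, kernel: int = 16,
                 name: str = "separable", rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.wd = Param(name + "/depthwise", glorot_uniform(rng, (kernel, in_features), kernel, kernel, dtype))
        self.wp = Param(name + "/pointwise", glorot_uniform(rng, (in_features, out_features), in_features, out_features, dtype))

    def params(self):
        return [self.wd, self.wp]

    def forward(self, x, training=False, rng=None):
        l, r = _same_pad(self.kernel)
        xp = np.pad(x, ((0, 0), (l, r), (0, 0)))
        self._xp = xp
        t = x.shape[1]
        h = np.zeros_like(x)
        for k in range(self.kernel):  # shifted-slice accumulation beats strided windows
            h += xp[:, k : k + t] * self.wd.value[k]
        self._h = h
        return h @ self.wp.value

    def backward(self, dy):
        n, t, _ = dy.shape
        self.wp.grad += np.tensordot(self._h, dy, axes=([0, 1], [0, 1]))
        dh = dy @ self.wp.value.T
        l, r = _same_pad(self.kernel)
        dxp = np.zeros(self._xp.shape, dy.dtype)
        for k in range(self.kernel):
            self.wd.grad[k] += np.einsum("ntc,ntc->c", self._xp[:, k : k + t], dh)
            dxp[:, k : k + t] += dh * self.wd.value[k]
        return dxp[:, l : dxp.shape[1] - r]


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with bias."""

    def __init__(self, in_features: int, out_features: int, name: str = "dense", rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.w = Param(name + "/w", glorot_uniform(rng, (in_features, out_features), in_features, out_features, dtype))
        self.b = Param(name + "/b", np.zeros(out_features, dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T
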