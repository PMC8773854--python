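"""FFT-domain fused entry block: temporal conv -> batch-norm -> depthwise spatial conv.

The first three stages of an EEGNet-style branch are, for fixed batch
statistics, a linear map of the input.  Materializing the intermediate
``(N, E, T, F1)`` tensor dominates the cost of a training step at EEG
scale (22 electrodes x 1125 samples), so this layer never forms it:

* the temporal convolution (same padding, bias-free) and the electrode
  collapse of the depthwise spatial convolution are composed in the
  frequency domain; only the collapsed ``(N, F1*D, T)`` tensor is ever
  inverse-transformed;
* the batch-norm statistics of the unmaterialized temporal-conv output
  are recovered exactly from the signal's autocorrelation (a Gram matrix
  of lagged products) and windowed sums, both cheap by FFT/cumsum;
* batch-norm then enters as a per-map affine correction applied after the
  electrode collapse.

Gradients for all parameters (temporal kernels, batch-norm scale/shift,
depthwise weights) are likewise evaluated spectrally, including the paths
through the batch statistics.  The input gradient is not computed — this
is always the first layer of a branch.

Equivalence with the naive path (``TemporalConv`` -> ``BatchNorm`` ->
``DepthwiseSpatialConv``) is asserted by the test-suite, for outputs and
for gradients.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

from .core import Layer, Param, glorot_uniform
from .layers import max_norm_constraint

__all__ = ["FusedEntry"]


def _same_pad_left(kernel: int) -> int:
    return (kernel - 1) // 2


class FusedEntry(Layer):
    """Temporal conv (1xKE, F1 maps) + BN + depthwise spatial conv (Ex1, D).

    Input ``(N, E, T)`` -> output ``(N, T, F1*D)`` with output feature
    index ``f*D + d``.  ``fft_length`` may be shared across branches so a
    single rfft of the input batch serves all kernel sizes.
    """

    def __init__(
        self,
        n_channels: int,
        n_samples: int,
        n_filters: int,
        kernel: int,
        depth_multiplier: int = 2,
        fft_length: int | None = None,
        momentum: float = 0.99,
        eps: float = 1e-3,
        max_norm: float | None = None,
        name: str = "entry",
        rng=None,
        dtype=np.float32,
    ):
        if kernel > n_samples:
            raise ValueError(f"kernel {kernel} exceeds {n_samples} samples")
        rng = rng or np.random.default_rng(0)
        self.E, self.T, self.F1, self.KE, self.D = n_channels, n_samples, n_filters, kernel, depth_multiplier
        self.L = fft_length or sfft.next_fast_len(n_samples + kernel - 1, real=True)
        if self.L < n_samples + kernel - 1:
            raise ValueError("fft_length too short for linear convolution")
        self.momentum, self.eps = momentum, eps
        self.wt = Param(name + "/temporal/w",
                        glorot_uniform(rng, (kernel, n_filters), kernel, kernel * n_filters, dtype))
        self.gamma = Param(name + "/bn/gamma", np.ones(n_filters, dtype))
        self.beta = Param(name + "/bn/beta", np.zeros(n_filters, dtype))
        constraint = None
        if max_norm:
            base = max_norm_constraint(max_norm)
            constraint = lambda w: base(w.reshape(self.E, -1)).reshape(w.shape)
        self.wdw = Param(name + "/depthwise/w",
                         glorot_uniform(rng, (n_channels, n_filters, depth_multiplier),
                                        n_channels, n_channels * depth_multiplier, dtype),
                         constraint=constraint)
        self.running_mean = np.zeros(n_filters, dtype)
        self.running_var = np.ones(n_filters, dtype)
        # spectral quadrature weights for Parseval inner products
        l2 = self.L // 2 + 1
        w = np.full(l2, 2.0)
        w[0] = 1.0
        if self.L % 2 == 0:
            w[-1] = 1.0
        self._specw = w

    # ------------------------------------------------------------------
    def params(self):
        return [self.wt, self.gamma, self.beta, self.wdw]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    # -- helpers -------------------------------------------------------
    def input_spectrum(self, x: np.ndarray) -> np.ndarray:
        """rfft of the raw input batch, laid out ``(N, E, L2)``."""
        return sfft.rfft(x, n=self.L, axis=-1)

    def _batch_stats(self, x: np.ndarray, xf: np.ndarray):
        """Exact mean/variance of the unmaterialized temporal-conv output.

        Returns ``(mu, var, s1, gram)`` where ``s1[k]`` is the windowed
        input sum feeding kernel tap ``k`` and ``gram[k, k']`` the lagged
        product sums, so that ``sum(y) = s1 @ wt`` and
        ``sum(y^2) = wt^T gram wt`` per filter.
        """
        n, e, t = x.shape
        ke, l = self.KE, _same_pad_left(self.KE)
        # windowed sums: S1[k] = sum over (n,e,t) of padded x[t + k]
        cs = np.zeros(t + 1)
        np.cumsum(x.sum(axis=(0, 1), dtype=np.float64), out=cs[1:])
        k = np.arange(ke)
        s1 = cs[np.minimum(t, k - l + t)] - cs[np.maximum(0, k - l)]

        # lagged-product Gram matrix
        if t >= 2 * ke:
            gram = self._gram_fft(x, xf)
        else:  # tiny inputs: direct evaluation
            xp = np.pad(x, ((0, 0), (0, 0), (l, ke - 1 - l))).astype(np.float64)
            from numpy.lib.stride_tricks import sliding_window_view
            win = sliding_window_view(xp, ke, axis=2)
            gram = np.einsum("netk,netj->kj", win, win, optimize=True)

        m = float(n * e * t)
        s_f = s1 @ self.wt.value.astype(np.float64)
        m2_f = np.einsum("kf,kj,jf->f", self.wt.value, gram, self.wt.value, optimize=True)
        mu = s_f / m
        var = np.maximum(m2_f / m - mu**2, 0.0)
        return mu, var, s1, gram

    def _gram_fft(self, x: np.ndarray, xf: np.ndarray) -> np.ndarray:
        """Gram of lagged products via autocorrelation + edge corrections."""
        n, e, t = x.shape
        ke, l = self.KE, _same_pad_left(self.KE)
        # full autocorrelation at lags 0..KE-1 (linear: L >= T + KE - 1)
        power = np.einsum("new,new->w", xf, np.conj(xf), dtype=np.complex128).real
        rr = sfft.irfft(power, n=self.L)[:ke]

        # edge segments of the conceptually padded signal (length 2*KE each)
        seg = 2 * ke
        hseg = np.zeros((n * e, seg))
        hseg[:, l:] = x.reshape(n * e, t)[:, : seg - l]
        tseg = np.zeros((n * e, seg))
        m = ke + 1 + l
        tseg[:, :m] = x.reshape(n * e, t)[:, t - m :]
        hout = hseg.T @ hseg
        tout = tseg.T @ tseg

        gram = np.empty((ke, ke))
        for d in range(ke):
            hd = np.diagonal(hout, offset=d)  # head products along lag d
            td = np.diagonal(tout, offset=d)
            head = np.concatenate([[0.0], np.cumsum(hd[: ke - 1])])  # head(k,d), k=0..KE-1
            # tail(k,d) = sum_{j=k+KE+1}^{2KE-1-d} tout[j, j+d]
            tail_rev = np.concatenate([np.cumsum(td[::-1])[::-1], [0.0]])
            idx = np.minimum(np.arange(ke) + ke + 1, td.shape[0])
            vals = rr[d] - head[:ke] - tail_rev[idx]
            ii = np.arange(ke - d)
            gram[ii, ii + d] = vals[: ke - d]
            gram[ii + d, ii] = vals[: ke - d]
        return gram

    # -- forward -------------------------------------------------------
    def forward(self, x, training=False, rng=None, xf=None):
        n = x.shape[0]
        if x.shape[1:] != (self.E, self.T):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match the built ({self.E}, {self.T})"
            )
        if xf is None:
            xf = self.input_spectrum(x)
        fd = self.F1 * self.D
        wf = sfft.rfft(self.wt.value, n=self.L, axis=0)                 # (L2, F1)
        wfc_fd = np.repeat(np.conj(wf).T, self.D, axis=0)               # (FD, L2)

        # electrode collapse + temporal filtering, all spectral
        wdw_c = self.wdw.value.reshape(self.E, fd).T.astype(xf.dtype)   # (FD, E)
        u = np.matmul(wdw_c[None], xf)                                  # (N, FD, L2)
        a = sfft.irfft(u * wfc_fd[None], n=self.L, axis=-1)             # (N, FD, L)
        a = np.roll(a, _same_pad_left(self.KE), axis=-1)[..., : self.T]
        a = np.ascontiguousarray(a.transpose(0, 2, 1), dtype=x.dtype)   # (N, T, FD)

        if training:
            mu, var, s1, gram = self._batch_stats(x, xf)
            self.running_mean += ((1 - self.momentum) * (mu - self.running_mean)).astype(self.running_mean.dtype)
            self.running_var += ((1 - self.momentum) * (var - self.running_var)).astype(self.running_var.dtype)
        else:
            mu, var = self.running_mean.astype(np.float64), self.running_var.astype(np.float64)
            s1 = gram = None

        sigma = np.sqrt(var + self.eps)
        wsum = self.wdw.value.sum(axis=0).reshape(fd)                   # (FD,)
        scale = self.gamma.value / sigma                                # (F1,)
        shift = self.beta.value - self.gamma.value * mu / sigma         # (F1,)
        scale_fd = np.repeat(scale, self.D).astype(x.dtype)
        shift_fd = (np.repeat(shift, self.D) * wsum).astype(x.dtype)
        out = a * scale_fd + shift_fd

        self._cache = dict(x=x, xf=xf, u=u, a=a, wf=wf, mu=mu, sigma=sigma, s1=s1,
                           gram=gram, wsum=wsum, training=training)
        return out

    # -- backward ------------------------------------------------------
    def backward(self, dz):
        c = self._cache
        n, t, fd = dz.shape
        f1, d, ke, l = self.F1, self.D, self.KE, _same_pad_left(self.KE)
        mu, sigma, wsum = c["mu"], c["sigma"], c["wsum"]
        gamma = self.gamma.value.astype(np.float64)

        s_z = np.einsum("ntk->k", dz, dtype=np.float64)                 # (FD,)
        s_az = np.einsum("ntk,ntk->k", dz, c["a"], dtype=np.float64)    # (FD,)
        wz = (wsum * s_z).reshape(f1, d).sum(axis=1)                    # per f
        az = s_az.reshape(f1, d).sum(axis=1)

        self.beta.grad += wz.astype(self.beta.grad.dtype)
        dgamma = (az - mu * wz) / sigma
        self.gamma.grad += dgamma.astype(self.gamma.grad.dtype)

        # spectrum of the gradient at the collapsed-conv output
        scale_fd = np.repeat(gamma / sigma, d)
        da = dz * scale_fd.astype(dz.dtype)
        buf = np.zeros((n, fd, self.L), dtype=dz.dtype)
        buf[:, :, :t] = da.transpose(0, 2, 1)
        buf = np.roll(buf, -l, axis=-1)
        dafc = np.conj(sfft.rfft(buf, axis=-1))                         # (N, FD, L2), conjugated

        # depthwise weights: spectral correlation with the input + wsum path
        specw = (self._specw / self.L).astype(c["a"].dtype)
        v1 = dafc * (np.repeat(np.conj(c["wf"]).T, d, axis=0) * specw)[None]
        dwdw = np.tensordot(c["xf"], v1, axes=([0, 2], [0, 2])).real    # (E, FD)
        shift = self.beta.value.astype(np.float64) - gamma * mu / sigma
        dwdw = dwdw + (np.repeat(shift, d) * s_z)[None, :]
        self.wdw.grad += dwdw.reshape(self.E, f1, d).astype(self.wdw.grad.dtype)

        # temporal kernels: spectral path + batch-statistics paths
        prod = np.einsum("nkw,nkw->kw", dafc, c["u"]).reshape(f1, d, -1).sum(axis=1)
        dwt = sfft.irfft(prod, n=self.L, axis=-1)[:, :ke].T             # (KE, F1)
        if c["training"]:
            m = float(c["x"].shape[0] * self.E * self.T)
            dmu = -(gamma / sigma) * wz
            dsigma = -(gamma / sigma**2) * (az - mu * wz)
            dvar = dsigma / (2.0 * sigma)
            s1, gram = c["s1"], c["gram"]
            gw = gram @ self.wt.value.astype(np.float64)                # (KE, F1)
            dwt = dwt + s1[:, None] * (dmu / m)[None, :]
            dwt = dwt + dvar[None, :] * (2.0 * gw - 2.0 * np.outer(s1, mu)) / m
        self.wt.grad += dwt.astype(self.wt.grad.dtype)
        return None  # entry layer: input gradient not propagated
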