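"""Minimal 1-D convolutional layer library with explicit backpropagation.

Arrays follow the (batch, channels, length) convention.  Each layer caches
what its backward pass needs, accumulates parameter gradients in ``.grads``
and returns the gradient with respect to its input.  All initialization is
drawn from a caller-supplied numpy Generator so whole models are reproducible
from a single seed.
"""

from __future__ import annotations

import numpy as np


def _im2col(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    # xp: (B, C, Lp) already padded -> (B, C, T, K)
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=-1)
    return win[:, :, ::stride, :]


def conv1d_forward(xp: np.ndarray, w: np.ndarray, stride: int):
    """y[b,o,t] = sum_{c,k} w[o,c,k] * xp[b,c,t*stride+k]. Returns (y, windows)."""
    win = _im2col(xp, w.shape[2], stride)
    y = np.einsum("ock,bctk->bot", w, win, optimize=True)
    return y, win


def conv1d_backward(dy: np.ndarray, win: np.ndarray, w: np.ndarray, stride: int, lp: int):
    """Gradients of a strided conv: returns (dxp, dw)."""
    dw = np.einsum("bot,bctk->ock", dy, win, optimize=True)
    b, _, t = dy.shape
    dxp = np.zeros((b, w.shape[1], lp))
    for k in range(w.shape[2]):
        contrib = np.einsum("bot,oc->bct", dy, w[:, :, k], optimize=True)
        dxp[:, :, k : k + stride * t : stride] += contrib
    return dxp, dw


class Layer:
    """Base: parameters/grads are dicts of same-shaped arrays."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def constrain(self):
        """Project parameters back to their valid domain (no-op by default)."""


class Conv1d(Layer):
    """Causal 1-D convolution: left zero-padding of (kernel-1) samples, so
    output bin t depends only on inputs at or before t*stride + kernel - 1
    of the padded axis (no future samples)."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.params["w"] = rng.standard_normal((out_ch, in_ch, kernel)) * scale
        if bias:
            self.params["b"] = np.zeros(out_ch)
        self.stride = stride
        self.kernel = kernel
        self.zero_grads()

    def forward(self, x):
        self._lp = x.shape[2] + self.kernel - 1
        xp = np.pad(x, ((0, 0), (0, 0), (self.kernel - 1, 0)))
        y, self._win = conv1d_forward(xp, self.params["w"], self.stride)
        if "b" in self.params:
            y = y + self.params["b"][None, :, None]
        return y

    def backward(self, dy):
        if "b" in self.params:
            self.grads["b"] += dy.sum(axis=(0, 2))
        dxp, dw = conv1d_backward(dy, self._win, self.params["w"], self.stride, self._lp)
        self.grads["w"] += dw
        return dxp[:, :, self.kernel - 1 :]


class SincConv(Layer):
    """Bank of parametric band-pass (windowed-sinc) filters applied causally.

    Learnable parameters are the low cut-off and bandwidth of each filter in
    normalized frequency (cycles/sample).  Cut-offs are initialized mel-spaced
    over [f_min, f_max] Hz and clamped to the valid band after each optimizer
    step via :meth:`constrain`.
    """

    F_MIN_NORM = 1e-4

    def __init__(self, n_filters, kernel, rate, f_min=50.0, f_max=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        f_max = f_max if f_max is not None else 0.45 * rate
        f_max = min(f_max, 0.45 * rate)

        def mel(f):
            return 2595.0 * np.log10(1.0 + f / 700.0)

        def imel(m):
            return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

        edges = imel(np.linspace(mel(f_min), mel(f_max), n_filters + 1))
        self.params["f_low"] = edges[:-1] / rate
        self.params["band"] = np.diff(edges) / rate
        self.kernel = kernel
        self._m = np.arange(kernel) - (kernel - 1) / 2.0
        self._window = np.hamming(kernel)
        self.zero_grads()

    def _kernels(self):
        f1 = self.params["f_low"]
        f2 = f1 + self.params["band"]
        m = self._m[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = (np.sin(2 * np.pi * f2[:, None] * m) - np.sin(2 * np.pi * f1[:, None] * m)) / (
                np.pi * m
            )
        center = self._m == 0
        h[:, center] = 2.0 * (f2 - f1)[:, None]
        return (h * self._window[None, :])[:, None, :]  # (F, 1, K)

    def forward(self, x):
        self._lp = x.shape[2] + self.kernel - 1
        xp = np.pad(x, ((0, 0), (0, 0), (self.kernel - 1, 0)))
        w = self._kernels()
        self._w = w
        y, self._win = conv1d_forward(xp, w, 1)
        return y

    def backward(self, dy):
        dxp, dw = conv1d_backward(dy, self._win, self._w, 1, self._lp)
        dw = dw[:, 0, :]  # (F, K)
        f1 = self.params["f_low"]
        f2 = f1 + self.params["band"]
        m = self._m[None, :]
        dh_df2 = 2.0 * np.cos(2 * np.pi * f2[:, None] * m) * self._window[None, :]
        dh_df1 = -2.0 * np.cos(2 * np.pi * f1[:, None] * m) * self._window[None, :]
        # d kernel / d f_low = dh_df1 + dh_df2 (f2 = f_low + band); d/d band = dh_df2
        self.grads["f_low"] += np.sum(dw * (dh_df1 + dh_df2), axis=1)
        self.grads["band"] += np.sum(dw * dh_df2, axis=1)
        return dxp[:, :, self.kernel - 1 :]

    def constrain(self):
        band_min = self.F_MIN_NORM
        np.clip(np.abs(self.params["band"], out=self.params["band"]), band_min, 0.5,
                out=self.params["band"])
        np.clip(np.abs(self.params["f_low"], out=self.params["f_low"]), self.F_MIN_NORM,
                0.5 - self.params["band"] - 1e-3, out=self.params["f_low"])


class PReLU(Layer):
    """Parametric rectifier, one learnable slope per channel (init 0.25)."""

    def __init__(self, n_ch, init=0.25):
        super().__init__()
        self.params["a"] = np.full(n_ch, float(init))
        self.zero_grads()

    def forward(self, x):
        self._x = x
        a = self.params["a"][None, :, None]
        return np.where(x > 0, x, a * x)

    def backward(self, dy):
        x = self._x
        self.grads["a"] += np.sum(np.where(x > 0, 0.0, x) * dy, axis=(0, 2))
        a = self.params["a"][None, :, None]
        return np.where(x > 0, dy, a * dy)


class SymLog(Layer):
    """Symmetric logarithmic activation y = sgn(x) * log(|x| + 1)."""

    def forward(self, x):
        self._x = x
        return np.sign(x) * np.log1p(np.abs(x))

    def backward(self, dy):
        return dy / (1.0 + np.abs(self._x))


class Crop(Layer):
    """Remove the first ``n`` time samples (left-context removal)."""

    def __init__(self, n):
        super().__init__()
        self.n = n

    def forward(self, x):
        self._l = x.shape[2]
        return x[:, :, self.n :]

    def backward(self, dy):
        dx = np.zeros(dy.shape[:2] + (self._l,))
        dx[:, :, self.n :] = dy
        return dx


def symmetric_log(x):
    """Functional form of the symmetric log activation (odd, monotone, y(0)=0)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x))
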