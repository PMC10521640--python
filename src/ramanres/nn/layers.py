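"""Layers: 1-D convolution (im2col + GEMM), batch normalization, ReLU,
inverted dropout, and a dense head.  Forward caches the minimum needed for
an exact analytic backward pass; ``backward`` returns the input gradient
and fills ``.grads``."""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Module", "Conv1d", "BatchNorm1d", "ReLU", "Dropout", "Linear", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Module:
    """Base class: parameter/gradient dicts plus train/eval forward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Module):
    """1-D convolution with 'same' padding semantics for stride 1.

    Weight layout is (out_channels, in_channels * kernel); the forward pass
    flattens the batch into one (C_in*k) x (N*L_out) GEMM.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int = 1, rng: Optional[np.random.Generator] = None,
                 dtype=np.float32) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        w = rng.standard_normal((out_channels, fan_in)) * np.sqrt(2.0 / fan_in)
        self.params = {"w": w.astype(dtype), "b": np.zeros(out_channels, dtype=dtype)}
        self._cols: Optional[np.ndarray] = None
        self._in_shape: Optional[tuple] = None

    def out_length(self, length: int) -> int:
        return (length + 2 * self.padding - self.kernel_size) // self.stride + 1

    def forward(self, x, training=False, rng=None):
        n, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        lout = self.out_length(length)
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]  # (N, C, Lout, k)
        cols = np.ascontiguousarray(win.transpose(1, 3, 0, 2)).reshape(c * k, n * lout)
        out = self.params["w"] @ cols + self.params["b"][:, None]
        self._cols = cols
        self._in_shape = (n, c, length)
        return np.ascontiguousarray(
            out.reshape(self.out_channels, n, lout).transpose(1, 0, 2)
        )

    def backward(self, dout):
        if self._cols is None:
            raise RuntimeError("backward before forward")
        n, c, length = self._in_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        lout = dout.shape[2]
        d2 = np.ascontiguousarray(dout.transpose(1, 0, 2)).reshape(self.out_channels, n * lout)
        self.grads["b"] = d2.sum(axis=1)
        self.grads["w"] = d2 @ self._cols.T
        dcols = self.params["w"].T @ d2                      # (C*k, N*Lout)
        dcols = dcols.reshape(c, k, n, lout).transpose(2, 0, 1, 3)
        dxp = np.zeros((n, c, length + 2 * p), dtype=dout.dtype)
        for j in range(k):
            dxp[:, :, j : j + s * lout : s] += dcols[:, :, j, :]
        self._cols = None
        return dxp[:, :, p : p + length] if p else dxp


class BatchNorm1d(Module):
    """Per-channel batch normalization over the (batch, length) axes.

    Training mode standardizes with batch statistics and updates running
    estimates; evaluation mode uses the running statistics.  epsilon is the
    usual variance stabilizer.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None
        self._stat_acc: Optional[list] = None  # [count, sum_mean, sum_var]

    def begin_stat_collection(self) -> None:
        self._stat_acc = [0, np.zeros(self.channels), np.zeros(self.channels)]

    def end_stat_collection(self) -> None:
        count, s_mu, s_var = self._stat_acc
        if count:
            self.running_mean = (s_mu / count).astype(self.running_mean.dtype)
            self.running_var = (s_var / count).astype(self.running_var.dtype)
        self._stat_acc = None

    def forward(self, x, training=False, rng=None):
        g = self.params["gamma"][None, :, None]
        b = self.params["beta"][None, :, None]
        if training:  # True or "calibrate": standardize with batch statistics
            if x.shape[0] < 2:
                raise ValueError("batch normalization needs batch size >= 2 in training mode")
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[None, :, None]) * inv[None, :, None]
            if training == "calibrate" and self._stat_acc is not None:
                self._stat_acc[0] += 1
                self._stat_acc[1] += mu
                self._stat_acc[2] += var
            else:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(self.running_mean.dtype)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
            self._cache = (xhat, inv, True)
            return g * xhat + b
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv.astype(x.dtype), False)
        return g * xhat + b

    def backward(self, dout):
        xhat, inv, was_training = self._cache
        g = self.params["gamma"]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * g[None, :, None]
        if not was_training:
            return dxhat * inv[None, :, None]
        m = dout.shape[0] * dout.shape[2]
        s1 = dxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
        return (inv[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Module):
    """Inverted dropout: active only in training mode, identity otherwise."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        # active only in genuine training mode, never during BN calibration
        if training is not True or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.standard_normal((in_features, out_features)) * np.sqrt(1.0 / in_features)
        self.params = {"w": w.astype(dtype), "b": np.zeros(out_features, dtype=dtype)}
        self._x = None

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T
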