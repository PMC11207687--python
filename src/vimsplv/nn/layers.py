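"""Feed-forward layers with explicit backward passes.

The convolutional stack runs in channels-last (NHWC) memory layout: all
im2col gathers then copy contiguous channel blocks instead of single
elements, which is what makes a pure-NumPy CNN trainable in reasonable
time.  Convolution is stride-1 im2col + GEMM; its input gradient is the
full correlation with the 180-degree-rotated kernels, realised through the
same im2col machinery.  All layers share a tiny protocol:
``forward(x, train)``, ``backward(dout) -> dx`` and ``params()`` yielding
(name, value, grad) triples for the optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "Dropout", "Linear"]


class Layer:
    """Base class; parameter-free layers only implement forward/backward."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        p = getattr(self, "p", None) or {}
        g = getattr(self, "g", {})
        return [(k, p[k], g[k]) for k in p]


def _im2col_nhwc(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, H, W, C) -> (B*Ho*Wo, k*k*C) patch matrix for stride-1 conv.

    Built from k*k bulk slice copies so the innermost (channel) axis is
    always copied contiguously.
    """
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    b, hp, wp, c = x.shape
    ho, wo = hp - k + 1, wp - k + 1
    cols = np.empty((b, ho, wo, k, k, c), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            cols[:, :, :, di, dj, :] = x[:, di:di + ho, dj:dj + wo, :]
    return cols.reshape(b * ho * wo, k * k * c)


class Conv2d(Layer):
    """kxk convolution, stride 1, 'same' padding by default (NHWC).

    ``first_layer=True`` skips the input-gradient computation (nothing
    upstream needs it).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 pad: int = 1, first_layer: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.k, self.pad = kernel, pad
        self.in_channels, self.out_channels = in_channels, out_channels
        self.first_layer = first_layer
        # weights stored as (k, k, C_in, C_out) to match the im2col order
        self.p = {
            "W": rng.uniform(-bound, bound,
                             (kernel, kernel, in_channels, out_channels)).astype(dtype),
            "b": rng.uniform(-bound, bound, out_channels).astype(dtype),
        }
        self.g = {k_: np.zeros_like(v) for k_, v in self.p.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, _ = x.shape
        self._in_shape = x.shape
        cols = _im2col_nhwc(x, self.k, self.pad)
        out = cols @ self.p["W"].reshape(-1, self.out_channels) + self.p["b"]
        self._cols = cols if train else None
        ho = h + 2 * self.pad - self.k + 1
        wo = w + 2 * self.pad - self.k + 1
        return out.reshape(b, ho, wo, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, ho, wo, f = dout.shape
        dflat = dout.reshape(-1, f)
        self.g["W"][...] = (self._cols.T @ dflat).reshape(self.p["W"].shape)
        self.g["b"][...] = dflat.sum(axis=0)
        self._cols = None
        if self.first_layer:
            return np.zeros(self._in_shape, dtype=dout.dtype)
        # dx = full correlation of dout with the rotated kernels:
        # W_rot[(di,dj),f,c] = W[k-1-di, k-1-dj, c, f]
        w_rot = self.p["W"][::-1, ::-1].transpose(0, 1, 3, 2)
        cols_d = _im2col_nhwc(dout, self.k, self.k - 1 - self.pad)
        dx = cols_d @ w_rot.reshape(-1, self.in_channels)
        return dx.reshape(self._in_shape)


class BatchNorm2d(Layer):
    """Per-feature-map batch normalization with running statistics (NHWC)."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.eps, self.momentum = eps, momentum
        self.p = {"gamma": np.ones(n_features, dtype), "beta": np.zeros(n_features, dtype)}
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}
        self.running_mean = np.zeros(n_features, dtype)
        self.running_var = np.ones(n_features, dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xf = x.reshape(-1, x.shape[-1])
        if train:
            m = xf.shape[0]
            mean = xf.mean(axis=0)
            var = np.einsum("ij,ij->j", xf, xf) / m - mean * mean
            var = np.maximum(var, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var * (m / max(m - 1, 1))
                                                 - self.running_var)
            self._istd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            xhat = np.subtract(x, mean.astype(x.dtype))
            np.multiply(xhat, self._istd, out=xhat)
            self._xhat = xhat
            return self.p["gamma"] * xhat + self.p["beta"]
        istd = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.p["gamma"] * ((x - self.running_mean) * istd) + self.p["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        df = dout.reshape(-1, dout.shape[-1])
        xf = self._xhat.reshape(-1, dout.shape[-1])
        m = df.shape[0]
        self.g["gamma"][...] = np.einsum("ij,ij->j", df, xf)
        self.g["beta"][...] = df.sum(axis=0)
        dx = np.multiply(dout, self.p["gamma"])
        np.subtract(dx, self.p["gamma"] * self.g["beta"] / m, out=dx)
        np.subtract(dx, self._xhat * (self.p["gamma"] * self.g["gamma"] / m), out=dx)
        np.multiply(dx, self._istd, out=dx)
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        self._mask = out > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 non-overlapping max pooling (NHWC); spatial dims must divide."""

    def __init__(self, size: int = 2):
        if size != 2:
            raise ValueError("only 2x2 pooling is supported")
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims ({h}, {w}) not divisible by pool size 2")
        xf = np.stack(
            (x[:, 0::2, 0::2], x[:, 0::2, 1::2], x[:, 1::2, 0::2], x[:, 1::2, 1::2]),
            axis=3,
        )  # (B, H/2, W/2, 4, C): channel runs stay contiguous
        idx = xf.argmax(axis=3)
        self._idx, self._shape = idx, x.shape
        return np.take_along_axis(xf, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        dx = np.zeros((b, h, w, c), dtype=dout.dtype)
        views = (dx[:, 0::2, 0::2], dx[:, 0::2, 1::2],
                 dx[:, 1::2, 0::2], dx[:, 1::2, 1::2])
        for q, view in enumerate(views):
            np.copyto(view, dout, where=self._idx == q)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.drop_p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.drop_p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.drop_p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.p = {
            "W": rng.uniform(-bound, bound, (in_features, out_features)).astype(dtype),
            "b": rng.uniform(-bound, bound, out_features).astype(dtype),
        }
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.p["W"] + self.p["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.g["W"][...] = self._x.T @ dout
        self.g["b"][...] = dout.sum(axis=0)
        dx = dout @ self.p["W"].T
        self._x = None
        return dx
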