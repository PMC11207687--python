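"""LSTM layer with explicit backpropagation through time.

One cell step, for input x_t and previous (h, c):

    f_t = sigmoid(W_fh h_{t-1} + W_fx x_t + b_f)      forget gate
    i_t = sigmoid(W_ih h_{t-1} + W_ix x_t + b_i)      input gate
    g_t = tanh   (W_gh h_{t-1} + W_gx x_t + b_g)      candidate state
    o_t = sigmoid(W_oh h_{t-1} + W_ox x_t + b_o)      output gate
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

The four gates are stored stacked in column blocks [f | i | g | o] of the
combined weight matrices Wx (D, 4H) and Wh (H, 4H).
"""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["LSTM", "lstm_step", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_step(
    wx: np.ndarray,
    wh: np.ndarray,
    b: np.ndarray,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
):
    """A single LSTM cell update; returns (h_t, c_t).

    ``wx`` is (D, 4H), ``wh`` is (H, 4H), ``b`` is (4H,), with gate blocks
    ordered [forget, input, candidate, output].  Inputs may be a single
    vector or a (batch, .) array.
    """
    hdim = wh.shape[0]
    a = x_t @ wx + h_prev @ wh + b
    f = sigmoid(a[..., :hdim])
    i = sigmoid(a[..., hdim:2 * hdim])
    g = np.tanh(a[..., 2 * hdim:3 * hdim])
    o = sigmoid(a[..., 3 * hdim:])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


class LSTM(Layer):
    """Sequence-to-sequence LSTM over inputs of shape (batch, time, features)."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(hidden_size)
        self.input_size, self.hidden_size = input_size, hidden_size
        self.p = {
            "Wx": rng.uniform(-bound, bound, (input_size, 4 * hidden_size)).astype(dtype),
            "Wh": rng.uniform(-bound, bound, (hidden_size, 4 * hidden_size)).astype(dtype),
            "b": rng.uniform(-bound, bound, 4 * hidden_size).astype(dtype),
        }
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        bsz, t, _ = x.shape
        hd = self.hidden_size
        h = np.zeros((bsz, hd), dtype=x.dtype)
        c = np.zeros((bsz, hd), dtype=x.dtype)
        hs = np.empty((bsz, t, hd), dtype=x.dtype)
        cache = []
        wx, wh, b = self.p["Wx"], self.p["Wh"], self.p["b"]
        for step in range(t):
            xt = x[:, step, :]
            a = xt @ wx + h @ wh + b
            f = sigmoid(a[:, :hd])
            i = sigmoid(a[:, hd:2 * hd])
            g = np.tanh(a[:, 2 * hd:3 * hd])
            o = sigmoid(a[:, 3 * hd:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((xt, h, c, f, i, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, step, :] = h
        self._cache = cache if train else None
        self._x_shape = x.shape
        return hs

    def backward(self, dout: np.ndarray) -> np.ndarray:
        bsz, t, _ = self._x_shape
        hd = self.hidden_size
        wx, wh = self.p["Wx"], self.p["Wh"]
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros_like(self.p["b"])
        dx = np.empty(self._x_shape, dtype=dout.dtype)
        dh_next = np.zeros((bsz, hd), dtype=dout.dtype)
        dc_next = np.zeros((bsz, hd), dtype=dout.dtype)
        for step in range(t - 1, -1, -1):
            xt, h_prev, c_prev, f, i, g, o, tanh_c = self._cache[step]
            dh = dout[:, step, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            da = np.concatenate(
                [
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    dg * (1.0 - g ** 2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dwx += xt.T @ da
            dwh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, step, :] = da @ wx.T
            dh_next = da @ wh.T
            dc_next = dc * f
        self.g["Wx"][...] = dwx
        self.g["Wh"][...] = dwh
        self.g["b"][...] = db
        self._cache = None
        return dx
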