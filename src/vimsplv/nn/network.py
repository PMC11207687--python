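"""The CNN-LSTM network: two conv blocks, two stacked LSTMs, softmax head.

Input is a 52x52 connectivity matrix treated as a one-channel image.  Each
conv block is conv(3x3, stride 1, pad 1) -> batch-norm -> ReLU -> max-pool
(2x2) -> dropout, giving feature maps of (64, 26, 26) then (128, 13, 13).
The block-2 output is read as a sequence of 13 row steps with 128*13
features per step, fed through LSTM(100) -> LSTM(50); the final hidden state
feeds a linear softmax head over the 2 or 3 motion-sickness classes.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, Dropout, Linear, MaxPool2d, ReLU
from .losses import softmax
from .lstm import LSTM

__all__ = ["CNNLSTMNet"]


class _Bridge:
    """(B, H, W, C) -> (B, H, W*C): scan the feature map row by row."""

    def forward(self, x, train=False):
        self._shape = x.shape
        b, h, w, c = x.shape
        return x.reshape(b, h, w * c)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _LastStep:
    """Keep only the final time step of a (B, T, H) sequence."""

    def forward(self, x, train=False):
        self._t = x.shape[1]
        return x[:, -1, :]

    def backward(self, dout):
        dx = np.zeros((dout.shape[0], self._t, dout.shape[1]), dtype=dout.dtype)
        dx[:, -1, :] = dout
        return dx

    def params(self):
        return []


class CNNLSTMNet:
    """Assembled network with explicit forward/backward over all layers."""

    def __init__(
        self,
        input_size: int = 52,
        n_classes: int = 3,
        conv1_channels: int = 64,
        conv2_channels: int = 128,
        kernel: int = 3,
        pool: int = 2,
        dropout1: float = 0.5,
        dropout2: float = 0.3,
        lstm1_hidden: int = 100,
        lstm2_hidden: int = 50,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng()
        self.input_size = input_size
        self.n_classes = n_classes
        self.dtype = dtype
        side2 = input_size // pool // pool
        if input_size % (pool * pool):
            raise ValueError("input side must be divisible by both pooling stages")
        seq_features = conv2_channels * side2
        self.block1 = [
            Conv2d(1, conv1_channels, kernel, pad=kernel // 2, first_layer=True,
                   rng=rng, dtype=dtype),
            BatchNorm2d(conv1_channels, dtype=dtype),
            ReLU(),
            MaxPool2d(pool),
            Dropout(dropout1, rng=rng),
        ]
        self.block2 = [
            Conv2d(conv1_channels, conv2_channels, kernel, pad=kernel // 2, rng=rng, dtype=dtype),
            BatchNorm2d(conv2_channels, dtype=dtype),
            ReLU(),
            MaxPool2d(pool),
            Dropout(dropout2, rng=rng),
        ]
        self.tail = [
            _Bridge(),
            LSTM(seq_features, lstm1_hidden, rng=rng, dtype=dtype),
            LSTM(lstm1_hidden, lstm2_hidden, rng=rng, dtype=dtype),
            _LastStep(),
            Linear(lstm2_hidden, n_classes, rng=rng, dtype=dtype),
        ]
        self.layers = self.block1 + self.block2 + self.tail

    # -- plumbing ----------------------------------------------------------

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        orig_shape = np.asarray(x).shape
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        s = self.input_size
        if x.ndim == 4 and x.shape[1] == 1 and x.shape[-2:] == (s, s):
            x = x[:, 0]  # accept channels-first (B, 1, s, s) too
        if x.ndim != 3 or x.shape[-2:] != (s, s):
            raise ValueError(
                f"expected {s}x{s} connectivity-matrix input "
                f"(or a batch of them), got array of shape {orig_shape}"
            )
        return x[..., None]  # NHWC with one input channel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (batch, n_classes)."""
        out = self._prepare(x)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def forward_blocks(self, x: np.ndarray) -> "tuple[np.ndarray, np.ndarray]":
        """Evaluation-mode feature maps after conv blocks 1 and 2, reported
        channels-first: (B, 64, 26, 26) and (B, 128, 13, 13) by default."""
        out = self._prepare(x)
        for layer in self.block1:
            out = layer.forward(out, train=False)
        b1 = out
        for layer in self.block2:
            out = layer.forward(out, train=False)
        return b1.transpose(0, 3, 1, 2), out.transpose(0, 3, 1, 2)

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities in evaluation mode (deterministic)."""
        x = np.asarray(x)
        if x.ndim == 2:
            x = x[None]
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(softmax(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=-1)

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> "dict[str, np.ndarray]":
        state = {}
        for i, layer in enumerate(self.layers):
            for name, value, _ in layer.params():
                state[f"layer{i}.{name}"] = value.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: "dict[str, np.ndarray]") -> None:
        for i, layer in enumerate(self.layers):
            for name, value, _ in layer.params():
                value[...] = state[f"layer{i}.{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))
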