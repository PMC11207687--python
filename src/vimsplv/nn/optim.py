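"""Adam optimizer over the layers' (name, value, grad) parameter triples."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [ly for ly in layers if ly.params()]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            [np.zeros_like(v) for _, v, _ in ly.params()] for ly in self.layers
        ]
        self.v = [
            [np.zeros_like(v) for _, v, _ in ly.params()] for ly in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for li, ly in enumerate(self.layers):
            for pi, (_, value, grad) in enumerate(ly.params()):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m += (1.0 - b1) * (grad - m)
                v += (1.0 - b2) * (grad * grad - v)
                value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
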