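"""Softmax and cross-entropy loss."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch.

    Returns (loss, dlogits, probs); ``dlogits`` is the gradient of the mean
    loss with respect to the logits.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.log(probs[np.arange(n), targets] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n, probs
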