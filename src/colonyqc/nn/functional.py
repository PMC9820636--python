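"""Numerically stable activations and losses on logits."""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "bce_with_logits"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz).

    Uses log(1+e^-|z|) + max(z,0) - y*z, which never overflows, and the exact
    gradient (sigmoid(z) - y) / N.
    """
    z = np.asarray(z, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = z.size
    loss = float(np.mean(np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / n
    return loss, grad
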