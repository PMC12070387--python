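"""Losses and activations with numerically stable gradients."""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from raw logits.

    Returns (loss, dloss/dlogits). The gradient is (sigmoid(z) - y) / n, which
    stays finite for arbitrarily large |z|.
    """
    z = np.asarray(logits, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.float64).ravel()
    # log(1 + e^-|z|) formulation avoids overflow
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad.reshape(np.shape(logits))


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element; gradient wrt pred."""
    diff = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size
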