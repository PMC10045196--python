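"""Pixelwise losses computed on logits for numerical stability."""

from __future__ import annotations

import numpy as np

from .layers import sigmoid


def weighted_bce_with_logits(logits: np.ndarray, target: np.ndarray,
                             weight: np.ndarray | float = 1.0):
    """Weighted binary cross-entropy against soft targets in [0, 1].

    Per pixel: ``bce = softplus(z) - t*z`` with ``z`` the logit and ``t``
    the target. Returns ``(loss, grad)`` where loss is the weighted mean
    over pixels and ``grad`` is d(loss)/d(logits).
    """
    z = logits.astype(np.float64, copy=False)
    bce = np.logaddexp(0.0, z) - target * z
    n = z.size
    loss = float(np.sum(weight * bce) / n)
    grad = (weight * (sigmoid(logits).astype(np.float64) - target) / n)
    return loss, grad.astype(np.float32)


def mae(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its (sub)gradient, for loss ablations."""
    diff = pred.astype(np.float64) - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad.astype(np.float32)
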