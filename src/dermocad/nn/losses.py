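"""Loss functions: weighted cross-entropy and mean squared error.

The weighted cross-entropy is

    L = -(1/N) * sum_n sum_k  w_k * T_{nk} * log(P_{nk})

with ``w`` a per-class weight vector, ``T`` one-hot targets and ``P`` rows
on the probability simplex.  Class weighting counters class imbalance: with
inverse-frequency weights the rarer class contributes proportionally more
per sample.
"""

from __future__ import annotations

import warnings

import numpy as np

_EPS = 1e-12


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_loss(probabilities: np.ndarray, one_hot_targets: np.ndarray,
                       class_weights: np.ndarray | None = None) -> float:
    """Weighted negative log-likelihood averaged over the N rows.

    ``probabilities`` and ``one_hot_targets`` are (N, K); ``class_weights``
    is length K (defaults to ones).  Probabilities of zero at a target
    position are clamped at 1e-12 (with a warning) so the loss stays finite.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(one_hot_targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("probabilities and targets must have the same shape")
    n, k = p.shape
    w = np.ones(k) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    at_target = t > 0
    if np.any(p[at_target] <= 0):
        warnings.warn("zero probability at a target position; clamping at 1e-12",
                      RuntimeWarning, stacklevel=2)
    p = np.clip(p, _EPS, None)
    return float(-(w[None, :] * t * np.log(p)).sum() / n)


def softmax_cross_entropy_with_grad(logits: np.ndarray, one_hot_targets: np.ndarray,
                                    class_weights: np.ndarray | None = None
                                    ) -> tuple[float, np.ndarray]:
    """Loss and d(loss)/d(logits) for softmax + weighted cross-entropy.

    With a one-hot target of class c and weight w_c the per-row gradient is
    ``w_c * (p - t) / N``.
    """
    p = softmax(logits.astype(np.float64), axis=1)
    n, k = p.shape
    w = np.ones(k) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    loss = cross_entropy_loss(p, one_hot_targets, w)
    row_w = (one_hot_targets * w[None, :]).sum(axis=1, keepdims=True)
    grad = (row_w * (p - one_hot_targets) / n).astype(np.float32)
    return loss, grad


def mse_loss_with_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float((diff ** 2).mean())
    grad = (2.0 * diff / diff.size).astype(np.float32)
    return loss, grad
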