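"""Focal loss with class-balanced weights.

The focal loss down-weights well-classified examples so training
concentrates on hard ones:

    FL(y, p) = - sum_i alpha_i * (1 - p_i)^gamma * y_i * log(p_i)

with ``y`` one-hot and ``p`` the softmax output.  ``gamma = 0`` and
``alpha = 1`` recover categorical cross-entropy.  Large gamma saturates
learning once predictions clear a low confidence bar, so gamma in [0, 5)
is the sensible range for this model family; the default is 2.

Class weights follow the complement-frequency rule

    alpha_i = 1 - S_i / S_total

so rarer behavior categories (e.g. "grinding", often a few dozen clips
against thousands of "normal") receive larger weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROB_FLOOR = 1e-7  # clamp before log; invisible at reported precision


@dataclass(frozen=True)
class FocalLossParams:
    """gamma >= 0 and per-class weights alpha_i in (0, 1]."""

    gamma: float = 2.0
    alpha: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        a = np.asarray(self.alpha, dtype=float)
        if np.any(a <= 0) or np.any(a > 1):
            raise ValueError("alpha weights must lie in (0, 1]")

    def alpha_vector(self, n_classes: int) -> np.ndarray:
        a = np.asarray(self.alpha, dtype=np.float64)
        if a.ndim == 0:
            return np.full(n_classes, float(a))
        if a.shape != (n_classes,):
            raise ValueError(f"alpha has shape {a.shape}, expected ({n_classes},)")
        return a


def focal_loss(
    probs: np.ndarray, target: np.ndarray, params: FocalLossParams
) -> float:
    """Focal loss of one prediction or the batch mean.

    ``probs`` are simplex points (last axis), ``target`` one-hot vectors of
    the same shape.  Natural log; probabilities are clamped at 1e-7 before
    the log so a confidently wrong prediction yields a large finite loss.
    """
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if probs.shape != target.shape:
        raise ValueError(
            f"probs shape {probs.shape} != target shape {target.shape}"
        )
    alpha = params.alpha_vector(probs.shape[-1])
    p = np.maximum(probs, PROB_FLOOR)
    per = -(alpha * (1.0 - p) ** params.gamma * target * np.log(p)).sum(axis=-1)
    return float(per.mean())


def focal_loss_grad_logits(
    probs: np.ndarray, target: np.ndarray, params: FocalLossParams
) -> np.ndarray:
    """Gradient of the batch-mean focal loss w.r.t. the pre-softmax logits.

    With p = softmax(z), t the true class, and L = -alpha_t (1-p_t)^g log p_t:
    dL/dp_t = alpha_t [ g (1-p_t)^(g-1) log p_t - (1-p_t)^g / p_t ] and
    dL/dz_j = dL/dp_t * p_t (delta_tj - p_j).
    """
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    n = probs.shape[0]
    alpha = params.alpha_vector(probs.shape[-1])
    g = params.gamma
    p_t = np.maximum((probs * target).sum(axis=-1, keepdims=True), PROB_FLOOR)
    a_t = (alpha * target).sum(axis=-1, keepdims=True)
    one_m = 1.0 - p_t
    dl_dpt = a_t * (g * one_m ** np.maximum(g - 1.0, 0.0) * np.log(p_t)
                    - one_m ** g / p_t)
    if g == 0.0:  # avoid 0^(-1) artifacts; reduces to plain CE
        dl_dpt = -a_t / p_t
    dz = dl_dpt * p_t * (target - probs)
    return (dz / n).astype(np.float32)


def class_weights(class_counts: np.ndarray) -> np.ndarray:
    """Complement-frequency weights alpha_i = 1 - S_i / S_total.

    Counts must be positive; with C classes the weights sum to C - 1 and
    the smallest class gets the largest weight.
    """
    counts = np.asarray(class_counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("class_counts must be a non-empty 1-D array")
    if np.any(counts <= 0):
        raise ValueError("class counts must be positive")
    total = counts.sum()
    return 1.0 - counts / total


def auto_params(class_counts: np.ndarray, gamma: float = 2.0) -> FocalLossParams:
    """FocalLossParams with Eq.-style complement-frequency alpha."""
    return FocalLossParams(gamma=gamma, alpha=class_weights(class_counts))
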