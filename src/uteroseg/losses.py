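"""Composite training loss.

Total = lambda1 * Lcls + lambda2 * Lbbox + lambda3 * Lmask with the branch
weights (1, 1.2, 1).  Lcls is (weighted) cross entropy over sampled ROIs,
Lbbox is smooth-L1 over the positive ROIs' box residuals, Lmask is binary
cross entropy -y log y' - (1-y) log(1-y') from both the coarse grid and the
refined points.  Class-imbalance handling enters through inverse-frequency
class weights in Lcls only.
"""

from __future__ import annotations

import numpy as np

from .grad import Tensor, log_softmax, binary_cross_entropy_with_logits

__all__ = ["smooth_l1", "cls_loss", "bbox_loss", "mask_loss", "total_loss",
           "inverse_frequency_weights", "LAMBDAS"]

#: branch weights (classification, localization, mask)
LAMBDAS = (1.0, 1.2, 1.0)


def smooth_l1(diff) -> Tensor:
    """Element-wise smooth L1 of a residual, summed over the last axis.

    0.5 d^2 for |d| < 1, |d| - 0.5 otherwise.
    """
    d = diff if isinstance(diff, Tensor) else Tensor(np.asarray(diff, float))
    quad_mask = (np.abs(d.data) < 1.0).astype(float)
    quad = d * d * 0.5
    lin = d.abs() - 0.5
    per = quad * quad_mask + lin * (1.0 - quad_mask)
    if per.data.ndim == 0:
        return per
    return per.sum(axis=-1)


def cls_loss(logits: Tensor, labels: np.ndarray,
             class_weights: np.ndarray | None = None) -> Tensor:
    """Mean weighted cross entropy over Ncls sampled ROIs.

    `logits` (R, K); `labels` int (R,); `class_weights` (K,) with unit
    weights by default.  Each sample contributes w[label] * NLL / R, so
    doubling a class's weight doubles its per-sample contribution.
    """
    labels = np.asarray(labels, dtype=int)
    R = len(labels)
    logp = log_softmax(logits, axis=1)
    nll = -logp[np.arange(R), labels]
    if class_weights is not None:
        nll = nll * np.asarray(class_weights, float)[labels]
    return nll.sum() * (1.0 / R)


def bbox_loss(pred_t: Tensor, target_t: np.ndarray,
              positive: np.ndarray, n_reg: int | None = None) -> Tensor:
    """Smooth-L1 localization loss over positive ROIs only.

    pred_t/target_t are (R, 4) regression parameterizations; `positive` is a
    boolean gate per ROI (the Pi' indicator): negatives contribute nothing.
    Normalized by `n_reg` (defaults to the number of positives).
    """
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    if n_pos == 0:
        return Tensor(0.0)
    if n_reg is None:
        n_reg = n_pos
    diff = pred_t[positive] - np.asarray(target_t, float)[positive]
    return smooth_l1(diff).sum() * (1.0 / n_reg)


def mask_loss(coarse_logits: Tensor | None, coarse_targets: np.ndarray | None,
              point_logits: Tensor | None = None,
              point_targets: np.ndarray | None = None) -> Tensor:
    """Binary cross entropy over coarse-grid cells plus refined points.

    Only the ground-truth class's channel is passed in by the caller; both
    parts are means over their own elements.
    """
    total = Tensor(0.0)
    if coarse_logits is not None:
        total = total + binary_cross_entropy_with_logits(
            coarse_logits.reshape(-1), np.asarray(coarse_targets, float).ravel())
    if point_logits is not None and point_logits.data.size:
        total = total + binary_cross_entropy_with_logits(
            point_logits.reshape(-1), np.asarray(point_targets, float).ravel())
    return total


def total_loss(lcls: Tensor, lbbox: Tensor, lmask: Tensor,
               lambdas: tuple = LAMBDAS) -> Tensor:
    l1, l2, l3 = lambdas
    return lcls * l1 + lbbox * l2 + lmask * l3


def inverse_frequency_weights(class_counts) -> np.ndarray:
    """w_c = T / (C * n_c): higher weight for rarer classes.

    Counts of zero get the maximum weight among observed classes.
    """
    counts = np.asarray(class_counts, dtype=float)
    T = counts.sum()
    C = len(counts)
    with np.errstate(divide="ignore"):
        w = T / (C * counts)
    if np.isinf(w).any():
        finite = w[np.isfinite(w)]
        w[np.isinf(w)] = finite.max() if len(finite) else 1.0
    return w
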