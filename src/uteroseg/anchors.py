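"""Data-adaptive anchor design.

Object boxes are clustered in (width, height) space with k-means under the
distance D(box, centroid) = 1 - IoU(box, centroid), where IoU is computed
with the two boxes' centers aligned (the YOLO-lineage convention for anchor
fitting).  Centroid update is the element-wise median; initialization is
k-means++-style seeding under D with multiple restarts keeping the best
average IoU.  With k = 9 the sorted centroids are split into triplets for
the P3/P4/P5 pyramid levels: smallest anchors on the highest-resolution map.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .cocoio import load_coco_raw

__all__ = ["ClusterResult", "collect_box_stats", "iou_center_aligned",
           "iou_wh_matrix", "kmeans_iou", "elbow_curve",
           "assign_anchors_to_levels", "DEFAULT_ANCHORS"]

#: Mask-RCNN-style default anchor set (scale x ratio), used as the baseline
#: the fitted anchors are compared against and as the no-k-means fallback.
DEFAULT_ANCHORS = [
    (w / np.sqrt(r), w * np.sqrt(r))
    for w in (32.0, 64.0, 128.0) for r in (0.5, 1.0, 2.0)
]


@dataclasses.dataclass
class ClusterResult:
    centroids: np.ndarray      # (k, 2) float, sorted by area ascending
    assignments: np.ndarray    # (n,) int
    avg_iou: float

    def __post_init__(self):
        if not (0.0 <= self.avg_iou <= 1.0):
            raise ValueError("avg_iou out of [0, 1]")


def collect_box_stats(coco_path):
    """Widths, heights and aspect ratios (w/h) of all annotation boxes."""
    doc = load_coco_raw(coco_path)
    anns = doc.get("annotations", [])
    if not anns:
        raise ValueError(f"no annotations in {coco_path}")
    widths, heights = [], []
    skipped = 0
    for ann in anns:
        w, h = float(ann["bbox"][2]), float(ann["bbox"][3])
        if w <= 0 or h <= 0:
            skipped += 1
            continue
        widths.append(w)
        heights.append(h)
    if skipped:
        warnings.warn(f"excluded {skipped} zero-size boxes")
    if not widths:
        raise ValueError("no valid (positive-size) boxes found")
    widths = np.asarray(widths)
    heights = np.asarray(heights)
    return widths, heights, widths / heights


def iou_center_aligned(a: tuple[float, float], b: tuple[float, float]) -> float:
    """IoU of two boxes compared with coincident centers."""
    wa, ha = a
    wb, hb = b
    if wa <= 0 or ha <= 0 or wb <= 0 or hb <= 0:
        raise ValueError("box dimensions must be positive")
    inter = min(wa, wb) * min(ha, hb)
    union = wa * ha + wb * hb - inter
    return inter / union


def iou_wh_matrix(boxes: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(n, k) center-aligned IoU between every box and every centroid."""
    bw = boxes[:, 0][:, None]
    bh = boxes[:, 1][:, None]
    cw = centroids[:, 0][None, :]
    ch = centroids[:, 1][None, :]
    inter = np.minimum(bw, cw) * np.minimum(bh, ch)
    union = bw * bh + cw * ch - inter
    return inter / union


def _seed_centroids(boxes: np.ndarray, k: int,
                    rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding under D = 1 - IoU."""
    n = boxes.shape[0]
    first = rng.integers(n)
    idx = [first]
    for _ in range(1, k):
        d = 1.0 - iou_wh_matrix(boxes, boxes[idx]).max(axis=1)
        d = np.maximum(d, 0.0)
        total = d.sum()
        if total <= 0:
            # all boxes coincide with a centroid; pick uniformly
            idx.append(int(rng.integers(n)))
            continue
        idx.append(int(rng.choice(n, p=d / total)))
    return boxes[idx].astype(float).copy()


def _lloyd(boxes: np.ndarray, centroids: np.ndarray, max_iter: int):
    """Lloyd alternation under 1-IoU with element-wise-median updates."""
    assign = None
    for _ in range(max_iter):
        iou = iou_wh_matrix(boxes, centroids)
        new_assign = np.argmax(iou, axis=1)   # ties -> lowest cluster index
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(centroids.shape[0]):
            members = boxes[assign == j]
            if len(members):
                centroids[j] = np.median(members, axis=0)
    iou = iou_wh_matrix(boxes, centroids)
    assign = np.argmax(iou, axis=1)
    avg = float(iou[np.arange(len(boxes)), assign].mean())
    return centroids, assign, avg


def kmeans_iou(boxes, k: int, seed: int = 0, max_iter: int = 100,
               restarts: int = 10, exhaustive_limit: int = 5000) -> ClusterResult:
    """Cluster (w, h) boxes under the 1-IoU distance.

    Lloyd iteration is a local search, so initialization matters: small
    problems (at most `exhaustive_limit` distinct k-subsets) are solved by
    running Lloyd from every k-subset of distinct boxes, which is
    deterministic and seed-independent; larger ones use k-means++-style
    seeding with `restarts` restarts, keeping the best average IoU.
    Output centroids are sorted by area ascending and every box is assigned
    to its maximum-IoU centroid.
    """
    import itertools
    import math

    boxes = np.asarray(boxes, dtype=float).reshape(-1, 2)
    if (boxes <= 0).any():
        raise ValueError("box dimensions must be positive")
    distinct = np.unique(boxes, axis=0)
    if k > len(distinct):
        raise ValueError(f"k={k} exceeds {len(distinct)} distinct boxes")
    best = None
    if math.comb(len(distinct), k) <= exhaustive_limit:
        for combo in itertools.combinations(range(len(distinct)), k):
            cents, assign, avg = _lloyd(boxes, distinct[list(combo)].copy(),
                                        max_iter)
            if best is None or avg > best[2]:
                best = (cents, assign, avg)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            init = _seed_centroids(boxes, k, rng)
            cents, assign, avg = _lloyd(boxes, init, max_iter)
            if best is None or avg > best[2]:
                best = (cents, assign, avg)
    cents, _, avg = best
    order = np.argsort(cents[:, 0] * cents[:, 1], kind="stable")
    cents = cents[order]
    iou = iou_wh_matrix(boxes, cents)
    assign = np.argmax(iou, axis=1)
    avg = float(iou[np.arange(len(boxes)), assign].mean())
    return ClusterResult(cents, assign, avg)


def elbow_curve(boxes, k_range, seed: int = 0, restarts: int = 10) -> dict[int, float]:
    """Best-of-restarts average IoU for each k in `k_range`."""
    return {int(k): kmeans_iou(boxes, int(k), seed=seed, restarts=restarts).avg_iou
            for k in k_range}


def average_iou(boxes, centroids) -> float:
    """Mean best-centroid IoU of a box set against a fixed anchor set."""
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 2)
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    return float(iou_wh_matrix(boxes, centroids).max(axis=1).mean())


def assign_anchors_to_levels(centroids, levels=("P3", "P4", "P5")) -> dict:
    """Split centroids into equal per-level groups by ascending area.

    P3 (highest resolution, smallest receptive field) receives the smallest
    anchors, P5 the largest.
    """
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = len(centroids)
    if n % len(levels) != 0:
        raise ValueError(f"{n} centroids not divisible by {len(levels)} levels")
    order = np.argsort(centroids[:, 0] * centroids[:, 1], kind="stable")
    cents = centroids[order]
    per = n // len(levels)
    return {lvl: [tuple(c) for c in cents[i * per:(i + 1) * per]]
            for i, lvl in enumerate(levels)}
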