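"""RPN and ROI heads: anchor grids, matching, box coding, NMS, ROIAlign.

Boxes are 0-based with (x, y) the top-left corner and half-open extents
[x, x + w), matching COCO.  Internally boxes travel as (x1, y1, x2, y2)
corner arrays.  The RPN is shared across pyramid levels; ROIs are routed to
a level by the FPN area rule level = floor(3 + log2(sqrt(area)/224)),
clamped to [3, 5].
"""

from __future__ import annotations

import numpy as np

from . import nn
from .grad import Tensor, grid_sample, concat

__all__ = ["generate_anchors", "match_anchors", "encode_box", "decode_box",
           "nms", "iou_matrix", "roi_align", "roi_level", "RPNHead", "BoxHead"]


# ---------------------------------------------------------------------------
# anchors & boxes
# ---------------------------------------------------------------------------

def generate_anchors(pyramid_shapes: dict, anchors_per_level: dict,
                     strides: dict | None = None) -> np.ndarray:
    """Tile every feature-map pixel with the level's anchor sizes.

    Returns (A, 4) corner boxes in input-image pixels, ordered by
    (level, row, col, size index); anchor centers sit at
    (stride*(col+0.5), stride*(row+0.5)).
    """
    strides = strides or {"P3": 8, "P4": 16, "P5": 32}
    out = []
    for level in ("P3", "P4", "P5"):
        if level not in pyramid_shapes:
            continue
        H, W = pyramid_shapes[level]
        s = strides[level]
        sizes = np.asarray(anchors_per_level[level], dtype=float)  # (k, 2)
        cy, cx = np.mgrid[0:H, 0:W]
        cx = (cx + 0.5) * s
        cy = (cy + 0.5) * s
        centers = np.stack([cx.ravel(), cy.ravel()], axis=1)       # (HW, 2)
        # order (row, col, size): expand sizes innermost
        ctr = np.repeat(centers, len(sizes), axis=0)
        wh = np.tile(sizes, (len(centers), 1))
        out.append(np.concatenate([ctr - wh / 2, ctr + wh / 2], axis=1))
    return np.concatenate(out, axis=0)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n, m) IoU between corner boxes."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def match_anchors(anchors: np.ndarray, gt_boxes: np.ndarray,
                  pos_iou: float = 0.7, neg_iou: float = 0.3):
    """Label anchors {1 positive, 0 negative, -1 ignore}; force-match so every
    ground-truth box owns at least one positive anchor.

    Returns (labels, matched_gt_index) with matched index valid on positives.
    """
    A = len(anchors)
    labels = -np.ones(A, dtype=int)
    matched = -np.ones(A, dtype=int)
    if len(gt_boxes) == 0:
        labels[:] = 0
        return labels, matched
    iou = iou_matrix(anchors, gt_boxes)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(A), best_gt]
    labels[best_iou < neg_iou] = 0
    pos = best_iou >= pos_iou
    labels[pos] = 1
    matched[pos] = best_gt[pos]
    # force-match: argmax anchor of each GT is positive regardless of threshold
    for g in range(iou.shape[1]):
        a = int(iou[:, g].argmax())
        labels[a] = 1
        matched[a] = g
    return labels, matched


def _to_cxcywh(boxes: np.ndarray):
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    return boxes[:, 0] + w / 2, boxes[:, 1] + h / 2, w, h


def encode_box(gt: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """(tx, ty, tw, th) of ground truth relative to anchor (Faster-RCNN form)."""
    gx, gy, gw, gh = _to_cxcywh(gt)
    ax, ay, aw, ah = _to_cxcywh(anchor)
    return np.stack([(gx - ax) / aw, (gy - ay) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def decode_box(t: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Inverse of encode_box; returns corner boxes."""
    t = np.asarray(t, dtype=float).reshape(-1, 4)
    ax, ay, aw, ah = _to_cxcywh(anchor)
    cx = t[:, 0] * aw + ax
    cy = t[:, 1] * ah + ay
    w = np.exp(np.clip(t[:, 2], None, 8.0)) * aw
    h = np.exp(np.clip(t[:, 3], None, 8.0)) * ah
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy descending-score suppression; ties keep the lower index."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    keep = []
    alive = np.ones(len(order), dtype=bool)
    for ii, i in enumerate(order):
        if not alive[ii]:
            continue
        keep.append(int(i))
        rest = order[ii + 1:]
        mask = alive[ii + 1:]
        if not mask.any():
            continue
        iou = iou_matrix(boxes[i][None], boxes[rest[mask]])[0]
        sub = np.where(mask)[0][iou > iou_threshold]
        alive[ii + 1 + sub] = False
    return np.asarray(keep, dtype=int)


def roi_level(boxes: np.ndarray, canonical: float = 224.0) -> np.ndarray:
    """FPN routing: level = floor(3 + log2(sqrt(area)/canonical)) in [3, 5]."""
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    area = np.clip((boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]),
                   1e-6, None)
    lvl = np.floor(3 + np.log2(np.sqrt(area) / canonical))
    return np.clip(lvl, 3, 5).astype(int)


def roi_align(feature: Tensor, rois: np.ndarray, output_size: int,
              stride: float = 1.0, sampling_ratio: int = 2) -> Tensor:
    """Quantization-free ROI pooling by averaged bilinear samples per bin.

    `feature` is (1, C, H, W) at `stride` relative to the ROI coordinate
    frame; `rois` are (R, 4) corner boxes in that frame.  Each output bin
    averages sampling_ratio^2 regularly spaced bilinear samples.
    Returns (R, C, output_size, output_size).
    """
    rois = np.asarray(rois, dtype=float).reshape(-1, 4) / stride
    R = len(rois)
    C = feature.data.shape[1]
    S = output_size
    n = sampling_ratio
    # sample coordinates: for each roi, bin (i,j), sample (a,b)
    xs = np.empty((R, S, n))
    ys = np.empty((R, S, n))
    for r, (x1, y1, x2, y2) in enumerate(rois):
        bw = (x2 - x1) / S
        bh = (y2 - y1) / S
        for i in range(S):
            for a in range(n):
                xs[r, i, a] = x1 + bw * (i + (a + 0.5) / n)
                ys[r, i, a] = y1 + bh * (i + (a + 0.5) / n)
    # full grid: (R, S, n, S, n) for (row bin, row sample, col bin, col sample)
    px = np.broadcast_to(xs[:, None, None, :, :], (R, S, n, S, n)).reshape(1, -1)
    py = np.broadcast_to(ys[:, :, :, None, None], (R, S, n, S, n)).reshape(1, -1)
    sampled = grid_sample(feature, px, py)            # (1, C, R*S*n*S*n)
    pooled = sampled.reshape(C, R, S, n, S, n).mean(axis=(3, 5))
    return pooled.transpose(1, 0, 2, 3)               # (R, C, S, S)


# ---------------------------------------------------------------------------
# network heads
# ---------------------------------------------------------------------------

class RPNHead(nn.Module):
    """Objectness + box-delta predictions, shared across pyramid levels."""

    def __init__(self, channels: int, anchors_per_loc: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv = nn.ConvNorm(channels, channels, 3, rng=rng)
        self.obj = nn.Conv2d(channels, anchors_per_loc, 1, rng=rng, std=0.01)
        self.delta = nn.Conv2d(channels, 4 * anchors_per_loc, 1, rng=rng,
                               std=0.01)
        self.k = anchors_per_loc

    def forward(self, pyramid: dict) -> tuple[Tensor, Tensor]:
        """Flattened (A,) objectness logits and (A, 4) deltas, ordered to
        match `generate_anchors` (level, row, col, size)."""
        logits, deltas = [], []
        for level in ("P3", "P4", "P5"):
            f = self.conv(pyramid[level]).relu()
            o = self.obj(f)                    # (1, k, H, W)
            d = self.delta(f)                  # (1, 4k, H, W)
            _, k, H, W = o.data.shape
            logits.append(o.transpose(0, 2, 3, 1).reshape(H * W * k))
            deltas.append(d.reshape(1, self.k, 4, H, W)
                           .transpose(0, 3, 4, 1, 2).reshape(H * W * self.k, 4))
        return concat(logits, axis=0), concat(deltas, axis=0)


class BoxHead(nn.Module):
    """Two-FC trunk with class scores (incl. background) and per-class deltas.

    Class index 0 is background; foreground classes follow the category ids.
    """

    def __init__(self, channels: int, pool: int = 7, n_classes: int = 3,
                 hidden: int = 256, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.fc1 = nn.Linear(channels * pool * pool, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, hidden, rng=rng)
        self.cls = nn.Linear(hidden, n_classes + 1, rng=rng, std=0.01)
        self.box = nn.Linear(hidden, 4 * n_classes, rng=rng, std=0.001)

    def forward(self, pooled: Tensor) -> tuple[Tensor, Tensor]:
        R = pooled.data.shape[0]
        t = pooled.reshape(R, -1)
        t = self.fc2(self.fc1(t).relu()).relu()
        return self.cls(t), self.box(t).reshape(R, self.n_classes, 4)
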