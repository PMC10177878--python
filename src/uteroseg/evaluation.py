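"""COCO-style evaluation: AP family for boxes and masks, confusion matrix.

AP follows the COCO protocol: greedy matching of detections to ground truth
in descending confidence per image, category and IoU threshold; ground
truths outside an area range are ignored, as are detections matched to them
(and unmatched detections outside the range); precision is interpolated on
101 recall points with the running-maximum envelope.  Area buckets use the
mask pixel count with breakpoints 32^2 and 96^2.

All values are returned in [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import CATEGORIES
from .cocoio import encode_mask, decode_mask, load_coco_raw

__all__ = ["EvalReport", "area_bucket", "evaluate_sets", "evaluate_files",
           "confusion_matrix", "mask_iou", "box_iou_xywh",
           "detections_to_results", "load_results", "AREA_RANGES",
           "IOU_THRESHOLDS"]

AREA_RANGES = {
    "all": (0.0, float("inf")),
    "small": (0.0, 32.0 ** 2),
    "medium": (32.0 ** 2, 96.0 ** 2),
    "large": (96.0 ** 2, float("inf")),
}
IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)
RECALL_THRESHOLDS = np.linspace(0.0, 1.0, 101)
MAX_DETS = 100


def area_bucket(area_px: float) -> str:
    """COCO size bucket of a mask area in pixels."""
    if area_px < AREA_RANGES["small"][1]:
        return "small"
    if area_px < AREA_RANGES["medium"][1]:
        return "medium"
    return "large"


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / union if union else 0.0


def box_iou_xywh(a, b) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    x1 = max(ax, bx)
    y1 = max(ay, by)
    x2 = min(ax + aw, bx + bw)
    y2 = min(ay + ah, by + bh)
    inter = max(0.0, x2 - x1) * max(0.0, y2 - y1)
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


@dataclasses.dataclass
class EvalReport:
    """AP family for boxes and masks plus per-category mask AP and the
    spatially matched confusion matrix."""

    box: dict
    mask: dict
    per_category: dict
    confusion: np.ndarray
    confusion_labels: tuple

    def to_dict(self) -> dict:
        return {
            "boxAP": self.box, "maskAP": self.mask,
            "per_category_maskAP": self.per_category,
            "confusion_matrix": self.confusion.tolist(),
            "confusion_labels": list(self.confusion_labels),
        }

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# matching & accumulation (COCO protocol)
# ---------------------------------------------------------------------------

def _match_one_image(ious: np.ndarray, gt_ignore: np.ndarray, thr: float):
    """Greedy COCO matching.  `ious` is (D, G) with detections already in
    descending score order and ground truths ordered non-ignored first.
    Returns (det_match, gt_match) with -1 for unmatched."""
    D, G = ious.shape
    gtm = -np.ones(G, dtype=int)
    dtm = -np.ones(D, dtype=int)
    for d in range(D):
        best = thr - 1e-10
        m = -1
        for g in range(G):
            if gtm[g] >= 0:
                continue
            if m > -1 and not gt_ignore[m] and gt_ignore[g]:
                break  # a real match exists and only ignored GTs remain
            if ious[d, g] < best:
                continue
            best = ious[d, g]
            m = g
        if m > -1:
            dtm[d] = m
            gtm[m] = d
    return dtm, gtm


def _ap_single(dets, gts, iou_fn, thr: float, area_range,
               max_dets: int = MAX_DETS):
    """AP at one IoU threshold for one category over all images.

    dets: {image_id: [(score, area, obj), ...]}, gts: {image_id: [(area, obj)]}
    where obj is whatever `iou_fn(det_obj, gt_obj)` consumes.
    Returns (ap, n_nonignored_gt); ap is None if there is no valid GT.
    """
    lo, hi = area_range
    all_scores, all_tp, all_ig = [], [], []
    npig = 0
    image_ids = sorted(set(dets) | set(gts))
    for img in image_ids:
        d = sorted(dets.get(img, []), key=lambda r: -r[0])[:max_dets]
        g = gts.get(img, [])
        g_ignore = np.array([not (lo <= ga < hi) for ga, _ in g], dtype=bool)
        order = np.argsort(g_ignore, kind="stable")
        g = [g[i] for i in order]
        g_ignore = g_ignore[order]
        npig += int((~g_ignore).sum())
        if d and g:
            ious = np.array([[iou_fn(dobj, gobj) for _, gobj in g]
                             for _, _, dobj in d])
            dtm, _ = _match_one_image(ious, g_ignore, thr)
        else:
            dtm = -np.ones(len(d), dtype=int)
        for k, (score, darea, _) in enumerate(d):
            matched = dtm[k]
            if matched >= 0:
                ignored = bool(g_ignore[matched])
                tp = not ignored
            else:
                ignored = not (lo <= darea < hi)
                tp = False
            all_scores.append(score)
            all_tp.append(tp)
            all_ig.append(ignored)
    if npig == 0:
        return None, 0
    if not all_scores:
        return 0.0, npig
    order = np.argsort(-np.asarray(all_scores), kind="stable")
    tp = np.asarray(all_tp)[order]
    ig = np.asarray(all_ig)[order]
    keep = ~ig
    tp = tp[keep]
    if not len(tp):
        return 0.0, npig
    ctp = np.cumsum(tp)
    cfp = np.cumsum(~tp)
    recall = ctp / npig
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    # running-max envelope from the right
    for i in range(len(precision) - 1, 0, -1):
        precision[i - 1] = max(precision[i - 1], precision[i])
    idx = np.searchsorted(recall, RECALL_THRESHOLDS, side="left")
    q = np.zeros(len(RECALL_THRESHOLDS))
    valid = idx < len(precision)
    q[valid] = precision[idx[valid]]
    return float(q.mean()), npig


def _collect(per_image_dets, per_image_gts, kind: str):
    """Regroup detections/GTs by category into the _ap_single structures."""
    cats = sorted(CATEGORIES)
    dets = {c: {} for c in cats}
    gts = {c: {} for c in cats}
    for img, recs in per_image_gts.items():
        for rec in recs:
            obj = rec.mask if kind == "mask" else rec.bbox
            gts[rec.category_id].setdefault(img, []).append(
                (float(rec.area), obj))
    for img, ds in per_image_dets.items():
        for det in ds:
            if kind == "mask":
                obj = det.mask
                darea = float(det.mask.sum())
            else:
                obj = det.box
                darea = float(det.box[2] * det.box[3])
            dets[det.category_id].setdefault(img, []).append(
                (float(det.score), darea, obj))
    return dets, gts


def _ap_family(per_image_dets, per_image_gts, kind: str):
    iou_fn = mask_iou if kind == "mask" else box_iou_xywh
    dets, gts = _collect(per_image_dets, per_image_gts, kind)
    cats = sorted(CATEGORIES)

    def mean_ap(thrs, area):
        vals = []
        for c in cats:
            per_thr = [_ap_single(dets[c], gts[c], iou_fn, t,
                                  AREA_RANGES[area])[0] for t in thrs]
            per_thr = [v for v in per_thr if v is not None]
            if per_thr:
                vals.append(np.mean(per_thr))
        return float(np.mean(vals)) if vals else 0.0

    family = {
        "AP": mean_ap(IOU_THRESHOLDS, "all"),
        "AP50": mean_ap([0.5], "all"),
        "AP75": mean_ap([0.75], "all"),
        "APs": mean_ap(IOU_THRESHOLDS, "small"),
        "APm": mean_ap(IOU_THRESHOLDS, "medium"),
        "APl": mean_ap(IOU_THRESHOLDS, "large"),
    }
    per_cat = {}
    for c in cats:
        per_thr = [_ap_single(dets[c], gts[c], iou_fn, t,
                              AREA_RANGES["all"])[0] for t in IOU_THRESHOLDS]
        per_thr = [v for v in per_thr if v is not None]
        per_cat[CATEGORIES[c]] = float(np.mean(per_thr)) if per_thr else None
    return family, per_cat


def confusion_matrix(per_image_dets, per_image_gts, iou_threshold: float = 0.5,
                     kind: str = "mask"):
    """Row-normalized confusion over spatially matched pairs.

    Rows are true categories; columns are predicted categories plus a final
    background column counting ground truths no detection claimed.  Matching
    is class-agnostic, greedy in descending confidence at `iou_threshold`.
    """
    iou_fn = mask_iou if kind == "mask" else box_iou_xywh
    cats = sorted(CATEGORIES)
    idx = {c: i for i, c in enumerate(cats)}
    C = np.zeros((len(cats), len(cats) + 1))
    for img, gts in per_image_gts.items():
        dets = sorted(per_image_dets.get(img, []), key=lambda d: -d.score)
        taken = np.zeros(len(gts), dtype=bool)
        for det in dets:
            dobj = det.mask if kind == "mask" else det.box
            best, bi = iou_threshold - 1e-10, -1
            for gi, rec in enumerate(gts):
                if taken[gi]:
                    continue
                gobj = rec.mask if kind == "mask" else rec.bbox
                v = iou_fn(dobj, gobj)
                if v >= best:
                    best, bi = v, gi
            if bi >= 0:
                taken[bi] = True
                C[idx[gts[bi].category_id], idx[det.category_id]] += 1
        for gi, rec in enumerate(gts):
            if not taken[gi]:
                C[idx[rec.category_id], -1] += 1
    sums = C.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = np.where(sums > 0, C / sums, 0.0)
    labels = tuple(CATEGORIES[c] for c in cats) + ("background",)
    return out, labels


def evaluate_sets(per_image_dets: dict, per_image_gts: dict) -> EvalReport:
    """Full report from in-memory detections and ground truths per image."""
    box_family, _ = _ap_family(per_image_dets, per_image_gts, "box")
    mask_family, per_cat = _ap_family(per_image_dets, per_image_gts, "mask")
    conf, labels = confusion_matrix(per_image_dets, per_image_gts)
    return EvalReport(box_family, mask_family, per_cat, conf, labels)


# ---------------------------------------------------------------------------
# results-file round trip
# ---------------------------------------------------------------------------

def detections_to_results(dets_per_image: dict) -> list[dict]:
    """COCO results records (image_id, category_id, bbox, score, segmentation)."""
    out = []
    for img, dets in sorted(dets_per_image.items()):
        for d in dets:
            out.append({
                "image_id": int(img),
                "category_id": int(d.category_id),
                "bbox": [float(v) for v in d.box],
                "score": float(d.score),
                "segmentation": encode_mask(d.mask),
            })
    return out


def load_results(path, image_sizes: dict) -> dict:
    """Results JSON -> {image_id: [Detection, ...]}."""
    from .model import Detection

    recs = json.loads(Path(path).read_text())
    out: dict = {}
    for r in recs:
        img = r["image_id"]
        mask = decode_mask(r["segmentation"], image_sizes[img])
        out.setdefault(img, []).append(
            Detection(r["category_id"], r["score"], tuple(r["bbox"]), mask))
    return out


def evaluate_files(results_path, gt_path) -> EvalReport:
    """Evaluate a COCO results file against a COCO annotation file."""
    from .cocoio import read_coco

    images, annos = read_coco(gt_path)
    sizes = {im["id"]: (im["height"], im["width"]) for im in images}
    gts: dict = {im["id"]: [] for im in images}
    for img_id, rec in annos:
        gts[img_id].append(rec)
    dets = load_results(results_path, sizes)
    for img_id in gts:
        dets.setdefault(img_id, [])
    return evaluate_sets(dets, gts)


def load_gt_per_image(gt_path) -> dict:
    doc = load_coco_raw(gt_path)
    from .phantom import InstanceRecord

    sizes = {im["id"]: (im["height"], im["width"]) for im in doc["images"]}
    cat_names = {c["id"]: c["name"] for c in doc["categories"]}
    out: dict = {im["id"]: [] for im in doc["images"]}
    for ann in doc["annotations"]:
        mask = decode_mask(ann["segmentation"], sizes[ann["image_id"]])
        out[ann["image_id"]].append(
            InstanceRecord(cat_names[ann["category_id"]], mask))
    return out
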