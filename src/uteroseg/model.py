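"""The two-stage detector: backbone -> RPN -> box/class + mask heads.

Training composes the branch losses of the composite objective
(classification, localization, mask) with weights (1, 1.2, 1); the RPN's
objectness/regression terms fold into the classification/localization
branches respectively.  Inference produces per-instance category, score,
box and a full-resolution binary mask obtained by uncertainty-guided
iterative refinement of the coarse mask grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grad import Tensor, concat
from .nn import Module
from .backbone import BackboneConfig, HRBackbone
from .anchors import DEFAULT_ANCHORS, assign_anchors_to_levels
from .heads import (RPNHead, BoxHead, generate_anchors, match_anchors,
                    encode_box, decode_box, nms, iou_matrix, roi_align,
                    roi_level)
from .pointrend import (CoarseMaskHead, PointHead, select_training_points,
                        point_features, iterative_refine, sample_grid_np)
from .losses import (cls_loss, bbox_loss, mask_loss, total_loss, smooth_l1,
                     LAMBDAS)

__all__ = ["DetectorConfig", "Detector", "Detection"]

_STRIDES = {"P3": 8, "P4": 16, "P5": 32}


@dataclasses.dataclass
class Detection:
    """One predicted instance in the input-image frame."""
    category_id: int
    score: float
    box: tuple          # (x, y, w, h)
    mask: np.ndarray    # full-resolution bool


@dataclasses.dataclass
class DetectorConfig:
    input_size: int = 128
    backbone: BackboneConfig = dataclasses.field(default_factory=BackboneConfig)
    anchors_per_level: dict | None = None   # None -> default scale/ratio set
    n_classes: int = 3
    # RPN
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    rpn_batch: int = 64
    rpn_nms: float = 0.7
    pre_nms_top: int = 600
    post_nms_train: int = 200
    post_nms_test: int = 100
    # ROI heads
    roi_fg_iou: float = 0.5
    rois_per_image: int = 32
    roi_fg_frac: float = 0.5
    mask_rois: int = 12
    box_hidden: int = 128
    bbox_std: tuple = (0.1, 0.1, 0.2, 0.2)
    # mask branch
    mask_grid: int = 7
    mask_out: int = 56
    point_k: float = 3.0
    point_beta: float = 0.75
    point_n: int = 49
    refine_per_step: int = 64
    point_hidden: int = 64
    pointrend: bool = True
    # inference
    score_thresh: float = 0.05
    test_nms: float = 0.5
    max_dets: int = 100

    @staticmethod
    def desk(**overrides) -> "DetectorConfig":
        return dataclasses.replace(DetectorConfig(), **overrides)

    @staticmethod
    def full(**overrides) -> "DetectorConfig":
        cfg = DetectorConfig(
            input_size=512, backbone=BackboneConfig.full(), rpn_batch=256,
            pre_nms_top=2000, post_nms_train=1000, post_nms_test=300,
            rois_per_image=128, mask_rois=32, box_hidden=1024,
            mask_grid=14, mask_out=112, point_n=196, refine_per_step=784,
            point_hidden=256)
        return dataclasses.replace(cfg, **overrides)

    def resolved_anchors(self) -> dict:
        if self.anchors_per_level is not None:
            return self.anchors_per_level
        return assign_anchors_to_levels(DEFAULT_ANCHORS)


class Detector(Module):
    def __init__(self, config: DetectorConfig | None = None, seed: int = 0):
        self.config = config or DetectorConfig()
        cfg = self.config
        C = cfg.backbone.out_channels
        self.backbone = HRBackbone(cfg.backbone, seed=seed)
        k_per_level = len(cfg.resolved_anchors()["P3"])
        self.rpn = RPNHead(C, k_per_level, seed=seed + 1)
        self.box_head = BoxHead(C, 7, cfg.n_classes, cfg.box_hidden,
                                seed=seed + 2)
        self.mask_head = CoarseMaskHead(C, cfg.n_classes, cfg.mask_grid,
                                        seed=seed + 3)
        self.point_head = PointHead(C + cfg.n_classes, cfg.n_classes,
                                    cfg.point_hidden, 3, seed=seed + 4)
        s = cfg.input_size
        self._shapes = {"P3": (s // 8, s // 8), "P4": (s // 16, s // 16),
                        "P5": (s // 32, s // 32)}
        self.anchors = generate_anchors(self._shapes, cfg.resolved_anchors())

    # ------------------------------------------------------------------ utils
    def _clip(self, boxes: np.ndarray) -> np.ndarray:
        s = self.config.input_size
        return np.clip(boxes, 0, s)

    def _proposals(self, logits: Tensor, deltas: Tensor, n_post: int) -> np.ndarray:
        cfg = self.config
        scores = logits.data
        boxes = self._clip(decode_box(deltas.data, self.anchors))
        wh = boxes[:, 2:] - boxes[:, :2]
        valid = (wh > 2).all(axis=1)
        idx = np.where(valid)[0]
        order = idx[np.argsort(-scores[idx], kind="stable")[:cfg.pre_nms_top]]
        keep = nms(boxes[order], scores[order], cfg.rpn_nms)[:n_post]
        return boxes[order[keep]]

    def _pool(self, pyramid: dict, rois: np.ndarray, out_size: int) -> Tensor:
        """ROIAlign with per-ROI pyramid-level routing; preserves order."""
        levels = roi_level(rois)
        chunks, owners = [], []
        for lv, name in ((3, "P3"), (4, "P4"), (5, "P5")):
            sel = np.where(levels == lv)[0]
            if not len(sel):
                continue
            chunks.append(roi_align(pyramid[name], rois[sel], out_size,
                                    stride=float(_STRIDES[name])))
            owners.append(sel)
        if len(chunks) == 1:
            pooled, order = chunks[0], owners[0]
        else:
            pooled = concat(chunks, axis=0)
            order = np.concatenate(owners)
        inv = np.argsort(order, kind="stable")
        return pooled[inv]

    # --------------------------------------------------------------- training
    def forward_train(self, image: np.ndarray, instances: list,
                      class_weights: np.ndarray | None = None,
                      rng: np.random.Generator | None = None) -> dict:
        """One training forward pass; returns the loss dictionary.

        `image` is a preprocessed (S, S) array; `instances` are
        InstanceRecords in the same frame.
        """
        cfg = self.config
        rng = rng or np.random.default_rng(0)
        gt_boxes = np.array([[r.bbox[0], r.bbox[1],
                              r.bbox[0] + r.bbox[2], r.bbox[1] + r.bbox[3]]
                             for r in instances], dtype=float).reshape(-1, 4)
        gt_classes = np.array([r.category_id for r in instances], dtype=int)

        x = Tensor(image[None, None])
        pyr = self.backbone(x).as_dict()
        rpn_logits, rpn_deltas = self.rpn(pyr)

        # ---- RPN losses ----
        labels, matched = match_anchors(self.anchors, gt_boxes,
                                        cfg.rpn_pos_iou, cfg.rpn_neg_iou)
        pos = np.where(labels == 1)[0]
        neg = np.where(labels == 0)[0]
        n_pos = min(len(pos), cfg.rpn_batch // 2)
        if len(pos) > n_pos:
            pos = rng.choice(pos, n_pos, replace=False)
        n_neg = min(len(neg), cfg.rpn_batch - n_pos)
        if len(neg) > n_neg:
            neg = rng.choice(neg, n_neg, replace=False)
        sel = np.concatenate([pos, neg])
        from .grad import binary_cross_entropy_with_logits
        rpn_obj = binary_cross_entropy_with_logits(
            rpn_logits[sel], (labels[sel] == 1).astype(float))
        if len(pos):
            t_star = encode_box(gt_boxes[matched[pos]], self.anchors[pos])
            rpn_box = smooth_l1(rpn_deltas[pos] - t_star).sum() * (1.0 / len(pos))
        else:
            rpn_box = Tensor(0.0)

        # ---- proposals & ROI sampling ----
        props = self._proposals(rpn_logits, rpn_deltas, cfg.post_nms_train)
        props = np.concatenate([props, gt_boxes], axis=0)
        iou = iou_matrix(props, gt_boxes)
        best = iou.argmax(axis=1) if iou.shape[1] else np.zeros(len(props), int)
        best_iou = iou.max(axis=1) if iou.shape[1] else np.zeros(len(props))
        roi_labels = np.where(best_iou >= cfg.roi_fg_iou, gt_classes[best], 0)
        fg = np.where(roi_labels > 0)[0]
        bg = np.where(roi_labels == 0)[0]
        n_fg = min(len(fg), int(cfg.rois_per_image * cfg.roi_fg_frac))
        if len(fg) > n_fg:
            fg = rng.choice(fg, n_fg, replace=False)
        n_bg = min(len(bg), cfg.rois_per_image - n_fg)
        if len(bg) > n_bg:
            bg = rng.choice(bg, n_bg, replace=False)
        keep = np.concatenate([fg, bg])
        rois = props[keep]
        roi_lab = roi_labels[keep]
        roi_gt = best[keep]

        pooled = self._pool(pyr, rois, 7)
        logits, deltas = self.box_head(pooled)
        roi_cls = cls_loss(logits, roi_lab, class_weights)

        fg_mask = roi_lab > 0
        if fg_mask.any():
            fi = np.where(fg_mask)[0]
            t = encode_box(gt_boxes[roi_gt[fi]], rois[fi])
            t = t / np.asarray(cfg.bbox_std)
            pred = deltas[fi, roi_lab[fi] - 1]
            roi_box = smooth_l1(pred - t).sum() * (1.0 / len(fi))
        else:
            roi_box = Tensor(0.0)

        # ---- mask branch ----
        # every GT box is supervised each pass; jittered foreground
        # proposals are added up to the cap so the head also sees the
        # slightly-off boxes it will get at inference time
        lmask = Tensor(0.0)
        n_gt = len(gt_boxes)
        fg_pool = np.where(fg_mask)[0]
        n_extra = max(0, cfg.mask_rois - n_gt)
        if len(fg_pool) > n_extra:
            fg_pool = rng.choice(fg_pool, n_extra, replace=False)
        m_all_rois = np.concatenate([gt_boxes, rois[fg_pool]], axis=0)
        m_cls = np.concatenate([gt_classes, roi_lab[fg_pool]]).astype(int)
        m_gt_idx = np.concatenate([np.arange(n_gt), roi_gt[fg_pool]]).astype(int)
        mi = np.arange(len(m_all_rois))
        if len(mi):
            m_rois = m_all_rois
            pooled14 = roi_align(pyr["fine"], m_rois, 2 * cfg.mask_grid,
                                 stride=4.0)
            coarse = self.mask_head(pooled14)      # (R, K, g, g)
            g = cfg.mask_grid
            coarse_parts, coarse_tgts = [], []
            point_parts, point_tgts = [], []
            for j in mi:
                cls = m_cls[j]
                gt_mask = instances[m_gt_idx[j]].mask.astype(float)
                roi = m_rois[j]
                uu, vv = np.meshgrid((np.arange(g) + 0.5) / g,
                                     (np.arange(g) + 0.5) / g)
                tx = (roi[0] + uu * (roi[2] - roi[0]))
                ty = (roi[1] + vv * (roi[3] - roi[1]))
                h, w = gt_mask.shape
                tgt = sample_grid_np(gt_mask, tx.ravel() / w, ty.ravel() / h)
                coarse_parts.append(coarse[j, cls - 1].reshape(g * g))
                coarse_tgts.append((tgt > 0.5).astype(float))
                if cfg.pointrend:
                    probs = 1.0 / (1.0 + np.exp(-coarse.data[j, cls - 1]))
                    sel_pts = select_training_points(
                        probs, cfg.point_k, cfg.point_beta, cfg.point_n, rng)
                    feats, c_at = point_features(
                        pyr["fine"], coarse[j:j + 1], roi, sel_pts.points, 4.0)
                    p_logits = self.point_head(feats, c_at)[:, cls - 1]
                    px = (roi[0] + sel_pts.points[:, 0] * (roi[2] - roi[0])) / w
                    py = (roi[1] + sel_pts.points[:, 1] * (roi[3] - roi[1])) / h
                    p_tgt = sample_grid_np(gt_mask, px, py) > 0.5
                    point_parts.append(p_logits)
                    point_tgts.append(p_tgt.astype(float))
            lmask = mask_loss(
                concat(coarse_parts, axis=0), np.concatenate(coarse_tgts),
                concat(point_parts, axis=0) if point_parts else None,
                np.concatenate(point_tgts) if point_tgts else None)

        lcls = rpn_obj + roi_cls
        lbbox = rpn_box + roi_box
        return {
            "rpn_obj": rpn_obj, "rpn_box": rpn_box, "roi_cls": roi_cls,
            "roi_box": roi_box, "mask": lmask,
            "cls": lcls, "bbox": lbbox,
            "total": total_loss(lcls, lbbox, lmask, LAMBDAS),
        }

    # -------------------------------------------------------------- inference
    def predict(self, image: np.ndarray) -> list[Detection]:
        cfg = self.config
        x = Tensor(image[None, None])
        pyr = self.backbone(x).as_dict()
        rpn_logits, rpn_deltas = self.rpn(pyr)
        props = self._proposals(rpn_logits, rpn_deltas, cfg.post_nms_test)
        if not len(props):
            return []
        pooled = self._pool(pyr, props, 7)
        logits, deltas = self.box_head(pooled)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        probs = np.exp(z)
        probs /= probs.sum(axis=1, keepdims=True)

        cand_boxes, cand_scores, cand_cls = [], [], []
        std = np.asarray(cfg.bbox_std)
        for c in range(1, cfg.n_classes + 1):
            sc = probs[:, c]
            keep = np.where(sc > cfg.score_thresh)[0]
            if not len(keep):
                continue
            boxes = self._clip(decode_box(deltas.data[keep, c - 1] * std,
                                          props[keep]))
            wh = boxes[:, 2:] - boxes[:, :2]
            ok = (wh >= 2).all(axis=1)
            boxes, kidx = boxes[ok], keep[ok]
            if not len(kidx):
                continue
            kn = nms(boxes, sc[kidx], cfg.test_nms)
            cand_boxes.append(boxes[kn])
            cand_scores.append(sc[kidx][kn])
            cand_cls.append(np.full(len(kn), c))
        if not cand_boxes:
            return []
        boxes = np.concatenate(cand_boxes)
        scores = np.concatenate(cand_scores)
        classes = np.concatenate(cand_cls)
        order = np.argsort(-scores, kind="stable")[:cfg.max_dets]
        boxes, scores, classes = boxes[order], scores[order], classes[order]

        pooled14 = roi_align(pyr["fine"], boxes, 2 * cfg.mask_grid,
                             stride=4.0)
        coarse = self.mask_head(pooled14)
        dets = []
        steps = int(np.log2(cfg.mask_out / cfg.mask_grid))
        for i in range(len(boxes)):
            c = int(classes[i])
            probs_grid = 1.0 / (1.0 + np.exp(-coarse.data[i, c - 1]))
            if cfg.pointrend:
                roi = boxes[i]

                def point_fn(points, interp, _roi=roi, _i=i, _c=c):
                    feats, c_at = point_features(
                        pyr["fine"], coarse[_i:_i + 1].detach(), _roi, points, 4.0)
                    out = self.point_head(feats, c_at)
                    return 1.0 / (1.0 + np.exp(-out.data[:, _c - 1]))

                probs_grid = iterative_refine(probs_grid, steps,
                                              cfg.refine_per_step, point_fn)
            else:
                probs_grid = iterative_refine(probs_grid, steps, 0, None)
            mask = paste_mask(probs_grid, boxes[i], cfg.input_size)
            if not mask.any():
                continue
            x1, y1, x2, y2 = boxes[i]
            dets.append(Detection(c, float(scores[i]),
                                  (float(x1), float(y1),
                                   float(x2 - x1), float(y2 - y1)), mask))
        return dets


def paste_mask(probs: np.ndarray, box: np.ndarray, size: int,
               thr: float = 0.5) -> np.ndarray:
    """Resample a ROI probability grid into the image frame and binarize."""
    x1, y1, x2, y2 = [float(v) for v in box]
    out = np.zeros((size, size), dtype=bool)
    c0 = int(np.floor(x1))
    r0 = int(np.floor(y1))
    c1 = min(size, int(np.ceil(x2)))
    r1 = min(size, int(np.ceil(y2)))
    if c1 <= c0 or r1 <= r0 or x2 <= x1 or y2 <= y1:
        return out
    cols = np.arange(max(0, c0), c1) + 0.5
    rows = np.arange(max(0, r0), r1) + 0.5
    uu = (cols - x1) / (x2 - x1)
    vv = (rows - y1) / (y2 - y1)
    inside_u = (uu >= 0) & (uu < 1)
    inside_v = (vv >= 0) & (vv < 1)
    uu, cols = uu[inside_u], cols[inside_u]
    vv, rows = vv[inside_v], rows[inside_v]
    if not len(uu) or not len(vv):
        return out
    U, V = np.meshgrid(uu, vv)
    vals = sample_grid_np(probs, U.ravel(), V.ravel()).reshape(len(vv), len(uu))
    rr = (rows - 0.5).astype(int)
    cc = (cols - 0.5).astype(int)
    out[np.ix_(rr, cc)] = vals > thr
    return out
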