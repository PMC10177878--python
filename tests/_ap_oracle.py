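"""Independent reference implementation of COCO-style AP, written as plain
loops over detections, for cross-checking the package evaluator.

Follows the published COCO evaluation protocol directly: per image, category
and IoU threshold, detections in descending score order greedily claim the
unmatched ground truth with the highest IoU (preferring non-ignored ones);
ground truths outside the area range are ignored, detections matched to them
are ignored, and unmatched detections outside the range are ignored too.
Precision is interpolated at 101 recall points under the running-maximum
envelope.
"""

import numpy as np


def mask_iou(a, b):
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


def box_iou(a, b):
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def ap_oracle(dets_by_image, gts_by_image, category, thr, area_lo, area_hi,
              kind="mask", max_dets=100):
    """AP for one category at one threshold and area range; None if no GT.

    dets_by_image: {img: [Detection-like]}, gts_by_image: {img: [record]}.
    """
    iou_fn = mask_iou if kind == "mask" else box_iou
    records = []  # (score, is_tp, is_ignored)
    n_gt = 0
    for img in sorted(set(dets_by_image) | set(gts_by_image)):
        gts = [g for g in gts_by_image.get(img, [])
               if g.category_id == category]
        ignore = [not (area_lo <= float(g.area) < area_hi) for g in gts]
        order = sorted(range(len(gts)), key=lambda i: ignore[i])
        gts = [gts[i] for i in order]
        ignore = [ignore[i] for i in order]
        n_gt += sum(1 for ig in ignore if not ig)
        dets = [d for d in dets_by_image.get(img, [])
                if d.category_id == category]
        dets = sorted(dets, key=lambda d: -d.score)[:max_dets]
        claimed = [False] * len(gts)
        for d in dets:
            dobj = d.mask if kind == "mask" else d.box
            best_iou = thr - 1e-10
            best_g = -1
            for gi, g in enumerate(gts):
                if claimed[gi]:
                    continue
                if best_g > -1 and not ignore[best_g] and ignore[gi]:
                    break
                v = iou_fn(dobj, g.mask if kind == "mask" else g.bbox)
                if v < best_iou:
                    continue
                best_iou = v
                best_g = gi
            if best_g > -1:
                claimed[best_g] = True
                records.append((d.score, not ignore[best_g],
                                ignore[best_g]))
            else:
                darea = (float(d.mask.sum()) if kind == "mask"
                         else float(d.box[2] * d.box[3]))
                out_of_range = not (area_lo <= darea < area_hi)
                records.append((d.score, False, out_of_range))
    if n_gt == 0:
        return None
    records.sort(key=lambda r: -r[0])
    tp = fp = 0
    curve = []  # (recall, precision)
    for score, is_tp, ignored in records:
        if ignored:
            continue
        if is_tp:
            tp += 1
        else:
            fp += 1
        curve.append((tp / n_gt, tp / (tp + fp)))
    if not curve:
        return 0.0
    recalls = [c[0] for c in curve]
    precisions = [c[1] for c in curve]
    for i in range(len(precisions) - 2, -1, -1):
        precisions[i] = max(precisions[i], precisions[i + 1])
    total = 0.0
    for rt in np.linspace(0, 1, 101):
        p = 0.0
        for r, pr in zip(recalls, precisions):
            if r >= rt - 1e-12:
                p = pr
                break
        total += p
    return total / 101


def family_oracle(dets_by_image, gts_by_image, kind="mask"):
    """The six-metric AP family via the loop oracle."""
    thrs = [round(0.5 + 0.05 * i, 2) for i in range(10)]
    ranges = {"all": (0, float("inf")), "small": (0, 32 ** 2),
              "medium": (32 ** 2, 96 ** 2), "large": (96 ** 2, float("inf"))}

    def mean_over_cats(thr_list, area):
        lo, hi = ranges[area]
        vals = []
        for c in (1, 2, 3):
            per = [ap_oracle(dets_by_image, gts_by_image, c, t, lo, hi, kind)
                   for t in thr_list]
            per = [v for v in per if v is not None]
            if per:
                vals.append(sum(per) / len(per))
        return sum(vals) / len(vals) if vals else 0.0

    return {
        "AP": mean_over_cats(thrs, "all"),
        "AP50": mean_over_cats([0.5], "all"),
        "AP75": mean_over_cats([0.75], "all"),
        "APs": mean_over_cats(thrs, "small"),
        "APm": mean_over_cats(thrs, "medium"),
        "APl": mean_over_cats(thrs, "large"),
    }


def random_result_set(seed, size=96, n_images=3):
    """A randomized phantom-like GT + detection set for oracle comparison.

    Detections are perturbed copies of the ground truth (jittered masks,
    random scores) plus spurious extras and random dropouts, so TP/FP
    orderings, area buckets and tie cases all occur.
    """
    from uteroseg.model import Detection
    from uteroseg.phantom import InstanceRecord

    rng = np.random.default_rng(seed)
    cats = {1: "uterine_wall", 2: "uterine_cavity", 3: "myoma"}
    gts = {}
    dets = {}
    for img in range(n_images):
        recs = []
        ds = []
        for _ in range(rng.integers(2, 6)):
            c = int(rng.integers(1, 4))
            r = int(rng.integers(2, 30))
            cx, cy = rng.integers(r + 1, size - r - 1, 2)
            yy, xx = np.mgrid[0:size, 0:size]
            m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
            recs.append(InstanceRecord(cats[c], m))
            if rng.uniform() < 0.85:  # detected, possibly jittered
                shift = rng.integers(-r // 2 - 1, r // 2 + 2, 2)
                dm = np.roll(m, shift, axis=(0, 1))
                x, y, w, h = recs[-1].bbox
                ds.append(Detection(
                    c if rng.uniform() < 0.9 else int(rng.integers(1, 4)),
                    float(np.round(rng.uniform(0.1, 1.0), 2)),
                    (float(x + shift[1]), float(y + shift[0]),
                     float(w), float(h)), dm))
        for _ in range(rng.integers(0, 3)):  # spurious detections
            c = int(rng.integers(1, 4))
            r = int(rng.integers(2, 20))
            cx, cy = rng.integers(r + 1, size - r - 1, 2)
            yy, xx = np.mgrid[0:size, 0:size]
            m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
            ds.append(Detection(c, float(np.round(rng.uniform(0.1, 1.0), 2)),
                                (float(cx - r), float(cy - r),
                                 float(2 * r), float(2 * r)), m))
        gts[img] = recs
        dets[img] = ds
    return dets, gts
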