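"""COCO-style evaluator: buckets, matching, AP values, confusion matrix."""

import numpy as np
import pytest

from uteroseg.evaluation import (area_bucket, evaluate_sets, confusion_matrix,
                                 mask_iou, box_iou_xywh, _ap_single,
                                 AREA_RANGES, detections_to_results,
                                 load_results)
from uteroseg.model import Detection
from uteroseg.phantom import InstanceRecord

from _ap_oracle import family_oracle, random_result_set


def _disc(size, cx, cy, r):
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _as_det(rec, score=0.9, cat=None):
    x, y, w, h = rec.bbox
    return Detection(cat or rec.category_id, score,
                     (float(x), float(y), float(w), float(h)),
                     rec.mask.copy())


class TestAreaBucket:
    @pytest.mark.parametrize("area,bucket", [
        (300, "small"), (1023, "small"), (1024, "medium"), (2000, "medium"),
        (9215, "medium"), (9216, "large"), (10000, "large"),
    ])
    def test_breakpoints(self, area, bucket):
        assert area_bucket(area) == bucket

    def test_ranges_consistent_with_buckets(self):
        assert AREA_RANGES["small"][1] == 32 ** 2
        assert AREA_RANGES["medium"] == (32 ** 2, 96 ** 2)


class TestMatchingSemantics:
    def test_identical_detection_is_tp_at_every_threshold(self):
        rec = InstanceRecord("myoma", _disc(64, 30, 30, 10))
        gts = {0: [rec]}
        dets = {0: [_as_det(rec)]}
        rep = evaluate_sets(dets, gts)
        assert rep.mask["AP"] == pytest.approx(1.0)
        assert rep.box["AP"] == pytest.approx(1.0)

    def test_two_detections_one_gt_gives_one_fp(self):
        rec = InstanceRecord("myoma", _disc(64, 30, 30, 10))
        gts = {0: [rec]}
        dets = {0: [_as_det(rec, 0.9), _as_det(rec, 0.8)]}
        d = {(1, 0.5): None}
        ap, npig = _ap_single(
            {0: [(0.9, 314, rec.mask), (0.8, 314, rec.mask)]},
            {0: [(float(rec.area), rec.mask)]},
            mask_iou, 0.5, AREA_RANGES["all"])
        assert npig == 1
        assert ap == pytest.approx(1.0)  # TP ranked first; FP after full recall
        _ = d

    def test_iou_point_six_is_tp_at_50_fp_at_75(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[5, 0:8] = True   # 8 px
        b[5, 2:10] = True  # 8 px, intersection 6, union 10 -> IoU 0.6
        assert mask_iou(a, b) == pytest.approx(0.6)
        gt = InstanceRecord("myoma", a)
        det = Detection(3, 0.9, (2.0, 5.0, 8.0, 1.0), b)
        rep = evaluate_sets({0: [det]}, {0: [gt]})
        ap50, _ = _ap_single({0: [(0.9, 8.0, b)]},
                             {0: [(8.0, a)]}, mask_iou, 0.5,
                             AREA_RANGES["all"])
        ap75, _ = _ap_single({0: [(0.9, 8.0, b)]},
                             {0: [(8.0, a)]}, mask_iou, 0.75,
                             AREA_RANGES["all"])
        assert ap50 == pytest.approx(1.0)
        assert ap75 == pytest.approx(0.0)
        _ = rep


class TestAPValues:
    def test_all_gt_found_no_fp(self):
        recs = [InstanceRecord("uterine_wall", _disc(96, 40, 40, 20)),
                InstanceRecord("myoma", _disc(96, 70, 70, 8))]
        rep = evaluate_sets({0: [_as_det(r) for r in recs]}, {0: recs})
        for key in ("AP", "AP50", "AP75"):
            assert rep.mask[key] == pytest.approx(1.0)

    def test_no_detections_zero(self):
        recs = [InstanceRecord("myoma", _disc(64, 30, 30, 9))]
        rep = evaluate_sets({0: []}, {0: recs})
        assert rep.mask["AP"] == 0.0 and rep.box["AP50"] == 0.0

    def test_one_tp_one_fp_two_gt_hand_computed(self):
        """PR curve: (0.5, 1.0) then (0.5, 0.5); the 101-point interpolated
        AP is 51/101."""
        g1 = InstanceRecord("myoma", _disc(64, 20, 20, 8))
        g2 = InstanceRecord("myoma", _disc(64, 45, 45, 8))
        fp_mask = _disc(64, 32, 10, 5)
        dets = {0: [_as_det(g1, 0.9),
                    Detection(3, 0.8, (27.0, 5.0, 10.0, 10.0), fp_mask)]}
        ap, _ = _ap_single(
            {0: [(0.9, float(g1.area), g1.mask),
                 (0.8, float(fp_mask.sum()), fp_mask)]},
            {0: [(float(g1.area), g1.mask), (float(g2.area), g2.mask)]},
            mask_iou, 0.5, AREA_RANGES["all"])
        assert ap == pytest.approx(51 / 101)

    def test_adding_low_ranked_fp_never_increases_ap(self, rng):
        dets, gts = random_result_set(5)
        base = evaluate_sets(dets, gts).mask
        extra = Detection(1, 0.01, (1.0, 1.0, 10.0, 10.0),
                          _disc(96, 6, 6, 5))
        dets2 = {k: list(v) for k, v in dets.items()}
        dets2[0] = dets2[0] + [extra]
        worse = evaluate_sets(dets2, gts).mask
        for key in base:
            assert worse[key] <= base[key] + 1e-12

    def test_adding_top_confidence_tp_never_decreases_ap(self):
        g1 = InstanceRecord("myoma", _disc(64, 20, 20, 8))
        g2 = InstanceRecord("myoma", _disc(64, 45, 45, 8))
        dets = {0: [_as_det(g1, 0.5)]}
        base = evaluate_sets(dets, {0: [g1, g2]}).mask
        dets2 = {0: dets[0] + [_as_det(g2, 1.0)]}
        better = evaluate_sets(dets2, {0: [g1, g2]}).mask
        for key in base:
            assert better[key] >= base[key] - 1e-12


def test_evaluator_matches_loop_oracle_on_random_sets():
    """The decisive cross-check: vectorized evaluator vs the independent
    loop implementation on randomized result sets, all six metrics."""
    for seed in range(8):
        dets, gts = random_result_set(seed)
        rep = evaluate_sets(dets, gts)
        for kind, got in (("mask", rep.mask), ("box", rep.box)):
            want = family_oracle(dets, gts, kind)
            for key in ("AP", "AP50", "AP75", "APs", "APm", "APl"):
                assert got[key] == pytest.approx(want[key], abs=1e-6), \
                    (seed, kind, key)


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self):
        recs = [InstanceRecord("uterine_wall", _disc(96, 40, 40, 20)),
                InstanceRecord("uterine_cavity", _disc(96, 40, 40, 6)),
                InstanceRecord("myoma", _disc(96, 75, 75, 9))]
        # cavity overlaps wall spatially; give each its own detection
        recs[0].mask &= ~recs[1].mask
        C, labels = confusion_matrix({0: [_as_det(r) for r in recs]},
                                     {0: recs})
        assert labels == ("uterine_wall", "uterine_cavity", "myoma",
                          "background")
        assert np.allclose(C[:, :3], np.eye(3))

    def test_rows_normalize_to_one(self):
        dets, gts = random_result_set(3)
        C, _ = confusion_matrix(dets, gts)
        sums = C.sum(axis=1)
        present = sums > 0
        assert np.allclose(sums[present], 1.0)

    def test_mislabeled_detection_increments_cross_cell(self):
        wall = InstanceRecord("uterine_wall", _disc(96, 40, 40, 20))
        det = _as_det(wall, 0.9, cat=3)  # labeled myoma
        C, _ = confusion_matrix({0: [det]}, {0: [wall]})
        assert C[0, 2] == 1.0  # row wall, column myoma

    def test_unmatched_gt_goes_to_background(self):
        wall = InstanceRecord("uterine_wall", _disc(96, 40, 40, 20))
        C, _ = confusion_matrix({0: []}, {0: [wall]})
        assert C[0, -1] == 1.0


def test_results_json_roundtrip(tmp_path):
    dets, gts = random_result_set(1)
    recs = detections_to_results(dets)
    path = tmp_path / "results.json"
    import json

    path.write_text(json.dumps(recs))
    sizes = {img: (96, 96) for img in dets}
    back = load_results(path, sizes)
    for img in dets:
        assert len(back[img]) == len(dets[img])
        got = sorted(back[img], key=lambda d: -d.score)
        want = sorted(dets[img], key=lambda d: -d.score)
        for a, b in zip(got, want):
            assert a.category_id == b.category_id
            assert a.score == pytest.approx(b.score)
            assert np.array_equal(a.mask, b.mask)
    rep_a = evaluate_sets(dets, gts)
    rep_b = evaluate_sets({k: back[k] for k in gts}, gts)
    assert rep_a.mask == pytest.approx(rep_b.mask)
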