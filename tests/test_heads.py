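"""Detection heads: anchors, matching, box coding, NMS, ROIAlign."""

import numpy as np
import pytest

from uteroseg.grad import Tensor
from uteroseg.heads import (generate_anchors, match_anchors, encode_box,
                            decode_box, nms, iou_matrix, roi_align, roi_level,
                            RPNHead, BoxHead)


class TestAnchorGrid:
    def test_counts_per_level(self):
        anchors = generate_anchors(
            {"P3": (16, 16)}, {"P3": [(10, 10), (20, 20), (30, 30)]})
        assert len(anchors) == 3 * 16 * 16

    def test_desk_profile_total(self):
        shapes = {"P3": (16, 16), "P4": (8, 8), "P5": (4, 4)}
        apl = {lvl: [(10, 10), (20, 20), (30, 30)] for lvl in shapes}
        assert len(generate_anchors(shapes, apl)) == (256 + 64 + 16) * 3

    def test_centers_at_half_stride(self):
        anchors = generate_anchors({"P3": (2, 2)}, {"P3": [(8, 8)]})
        centers = (anchors[:, :2] + anchors[:, 2:]) / 2
        assert np.allclose(centers, [[4, 4], [12, 4], [4, 12], [12, 12]])


class TestMatching:
    def test_identical_anchor_is_positive(self):
        gt = np.array([[10, 10, 30, 30]])
        anchors = np.array([[10, 10, 30, 30], [100, 100, 120, 120]])
        labels, matched = match_anchors(anchors, gt)
        assert labels[0] == 1 and matched[0] == 0

    def test_zero_overlap_is_negative(self):
        gt = np.array([[0, 0, 10, 10]])
        anchors = np.array([[50, 50, 60, 60], [0, 0, 10, 10]])
        labels, _ = match_anchors(anchors, gt)
        assert labels[0] == 0

    def test_every_gt_force_matched(self, rng):
        anchors = rng.uniform(0, 100, size=(50, 2))
        anchors = np.concatenate([anchors, anchors + 8], axis=1)
        gt = np.array([[200.0, 200.0, 203.0, 203.0]])  # overlaps nothing
        labels, matched = match_anchors(anchors, gt)
        iou = iou_matrix(anchors, gt)[:, 0]
        forced = int(iou.argmax())
        assert labels[forced] == 1 and matched[forced] == 0

    def test_no_gt_all_negative(self):
        anchors = np.array([[0, 0, 10, 10], [5, 5, 20, 20]])
        labels, _ = match_anchors(anchors, np.zeros((0, 4)))
        assert np.all(labels == 0)


class TestBoxCodec:
    def test_gt_equals_anchor_gives_zero(self):
        b = np.array([[5, 5, 25, 45]])
        assert np.allclose(encode_box(b, b), 0)

    def test_roundtrip_many(self, rng):
        gt = rng.uniform(0, 50, size=(100, 2))
        gt = np.concatenate([gt, gt + rng.uniform(5, 60, (100, 2))], axis=1)
        an = rng.uniform(0, 50, size=(100, 2))
        an = np.concatenate([an, an + rng.uniform(5, 60, (100, 2))], axis=1)
        back = decode_box(encode_box(gt, an), an)
        assert np.abs(back - gt).max() < 1e-6

    def test_log_width_parameterization(self):
        anchor = np.array([[0, 0, 10, 10]])
        gt = np.array([[-5, 0, 15, 10]])  # same center, double width
        t = encode_box(gt, anchor)[0]
        assert t[2] == pytest.approx(np.log(2))
        assert t[0] == pytest.approx(0) and t[3] == pytest.approx(0)


class TestNMS:
    def test_single_box_kept(self):
        assert list(nms(np.array([[0, 0, 10, 10]]), np.array([0.9]), 0.5)) == [0]

    def test_duplicate_keeps_higher_score_then_lower_index(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]])
        assert list(nms(boxes, np.array([0.5, 0.9]), 0.5)) == [1]
        assert list(nms(boxes, np.array([0.7, 0.7]), 0.5)) == [0]

    def test_matches_brute_force_oracle(self, rng):
        def brute(boxes, scores, thr):
            order = np.argsort(-scores, kind="stable")
            kept = []
            for i in order:
                if all(iou_matrix(boxes[i][None], boxes[j][None])[0, 0] <= thr
                       for j in kept):
                    kept.append(int(i))
            return kept

        for _ in range(5):
            xy = rng.uniform(0, 80, (50, 2))
            boxes = np.concatenate([xy, xy + rng.uniform(5, 40, (50, 2))], axis=1)
            scores = rng.uniform(size=50)
            assert list(nms(boxes, scores, 0.5)) == brute(boxes, scores, 0.5)


class TestROIAlign:
    def test_integer_aligned_roi_is_exact_crop(self, rng):
        f = Tensor(rng.normal(size=(1, 3, 12, 12)))
        out = roi_align(f, np.array([[2, 3, 10, 11]]), 8, sampling_ratio=1)
        assert np.array_equal(out.data[0], f.data[0][:, 3:11, 2:10])

    def test_constant_map_gives_constant_output(self):
        f = Tensor(np.full((1, 2, 10, 10), 3.25))
        out = roi_align(f, np.array([[1.3, 2.7, 8.9, 9.1]]), 7)
        assert np.allclose(out.data, 3.25)

    def test_integer_translation_equivariance(self, rng):
        f = Tensor(rng.normal(size=(1, 3, 20, 20)))
        roi = np.array([[2.3, 3.7, 10.1, 11.9]])
        out = roi_align(f, roi, 7)
        f2 = Tensor(np.roll(f.data, (2, 3), axis=(2, 3)))
        out2 = roi_align(f2, roi + [3, 2, 3, 2], 7)
        assert np.abs(out2.data - out.data).max() < 1e-12

    def test_stride_rescales_coordinates(self, rng):
        f = Tensor(rng.normal(size=(1, 2, 16, 16)))
        a = roi_align(f, np.array([[8, 8, 64, 64]]), 7, stride=8.0)
        b = roi_align(f, np.array([[1, 1, 8, 8]]), 7, stride=1.0)
        assert np.allclose(a.data, b.data)


def test_roi_level_routing_is_pure_area_function():
    boxes = np.array([[0, 0, 32, 32], [0, 0, 224, 224], [0, 0, 500, 500],
                      [0, 0, 900, 900]])
    assert list(roi_level(boxes)) == [3, 3, 4, 5]


class TestHeads:
    def test_rpn_output_shapes_follow_anchor_count(self, rng):
        from uteroseg.backbone import HRBackbone, BackboneConfig

        bb = HRBackbone(BackboneConfig(), seed=0)
        pyr = bb(Tensor(rng.normal(size=(1, 1, 128, 128)))).as_dict()
        rpn = RPNHead(32, 3, seed=0)
        logits, deltas = rpn(pyr)
        assert logits.data.shape == (1008,)
        assert deltas.data.shape == (1008, 4)

    def test_box_head_scores_normalize(self, rng):
        head = BoxHead(8, pool=7, n_classes=3, hidden=16, seed=0)
        pooled = Tensor(rng.normal(size=(5, 8, 7, 7)))
        logits, deltas = head(pooled)
        from uteroseg.grad import softmax
        probs = softmax(logits, axis=1).data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert deltas.data.shape == (5, 3, 4)

    def test_zero_weight_head_is_uniform(self, rng):
        head = BoxHead(4, pool=7, n_classes=3, hidden=8, seed=0)
        for lin in (head.fc1, head.fc2, head.cls, head.box):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        logits, _ = head(Tensor(rng.normal(size=(3, 4, 7, 7))))
        from uteroseg.grad import softmax
        assert np.allclose(softmax(logits, axis=1).data, 0.25)

    def test_batch_independence(self, rng):
        head = BoxHead(4, pool=7, n_classes=3, hidden=8, seed=1)
        pooled = rng.normal(size=(6, 4, 7, 7))
        logits, _ = head(Tensor(pooled))
        perm = rng.permutation(6)
        logits_p, _ = head(Tensor(pooled[perm]))
        assert np.allclose(logits.data[perm], logits_p.data)
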