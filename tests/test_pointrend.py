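"""Uncertainty-guided point selection and iterative mask refinement."""

import numpy as np
import pytest

from uteroseg.grad import Tensor
from uteroseg.pointrend import (CoarseMaskHead, PointHead,
                                select_training_points,
                                select_inference_points, point_features,
                                iterative_refine, upsample2x_np,
                                sample_grid_np)


class TestCoarseMaskHead:
    def test_zero_weight_head_gives_half_probability(self, rng):
        head = CoarseMaskHead(4, n_classes=3, grid=7, seed=0)
        head.out.weight.data[:] = 0
        head.out.bias.data[:] = 0
        logits = head(Tensor(rng.normal(size=(2, 4, 14, 14))))
        probs = 1 / (1 + np.exp(-logits.data))
        assert logits.data.shape == (2, 3, 7, 7)
        assert np.allclose(probs, 0.5)

    def test_deterministic(self, rng):
        head = CoarseMaskHead(4, seed=1)
        x = Tensor(rng.normal(size=(1, 4, 14, 14)))
        assert np.array_equal(head(x).data, head(x).data)


class TestTrainingPointSelection:
    def test_beta_one_takes_most_uncertain_of_candidates(self):
        grid = np.linspace(0, 1, 64).reshape(8, 8)
        rng = np.random.default_rng(0)
        sel = select_training_points(grid, k=3.0, beta=1.0, N=10, rng=rng)
        assert len(sel.points) == 10
        # oracle: the 10 smallest |p-0.5| among the same kN candidates
        rng2 = np.random.default_rng(0)
        cand = rng2.uniform(size=(30, 2))
        probs = sample_grid_np(grid, cand[:, 0], cand[:, 1])
        expect = np.sort(np.abs(probs - 0.5))[:10]
        assert np.allclose(np.sort(sel.uncertainty), expect)

    def test_beta_zero_is_uniform_random(self):
        grid = np.full((4, 4), 0.9)
        rng = np.random.default_rng(1)
        sel = select_training_points(grid, k=2.0, beta=0.0, N=16, rng=rng)
        assert len(sel.points) == 16
        assert np.all((sel.points >= 0) & (sel.points <= 1))

    def test_specified_uncertainty_ordering(self):
        """Candidates 0.1/0.45/0.8/0.52: the two most uncertain are 0.52
        (|d|=0.02) then 0.45 (|d|=0.05)."""
        probs = np.array([0.1, 0.45, 0.8, 0.52])
        order = np.argsort(np.abs(probs - 0.5), kind="stable")
        assert list(probs[order[:2]]) == [0.52, 0.45]

    def test_parameter_validation(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            select_training_points(np.full((4, 4), 0.5), k=1.0, beta=0.5,
                                   N=4, rng=rng)
        with pytest.raises(ValueError):
            select_training_points(np.full((4, 4), 0.5), k=2.0, beta=1.5,
                                   N=4, rng=rng)
        with pytest.raises(ValueError):
            select_training_points(np.full((4, 4), np.nan), k=2.0, beta=0.5,
                                   N=4, rng=rng)


class TestInferencePointSelection:
    def test_saturated_grid_ties_break_row_major(self):
        grid = np.array([[0.0, 1.0], [1.0, 0.0]])
        sel = select_inference_points(grid, 3)
        assert list(sel.indices) == [0, 1, 2]

    def test_exact_half_probabilities_selected(self):
        grid = np.full((4, 4), 0.9)
        grid[0, 1] = grid[2, 3] = grid[3, 0] = 0.5
        sel = select_inference_points(grid, 3)
        assert sorted(sel.indices) == [1, 11, 12]

    def test_matches_exhaustive_sort_oracle(self, rng):
        for _ in range(100):
            grid = rng.uniform(size=(16, 16))
            n = int(rng.integers(1, 40))
            sel = select_inference_points(grid, n)
            oracle = np.argsort(np.abs(grid.ravel() - 0.5),
                                kind="stable")[:n]
            assert np.array_equal(sel.indices, oracle)


class TestPointFeatures:
    def test_grid_node_recovers_node_vector(self, rng):
        fmap = Tensor(rng.normal(size=(1, 5, 8, 8)))
        coarse = Tensor(np.zeros((1, 3, 7, 7)))
        roi = np.array([0.0, 0.0, 8.0, 8.0])
        # unit point u=(2.5/8) -> feature coord 2.5 = center of pixel 2
        pts = np.array([[2.5 / 8, 3.5 / 8]])
        feats, _ = point_features(fmap, coarse, roi, pts, stride=1.0)
        assert np.allclose(feats.data[0, :5], fmap.data[0, :, 3, 2])

    def test_constant_map_constant_features(self, rng):
        fmap = Tensor(np.full((1, 4, 8, 8), 1.5))
        coarse = Tensor(np.zeros((1, 3, 7, 7)))
        pts = rng.uniform(0.2, 0.8, size=(6, 2))
        feats, _ = point_features(fmap, coarse, np.array([8, 8, 56, 56]),
                                  pts, stride=8.0)
        assert np.allclose(feats.data[:, :4], 1.5)

    def test_midpoint_of_linear_ramp_is_average(self):
        ramp = np.arange(8, dtype=float)
        fmap = Tensor(np.broadcast_to(ramp, (1, 1, 8, 8)).copy())
        coarse = Tensor(np.zeros((1, 3, 7, 7)))
        pts = np.array([[3.0 / 8, 0.5]])  # between centers of cols 2 and 3
        feats, _ = point_features(fmap, coarse, np.array([0, 0, 8, 8]),
                                  pts, stride=1.0)
        assert feats.data[0, 0] == pytest.approx((2.0 + 3.0) / 2)


class TestPointHead:
    def test_zero_weights_give_half(self, rng):
        head = PointHead(9, n_classes=3, hidden=8, seed=0)
        for fc in head.fcs + [head.out]:
            fc.weight.data[:] = 0
            fc.bias.data[:] = 0
        out = head(Tensor(rng.normal(size=(5, 9))),
                   Tensor(rng.normal(size=(5, 3))))
        assert np.allclose(1 / (1 + np.exp(-out.data)), 0.5)

    def test_pointwise_independence(self, rng):
        head = PointHead(7, n_classes=3, hidden=8, seed=1)
        feats = rng.normal(size=(6, 7))
        coarse = rng.normal(size=(6, 3))
        out = head(Tensor(feats), Tensor(coarse)).data
        perm = rng.permutation(6)
        out_p = head(Tensor(feats[perm]), Tensor(coarse[perm])).data
        assert np.allclose(out[perm], out_p)

    def test_full_profile_layer_sizes(self):
        head = PointHead(131, n_classes=3, hidden=256, layers=3, seed=0)
        assert len(head.fcs) == 3
        assert all(fc.weight.data.shape[1] == 256 for fc in head.fcs)


class TestIterativeRefine:
    def test_zero_steps_returns_coarse(self, rng):
        grid = rng.uniform(size=(7, 7))
        assert np.array_equal(iterative_refine(grid, 0, 10, None), grid)

    def test_interpolating_point_head_is_noop(self, rng):
        """A point head that echoes the interpolated value leaves the
        output bit-identical to plain repeated bilinear upsampling."""
        grid = rng.uniform(size=(7, 7))
        plain = grid
        for _ in range(3):
            plain = upsample2x_np(plain)
        echoed = iterative_refine(grid, 3, 16,
                                  point_fn=lambda pts, interp: interp)
        assert np.array_equal(plain, echoed)

    def test_output_side_doubles_per_step(self):
        out = iterative_refine(np.full((4, 4), 0.5), 3, 0, None)
        assert out.shape == (32, 32)

    def test_replaces_at_most_n_points_per_step(self, rng):
        grid = rng.uniform(size=(4, 4))
        n_per = 5
        one_step = iterative_refine(grid, 1, n_per,
                                    point_fn=lambda p, i: i + 100)
        plain = upsample2x_np(grid)
        assert (one_step != plain).sum() <= n_per
        # over multiple steps the point head is consulted for exactly
        # steps * n_per points in total
        calls = []
        iterative_refine(grid, 3, n_per,
                         point_fn=lambda p, i: calls.append(len(p)) or i)
        assert sum(calls) == 3 * n_per


def test_refinement_improves_boundary_over_plain_upsampling(rng):
    """With an oracle point head, refining the most uncertain points of a
    blurred disc recovers a sharper boundary than plain upsampling."""
    yy, xx = np.mgrid[0:56, 0:56]
    gt = ((xx - 28) ** 2 / 18 ** 2 + (yy - 28) ** 2 / 11 ** 2) <= 1.0
    coarse = sample_grid_np(gt.astype(float),
                            *np.meshgrid((np.arange(7) + 0.5) / 7,
                                         (np.arange(7) + 0.5) / 7))
    coarse = np.clip(coarse + rng.normal(0, 0.05, coarse.shape), 0, 1)

    def oracle_fn(pts, interp):
        return sample_grid_np(gt.astype(float), pts[:, 0], pts[:, 1])

    refined = iterative_refine(coarse, 3, 64, oracle_fn) > 0.5
    plain = iterative_refine(coarse, 3, 0, None) > 0.5

    def boundary_iou(pred):
        from scipy.ndimage import binary_dilation, binary_erosion
        band = binary_dilation(gt, iterations=2) & ~binary_erosion(
            gt, iterations=2)
        inter = (pred & gt & band).sum()
        union = ((pred | gt) & band).sum()
        return inter / union

    assert boundary_iou(refined) >= boundary_iou(plain)
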