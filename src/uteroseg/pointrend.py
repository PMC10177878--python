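"""Coarse mask prediction with uncertainty-guided point refinement.

The mask branch first predicts a low-resolution per-class probability grid
for each ROI.  At inference the grid is repeatedly 2x bilinearly upsampled;
after each upsampling the N most uncertain points — those whose foreground
probability is closest to 0.5, i.e. argmin |p(n_i) - 0.5| — are re-predicted
by a small shared MLP (the point head) that consumes fine-grained backbone
features concatenated with the coarse prediction, bilinearly sampled at the
point.  During training, point supervision uses biased random sampling:
of kN uniformly drawn candidate points the beta*N most uncertain are kept
and the remaining (1-beta)*N are drawn uniformly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .grad import Tensor, grid_sample, _bilinear_resize_matrix

__all__ = ["PointSelection", "CoarseMaskHead", "PointHead",
           "select_training_points", "select_inference_points",
           "point_features", "iterative_refine", "upsample2x_np",
           "sample_grid_np"]


@dataclasses.dataclass
class PointSelection:
    """Selected refinement points: unit-square coords and their uncertainty."""
    points: np.ndarray          # (N, 2) as (u, v) in [0, 1]
    probability: np.ndarray     # (N,) p at each point
    indices: np.ndarray | None = None  # flat grid indices when grid-aligned

    @property
    def uncertainty(self) -> np.ndarray:
        return np.abs(self.probability - 0.5)


class CoarseMaskHead(nn.Module):
    """Per-class coarse mask logits on a low-resolution grid.

    Input: ROI features (R, C, 2g, 2g); output logits (R, n_classes, g, g).
    """

    def __init__(self, channels: int, n_classes: int = 3, grid: int = 7,
                 hidden: int | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        hidden = hidden or channels
        self.grid = grid
        self.conv1 = nn.ConvNorm(channels, hidden, 3, rng=rng)
        self.conv2 = nn.ConvNorm(hidden, hidden, 3, rng=rng)
        self.down = nn.ConvNorm(hidden, hidden, 3, stride=2, rng=rng)
        self.out = nn.Conv2d(hidden, n_classes, 1, rng=rng, std=0.01)

    def forward(self, roi_features: Tensor) -> Tensor:
        t = self.conv1(roi_features).relu()
        t = self.conv2(t).relu()
        t = self.down(t).relu()
        return self.out(t)


class PointHead(nn.Module):
    """Shared MLP over per-point feature vectors -> per-class logits.

    Three hidden layers (256 channels at full scale); the coarse prediction
    is re-appended to the input of every hidden layer, as is standard for
    point-wise refinement heads.
    """

    def __init__(self, in_channels: int, n_classes: int = 3,
                 hidden: int = 256, layers: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        dims = [in_channels] + [hidden] * layers
        self.fcs = [nn.Linear(dims[i] + (n_classes if i > 0 else 0), dims[i + 1],
                              rng=rng) for i in range(layers)]
        self.out = nn.Linear(hidden + n_classes, n_classes, rng=rng)

    def forward(self, feats: Tensor, coarse: Tensor) -> Tensor:
        """feats: (P, C_fine + n_classes); coarse: (P, n_classes) logits."""
        from .grad import concat
        t = feats
        for i, fc in enumerate(self.fcs):
            t = fc(t if i == 0 else concat([t, coarse], axis=1)).relu()
        return self.out(concat([t, coarse], axis=1))


# ---------------------------------------------------------------------------
# point selection
# ---------------------------------------------------------------------------

def sample_grid_np(grid: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Bilinear sample of a (h, w) grid at unit-square points, border-clamped."""
    h, w = grid.shape
    x = np.clip(u * w - 0.5, 0.0, w - 1.0)
    y = np.clip(v * h - 0.5, 0.0, h - 1.0)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    tx = x - x0
    ty = y - y0
    return (grid[y0, x0] * (1 - tx) * (1 - ty) + grid[y0, x1] * tx * (1 - ty)
            + grid[y1, x0] * (1 - tx) * ty + grid[y1, x1] * tx * ty)


def select_training_points(prob_grid: np.ndarray, k: float, beta: float,
                           N: int, rng: np.random.Generator) -> PointSelection:
    """Biased random point sampling for training supervision.

    Draw kN uniform candidates, keep the round(beta*N) most uncertain, and
    fill up to N with fresh uniform points.
    """
    if not np.isfinite(prob_grid).all():
        raise ValueError("non-finite probabilities in coarse grid")
    if not k > 1:
        raise ValueError("oversampling factor k must be > 1")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    n_cand = int(np.ceil(k * N))
    cand = rng.uniform(size=(n_cand, 2))
    probs = sample_grid_np(prob_grid, cand[:, 0], cand[:, 1])
    n_unc = int(round(beta * N))
    order = np.argsort(np.abs(probs - 0.5), kind="stable")[:n_unc]
    pts = [cand[order]]
    pvals = [probs[order]]
    n_rand = N - n_unc
    if n_rand > 0:
        extra = rng.uniform(size=(n_rand, 2))
        pts.append(extra)
        pvals.append(sample_grid_np(prob_grid, extra[:, 0], extra[:, 1]))
    return PointSelection(np.concatenate(pts, axis=0),
                          np.concatenate(pvals, axis=0))


def select_inference_points(prob_grid: np.ndarray, N: int) -> PointSelection:
    """The N grid points with smallest |p - 0.5|; ties by row-major index."""
    if not np.isfinite(prob_grid).all():
        raise ValueError("non-finite probabilities in grid")
    h, w = prob_grid.shape
    flat = prob_grid.ravel()
    idx = np.argsort(np.abs(flat - 0.5), kind="stable")[:N]
    rows, cols = np.unravel_index(idx, (h, w))
    pts = np.stack([(cols + 0.5) / w, (rows + 0.5) / h], axis=1)
    return PointSelection(pts, flat[idx], indices=idx)


def point_features(fine_feature: Tensor, coarse_logits: Tensor,
                   roi: np.ndarray, points: np.ndarray,
                   stride: float) -> tuple[Tensor, Tensor]:
    """Per-point vectors: fine backbone features ⊕ coarse class logits.

    `fine_feature` is (1, C, H, W) at `stride`; `coarse_logits` is
    (1, n_classes, g, g) for this ROI; `points` are (P, 2) unit-square
    coordinates within `roi` = (x1, y1, x2, y2) in input pixels.
    Returns (features (P, C + n_classes), coarse_at_points (P, n_classes)).
    """
    from .grad import concat
    x1, y1, x2, y2 = np.asarray(roi, dtype=float)
    px = (x1 + points[:, 0] * (x2 - x1)) / stride
    py = (y1 + points[:, 1] * (y2 - y1)) / stride
    fine = grid_sample(fine_feature, px[None], py[None])       # (1, C, P)
    g_h, g_w = coarse_logits.data.shape[2:]
    cx = np.clip(points[:, 0] * g_w, 0.5, g_w - 0.5)
    cy = np.clip(points[:, 1] * g_h, 0.5, g_h - 0.5)
    coarse = grid_sample(coarse_logits, cx[None], cy[None])    # (1, K, P)
    fine2 = fine.reshape(fine.data.shape[1], -1).transpose(1, 0)
    coarse2 = coarse.reshape(coarse.data.shape[1], -1).transpose(1, 0)
    return concat([fine2, coarse2], axis=1), coarse2


def upsample2x_np(grid: np.ndarray) -> np.ndarray:
    """2x bilinear upsampling (half-pixel convention), plain numpy."""
    h, w = grid.shape
    Mr = _bilinear_resize_matrix(h, 2 * h)
    Mc = _bilinear_resize_matrix(w, 2 * w)
    return Mr @ grid @ Mc.T


def iterative_refine(coarse_probs: np.ndarray, steps: int, n_per_step: int,
                     point_fn=None) -> np.ndarray:
    """Coarse-to-fine refinement of a single-class probability grid.

    Each step: 2x bilinear upsampling, selection of the `n_per_step` most
    uncertain grid points, and replacement of their probabilities by
    `point_fn(points, current_probs)` — the point head in the real model.
    With `point_fn=None` (or one that returns its input) the result equals
    plain repeated bilinear upsampling.
    """
    probs = np.asarray(coarse_probs, dtype=float)
    for _ in range(int(steps)):
        probs = upsample2x_np(probs)
        if point_fn is None or n_per_step <= 0:
            continue
        sel = select_inference_points(probs, n_per_step)
        new = np.asarray(point_fn(sel.points, sel.probability), dtype=float)
        rows, cols = np.unravel_index(sel.indices, probs.shape)
        probs[rows, cols] = new
    return probs
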