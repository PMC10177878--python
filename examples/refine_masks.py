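"""Uncertainty-guided point refinement on a known shape.

A coarse 7x7 probability grid of an ellipse is upsampled to 56x56; at each
step the points whose probability is closest to 0.5 (the uncertain boundary
band) are re-predicted — here by an oracle that knows the true shape, which
isolates the effect of the selection rule itself.
"""

import numpy as np

from uteroseg.pointrend import (iterative_refine, select_inference_points,
                                sample_grid_np)

yy, xx = np.mgrid[0:56, 0:56]
truth = ((xx - 28) ** 2 / 20 ** 2 + (yy - 28) ** 2 / 10 ** 2) <= 1.0

uu, vv = np.meshgrid((np.arange(7) + 0.5) / 7, (np.arange(7) + 0.5) / 7)
coarse = sample_grid_np(truth.astype(float), uu, vv)

sel = select_inference_points(coarse, 10)
print("10 most uncertain coarse cells (|p - 0.5| ascending):")
for (u, v), p in zip(sel.points, sel.probability):
    print(f"  point ({u:.2f}, {v:.2f})  p={p:.2f}  |p-0.5|={abs(p-0.5):.2f}")


def oracle(points, interp):
    return sample_grid_np(truth.astype(float), points[:, 0], points[:, 1])


plain = iterative_refine(coarse, steps=3, n_per_step=0) > 0.5
refined = iterative_refine(coarse, steps=3, n_per_step=64,
                           point_fn=oracle) > 0.5


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


print(f"\nmask IoU vs truth: plain upsampling {iou(plain, truth):.3f}, "
      f"point-refined {iou(refined, truth):.3f}")
print("refinement only touches the uncertain boundary band, so the gain is")
print("concentrated where masks are usually wrong: at the contour.")
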