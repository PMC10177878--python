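"""Annotation-preserving data augmentation.

Random horizontal/vertical flips, small rotations and central crops; masks
and boxes are transformed with the image, and instances whose mask is
cropped away entirely are dropped.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import transform

from .phantom import InstanceRecord

__all__ = ["AugmentConfig", "augment", "hflip", "vflip", "rotate",
           "central_crop"]


@dataclasses.dataclass
class AugmentConfig:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_rotate: float = 0.5
    max_angle_deg: float = 15.0
    p_crop: float = 0.5
    crop_scale_range: tuple = (0.8, 1.0)


def _rebuild(image, masks, categories):
    out = []
    for m, c in zip(masks, categories):
        if m.any():
            out.append(InstanceRecord(c, m))
    return image, out


def hflip(image: np.ndarray, instances: list[InstanceRecord]):
    masks = [np.flip(r.mask, axis=1) for r in instances]
    return _rebuild(np.flip(image, axis=1).copy(),
                    [m.copy() for m in masks], [r.category for r in instances])


def vflip(image: np.ndarray, instances: list[InstanceRecord]):
    masks = [np.flip(r.mask, axis=0) for r in instances]
    return _rebuild(np.flip(image, axis=0).copy(),
                    [m.copy() for m in masks], [r.category for r in instances])


def rotate(image: np.ndarray, instances: list[InstanceRecord], angle_deg: float):
    img = transform.rotate(image, angle_deg, order=1, preserve_range=True,
                           mode="edge")
    masks = [transform.rotate(r.mask.astype(float), angle_deg, order=0,
                              preserve_range=True) > 0.5 for r in instances]
    return _rebuild(img, masks, [r.category for r in instances])


def central_crop(image: np.ndarray, instances: list[InstanceRecord],
                 scale: float):
    """Crop the central scale x side square, then resize back to full size."""
    h, w = image.shape
    ch, cw = max(32, int(round(h * scale))), max(32, int(round(w * scale)))
    y0 = (h - ch) // 2
    x0 = (w - cw) // 2
    img = image[y0:y0 + ch, x0:x0 + cw]
    if (ch, cw) != (h, w):
        img = transform.resize(img, (h, w), order=1, preserve_range=True,
                               anti_aliasing=False)
    masks = []
    for r in instances:
        m = r.mask[y0:y0 + ch, x0:x0 + cw].astype(float)
        if (ch, cw) != (h, w):
            m = transform.resize(m, (h, w), order=0, preserve_range=True,
                                 anti_aliasing=False)
        masks.append(m > 0.5)
    return _rebuild(img, masks, [r.category for r in instances])


def augment(image: np.ndarray, instances: list[InstanceRecord],
            rng: np.random.Generator, config: AugmentConfig | None = None):
    """Apply the configured random transforms in a fixed order."""
    cfg = config or AugmentConfig()
    if rng.uniform() < cfg.p_hflip:
        image, instances = hflip(image, instances)
    if rng.uniform() < cfg.p_vflip:
        image, instances = vflip(image, instances)
    if rng.uniform() < cfg.p_rotate:
        angle = rng.uniform(-cfg.max_angle_deg, cfg.max_angle_deg)
        image, instances = rotate(image, instances, angle)
    if rng.uniform() < cfg.p_crop:
        scale = rng.uniform(*cfg.crop_scale_range)
        image, instances = central_crop(image, instances, scale)
    return image, instances
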