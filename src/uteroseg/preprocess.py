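"""Image preprocessing chain: CLAHE -> (external bias hook) -> Z-score -> resize.

Contrast-limited adaptive histogram equalization lifts the dark myoma/wall
range; intensities are then standardized per image.  Bias-field correction is
delegated to an optional external command operating on files (a published
N4-style tool); it is a hook, not re-implemented here.
"""

from __future__ import annotations

import subprocess
import warnings

import numpy as np
from skimage import exposure, transform

__all__ = ["adaptive_hist_eq", "zscore_normalize", "resize_input",
           "preprocess_image", "external_bias_correction"]


def adaptive_hist_eq(image: np.ndarray, clip_limit: float = 0.01,
                     tile_grid: int = 8) -> np.ndarray:
    """CLAHE on a single-channel image; output in [0, 1].

    `tile_grid` is the number of tiles per side.  A constant image is
    returned unchanged (clipped into [0, 1]): there is no contrast to create.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("adaptive_hist_eq: image contains non-finite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.clip(image, 0.0, 1.0)
    scaled = (image - lo) / (hi - lo)
    kernel = max(1, image.shape[0] // tile_grid), max(1, image.shape[1] // tile_grid)
    out = exposure.equalize_adapthist(scaled, kernel_size=kernel,
                                      clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit population standard deviation."""
    image = np.asarray(image, dtype=np.float64)
    sd = image.std()
    if sd == 0:
        warnings.warn("zscore_normalize: constant image, returning zeros")
        return np.zeros_like(image)
    return (image - image.mean()) / sd


def resize_input(image: np.ndarray, masks: list[np.ndarray] | None,
                 target: int):
    """Resize to target x target: bilinear for the image, nearest for masks.

    Returns (image, masks, scale) where scale = (sx, sy) maps source box
    coordinates to target coordinates (x*sx, y*sy, w*sx, h*sy).
    """
    if target < 32:
        raise ValueError("target size must be >= 32")
    h, w = image.shape
    sx, sy = target / w, target / h
    if (h, w) == (target, target):
        out = np.asarray(image, dtype=np.float64)
        out_masks = None if masks is None else [m.astype(bool) for m in masks]
        return out, out_masks, (1.0, 1.0)
    out = transform.resize(image.astype(np.float64), (target, target),
                           order=1, anti_aliasing=sx < 1, preserve_range=True)
    out_masks = None
    if masks is not None:
        out_masks = [transform.resize(m.astype(float), (target, target),
                                      order=0, anti_aliasing=False,
                                      preserve_range=True) > 0.5
                     for m in masks]
    return out, out_masks, (sx, sy)


def external_bias_correction(in_path, out_path, command: str | None = None) -> bool:
    """Optional hook: run an external bias-field correction tool on a file.

    `command` is a template like "n4 {inp} {out}".  Returns True if the tool
    ran; False (with a warning) when no command is configured.
    """
    if not command:
        warnings.warn("no bias-correction command configured; skipping")
        return False
    subprocess.run(command.format(inp=str(in_path), out=str(out_path)),
                   shell=True, check=True)
    return True


def preprocess_image(image: np.ndarray, masks: list[np.ndarray] | None = None,
                     target: int | None = None, clip_limit: float = 0.01,
                     tile_grid: int = 8):
    """The fixed-order chain used at train and inference time."""
    out = adaptive_hist_eq(image, clip_limit=clip_limit, tile_grid=tile_grid)
    out = zscore_normalize(out)
    if target is not None:
        out, masks, scale = resize_input(out, masks, target)
        return out, masks, scale
    return out, masks, (1.0, 1.0)
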