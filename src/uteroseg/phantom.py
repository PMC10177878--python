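"""Synthetic pelvic phantom generator.

Emulates the statistical structure of sagittal T2-weighted uterine MRI so the
detector can be trained and evaluated without clinical data: a darker annular
uterine wall containing a bright, thin, elongated cavity; dark myoma blobs of
widely varying size placed intramurally, submucosally or subserosally;
low-contrast bright distractor structures and a dark vertical column (spine
analog) outside the uterus; a smooth multiplicative bias field; additive
Gaussian noise.  The cavity is the rare/hard class: exactly one thin instance
per image versus one wall and up to several myomas.

Sizes are parameterised by the image side so that, at the clinical 512-pixel
scale, instance bounding boxes fall mostly below 260 px with aspect ratios
mostly below 2 and a mode at 1.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from . import CATEGORY_IDS
from .cocoio import write_coco

__all__ = ["PhantomConfig", "InstanceRecord", "generate_phantom",
           "generate_dataset", "split_counts"]


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and noise settings for phantom generation.

    Intensities are in [0, 1]; `contrast_levels` must respect the T2W
    ordering cavity > wall > myoma (bright fluid-filled cavity, dark
    fibrotic myomas).  `cavity_thickness_frac` is the cavity band thickness
    as a fraction of the wall's inner semi-minor axis.  `bias_amplitude` is
    the peak fractional deviation of the multiplicative bias field from 1.
    """

    image_size: int = 512
    n_images: int = 100
    myoma_count_range: tuple[int, int] = (0, 4)
    cavity_thickness_frac: float = 0.5
    contrast_levels: dict = dataclasses.field(default_factory=lambda: {
        "background": 0.40, "wall": 0.52, "cavity": 0.90, "myoma": 0.25})
    bias_amplitude: float = 0.15
    noise_sigma: float = 0.03
    distractor_count_range: tuple[int, int] = (1, 3)
    edge_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        c = self.contrast_levels
        if not (c["cavity"] > c["wall"] > c["myoma"]):
            raise ValueError("contrast ordering must be cavity > wall > myoma")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64 to fit the wall annulus")


@dataclasses.dataclass
class InstanceRecord:
    """One annotated instance: category, binary mask and derived box/area."""

    category: str
    mask: np.ndarray

    def __post_init__(self):
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        if not self.mask.any():
            raise ValueError("empty instance mask")

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Tight (x, y, w, h), 0-based, x/y top-left."""
        rows = np.any(self.mask, axis=1)
        cols = np.any(self.mask, axis=0)
        y0, y1 = np.where(rows)[0][[0, -1]]
        x0, x1 = np.where(cols)[0][[0, -1]]
        return (int(x0), int(y0), int(x1 - x0 + 1), int(y1 - y0 + 1))

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def category_id(self) -> int:
        return CATEGORY_IDS[self.category]


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    """Filled rotated ellipse; pixel (r, c) is inside if its center is."""
    yy, xx = np.mgrid[0:size, 0:size]
    x = xx + 0.5 - cx
    y = yy + 0.5 - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _bias_field(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """exp of a random low-order 2-D polynomial, peak |log| = amplitude."""
    if amplitude <= 0:
        return np.ones((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    u = xx / size * 2 - 1
    v = yy / size * 2 - 1
    coeff = rng.normal(size=6)
    poly = (coeff[0] * u + coeff[1] * v + coeff[2] * u * v
            + coeff[3] * u ** 2 + coeff[4] * v ** 2 + coeff[5] * (u ** 2 - v ** 2))
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak * amplitude
    return np.exp(poly)


def generate_phantom(config: PhantomConfig, index: int):
    """Render phantom `index`: returns (image in [0, 1], list of InstanceRecord).

    Deterministic in (config, index).  Exactly one wall and one cavity
    instance; myoma count drawn from `myoma_count_range`.  Distractor
    structures carry no instance record.
    """
    s = config.image_size
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, index])
    lv = config.contrast_levels

    # ---- uterus geometry ----------------------------------------------------
    cx = s * rng.uniform(0.42, 0.58)
    cy = s * rng.uniform(0.42, 0.58)
    a_out = s * rng.uniform(0.20, 0.30)
    b_out = s * rng.uniform(0.16, 0.24)
    theta = rng.uniform(-0.5, 0.5)
    inner_frac = rng.uniform(0.55, 0.68)
    a_in, b_in = a_out * inner_frac, b_out * inner_frac

    outer = _ellipse_mask(s, cx, cy, a_out, b_out, theta)
    hole = _ellipse_mask(s, cx, cy, a_in, b_in, theta)
    wall = outer & ~hole

    cav_a = a_in * rng.uniform(0.65, 0.8)
    cav_b = max(1.5, 0.5 * config.cavity_thickness_frac * b_in)
    cavity = _ellipse_mask(s, cx, cy, cav_a, cav_b, theta)
    cavity &= hole  # cavity strictly inside the wall's interior

    # ---- myomas -------------------------------------------------------------
    lo, hi = config.myoma_count_range
    n_myoma = int(rng.integers(lo, hi + 1))
    myomas: list[np.ndarray] = []
    kinds = ["intramural", "submucosal", "subserosal"]
    for _ in range(n_myoma):
        kind = kinds[rng.integers(0, 3)]
        r = float(np.exp(rng.uniform(np.log(0.02), np.log(0.17)))) * s
        phi = rng.uniform(0, 2 * np.pi)
        if kind == "intramural":
            rad = rng.uniform(inner_frac, 1.0)
        elif kind == "submucosal":
            rad = rng.uniform(0.25, inner_frac * 0.9)
        else:  # subserosal, bulging outward
            rad = rng.uniform(1.0, 1.15)
        ct, st = np.cos(theta), np.sin(theta)
        ex = rad * a_out * np.cos(phi)
        ey = rad * b_out * np.sin(phi)
        mx = cx + ex * ct - ey * st
        my = cy + ex * st + ey * ct
        ratio = rng.uniform(0.7, 1.0)
        m_theta = rng.uniform(0, np.pi)
        m = _ellipse_mask(s, mx, my, r, r * ratio, m_theta)
        m &= _ellipse_mask(s, cx, cy, a_out * 1.25, b_out * 1.25, theta)  # stay near uterus
        if m.sum() >= 9:
            myomas.append(m)

    # ---- paint clean intensities -------------------------------------------
    img = np.full((s, s), lv["background"])
    img[wall] = lv["wall"]
    uterus_region = outer.copy()
    for m in myomas:
        img[m] = lv["myoma"]
        uterus_region |= m
    img[cavity] = lv["cavity"]  # the bright fluid line stays visible on T2W

    # ---- distractors (no annotation) ---------------------------------------
    col_w = int(s * rng.uniform(0.05, 0.09))
    col_x = int(s * rng.uniform(0.86, 0.92))
    column = np.zeros((s, s), bool)
    column[:, col_x:min(col_x + col_w, s)] = True
    img[column & ~uterus_region] = 0.15
    dlo, dhi = config.distractor_count_range
    for _ in range(int(rng.integers(dlo, dhi + 1))):
        dr = s * rng.uniform(0.03, 0.10)
        dx = s * rng.uniform(0.08, 0.92)
        dy = s * rng.uniform(0.08, 0.92)
        disc = _ellipse_mask(s, dx, dy, dr, dr * rng.uniform(0.7, 1.0),
                             rng.uniform(0, np.pi))
        img[disc & ~uterus_region] = rng.uniform(0.6, 0.8)

    # optional soft tissue boundaries, then bias field and noise
    if config.edge_sigma > 0:
        img = gaussian_filter(img, sigma=config.edge_sigma)
    img = img * _bias_field(s, config.bias_amplitude, rng)
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    instances = [InstanceRecord("uterine_wall", wall),
                 InstanceRecord("uterine_cavity", cavity)]
    instances += [InstanceRecord("myoma", m) for m in myomas]
    return img, instances


def split_counts(n_images: int, split_ratio: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n_images to normalized ratios."""
    r = np.asarray(split_ratio, dtype=float)
    if (r <= 0).any():
        raise ValueError("split ratios must be positive")
    r = r / r.sum()
    if n_images < len(r):
        raise ValueError(f"n_images={n_images} smaller than number of splits")
    raw = r * n_images
    base = np.floor(raw).astype(int)
    rem = n_images - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i]] += 1
    return [int(x) for x in base]


def generate_dataset(config: PhantomConfig, out_dir,
                     split_ratio: tuple[float, float, float] = (8, 1, 1)) -> dict:
    """Generate a full phantom dataset on disk in COCO layout.

    Writes images/{split}/*.png (16-bit grayscale) and annotations/{split}.json.
    Returns {split: {"images": n, "instances": n, "json": path}}.
    """
    out_dir = Path(out_dir)
    counts = split_counts(config.n_images, split_ratio)
    splits = ["train", "val", "test"]
    index = 0
    summary = {}
    for split, n in zip(splits, counts):
        img_dir = out_dir / "images" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
        images, annos = [], []
        for _ in range(n):
            img, instances = generate_phantom(config, index)
            fname = f"phantom_{index:04d}.png"
            arr16 = np.round(img * 65535.0).astype(np.uint16)
            Image.fromarray(arr16).save(img_dir / fname)
            image_id = index + 1
            images.append({"id": image_id, "file_name": fname,
                           "width": config.image_size,
                           "height": config.image_size})
            annos.extend((image_id, rec) for rec in instances)
            index += 1
        json_path = out_dir / "annotations" / f"{split}.json"
        write_coco(images, annos, json_path)
        summary[split] = {"images": n, "instances": len(annos),
                          "json": str(json_path)}
    cfg_path = out_dir / "phantom_config.json"
    cfg = dataclasses.asdict(config)
    cfg_path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    if index != config.n_images:
        warnings.warn("image count mismatch after splitting")
    return summary
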