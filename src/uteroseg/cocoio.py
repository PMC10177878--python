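"""COCO-format JSON annotation I/O with lossless mask codecs.

Masks are stored either as a single polygon (when the traced contour
rasterizes back to the identical pixel mask) or as uncompressed column-major
run-length encoding (always exact).  `write_coco` / `read_coco` therefore
round-trip masks pixel-for-pixel, and boxes/areas/category ids bit-exactly.

Categories are fixed: 1 uterine_wall, 2 uterine_cavity, 3 myoma.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage import measure
from skimage.draw import polygon2mask

from . import CATEGORIES


def mask_to_rle(mask: np.ndarray) -> dict:
    """Uncompressed COCO RLE: column-major runs, starting with zeros."""
    h, w = mask.shape
    flat = np.asarray(mask, dtype=np.uint8).flatten(order="F")
    # run boundaries
    diff = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate([[0], diff, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(h), int(w)], "counts": counts}


def rle_to_mask(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in rle["counts"]:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


def mask_to_polygon(mask: np.ndarray) -> list | None:
    """Trace the mask outline; return a COCO polygon [x1,y1,...] only if it
    rasterizes back (center-in-polygon rule) to the identical mask."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if len(contours) != 1:
        return None  # multiply-connected or with holes: use RLE
    contour = contours[0]                      # (row, col) points
    if len(contour) < 6:
        return None
    poly = contour[:, ::-1].ravel().tolist()   # -> x, y pairs
    if polygon_to_mask(poly, mask.shape).tobytes() != mask.tobytes():
        return None
    return poly


def polygon_to_mask(poly: list, shape: tuple[int, int]) -> np.ndarray:
    pts = np.asarray(poly, dtype=float).reshape(-1, 2)[:, ::-1]  # (row, col)
    return polygon2mask(shape, pts)


def encode_mask(mask: np.ndarray):
    """Polygon when the shape is simply connected and exact, else RLE."""
    poly = mask_to_polygon(mask)
    if poly is not None:
        return [poly]
    return mask_to_rle(mask)


def decode_mask(segmentation, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(segmentation, dict):
        return rle_to_mask(segmentation)
    out = np.zeros(shape, dtype=bool)
    for poly in segmentation:
        out |= polygon_to_mask(poly, shape)
    return out


def write_coco(images: list[dict], annotations: list, path) -> None:
    """Write a COCO annotation file.

    `images`: dicts with id, file_name, width, height.
    `annotations`: (image_id, InstanceRecord) pairs.
    """
    doc = {
        "images": list(images),
        "annotations": [],
        "categories": [{"id": cid, "name": name}
                       for cid, name in sorted(CATEGORIES.items())],
    }
    ann_id = 1
    for image_id, rec in annotations:
        x, y, w, h = rec.bbox
        doc["annotations"].append({
            "id": ann_id,
            "image_id": int(image_id),
            "category_id": int(rec.category_id),
            "bbox": [float(x), float(y), float(w), float(h)],
            "area": int(rec.area),
            "iscrowd": 0,
            "segmentation": encode_mask(rec.mask),
        })
        ann_id += 1
    Path(path).write_text(json.dumps(doc))


def read_coco(path):
    """Read a COCO file back into (images, [(image_id, InstanceRecord)]).

    Malformed records raise ValueError naming the offending annotation.
    """
    from .phantom import InstanceRecord  # local import: avoid cycle

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed COCO JSON in {path}: {e}") from e
    cat_names = {c["id"]: c["name"] for c in doc.get("categories", [])}
    sizes = {im["id"]: (im["height"], im["width"]) for im in doc["images"]}
    annotations = []
    for ann in doc.get("annotations", []):
        try:
            shape = sizes[ann["image_id"]]
            mask = decode_mask(ann["segmentation"], shape)
            rec = InstanceRecord(cat_names[ann["category_id"]], mask)
        except Exception as e:
            raise ValueError(
                f"malformed annotation id={ann.get('id')} "
                f"(image_id={ann.get('image_id')}): {e}") from e
        annotations.append((ann["image_id"], rec))
    return doc["images"], annotations


def load_coco_raw(path) -> dict:
    """The raw parsed document, for consumers that only need boxes/areas."""
    return json.loads(Path(path).read_text())
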