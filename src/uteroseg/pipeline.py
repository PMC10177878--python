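"""End-to-end pipeline: generate -> preprocess -> anchors -> train -> predict
-> evaluate, driven by a single YAML-able configuration.

Every run writes a self-describing directory: the resolved configuration,
a content hash of the package source, fitted anchors, the training log,
checkpoint, COCO results and the final report.  Reruns with the same
configuration and seed reproduce the dataset and anchors byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .phantom import PhantomConfig, generate_dataset
from .preprocess import preprocess_image
from .anchors import kmeans_iou, assign_anchors_to_levels, collect_box_stats
from .backbone import BackboneConfig
from .model import Detector, DetectorConfig
from .train import TrainConfig, train, save_checkpoint, class_weights_from_instances
from .evaluation import (evaluate_sets, detections_to_results, load_results,
                         load_gt_per_image)
from .cocoio import read_coco, load_coco_raw

__all__ = ["PipelineConfig", "run_pipeline", "desk_profile", "full_profile",
           "fit_anchors", "load_split", "predict_split"]


@dataclasses.dataclass
class PipelineConfig:
    phantom: PhantomConfig
    detector: DetectorConfig
    train: TrainConfig
    kmeans_anchors: bool = True
    anchor_k: int = 9
    anchor_seed: int = 0
    split_ratio: tuple = (8, 1, 1)

    def to_dict(self) -> dict:
        return {
            "phantom": dataclasses.asdict(self.phantom),
            "detector": dataclasses.asdict(self.detector),
            "train": dataclasses.asdict(self.train),
            "kmeans_anchors": self.kmeans_anchors,
            "anchor_k": self.anchor_k,
            "anchor_seed": self.anchor_seed,
            "split_ratio": list(self.split_ratio),
        }


def desk_profile(n_images: int = 40, seed: int = 0) -> PipelineConfig:
    """CPU-sized profile: 128-pixel phantoms, small widths, 10 epochs."""
    return PipelineConfig(
        phantom=PhantomConfig(image_size=128, n_images=n_images, seed=seed),
        detector=DetectorConfig.desk(),
        train=TrainConfig.desk(seed=seed),
    )


def full_profile(n_images: int = 1687, seed: int = 0) -> PipelineConfig:
    """Clinical-scale profile mirroring the published training recipe."""
    return PipelineConfig(
        phantom=PhantomConfig(image_size=512, n_images=n_images, seed=seed),
        detector=DetectorConfig.full(),
        train=TrainConfig(seed=seed),
    )


def apply_ablations(config: PipelineConfig, dcn: bool = True, cbam: bool = True,
                    kmeans_anchors: bool = True, pointrend: bool = True
                    ) -> PipelineConfig:
    """Structural ablation switches for the four design components."""
    det = dataclasses.replace(
        config.detector,
        backbone=dataclasses.replace(config.detector.backbone,
                                     dcn=dcn, cbam=cbam),
        pointrend=pointrend)
    return dataclasses.replace(config, detector=det,
                               kmeans_anchors=kmeans_anchors)


def _code_hash() -> str:
    pkg = Path(__file__).parent
    h = hashlib.sha256()
    for f in sorted(pkg.glob("*.py")):
        h.update(f.read_bytes())
    return h.hexdigest()[:16]


def load_split(run_dir: Path, split: str):
    """Load a generated split as [(preprocessed image, instances), ...]."""
    run_dir = Path(run_dir)
    json_path = run_dir / "dataset" / "annotations" / f"{split}.json"
    if not json_path.exists():
        raise FileNotFoundError(
            f"missing {json_path}; run the 'generate' stage first")
    images, annos = read_coco(json_path)
    by_image: dict = {im["id"]: [] for im in images}
    for img_id, rec in annos:
        by_image[img_id].append(rec)
    out = []
    for im in images:
        path = run_dir / "dataset" / "images" / split / im["file_name"]
        arr = np.asarray(Image.open(path), dtype=np.float64) / 65535.0
        pimg, _, _ = preprocess_image(arr)
        out.append((pimg, by_image[im["id"]]))
    return out, images


def fit_anchors(coco_path, k: int = 9, seed: int = 0) -> dict:
    """Cluster training boxes and split centroids across pyramid levels.

    k is reduced to the largest multiple of 3 the distinct boxes support.
    """
    widths, heights, _ = collect_box_stats(coco_path)
    boxes = np.stack([widths, heights], axis=1)
    distinct = len(np.unique(boxes, axis=0))
    k_eff = min(k, 3 * (distinct // 3))
    if k_eff < 3:
        raise ValueError("fewer than 3 distinct boxes; cannot fit anchors")
    result = kmeans_iou(boxes, k_eff, seed=seed)
    return {
        "avg_iou": result.avg_iou,
        "k": k_eff,
        "levels": {lvl: [[float(w), float(h)] for w, h in cents]
                   for lvl, cents in
                   assign_anchors_to_levels(result.centroids).items()},
    }


def predict_split(model: Detector, run_dir: Path, split: str):
    data, images = load_split(run_dir, split)
    dets = {}
    for (img, _), im in zip(data, images):
        dets[im["id"]] = model.predict(img)
    return dets


def run_pipeline(config: PipelineConfig, run_dir, stages=None) -> dict:
    """Execute the pipeline stages in order; returns a summary dict."""
    all_stages = ["generate", "anchors", "train", "predict", "evaluate"]
    stages = stages or all_stages
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(
        yaml.safe_dump({**config.to_dict(), "code_hash": _code_hash()},
                       sort_keys=True))
    summary: dict = {}

    if "generate" in stages:
        summary["generate"] = generate_dataset(
            config.phantom, run_dir / "dataset", config.split_ratio)

    anchors_path = run_dir / "anchors.yaml"
    if "anchors" in stages:
        train_json = run_dir / "dataset" / "annotations" / "train.json"
        if not train_json.exists():
            raise FileNotFoundError(
                f"missing {train_json}; run the 'generate' stage first")
        if config.kmeans_anchors:
            fitted = fit_anchors(train_json, config.anchor_k,
                                 config.anchor_seed)
        else:
            fitted = {"avg_iou": None, "k": None,
                      "levels": {lvl: [[float(w), float(h)] for w, h in cents]
                                 for lvl, cents in
                                 DetectorConfig().resolved_anchors().items()}}
        anchors_path.write_text(yaml.safe_dump(fitted, sort_keys=True))
        summary["anchors"] = fitted

    model = None
    if "train" in stages:
        if not anchors_path.exists():
            raise FileNotFoundError(
                f"missing {anchors_path}; run the 'anchors' stage first")
        fitted = yaml.safe_load(anchors_path.read_text())
        det_cfg = dataclasses.replace(
            config.detector,
            anchors_per_level={lvl: [tuple(c) for c in cents]
                               for lvl, cents in fitted["levels"].items()})
        model = Detector(det_cfg, seed=config.train.seed)
        data, _ = load_split(run_dir, "train")
        weights = class_weights_from_instances(data)
        history = train(model, data, config.train, weights,
                        log_path=run_dir / "train_log.jsonl")
        save_checkpoint(model, run_dir / "checkpoint.npz",
                        {"epochs": config.train.epochs})
        summary["train"] = {"final_loss": history[-1] if history else None}

    if "predict" in stages:
        if model is None:
            raise FileNotFoundError(
                "no trained model in this invocation; run the 'train' stage")
        dets = predict_split(model, run_dir, "test")
        (run_dir / "results.json").write_text(
            json.dumps(detections_to_results(dets)))
        summary["predict"] = {"n_detections": sum(map(len, dets.values()))}

    if "evaluate" in stages:
        results_path = run_dir / "results.json"
        if not results_path.exists():
            raise FileNotFoundError(
                f"missing {results_path}; run the 'predict' stage first")
        gt_json = run_dir / "dataset" / "annotations" / "test.json"
        gts = load_gt_per_image(gt_json)
        sizes = {im["id"]: (im["height"], im["width"])
                 for im in load_coco_raw(gt_json)["images"]}
        dets = load_results(results_path, sizes)
        for img_id in gts:
            dets.setdefault(img_id, [])
        report = evaluate_sets(dets, gts)
        report.save(run_dir / "report.json")
        summary["evaluate"] = report.to_dict()

    (run_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    return summary
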