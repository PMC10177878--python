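"""Optimization loop: SGD with momentum, per-epoch loss logging.

Defaults mirror the full-scale recipe (lr 0.001, momentum 0.9, weight decay
0.0001, 60 epochs, batch 4, input 512); the desk profile trains the small
backbone at 128 pixels for 10 epochs with batch 2.  Class weights are the
inverse-frequency weights of the training set and enter the classification
loss only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn import SGD
from .model import Detector
from .augment import AugmentConfig, augment
from .losses import inverse_frequency_weights

__all__ = ["TrainConfig", "train", "class_weights_from_instances",
           "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass
class TrainConfig:
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0001
    epochs: int = 60
    batch_size: int = 4
    input_size: int = 512
    seed: int = 0
    use_augment: bool = True
    augment_config: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)

    @staticmethod
    def desk(**overrides) -> "TrainConfig":
        # the small desk network trains from scratch without pretraining, so
        # it takes a larger step size than the full-scale recipe
        cfg = TrainConfig(epochs=10, batch_size=2, input_size=128, lr=0.02)
        return dataclasses.replace(cfg, **overrides)


def class_weights_from_instances(dataset, n_classes: int = 3) -> np.ndarray:
    """Background weight 1 followed by inverse-frequency foreground weights."""
    counts = np.zeros(n_classes)
    for _, instances in dataset:
        for rec in instances:
            counts[rec.category_id - 1] += 1
    w = inverse_frequency_weights(np.maximum(counts, 1))
    return np.concatenate([[1.0], w])


def train(model: Detector, dataset: list, config: TrainConfig | None = None,
          class_weights: np.ndarray | None = None,
          log_path=None) -> list[dict]:
    """Train on [(image, instances), ...]; returns the per-epoch loss history.

    Gradients are accumulated over `batch_size` single-image passes before
    each SGD step.  A non-finite total loss aborts with a diagnostic.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    if class_weights is None:
        class_weights = class_weights_from_instances(dataset)
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    history: list[dict] = []
    log_f = open(log_path, "a") if log_path else None
    try:
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(dataset))
            sums: dict[str, float] = {}
            n_in_batch = 0
            opt.zero_grad()
            for pos, di in enumerate(order):
                image, instances = dataset[di]
                if cfg.use_augment:
                    image, instances = augment(image, instances, rng,
                                               cfg.augment_config)
                    if not instances:
                        continue
                losses = model.forward_train(image, instances,
                                             class_weights, rng)
                total = losses["total"]
                if not np.isfinite(total.data):
                    raise RuntimeError(
                        f"divergent loss at epoch {epoch}, image {di}: "
                        + ", ".join(f"{k}={v.item():.4g}"
                                    for k, v in losses.items()))
                total.backward(np.asarray(1.0 / cfg.batch_size))
                n_in_batch += 1
                if n_in_batch == cfg.batch_size or pos == len(order) - 1:
                    opt.step()
                    opt.zero_grad()
                    n_in_batch = 0
                for k, v in losses.items():
                    sums[k] = sums.get(k, 0.0) + v.item()
            n = max(1, len(order))
            entry = {"epoch": epoch, **{k: v / n for k, v in sums.items()}}
            history.append(entry)
            if log_f:
                log_f.write(json.dumps(entry) + "\n")
                log_f.flush()
    finally:
        if log_f:
            log_f.close()
    return history


def save_checkpoint(model: Detector, path, extra: dict | None = None):
    arrays = {f"p{i}": a for i, a in enumerate(model.state_dict())}
    meta = json.dumps(extra or {})
    np.savez(Path(path), meta=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(model: Detector, path) -> dict:
    with np.load(Path(path)) as z:
        n = sum(1 for k in z.files if k.startswith("p"))
        model.load_state_dict([z[f"p{i}"] for i in range(n)])
        meta = bytes(z["meta"]).decode() if "meta" in z.files else "{}"
    return json.loads(meta)
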