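"""Training loop for the mini relation detector.

Both query streams are trained jointly: the matching stream (plus the
encoder proposal heads, supervised as an extra one-to-one "layer 0") with
one-to-one Hungarian assignment, the hybrid stream with one-to-K repeated
ground truth. The optimizer is Adam with decoupled weight decay and a step
learning-rate schedule. Per-epoch loss components and validation mAP can be
logged to CSV.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam
from .coco import CENTER_NORMALIZED, DatasetAnnotations, convert_box
from .errors import ConfigurationError
from .matching import CostWeights, detection_loss
from .model import RelationDetector, predict
from .evaluation import map_range


@dataclass
class TrainConfig:
    """Optimization settings (mini-scale defaults; the published full-scale
    regime is lr 1e-4 with milestone 12, gamma 0.1, weight decay 1e-4,
    16 epochs)."""

    epochs: int = 10
    batch_size: int = 4
    lr: float = 1e-3
    lr_milestone: int = 8  # epoch after which lr is multiplied by gamma
    lr_gamma: float = 0.1
    weight_decay: float = 1e-4
    k: int = 6
    weights: CostWeights = field(default_factory=CostWeights)
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    seed: int = 0


def _targets_per_image(gts: DatasetAnnotations) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """image_id -> (class indices, center-normalized boxes)."""
    cat_index = gts.category_index()
    size_of = {im.image_id: (im.width, im.height) for im in gts.images}
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for image_id, anns in gts.annotations_by_image().items():
        cls = np.array([cat_index[a.category_id] for a in anns], dtype=int)
        boxes = np.array([
            [b.x, b.y, b.w, b.h]
            for a in anns
            for b in (convert_box(a.box, CENTER_NORMALIZED, size_of[image_id]),)
        ]) if anns else np.zeros((0, 4))
        out[image_id] = (cls, boxes)
    return out


def train(
    model: RelationDetector,
    train_images: dict[int, np.ndarray],
    train_gts: DatasetAnnotations,
    config: TrainConfig | None = None,
    val_images: dict[int, np.ndarray] | None = None,
    val_gts: DatasetAnnotations | None = None,
    log_csv: str | Path | None = None,
    verbose: bool = False,
) -> list[dict]:
    """Train in place; returns the per-epoch log rows."""
    cfg = config or TrainConfig()
    if not train_images:
        raise ConfigurationError("empty training set")
    n_classes = model.config.n_classes
    targets = _targets_per_image(train_gts)
    image_ids = list(train_images.keys())
    stack = {iid: np.asarray(train_images[iid]) for iid in image_ids}
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr,
                     weight_decay=cfg.weight_decay)
    rows: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        optimizer.lr = cfg.lr * (cfg.lr_gamma if epoch > cfg.lr_milestone else 1.0)
        order = rng.permutation(len(image_ids))
        epoch_loss = 0.0
        comps = {"cls": 0.0, "l1": 0.0, "giou": 0.0}
        n_batches = 0
        t0 = time.time()
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            ids = [image_ids[i] for i in idx]
            batch = np.stack([stack[i] for i in ids])
            out = model.forward_train(batch)
            enc_logits, enc_boxes = out["encoder"]
            total = None
            for bi, image_id in enumerate(ids):
                cls_idx, boxes = targets[image_id]
                match_layers = [(enc_logits[bi], enc_boxes[bi])] + [
                    (lo.class_logits[bi], lo.boxes[bi]) for lo in out["matching"]]
                loss_m, info_m = detection_loss(
                    match_layers, cls_idx, boxes, n_classes,
                    mode="one-to-one", weights=cfg.weights,
                    focal_alpha=cfg.focal_alpha, focal_gamma=cfg.focal_gamma)
                hybrid_layers = [(lo.class_logits[bi], lo.boxes[bi])
                                 for lo in out["hybrid"]]
                loss_h, info_h = detection_loss(
                    hybrid_layers, cls_idx, boxes, n_classes,
                    mode="one-to-k", k=cfg.k, weights=cfg.weights,
                    focal_alpha=cfg.focal_alpha, focal_gamma=cfg.focal_gamma)
                loss_i = loss_m + loss_h
                total = loss_i if total is None else total + loss_i
                for key in comps:
                    comps[key] += info_m["components"][key] + info_h["components"][key]
            total = total / float(len(ids))
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            epoch_loss += total.item()
            n_batches += 1
        row = {
            "epoch": epoch,
            "loss": epoch_loss / max(1, n_batches),
            "loss_cls": comps["cls"] / max(1, len(order)),
            "loss_l1": comps["l1"] / max(1, len(order)),
            "loss_giou": comps["giou"] / max(1, len(order)),
            "lr": optimizer.lr,
            "seconds": round(time.time() - t0, 2),
            "val_map50": float("nan"),
        }
        if val_images is not None and val_gts is not None:
            row["val_map50"] = evaluate_map50(model, val_images, val_gts)
        rows.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d} loss {row['loss']:.4f} "
                f"val mAP@50 {row['val_map50']:.1f} ({row['seconds']}s)")
    if log_csv is not None:
        with open(log_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows


def evaluate_map50(model: RelationDetector, images: dict[int, np.ndarray],
                   gts: DatasetAnnotations) -> float:
    ids = list(images.keys())
    preds = predict(model, [images[i] for i in ids], ids)
    return map_range(preds, gts, thresholds=(0.5,)).map50
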