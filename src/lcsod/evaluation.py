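"""COCO-protocol detection evaluation: per-class AP, mAP@50:95, PR curves.

AP is the area under the interpolated precision-recall curve for one class at
one IoU threshold, estimated with the COCO 101-recall-point rule: predictions
are sorted by descending score and matched greedily to the not-yet-matched
ground-truth box of highest IoU (at or above the threshold) in the same
image; precision is made monotone non-increasing by taking the running
maximum from the right, then sampled at recalls 0.00, 0.01, ..., 1.00.
``map_range`` averages per-class AP over the ten thresholds 0.50:0.05:0.95
and over classes; classes with no ground truth are excluded from the mean.
An exact trapezoid-free integral of the raw step curve is available as
``integration="exact"`` for comparison.

All AP values are reported on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coco import CORNER_ABSOLUTE, DatasetAnnotations, PredictionSet, convert_box
from .errors import ValidationError
from .matching import pairwise_iou_corners

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
RECALL_POINTS = np.linspace(0.0, 1.0, 101)
_IOU_EPS = 1e-10  # an IoU exactly at the threshold counts as a match
MAX_DETECTIONS = 100  # per image, across classes (COCO "all" setting)


def _corner4(box) -> np.ndarray:
    b = convert_box(box, CORNER_ABSOLUTE)
    return np.array([b.x, b.y, b.x + b.w, b.y + b.h])


def _limit_detections(preds: PredictionSet, max_dets: int) -> PredictionSet:
    kept = []
    for _, recs in preds.by_image().items():
        order = sorted(range(len(recs)), key=lambda i: (-recs[i].score, i))
        kept.extend(recs[i] for i in sorted(order[:max_dets]))
    return PredictionSet(records=kept)


def _match_class(
    preds: PredictionSet, gts: DatasetAnnotations, category_id: int,
    iou_threshold: float,
) -> tuple[np.ndarray, int]:
    """Greedy score-descending matching; returns (is_tp per prediction in
    score order, n_gt)."""
    gt_by_image = {
        iid: np.array([_corner4(a.box) for a in anns if a.category_id == category_id])
        for iid, anns in gts.annotations_by_image().items()
    }
    n_gt = sum(len(v) for v in gt_by_image.values())
    recs = [r for r in preds.records if r.category_id == category_id]
    order = sorted(range(len(recs)), key=lambda i: (-recs[i].score, i))
    matched: dict[int, np.ndarray] = {
        iid: np.zeros(len(v), dtype=bool) for iid, v in gt_by_image.items()
    }
    is_tp = np.zeros(len(recs), dtype=bool)
    for rank, i in enumerate(order):
        rec = recs[i]
        gt_boxes = gt_by_image.get(rec.image_id)
        if gt_boxes is None or len(gt_boxes) == 0:
            continue
        ious = pairwise_iou_corners(_corner4(rec.box)[None, :], gt_boxes)[0]
        free = ~matched[rec.image_id]
        ious = np.where(free, ious, -1.0)
        j = int(np.argmax(ious))
        if ious[j] >= iou_threshold - _IOU_EPS:
            matched[rec.image_id][j] = True
            is_tp[rank] = True
    return is_tp, n_gt


def _precision_recall(is_tp: np.ndarray, n_gt: int) -> tuple[np.ndarray, np.ndarray]:
    tp = np.cumsum(is_tp)
    fp = np.cumsum(~is_tp)
    recall = tp / n_gt if n_gt > 0 else np.zeros_like(tp, dtype=float)
    precision = tp / np.maximum(tp + fp, 1)
    return recall.astype(float), precision.astype(float)


def _interpolated(recall: np.ndarray, precision: np.ndarray) -> np.ndarray:
    """Precision envelope sampled at the 101 recall points."""
    env = np.maximum.accumulate(precision[::-1])[::-1] if len(precision) else precision
    idx = np.searchsorted(recall, RECALL_POINTS, side="left")
    out = np.zeros_like(RECALL_POINTS)
    valid = idx < len(env)
    out[valid] = env[idx[valid]]
    return out


def _check_category(gts: DatasetAnnotations, category_id: int) -> None:
    if category_id not in set(gts.category_ids):
        raise ValidationError(f"unknown category id {category_id}")


def ap_per_class(
    preds: PredictionSet, gts: DatasetAnnotations, category_id: int,
    iou_threshold: float, integration: str = "coco101",
) -> float:
    """AP (0-100) for one class at one IoU threshold; ``nan`` if the class
    has no ground truth."""
    _check_category(gts, category_id)
    if not (0.0 < iou_threshold < 1.0):
        raise ValidationError(f"iou_threshold must be in (0,1), got {iou_threshold}")
    is_tp, n_gt = _match_class(preds, gts, category_id, iou_threshold)
    if n_gt == 0:
        return float("nan")
    recall, precision = _precision_recall(is_tp, n_gt)
    if integration == "coco101":
        return float(_interpolated(recall, precision).mean() * 100.0)
    if integration == "exact":
        # exact area under the interpolated step curve
        env = np.maximum.accumulate(precision[::-1])[::-1] if len(precision) else precision
        r = np.concatenate([[0.0], recall])
        p = np.concatenate([[env[0] if len(env) else 0.0], env])
        return float(np.sum(np.diff(r) * p[1:]) * 100.0)
    raise ValidationError(f"unknown integration rule {integration!r}")


def pr_curve(
    preds: PredictionSet, gts: DatasetAnnotations, category_id: int,
    iou_threshold: float,
) -> np.ndarray:
    """Interpolated PR curve as a ``(101, 2)`` array of (recall, precision)."""
    _check_category(gts, category_id)
    is_tp, n_gt = _match_class(preds, gts, category_id, iou_threshold)
    recall, precision = _precision_recall(is_tp, n_gt)
    return np.column_stack([RECALL_POINTS, _interpolated(recall, precision)])


@dataclass
class EvalResult:
    """Per-class AP at each IoU threshold plus the usual summaries."""

    per_class_ap: dict[int, dict[float, float]]
    category_names: dict[int, str]
    thresholds: tuple[float, ...] = IOU_THRESHOLDS
    pr_curves: dict[tuple[int, float], np.ndarray] = field(default_factory=dict)

    def class_ap(self, category_id: int, threshold: float) -> float:
        return self.per_class_ap[category_id][threshold]

    def class_ap_range(self, category_id: int) -> float:
        vals = [self.per_class_ap[category_id][t] for t in self.thresholds]
        return float(np.mean(vals))

    def _overall(self, threshold: float | None) -> float:
        vals = []
        for cid, by_thr in self.per_class_ap.items():
            v = (self.class_ap_range(cid) if threshold is None
                 else by_thr[threshold])
            if not np.isnan(v):
                vals.append(v)
        if not vals:
            return float("nan")
        return float(np.mean(vals))

    @property
    def map50(self) -> float:
        return self._overall(0.5)

    @property
    def map75(self) -> float:
        return self._overall(0.75)

    @property
    def map50_95(self) -> float:
        return self._overall(None)

    def to_dict(self) -> dict:
        def clean(v: float):
            return None if np.isnan(v) else round(v, 4)

        return {
            "per_class": {
                self.category_names[cid]: {
                    "ap50": clean(by_thr[0.5]),
                    "ap75": clean(by_thr[0.75]),
                    "ap50_95": clean(self.class_ap_range(cid)),
                    "by_threshold": {str(t): clean(v) for t, v in by_thr.items()},
                }
                for cid, by_thr in self.per_class_ap.items()
            },
            "overall": {
                "map50": clean(self.map50),
                "map75": clean(self.map75),
                "map50_95": clean(self.map50_95),
            },
        }


def map_range(
    preds: PredictionSet,
    gts: DatasetAnnotations,
    thresholds: tuple[float, ...] = IOU_THRESHOLDS,
    integration: str = "coco101",
    with_pr_curves: bool = False,
    max_detections: int = MAX_DETECTIONS,
) -> EvalResult:
    """Evaluate predictions against ground truth over an IoU-threshold range."""
    if not gts.annotations:
        raise ValidationError("cannot evaluate: ground truth has no annotations")
    preds = _limit_detections(preds, max_detections)
    per_class: dict[int, dict[float, float]] = {}
    curves: dict[tuple[int, float], np.ndarray] = {}
    for cat in gts.categories:
        by_thr: dict[float, float] = {}
        for t in thresholds:
            by_thr[float(t)] = ap_per_class(preds, gts, cat.category_id, float(t),
                                            integration=integration)
            if with_pr_curves:
                curves[(cat.category_id, float(t))] = pr_curve(
                    preds, gts, cat.category_id, float(t))
        per_class[cat.category_id] = by_thr
    return EvalResult(
        per_class_ap=per_class,
        category_names={c.category_id: c.name for c in gts.categories},
        thresholds=tuple(float(t) for t in thresholds),
        pr_curves=curves,
    )
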