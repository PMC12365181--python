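"""Box geometry (IoU / GIoU), Hungarian assignment and the training loss.

Training a DETR-family detector requires a bipartite assignment between the
model's query predictions and the ground-truth boxes of each image. The
matching-query stream uses strict one-to-one minimum-cost assignment, which
is what suppresses duplicate detections; the hybrid stream relaxes this to
one-to-K by tiling the ground-truth list K times before matching, so each
object supervises up to K queries. The per-layer loss combines a focal
classification term over all queries (unmatched queries trained toward the
background column) with an L1 and a GIoU box term over matched pairs; the
total is the sum over decoder layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .autodiff import Tensor
from .coco import BoundingBox, CORNER_ABSOLUTE, convert_box
from .errors import DegenerateBoxError, ValidationError

# ---------------------------------------------------------------------------
# IoU / GIoU
# ---------------------------------------------------------------------------


def _to_corner_array(box) -> np.ndarray:
    if isinstance(box, BoundingBox):
        box = convert_box(box, CORNER_ABSOLUTE)
        return np.array([box.x, box.y, box.x + box.w, box.y + box.h])
    arr = np.asarray(box, dtype=float)
    if arr[2] <= 0 or arr[3] <= 0:
        raise DegenerateBoxError(f"degenerate box {arr}")
    return np.array([arr[0], arr[1], arr[0] + arr[2], arr[1] + arr[3]])


def iou(box_a, box_b) -> float:
    """IoU of two boxes (``BoundingBox`` or corner ``[x, y, w, h]`` arrays)."""
    a, b = _to_corner_array(box_a), _to_corner_array(box_b)
    iw = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    ih = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = iw * ih
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / union


def cxcywh_to_corners(boxes: np.ndarray) -> np.ndarray:
    """``[cx, cy, w, h]`` -> ``[x1, y1, x2, y2]`` (vectorized)."""
    b = np.asarray(boxes, dtype=float)
    half = b[..., 2:] / 2.0
    return np.concatenate([b[..., :2] - half, b[..., :2] + half], axis=-1)


def pairwise_iou_corners(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix ``(Na, Nb)`` for ``[x1, y1, x2, y2]`` arrays."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0.0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / union


def pairwise_giou_corners(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Generalized IoU matrix in ``(-1, 1]`` for corner arrays."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0.0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    iou_mat = inter / union
    ctl = np.minimum(a[:, None, :2], b[None, :, :2])
    cbr = np.maximum(a[:, None, 2:], b[None, :, 2:])
    cwh = cbr - ctl
    c_area = cwh[..., 0] * cwh[..., 1]
    return iou_mat - (c_area - union) / c_area


def giou_aligned_t(pred_cxcywh: Tensor, gt_cxcywh: np.ndarray) -> Tensor:
    """Differentiable per-pair GIoU for aligned ``(N, 4)`` center boxes."""
    gt = np.asarray(gt_cxcywh, dtype=float)
    px1 = pred_cxcywh[:, 0] - pred_cxcywh[:, 2] * 0.5
    py1 = pred_cxcywh[:, 1] - pred_cxcywh[:, 3] * 0.5
    px2 = pred_cxcywh[:, 0] + pred_cxcywh[:, 2] * 0.5
    py2 = pred_cxcywh[:, 1] + pred_cxcywh[:, 3] * 0.5
    gc = cxcywh_to_corners(gt)
    gx1, gy1, gx2, gy2 = gc[:, 0], gc[:, 1], gc[:, 2], gc[:, 3]
    iw = (px2.minimum(gx2) - px1.maximum(gx1)).relu()
    ih = (py2.minimum(gy2) - py1.maximum(gy1)).relu()
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + area_g - inter
    iou_v = inter / union
    cw = px2.maximum(gx2) - px1.minimum(gx1)
    ch = py2.maximum(gy2) - py1.minimum(gy1)
    c_area = cw * ch
    return iou_v - (c_area - union) / c_area


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


@dataclass
class Assignment:
    """Query -> ground-truth pairing; unmatched queries are background.

    ``pairs`` holds ``(query_index, gt_index)`` with original (untiled) gt
    indices; in one-to-K mode a gt index may appear up to K times while each
    query appears at most once.
    """

    pairs: list[tuple[int, int]]
    total_cost: float = 0.0

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def query_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    def gt_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


def hungarian_match(cost: np.ndarray) -> Assignment:
    """Minimum-total-cost one-to-one assignment on a rectangular cost matrix.

    Covers ``min(n_rows, n_cols)`` pairs; pairs are sorted by query (row)
    index for determinism.
    """
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    if cost.size and np.isnan(cost).any():
        raise ValidationError("cost matrix contains NaN")
    if 0 in cost.shape:
        return Assignment(pairs=[], total_cost=0.0)
    rows, cols = linear_sum_assignment(cost)
    order = np.argsort(rows, kind="stable")
    pairs = [(int(r), int(c)) for r, c in zip(rows[order], cols[order])]
    return Assignment(pairs=pairs, total_cost=float(cost[rows, cols].sum()))


@dataclass
class CostWeights:
    """Weights of the matching cost / loss components."""

    cls: float = 2.0
    l1: float = 5.0
    giou: float = 2.0


def match_cost(
    pred_probs: np.ndarray,
    pred_boxes_cxcywh: np.ndarray,
    gt_class_idx: np.ndarray,
    gt_boxes_cxcywh: np.ndarray,
    weights: CostWeights | None = None,
) -> np.ndarray:
    """Assignment cost matrix ``(n_queries, n_gt)``.

    ``cost[q, g] = w_cls*(1 - prob_q[class_g]) + w_l1*||B_q - B_g||_1
    + w_giou*(1 - GIoU(B_q, B_g))`` with boxes in a common center convention.
    """
    w = weights or CostWeights()
    probs = np.atleast_2d(np.asarray(pred_probs, dtype=float))
    pb = np.atleast_2d(np.asarray(pred_boxes_cxcywh, dtype=float))
    gt_idx = np.asarray(gt_class_idx, dtype=int)
    gb = np.atleast_2d(np.asarray(gt_boxes_cxcywh, dtype=float))
    if len(gt_idx) == 0:
        return np.zeros((pb.shape[0], 0))
    cls_cost = 1.0 - probs[:, gt_idx]
    l1_cost = np.abs(pb[:, None, :] - gb[None, :, :]).sum(axis=-1)
    giou_cost = 1.0 - pairwise_giou_corners(
        cxcywh_to_corners(pb), cxcywh_to_corners(gb))
    return w.cls * cls_cost + w.l1 * l1_cost + w.giou * giou_cost


def assign(
    pred_probs: np.ndarray,
    pred_boxes_cxcywh: np.ndarray,
    gt_class_idx: np.ndarray,
    gt_boxes_cxcywh: np.ndarray,
    mode: str = "one-to-one",
    k: int = 6,
    weights: CostWeights | None = None,
) -> Assignment:
    """Hungarian assignment in one-to-one or one-to-K (tiled gt) mode."""
    gt_idx = np.asarray(gt_class_idx, dtype=int)
    gb = np.atleast_2d(np.asarray(gt_boxes_cxcywh, dtype=float))
    n_gt = len(gt_idx)
    n_q = np.atleast_2d(pred_boxes_cxcywh).shape[0]
    if n_gt == 0:
        return Assignment(pairs=[])
    if mode == "one-to-one":
        repeats = 1
    elif mode == "one-to-k":
        repeats = k
        if k * n_gt > n_q:
            repeats = min(k, n_q // n_gt)
            warnings.warn(
                f"one-to-K wants {k}x{n_gt} targets but only {n_q} queries; "
                f"using K={repeats}", stacklevel=2)
    else:
        raise ValidationError(f"unknown matching mode {mode!r}")
    tiled_idx = np.tile(gt_idx, repeats)
    tiled_boxes = np.tile(gb, (repeats, 1))
    cost = match_cost(pred_probs, pred_boxes_cxcywh, tiled_idx, tiled_boxes, weights)
    raw = hungarian_match(cost)
    pairs = [(q, g % n_gt) for q, g in raw.pairs]
    return Assignment(pairs=pairs, total_cost=raw.total_cost)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def focal_loss_t(logits: Tensor, targets_onehot: np.ndarray,
                 alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Sigmoid focal loss summed over all entries (logits ``(N, C)``)."""
    t = np.asarray(targets_onehot, dtype=float)
    p = logits.sigmoid().clamp(1e-7, 1.0 - 1e-7)
    pos = Tensor(t) * ((1.0 - p) ** gamma) * p.log() * (-alpha)
    neg = Tensor(1.0 - t) * (p ** gamma) * (1.0 - p).log() * (-(1.0 - alpha))
    return (pos + neg).sum()


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def detection_loss(
    layer_outputs: list[tuple],
    gt_class_idx: np.ndarray,
    gt_boxes_cxcywh: np.ndarray,
    n_classes: int,
    mode: str = "one-to-one",
    k: int = 6,
    weights: CostWeights | None = None,
    focal_alpha: float = 0.25,
    focal_gamma: float = 2.0,
) -> tuple[Tensor, dict]:
    """Summed per-layer detection loss for one image and one query stream.

    ``layer_outputs`` is a list of ``(class_logits, boxes_cxcywh)`` per
    decoder layer (Tensors during training, arrays accepted for analysis);
    class logits have ``n_classes + 1`` columns, the last being background.
    Returns the total loss Tensor plus a dict of per-component floats and the
    per-layer assignments.
    """
    w = weights or CostWeights()
    gt_idx = np.asarray(gt_class_idx, dtype=int)
    gb = np.atleast_2d(np.asarray(gt_boxes_cxcywh, dtype=float)) \
        if len(gt_idx) else np.zeros((0, 4))
    total: Tensor | None = None
    components = {"cls": 0.0, "l1": 0.0, "giou": 0.0}
    assignments: list[Assignment] = []
    for logits_in, boxes_in in layer_outputs:
        logits, boxes = _as_tensor(logits_in), _as_tensor(boxes_in)
        n_q = logits.shape[0]
        probs_np = 1.0 / (1.0 + np.exp(-logits.data))
        assignment = assign(probs_np[:, :n_classes], boxes.data, gt_idx, gb,
                            mode=mode, k=k, weights=w)
        assignments.append(assignment)
        n_matched = max(1, assignment.n_matched)

        targets = np.zeros((n_q, n_classes + 1))
        targets[:, n_classes] = 1.0  # background by default
        if assignment.n_matched:
            qi, gi = assignment.query_indices(), assignment.gt_indices()
            targets[qi, n_classes] = 0.0
            targets[qi, gt_idx[gi]] = 1.0
        cls_term = focal_loss_t(logits, targets, focal_alpha, focal_gamma) \
            * (w.cls / n_matched)
        layer_loss = cls_term
        components["cls"] += cls_term.item()

        if assignment.n_matched:
            matched_boxes = boxes[qi]
            gt_matched = gb[gi]
            l1_term = (matched_boxes - Tensor(gt_matched)).abs().sum() \
                * (w.l1 / n_matched)
            giou_term = (1.0 - giou_aligned_t(matched_boxes, gt_matched)).sum() \
                * (w.giou / n_matched)
            layer_loss = layer_loss + l1_term + giou_term
            components["l1"] += l1_term.item()
            components["giou"] += giou_term.item()

        total = layer_loss if total is None else total + layer_loss
    info = {"components": components, "assignments": assignments,
            "total": 0.0 if total is None else total.item()}
    return (total if total is not None else Tensor(0.0)), info
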