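"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately written as direct, loop-based
transcriptions of the textbook definitions (Pearson correlation, exhaustive
assignment enumeration, greedy COCO matching with 101-point interpolation)
so they share no code path with the package implementations they check.
"""

from __future__ import annotations

import itertools
import json
import math

import numpy as np
import pytest

from lcsod.coco import BoundingBox, Category, DatasetAnnotations, ImageInfo, Annotation


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def pcc_oracle(u, v) -> float:
    """Textbook Pearson correlation of two 4-vectors."""
    u, v = [float(x) for x in u], [float(x) for x in v]
    n = len(u)
    mu, mv = sum(u) / n, sum(v) / n
    su = math.sqrt(sum((x - mu) ** 2 for x in u) / n)
    sv = math.sqrt(sum((x - mv) ** 2 for x in v) / n)
    if su == 0.0 or sv == 0.0:
        return float("nan")
    cov = sum((x - mu) * (y - mv) for x, y in zip(u, v)) / n
    return cov / (su * sv)


def mc_oracle(box_rows) -> float:
    """Brute-force ordered-pair mean of |PCC| (nan when undefined)."""
    n = len(box_rows)
    if n < 2:
        return float("nan")
    total, count = 0.0, 0
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            r = pcc_oracle(box_rows[a], box_rows[b])
            if not math.isnan(r):
                total += abs(r)
                count += 1
    return total / count if count else float("nan")


def hungarian_oracle(cost: np.ndarray) -> float:
    """Exhaustive-permutation minimum total assignment cost."""
    cost = np.atleast_2d(cost)
    n_rows, n_cols = cost.shape
    if n_rows >= n_cols:
        best = min(
            sum(cost[r, c] for r, c in zip(rows, range(n_cols)))
            for rows in itertools.permutations(range(n_rows), n_cols)
        )
    else:
        best = min(
            sum(cost[r, c] for r, c in zip(range(n_rows), cols))
            for cols in itertools.permutations(range(n_cols), n_rows)
        )
    return float(best)


def _iou_oracle(box_a: BoundingBox, box_b: BoundingBox) -> float:
    ax1, ay1, ax2, ay2 = box_a.x, box_a.y, box_a.x + box_a.w, box_a.y + box_a.h
    bx1, by1, bx2, by2 = box_b.x, box_b.y, box_b.x + box_b.w, box_b.y + box_b.h
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (box_a.w * box_a.h + box_b.w * box_b.h - inter)


def coco_ap_oracle(preds, gts: DatasetAnnotations, category_id: int,
                   iou_threshold: float) -> float:
    """Independent greedy-matching AP with 101-point interpolation (0-100)."""
    dets = [(r.score, i, r) for i, r in enumerate(preds.records)
            if r.category_id == category_id]
    dets.sort(key=lambda t: (-t[0], t[1]))
    gt: dict[int, list] = {}
    for a in gts.annotations:
        if a.category_id == category_id:
            gt.setdefault(a.image_id, []).append([a.box, False])
    n_pos = sum(len(v) for v in gt.values())
    if n_pos == 0:
        return float("nan")
    flags = []
    for _, _, rec in dets:
        candidates = gt.get(rec.image_id, [])
        best, best_j = -1.0, None
        for j, (box, used) in enumerate(candidates):
            if used:
                continue
            v = _iou_oracle(rec.box, box)
            if v > best:
                best, best_j = v, j
        if best_j is not None and best >= iou_threshold - 1e-10:
            candidates[best_j][1] = True
            flags.append(1)
        else:
            flags.append(0)
    tp = fp = 0
    recall, precision = [], []
    for f in flags:
        tp += f
        fp += 1 - f
        recall.append(tp / n_pos)
        precision.append(tp / (tp + fp))
    ap = 0.0
    for i in range(101):
        r_t = i / 100.0
        p = max((p_ for p_, r_ in zip(precision, recall) if r_ >= r_t - 1e-12),
                default=0.0)
        ap += p / 101.0
    return ap * 100.0


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


def random_boxes(rng: np.random.Generator, n: int, image_size: float = 100.0) -> np.ndarray:
    """Random non-degenerate corner-absolute [x, y, w, h] rows."""
    w = rng.uniform(2.0, image_size / 2, size=n)
    h = rng.uniform(2.0, image_size / 2, size=n)
    x = rng.uniform(0.0, image_size - w)
    y = rng.uniform(0.0, image_size - h)
    return np.column_stack([x, y, w, h])


@pytest.fixture
def tiny_dataset() -> DatasetAnnotations:
    """1 image, 2 categories, 2 annotations."""
    return DatasetAnnotations(
        images=[ImageInfo(1, 100, 80, "img_00001.png")],
        categories=[Category(1, "gallbladder"), Category(2, "tool")],
        annotations=[
            Annotation(1, 1, 1, BoundingBox(10, 20, 30, 40)),
            Annotation(2, 1, 2, BoundingBox(50, 10, 20, 30)),
        ],
    )


@pytest.fixture
def tiny_coco_file(tmp_path, tiny_dataset):
    path = tmp_path / "tiny.json"
    payload = {
        "images": [{"id": 1, "width": 100, "height": 80, "file_name": "img_00001.png"}],
        "categories": [{"id": 1, "name": "gallbladder"}, {"id": 2, "name": "tool"}],
        "annotations": [
            {"id": 1, "image_id": 1, "category_id": 1, "bbox": [10, 20, 30, 40]},
            {"id": 2, "image_id": 1, "category_id": 2, "bbox": [50, 10, 20, 30]},
        ],
    }
    path.write_text(json.dumps(payload))
    return path
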