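"""Per-class top-k prediction filtering and before/after reduction accounting.

End-to-end detectors emit one scored box per query, so the raw prediction
count per image can exceed the true object count by an order of magnitude.
When the expected per-image multiplicity of each class is known (in
laparoscopic scenes most anatomy classes appear at most once per frame and
tools once or twice), keeping only the k highest-scoring predictions per
image and class aligns the output with that prior while barely moving the
evaluation metric. ``KMap`` carries the per-class k (default 1, with named
overrides, e.g. ``{"tool": 2}``); ``reduction_report`` produces the
before/after accounting table including the percent reduction in prediction
counts and, when evaluation results are supplied, the metric change.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from .coco import Category, DatasetAnnotations, PredictionSet
from .errors import ConfigurationError
from .evaluation import EvalResult


@dataclass
class KMap:
    """How many predictions to keep per image for each category (by name)."""

    default_k: int = 1
    overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.default_k < 1 or any(k < 1 for k in self.overrides.values()):
            raise ConfigurationError("all k values must be >= 1")

    def k_for(self, category_name: str) -> int:
        return self.overrides.get(category_name, self.default_k)

    @staticmethod
    def endoscapes_preset() -> "KMap":
        return KMap(default_k=1, overrides={"tool": 2, "Tool": 2})

    @staticmethod
    def m2cai16_preset() -> "KMap":
        return KMap(default_k=1, overrides={"grasper": 2, "Grasper": 2})


def topk_filter(
    preds: PredictionSet,
    kmap: KMap,
    categories: list[Category] | DatasetAnnotations,
) -> PredictionSet:
    """Keep the k highest-scoring records per (image, category).

    Score ties at the k-th rank keep the earlier record in input order; the
    relative input order of kept records is preserved, so the operation is
    idempotent. Overrides naming unknown categories are ignored with a
    warning.
    """
    if isinstance(categories, DatasetAnnotations):
        categories = categories.categories
    name_of = {c.category_id: c.name for c in categories}
    known_names = set(name_of.values())
    for name in kmap.overrides:
        if name not in known_names:
            warnings.warn(f"KMap override for unknown category {name!r} ignored",
                          stacklevel=2)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, rec in enumerate(preds.records):
        groups.setdefault((rec.image_id, rec.category_id), []).append(i)
    keep: set[int] = set()
    for (image_id, category_id), indices in groups.items():
        k = kmap.k_for(name_of.get(category_id, ""))
        ranked = sorted(indices, key=lambda i: (-preds.records[i].score, i))
        keep.update(ranked[:k])
    return PredictionSet(records=[r for i, r in enumerate(preds.records) if i in keep])


@dataclass
class ReductionRow:
    category: str
    n_ground_truth: int
    n_before: int
    n_after: int
    metric_before: float = float("nan")
    metric_after: float = float("nan")

    @property
    def count_reduction_percent(self) -> float:
        if self.n_before == 0:
            return float("nan")
        return 100.0 * (self.n_before - self.n_after) / self.n_before

    @property
    def metric_change_percent(self) -> float:
        if np.isnan(self.metric_before) or self.metric_before == 0:
            return float("nan")
        return 100.0 * (self.metric_after - self.metric_before) / self.metric_before


@dataclass
class ReductionReport:
    """Per-class and total before/after accounting of a filtering step."""

    per_class: dict[str, ReductionRow]
    totals: ReductionRow

    @property
    def total_count_reduction_percent(self) -> float:
        return self.totals.count_reduction_percent

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow([
            "category", "ground_truth", "predictions_before", "predictions_after",
            "metric_before", "metric_after", "metric_change_percent",
            "count_reduction_percent",
        ])

        def fmt(v: float) -> str:
            return "" if np.isnan(v) else f"{v:.4f}"

        for row in list(self.per_class.values()) + [self.totals]:
            writer.writerow([
                row.category, row.n_ground_truth, row.n_before, row.n_after,
                fmt(row.metric_before), fmt(row.metric_after),
                fmt(row.metric_change_percent), fmt(row.count_reduction_percent),
            ])
        return buf.getvalue()


def reduction_report(
    before: PredictionSet,
    after: PredictionSet,
    gts: DatasetAnnotations,
    metrics: tuple[EvalResult, EvalResult] | None = None,
) -> ReductionReport:
    """Tabulate prediction counts (and optionally AP@50:95) before vs after."""

    def counts(preds: PredictionSet) -> dict[int, int]:
        out = {c.category_id: 0 for c in gts.categories}
        for rec in preds.records:
            if rec.category_id in out:
                out[rec.category_id] += 1
        return out

    n_before, n_after = counts(before), counts(after)
    for cid in n_before:
        if n_after[cid] > n_before[cid]:
            raise ConfigurationError(
                f"'after' has more predictions than 'before' for category {cid}")
    gt_counts = {c.category_id: 0 for c in gts.categories}
    for ann in gts.annotations:
        gt_counts[ann.category_id] += 1
    per_class: dict[str, ReductionRow] = {}
    for cat in gts.categories:
        row = ReductionRow(
            category=cat.name,
            n_ground_truth=gt_counts[cat.category_id],
            n_before=n_before[cat.category_id],
            n_after=n_after[cat.category_id],
        )
        if metrics is not None:
            row.metric_before = metrics[0].class_ap_range(cat.category_id)
            row.metric_after = metrics[1].class_ap_range(cat.category_id)
        per_class[cat.name] = row
    totals = ReductionRow(
        category="overall",
        n_ground_truth=sum(gt_counts.values()),
        n_before=sum(n_before.values()),
        n_after=sum(n_after.values()),
    )
    if metrics is not None:
        totals.metric_before = metrics[0].map50_95
        totals.metric_after = metrics[1].map50_95
    return ReductionReport(per_class=per_class, totals=totals)
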