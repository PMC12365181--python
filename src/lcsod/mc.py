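"""Macroscopic Correlation (MC) of bounding-box layouts.

MC treats every annotated box in an image as a 4-vector ``[x, y, w, h]`` and
averages the absolute Pearson correlation over all ordered pairs of boxes:

    MC = sum_{a} sum_{b != a} |PCC(B_a, B_b)| / (N (N - 1))

so ``MC`` lies in ``[0, 1]`` and measures how strongly box positions and sizes
in one image move together. Conventional correlation-strength bands are used
at dataset level: low ``[0, 0.3)``, moderate ``[0.3, 0.5)``, strong
``[0.5, 1.0]`` (half-open on the left boundary by this package's convention,
since the band endpoints overlap in the usual statistical phrasing).

Boxes whose 4 components are all equal have zero variance and an undefined
PCC; such pairs are excluded from both numerator and denominator, and images
with fewer than two boxes (or no defined pair at all) get an undefined MC,
reported as ``nan`` and counted separately — never coerced to 0.

The value of MC depends on the box convention (corner vs center coordinates
change the x/y components). The default is corner-absolute pixels, i.e. the
boxes exactly as stored in COCO annotations; callers may select another
convention explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coco import (
    CORNER_ABSOLUTE,
    BoundingBox,
    DatasetAnnotations,
    boxes_to_array,
    convert_box,
)

BANDS = (("low", 0.0, 0.3), ("moderate", 0.3, 0.5), ("strong", 0.5, 1.0))

UNDEFINED = float("nan")


def _standardize(v: np.ndarray) -> np.ndarray | None:
    """Z-score a 4-vector across its components; None if zero variance."""
    sd = v.std()
    if sd == 0.0:
        return None
    return (v - v.mean()) / sd


def pcc(box_a: BoundingBox | np.ndarray, box_b: BoundingBox | np.ndarray) -> float:
    """Pearson correlation of two boxes viewed as 4-component vectors.

    Returns ``nan`` when either vector has zero variance across its four
    components (the correlation is undefined there).
    """
    va = box_a.as_array() if isinstance(box_a, BoundingBox) else np.asarray(box_a, float)
    vb = box_b.as_array() if isinstance(box_b, BoundingBox) else np.asarray(box_b, float)
    za, zb = _standardize(va), _standardize(vb)
    if za is None or zb is None:
        return UNDEFINED
    r = float(za @ zb) / 4.0
    return max(-1.0, min(1.0, r))


def mc_image(boxes: list[BoundingBox] | np.ndarray) -> float:
    """MC of one image's box set; ``nan`` when undefined (N < 2 or no pair
    with a defined PCC)."""
    if isinstance(boxes, np.ndarray):
        arr = np.asarray(boxes, dtype=float)
    else:
        arr = boxes_to_array(boxes)
    n = arr.shape[0]
    if n < 2:
        return UNDEFINED
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1)
    defined = sd > 0.0
    if defined.sum() < 2:
        return UNDEFINED
    z = np.zeros_like(arr)
    z[defined] = (arr[defined] - mean[defined]) / sd[defined, None]
    corr = np.clip((z @ z.T) / 4.0, -1.0, 1.0)
    mask = np.outer(defined, defined)
    np.fill_diagonal(mask, False)
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        return UNDEFINED
    return float(np.abs(corr[mask]).sum() / n_pairs)


@dataclass
class MCReport:
    """Dataset-level MC distribution."""

    per_image: dict[int, float]  # image_id -> MC (nan = undefined)
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    band_counts: dict[str, int]
    n_undefined: int

    @property
    def n_images(self) -> int:
        return len(self.per_image)

    def defined_values(self) -> np.ndarray:
        vals = np.array(list(self.per_image.values()), dtype=float)
        return vals[~np.isnan(vals)]

    def band_fractions(self) -> dict[str, float]:
        n_def = len(self.defined_values())
        if n_def == 0:
            return {name: 0.0 for name in self.band_counts}
        return {name: c / n_def for name, c in self.band_counts.items()}

    def to_dict(self) -> dict:
        return {
            "per_image": {str(k): (None if np.isnan(v) else v)
                          for k, v in self.per_image.items()},
            "histogram": {
                "edges": self.hist_edges.tolist(),
                "counts": self.hist_counts.tolist(),
            },
            "band_counts": dict(self.band_counts),
            "n_undefined": self.n_undefined,
            "n_images": self.n_images,
        }


def band_of(value: float) -> str | None:
    if np.isnan(value):
        return None
    for name, lo, hi in BANDS:
        if (lo <= value < hi) or (name == "strong" and value == hi):
            return name
    return None


def mc_distribution(
    gts: DatasetAnnotations,
    convention: str = CORNER_ABSOLUTE,
    bins: int = 20,
) -> MCReport:
    """Per-image MC values, histogram and correlation-band counts."""
    per_image: dict[int, float] = {}
    for image_id, boxes in gts.boxes_by_image().items():
        im = next(i for i in gts.images if i.image_id == image_id)
        converted = [convert_box(b, convention, (im.width, im.height)) for b in boxes]
        arr = np.array([[b.x, b.y, b.w, b.h] for b in converted], dtype=float)
        per_image[image_id] = mc_image(arr) if len(converted) else UNDEFINED

    values = np.array(list(per_image.values()), dtype=float)
    defined = values[~np.isnan(values)]
    counts, edges = np.histogram(defined, bins=bins, range=(0.0, 1.0))
    band_counts = {name: 0 for name, _, _ in BANDS}
    for v in defined:
        band = band_of(float(v))
        if band is not None:
            band_counts[band] += 1
    return MCReport(
        per_image=per_image,
        hist_edges=edges,
        hist_counts=counts,
        band_counts=band_counts,
        n_undefined=int(np.isnan(values).sum()),
    )
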