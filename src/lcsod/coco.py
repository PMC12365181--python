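"""COCO-format detection annotations and predictions.

Ground truth follows the standard COCO detection schema
(``images`` / ``annotations`` / ``categories``); predictions follow the COCO
results schema (a flat list of ``{image_id, category_id, bbox, score}``).
Boxes on disk are always corner-absolute ``[x_min, y_min, w, h]`` in pixels
(COCO convention, origin top-left, y downward); in memory every box carries an
explicit convention tag so center-based model code cannot be mixed up with
corner-based annotation code silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateBoxError, FormatError, IntegrityError, ValidationError

CORNER_ABSOLUTE = "corner-absolute"
CENTER_ABSOLUTE = "center-absolute"
CENTER_NORMALIZED = "center-normalized"
CONVENTIONS = (CORNER_ABSOLUTE, CENTER_ABSOLUTE, CENTER_NORMALIZED)


@dataclass(frozen=True)
class BoundingBox:
    """A single box under an explicit coordinate convention.

    ``(x, y)`` is the top-left corner for :data:`CORNER_ABSOLUTE` and the box
    center for the two center conventions; ``w``/``h`` are always the full
    width and height. Center-normalized values are fractions of image size.
    """

    x: float
    y: float
    w: float
    h: float
    convention: str = CORNER_ABSOLUTE

    def __post_init__(self) -> None:
        if self.convention not in CONVENTIONS:
            raise ValidationError(f"unknown box convention {self.convention!r}")
        if not (self.w > 0 and self.h > 0):
            raise DegenerateBoxError(
                f"box width/height must be positive, got w={self.w}, h={self.h}"
            )
        if self.convention == CENTER_NORMALIZED:
            vals = (self.x, self.y, self.w, self.h)
            if not all(0.0 <= v <= 1.0 for v in vals):
                raise ValidationError(
                    f"center-normalized coordinates must lie in [0,1], got {vals}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.w, self.h], dtype=float)


@dataclass(frozen=True)
class ImageInfo:
    image_id: int
    width: int
    height: int
    file_name: str = ""


@dataclass(frozen=True)
class Category:
    category_id: int
    name: str


@dataclass(frozen=True)
class Annotation:
    annotation_id: int
    image_id: int
    category_id: int
    box: BoundingBox


@dataclass
class DatasetAnnotations:
    """Ground truth for a detection dataset in COCO semantics."""

    images: list[ImageInfo] = field(default_factory=list)
    categories: list[Category] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        image_ids = {im.image_id for im in self.images}
        if len(image_ids) != len(self.images):
            raise IntegrityError("duplicate image ids")
        cat_ids = {c.category_id for c in self.categories}
        if len(cat_ids) != len(self.categories):
            raise IntegrityError("duplicate category ids")
        seen_ann: set[int] = set()
        for ann in self.annotations:
            if ann.annotation_id in seen_ann:
                raise IntegrityError(f"duplicate annotation id {ann.annotation_id}")
            seen_ann.add(ann.annotation_id)
            if ann.image_id not in image_ids:
                raise IntegrityError(
                    f"annotation {ann.annotation_id} references unknown image_id "
                    f"{ann.image_id}"
                )
            if ann.category_id not in cat_ids:
                raise IntegrityError(
                    f"annotation {ann.annotation_id} references unknown category_id "
                    f"{ann.category_id}"
                )

    # -- convenience views -------------------------------------------------
    @property
    def image_ids(self) -> list[int]:
        return [im.image_id for im in self.images]

    @property
    def category_ids(self) -> list[int]:
        return [c.category_id for c in self.categories]

    def category_index(self) -> dict[int, int]:
        """Contiguous 0-based index for each category id (ids are preserved,
        never rewritten; this map is the only place order matters)."""
        return {c.category_id: i for i, c in enumerate(self.categories)}

    def annotations_by_image(self) -> dict[int, list[Annotation]]:
        out: dict[int, list[Annotation]] = {im.image_id: [] for im in self.images}
        for ann in self.annotations:
            out[ann.image_id].append(ann)
        return out

    def boxes_by_image(self) -> dict[int, list[BoundingBox]]:
        return {
            iid: [a.box for a in anns]
            for iid, anns in self.annotations_by_image().items()
        }


@dataclass(frozen=True)
class PredictionRecord:
    image_id: int
    category_id: int
    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score must be in [0,1], got {self.score}")


@dataclass
class PredictionSet:
    """Scored, class-labelled boxes per image (raw or postprocessed)."""

    records: list[PredictionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def by_image(self) -> dict[int, list[PredictionRecord]]:
        out: dict[int, list[PredictionRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.image_id, []).append(rec)
        return out

    def validate_against(self, gts: DatasetAnnotations) -> None:
        known = set(gts.image_ids)
        for rec in self.records:
            if rec.image_id not in known:
                raise IntegrityError(
                    f"prediction references unknown image_id {rec.image_id}"
                )


# ---------------------------------------------------------------------------
# box conversion
# ---------------------------------------------------------------------------

def convert_box(
    box: BoundingBox,
    target: str,
    image_size: tuple[float, float] | None = None,
) -> BoundingBox:
    """Re-express ``box`` in ``target`` convention; the pixel rectangle it
    represents is unchanged. ``image_size = (width, height)`` is required
    whenever normalization is involved on either side."""
    if target not in CONVENTIONS:
        raise ValidationError(f"unknown target convention {target!r}")
    if box.convention == target:
        return box

    needs_size = CENTER_NORMALIZED in (box.convention, target)
    if needs_size:
        if image_size is None:
            raise ValidationError("image_size required for normalized conversion")
        iw, ih = float(image_size[0]), float(image_size[1])
        if iw <= 0 or ih <= 0:
            raise ValidationError(f"image_size must be positive, got {image_size}")

    # to center-absolute first
    if box.convention == CORNER_ABSOLUTE:
        cx, cy, w, h = box.x + box.w / 2.0, box.y + box.h / 2.0, box.w, box.h
    elif box.convention == CENTER_ABSOLUTE:
        cx, cy, w, h = box.x, box.y, box.w, box.h
    else:  # center-normalized
        cx, cy, w, h = box.x * iw, box.y * ih, box.w * iw, box.h * ih

    if target == CORNER_ABSOLUTE:
        return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h, CORNER_ABSOLUTE)
    if target == CENTER_ABSOLUTE:
        return BoundingBox(cx, cy, w, h, CENTER_ABSOLUTE)
    return BoundingBox(cx / iw, cy / ih, w / iw, h / ih, CENTER_NORMALIZED)


def boxes_to_array(boxes: Sequence[BoundingBox], convention: str | None = None) -> np.ndarray:
    """Stack boxes into an ``(N, 4)`` float array, converting if asked.

    Conversion here never involves normalization, so ``convention`` may only
    be corner/center absolute (or None to require a uniform input)."""
    if convention is not None and convention == CENTER_NORMALIZED:
        raise ValidationError("boxes_to_array cannot normalize; use convert_box")
    out = np.empty((len(boxes), 4), dtype=float)
    for i, b in enumerate(boxes):
        if convention is not None and b.convention != convention:
            b = convert_box(b, convention)
        elif convention is None and boxes and b.convention != boxes[0].convention:
            raise ValidationError("boxes mix conventions; pass an explicit target")
        out[i] = (b.x, b.y, b.w, b.h)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_coco_dataset(path: str | Path) -> DatasetAnnotations:
    """Read a COCO detection annotation file; boxes come back corner-absolute."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("images", "annotations", "categories"):
        if key not in payload:
            raise FormatError(f"{path}: missing COCO key {key!r}")
    images = [
        ImageInfo(
            image_id=int(im["id"]),
            width=int(im["width"]),
            height=int(im["height"]),
            file_name=str(im.get("file_name", "")),
        )
        for im in payload["images"]
    ]
    categories = [
        Category(category_id=int(c["id"]), name=str(c["name"]))
        for c in payload["categories"]
    ]
    annotations = []
    for ann in payload["annotations"]:
        x, y, w, h = (float(v) for v in ann["bbox"])
        annotations.append(
            Annotation(
                annotation_id=int(ann["id"]),
                image_id=int(ann["image_id"]),
                category_id=int(ann["category_id"]),
                box=BoundingBox(x, y, w, h, CORNER_ABSOLUTE),
            )
        )
    return DatasetAnnotations(images=images, categories=categories, annotations=annotations)


def write_coco_dataset(gts: DatasetAnnotations, path: str | Path) -> None:
    payload = {
        "images": [
            {"id": im.image_id, "width": im.width, "height": im.height,
             "file_name": im.file_name}
            for im in gts.images
        ],
        "categories": [
            {"id": c.category_id, "name": c.name} for c in gts.categories
        ],
        "annotations": [
            {
                "id": a.annotation_id,
                "image_id": a.image_id,
                "category_id": a.category_id,
                "bbox": [b.x, b.y, b.w, b.h],
                "area": b.w * b.h,
                "iscrowd": 0,
            }
            for a in gts.annotations
            for b in (convert_box(a.box, CORNER_ABSOLUTE),)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_predictions(preds: PredictionSet, path: str | Path) -> None:
    """Write a COCO results-format JSON list with corner-absolute boxes."""
    payload = []
    for rec in preds.records:
        b = convert_box(rec.box, CORNER_ABSOLUTE)
        payload.append(
            {
                "image_id": rec.image_id,
                "category_id": rec.category_id,
                "bbox": [b.x, b.y, b.w, b.h],
                "score": rec.score,
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_predictions(path: str | Path) -> PredictionSet:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, list):
        raise FormatError(f"{path}: COCO results file must be a JSON list")
    records = []
    for entry in payload:
        x, y, w, h = (float(v) for v in entry["bbox"])
        records.append(
            PredictionRecord(
                image_id=int(entry["image_id"]),
                category_id=int(entry["category_id"]),
                box=BoundingBox(x, y, w, h, CORNER_ABSOLUTE),
                score=float(entry["score"]),
            )
        )
    return PredictionSet(records=records)
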