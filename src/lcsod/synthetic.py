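"""Synthetic laparoscopy-like scenes with controllable positional correlation.

Real laparoscopic datasets differ sharply in how strongly their annotated
objects co-locate: anatomy-rich scenes (gallbladder, cystic structures, a
tool or two working on them) put boxes in tight spatial arrangements, while
tool-only datasets scatter one or two instruments anywhere in the frame. The
generator reproduces that contrast with a single coupling knob ``rho``: every
image draws a latent anchor point and a shared scale factor, and each box is
placed at ``anchor + (1 - rho) * independent offset`` with size
``shared_scale**rho * independent draw``. ``rho = 0`` gives independent
placement, ``rho = 1`` a rigid cluster of similar-size boxes; the mean
macroscopic correlation of the dataset rises monotonically with ``rho``.

Rendering is deliberately simple — flat-colored ellipses / rectangles /
triangles per category on a low-frequency textured background — so that a
small detector can learn the scenes on a CPU. No claim of anatomical realism
is made. The module also fabricates over-complete scored prediction sets
(jittered copies of true boxes plus random low-score boxes) that stand in
for a detector's raw per-query output in postprocessing and evaluation tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw

from .coco import (
    CORNER_ABSOLUTE,
    Annotation,
    BoundingBox,
    Category,
    DatasetAnnotations,
    ImageInfo,
    PredictionRecord,
    PredictionSet,
)
from .errors import ConfigurationError

MAX_BOXES_PER_IMAGE = 8

# fixed palette: visually separable flat colors, one per category slot
_PALETTE = [
    (220, 60, 60), (70, 160, 220), (90, 200, 90), (230, 200, 60),
    (180, 90, 210), (240, 140, 50), (100, 220, 210), (160, 160, 160),
]
_SHAPES = ("ellipse", "rectangle", "triangle")


@dataclass
class SceneConfig:
    """Configuration of one synthetic dataset."""

    n_images: int
    categories: list[str]
    image_size: tuple[int, int] = (64, 64)  # (width, height)
    multiplicity: tuple[int, int] = (0, 2)  # boxes per category per image
    anchor_coupling: float = 0.5  # rho in [0, 1]
    size_range: tuple[float, float] = (0.15, 0.45)  # box side, fraction of image
    render_style: str = "flat-color"  # or "none"
    min_boxes_per_image: int = 1
    max_boxes_per_image: int = MAX_BOXES_PER_IMAGE
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.categories:
            raise ConfigurationError("categories must be non-empty")
        if not (0.0 <= self.anchor_coupling <= 1.0):
            raise ConfigurationError(
                f"anchor_coupling must be in [0,1], got {self.anchor_coupling}")
        lo, hi = self.multiplicity
        if lo > hi or lo < 0:
            raise ConfigurationError(f"bad multiplicity range {self.multiplicity}")
        slo, shi = self.size_range
        if not (0.0 < slo <= shi <= 1.0):
            raise ConfigurationError(f"bad size_range {self.size_range}")
        if self.render_style not in ("flat-color", "none"):
            raise ConfigurationError(f"unknown render_style {self.render_style!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @staticmethod
    def from_yaml(path: str | Path) -> "SceneConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("image_size", "multiplicity", "size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return SceneConfig(**raw)


# -- presets ----------------------------------------------------------------

def endoscapes_like(n_images: int = 200, seed: int = 0,
                    image_size: tuple[int, int] = (64, 64)) -> SceneConfig:
    """Anatomy-style regime: 6 classes, several boxes per image, strong
    positional coupling (approximate, not a clinical simulation)."""
    return SceneConfig(
        n_images=n_images,
        categories=["cystic_plate", "hc_triangle", "cystic_artery",
                    "cystic_duct", "gallbladder", "tool"],
        image_size=image_size,
        multiplicity=(0, 1),
        anchor_coupling=0.85,
        size_range=(0.15, 0.45),
        min_boxes_per_image=2,
        seed=seed,
    )


def m2cai16_like(n_images: int = 200, seed: int = 0,
                 image_size: tuple[int, int] = (64, 64)) -> SceneConfig:
    """Tool-only regime: 7 classes, 1-2 boxes per image, weak coupling."""
    return SceneConfig(
        n_images=n_images,
        categories=["grasper", "bipolar", "hook", "scissors", "clipper",
                    "irrigator", "specimen_bag"],
        image_size=image_size,
        multiplicity=(0, 1),
        anchor_coupling=0.1,
        size_range=(0.15, 0.4),
        min_boxes_per_image=1,
        max_boxes_per_image=2,
        seed=seed,
    )


def easy_scenes(n_images: int = 200, seed: int = 0,
                image_size: tuple[int, int] = (64, 64)) -> SceneConfig:
    """Few classes, large well-separated colored shapes: the regime used to
    check that the mini detector can learn at desk scale."""
    return SceneConfig(
        n_images=n_images,
        categories=["disc", "slab", "wedge"],
        image_size=image_size,
        multiplicity=(0, 1),
        anchor_coupling=0.3,
        size_range=(0.3, 0.55),
        min_boxes_per_image=1,
        seed=seed,
    )


PRESETS = {
    "endoscapes-like": endoscapes_like,
    "m2cai16-like": m2cai16_like,
    "easy": easy_scenes,
}


# -- generation -------------------------------------------------------------


@dataclass
class SceneDataset:
    annotations: DatasetAnnotations
    images: dict[int, np.ndarray] | None  # image_id -> (H, W, 3) uint8

    def write(self, out_dir: str | Path) -> None:
        from .coco import write_coco_dataset

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_coco_dataset(self.annotations, out / "annotations.json")
        if self.images is not None:
            for info in self.annotations.images:
                Image.fromarray(self.images[info.image_id]).save(out / info.file_name)

    def image_arrays(self) -> dict[int, np.ndarray]:
        if self.images is None:
            raise ConfigurationError("dataset was generated without rendering")
        return self.images


def _sample_counts(rng: np.random.Generator, cfg: SceneConfig) -> np.ndarray:
    lo, hi = cfg.multiplicity
    n_cat = len(cfg.categories)
    counts = rng.integers(lo, hi + 1, size=n_cat)
    while counts.sum() < max(cfg.min_boxes_per_image, 1 if hi > 0 else 0):
        bumpable = np.flatnonzero(counts < hi)
        if len(bumpable) == 0:
            break
        counts[rng.choice(bumpable)] += 1
    while counts.sum() > min(cfg.max_boxes_per_image, MAX_BOXES_PER_IMAGE):
        shrinkable = np.flatnonzero(counts > lo)
        counts[rng.choice(shrinkable)] -= 1
    return counts


def _place_boxes(rng: np.random.Generator, cfg: SceneConfig,
                 n_boxes: int) -> np.ndarray:
    """Corner-absolute [x, y, w, h] boxes, fully inside the image."""
    iw, ih = cfg.image_size
    rho = cfg.anchor_coupling
    slo, shi = cfg.size_range
    anchor = rng.uniform(0.3, 0.7, size=2)
    shared_scale = rng.uniform(0.6, 1.4)
    mid, half = (slo + shi) / 2.0, (shi - slo) / 2.0
    boxes = np.empty((n_boxes, 4))
    for i in range(n_boxes):
        offset = rng.uniform(-0.45, 0.45, size=2)
        cx, cy = anchor + (1.0 - rho) * offset
        # size spread also shrinks with rho: at rho=1 all boxes share the
        # per-image scale exactly, at rho=0 sizes are fully independent
        w = shared_scale ** rho * (mid + (1.0 - rho) * rng.uniform(-half, half))
        h = shared_scale ** rho * (mid + (1.0 - rho) * rng.uniform(-half, half))
        w = float(np.clip(w, 2.0 / iw, 0.9))
        h = float(np.clip(h, 2.0 / ih, 0.9))
        cx = float(np.clip(cx, w / 2.0 + 0.01, 0.99 - w / 2.0))
        cy = float(np.clip(cy, h / 2.0 + 0.01, 0.99 - h / 2.0))
        boxes[i] = ((cx - w / 2.0) * iw, (cy - h / 2.0) * ih, w * iw, h * ih)
    return boxes


def _render_background(rng: np.random.Generator, size: tuple[int, int]) -> Image.Image:
    """Low-frequency brownish noise background."""
    iw, ih = size
    coarse = rng.uniform(40, 90, size=(8, 8, 3))
    coarse[..., 0] += 25  # warm tint
    img = Image.fromarray(coarse.astype(np.uint8), mode="RGB")
    return img.resize((iw, ih), Image.BILINEAR)


def _draw_shape(draw: ImageDraw.ImageDraw, box: np.ndarray, cat_index: int,
                rng: np.random.Generator) -> None:
    x, y, w, h = box
    base = np.array(_PALETTE[cat_index % len(_PALETTE)], dtype=float)
    jitter = rng.integers(-20, 21, size=3)
    color = tuple(int(v) for v in np.clip(base + jitter, 0, 255))
    shape = _SHAPES[cat_index % len(_SHAPES)]
    x2, y2 = x + w, y + h
    if shape == "ellipse":
        draw.ellipse([x, y, x2, y2], fill=color)
    elif shape == "rectangle":
        draw.rectangle([x, y, x2, y2], fill=color)
    else:  # triangle touching the three box edges
        draw.polygon([(x + w / 2.0, y), (x, y2), (x2, y2)], fill=color)


def generate_scene_dataset(
    config: SceneConfig, out_dir: str | Path | None = None,
) -> SceneDataset:
    """Generate a synthetic dataset; identical config+seed give identical
    output. With ``out_dir`` the images and COCO JSON are also written."""
    rng = np.random.default_rng(config.seed)
    iw, ih = config.image_size
    images: list[ImageInfo] = []
    annotations: list[Annotation] = []
    arrays: dict[int, np.ndarray] | None = (
        {} if config.render_style == "flat-color" else None)
    ann_id = 1
    for image_id in range(1, config.n_images + 1):
        counts = _sample_counts(rng, config)
        n_boxes = int(counts.sum())
        boxes = _place_boxes(rng, config, n_boxes)
        cat_of_box = np.repeat(np.arange(len(config.categories)), counts)
        images.append(ImageInfo(image_id, iw, ih, f"img_{image_id:05d}.png"))
        if arrays is not None:
            img = _render_background(rng, config.image_size)
            draw = ImageDraw.Draw(img)
        # draw large boxes first so smaller ones stay visible
        order = np.argsort(-(boxes[:, 2] * boxes[:, 3]))
        for bi in order:
            if arrays is not None:
                _draw_shape(draw, boxes[bi], int(cat_of_box[bi]), rng)
        for bi in range(n_boxes):
            x, y, w, h = boxes[bi]
            annotations.append(
                Annotation(ann_id, image_id, int(cat_of_box[bi]) + 1,
                           BoundingBox(x, y, w, h, CORNER_ABSOLUTE)))
            ann_id += 1
        if arrays is not None:
            arrays[image_id] = np.asarray(img, dtype=np.uint8)
    gts = DatasetAnnotations(
        images=images,
        categories=[Category(i + 1, name) for i, name in enumerate(config.categories)],
        annotations=annotations,
    )
    ds = SceneDataset(annotations=gts, images=arrays)
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def generate_prediction_set(
    gts: DatasetAnnotations,
    queries_per_image: int,
    noise: tuple[float, float, float] = (0.05, 0.05, 0.1),
    seed: int = 0,
    hit_fraction: float = 0.3,
) -> PredictionSet:
    """Fabricate an over-complete raw prediction set.

    Per image: ``hit_fraction`` of the records are jittered copies of true
    boxes with high scores (every ground-truth box gets at least one copy),
    the rest uniformly random boxes with low scores. ``noise`` is
    (center jitter sd, size jitter sd, score temperature), jitters relative
    to box size.
    """
    if queries_per_image < 1:
        raise ConfigurationError("queries_per_image must be >= 1")
    center_sd, size_sd, score_temp = noise
    rng = np.random.default_rng(seed)
    size_of = {im.image_id: (im.width, im.height) for im in gts.images}
    cat_ids = gts.category_ids
    records: list[PredictionRecord] = []
    anns_by_image = gts.annotations_by_image()
    for image_id in gts.image_ids:
        iw, ih = size_of[image_id]
        anns = anns_by_image.get(image_id, [])
        n_hits = int(round(hit_fraction * queries_per_image))
        n_hits = min(queries_per_image, max(n_hits, len(anns)))
        if not anns:
            n_hits = 0
        for j in range(n_hits):
            ann = anns[j % len(anns)]
            b = ann.box
            scale = min(b.w, b.h)
            cx = b.x + b.w / 2.0 + rng.normal(0.0, center_sd * scale)
            cy = b.y + b.h / 2.0 + rng.normal(0.0, center_sd * scale)
            w = b.w * float(np.exp(rng.normal(0.0, size_sd)))
            h = b.h * float(np.exp(rng.normal(0.0, size_sd)))
            w = float(np.clip(w, 1.0, iw))
            h = float(np.clip(h, 1.0, ih))
            cx = float(np.clip(cx, w / 2.0, iw - w / 2.0))
            cy = float(np.clip(cy, h / 2.0, ih - h / 2.0))
            dup_rank = j // len(anns)
            score = 0.95 - 0.05 * dup_rank + score_temp * float(rng.normal())
            records.append(PredictionRecord(
                image_id, ann.category_id,
                BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h, CORNER_ABSOLUTE),
                float(np.clip(score, 0.0, 1.0))))
        for _ in range(queries_per_image - n_hits):
            w = float(rng.uniform(2.0, 0.8 * iw))
            h = float(rng.uniform(2.0, 0.8 * ih))
            x = float(rng.uniform(0.0, iw - w))
            y = float(rng.uniform(0.0, ih - h))
            score = 0.05 + 0.15 * float(rng.random()) \
                + score_temp * abs(float(rng.normal())) * 0.1
            records.append(PredictionRecord(
                image_id, int(rng.choice(cat_ids)),
                BoundingBox(x, y, w, h, CORNER_ABSOLUTE),
                float(np.clip(score, 0.0, 1.0))))
    return PredictionSet(records=records)
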