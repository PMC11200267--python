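"""YOLO annotation I/O, fixed-square box standardization, the box-size
sweep harness, dataset statistics, and block-level label cropping.

Labels use the YOLO TXT convention: one ``class cx cy w h`` line per box,
all four geometry fields normalized to the image dimensions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import Block, ImageSpec

__all__ = [
    "TasselCategory",
    "BBox",
    "AnnotationSet",
    "DatasetStats",
    "YoloFormatError",
    "read_yolo",
    "write_yolo",
    "standardize_boxes",
    "STANDARD_TARGETS",
    "OPTIMAL_TARGETS",
    "sweep_sizes",
    "dataset_stats",
    "crop_annotations_to_block",
    "split_dataset",
]


class TasselCategory(enum.IntEnum):
    """Plant-center state: removed/absent (N), formed-unemerged (S), mature (L)."""

    TASSEL_N = 0
    TASSEL_S = 1
    TASSEL_L = 2

    @property
    def short_name(self) -> str:
        return {0: "N", 1: "S", 2: "L"}[int(self)]


#: NSL-B style standardization: N and S forced to 140 px squares, L untouched.
STANDARD_TARGETS: Mapping[TasselCategory, int | None] = {
    TasselCategory.TASSEL_N: 140,
    TasselCategory.TASSEL_S: 140,
    TasselCategory.TASSEL_L: None,
}

#: Per-category sweep optima (N: 200 px, S: 160 px).
OPTIMAL_TARGETS: Mapping[TasselCategory, int | None] = {
    TasselCategory.TASSEL_N: 200,
    TasselCategory.TASSEL_S: 160,
    TasselCategory.TASSEL_L: None,
}


class YoloFormatError(ValueError):
    """Raised on malformed YOLO label content."""


@dataclass(frozen=True)
class BBox:
    """One labeled object: category plus a center/size box in pixels."""

    category: TasselCategory
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")

    @property
    def x_min(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def x_max(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y_min(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def y_max(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def aspect_ratio(self) -> float:
        """Length-width ratio as min(w, h) / max(w, h), in (0, 1]."""
        return min(self.w, self.h) / max(self.w, self.h)

    def clipped(self, x_lo: float, y_lo: float, x_hi: float, y_hi: float) -> "BBox | None":
        """Intersect with a window; None if the intersection has no area."""
        xa = max(self.x_min, x_lo)
        xb = min(self.x_max, x_hi)
        ya = max(self.y_min, y_lo)
        yb = min(self.y_max, y_hi)
        if xb <= xa or yb <= ya:
            return None
        return BBox(self.category, (xa + xb) / 2.0, (ya + yb) / 2.0, xb - xa, yb - ya)

    def translated(self, dx: float, dy: float) -> "BBox":
        return replace(self, cx=self.cx + dx, cy=self.cy + dy)


@dataclass(frozen=True)
class AnnotationSet:
    """All labeled boxes of one image."""

    image_id: str
    image_spec: ImageSpec
    boxes: tuple[BBox, ...] = ()

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)

    def category_counts(self) -> dict[TasselCategory, int]:
        counts = {c: 0 for c in TasselCategory}
        for b in self.boxes:
            counts[b.category] += 1
        return counts


def read_yolo(label_text: str, img: ImageSpec, image_id: str = "") -> AnnotationSet:
    """Parse per-image YOLO TXT content into pixel-unit boxes."""
    boxes: list[BBox] = []
    for lineno, raw in enumerate(label_text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise YoloFormatError(
                f"line {lineno}: expected 5 fields 'class cx cy w h', got {len(parts)}"
            )
        try:
            cls = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise YoloFormatError(f"line {lineno}: non-numeric field ({exc})") from exc
        if cls not in (0, 1, 2):
            raise YoloFormatError(f"line {lineno}: class code {cls} outside {{0, 1, 2}}")
        for name, v in zip(("cx", "cy", "w", "h"), vals):
            if not 0.0 <= v <= 1.0:
                raise YoloFormatError(
                    f"line {lineno}: normalized {name}={v} outside [0, 1]"
                )
        cx, cy, w, h = vals
        boxes.append(
            BBox(
                TasselCategory(cls),
                cx * img.width_px,
                cy * img.height_px,
                w * img.width_px,
                h * img.height_px,
            )
        )
    return AnnotationSet(image_id=image_id, image_spec=img, boxes=tuple(boxes))


def write_yolo(anns: AnnotationSet) -> str:
    """Serialize to YOLO TXT with 6-decimal normalized coordinates."""
    img = anns.image_spec
    lines = [
        f"{int(b.category)} "
        f"{b.cx / img.width_px:.6f} {b.cy / img.height_px:.6f} "
        f"{b.w / img.width_px:.6f} {b.h / img.height_px:.6f}"
        for b in anns.boxes
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def standardize_boxes(
    anns: AnnotationSet, targets: Mapping[TasselCategory, int | None] = STANDARD_TARGETS
) -> AnnotationSet:
    """Replace each targeted category's boxes with fixed squares at the same
    center, clipped to the image; untargeted categories pass through."""
    for cat, side in targets.items():
        if side is not None and side <= 0:
            raise ValueError(f"target side for {cat.name} must be positive, got {side}")
    img = anns.image_spec
    out: list[BBox] = []
    for b in anns.boxes:
        side = targets.get(b.category)
        if side is None:
            out.append(b)
            continue
        square = BBox(b.category, b.cx, b.cy, float(side), float(side))
        if (
            square.x_min >= 0
            and square.y_min >= 0
            and square.x_max <= img.width_px
            and square.y_max <= img.height_px
        ):
            out.append(square)
            continue
        clipped = square.clipped(0.0, 0.0, float(img.width_px), float(img.height_px))
        if clipped is None:
            # Center off-frame: keep the pre-clip square rather than drop it,
            # preserving box count.
            clipped = square
        out.append(clipped)
    return replace(anns, boxes=tuple(out))


def sweep_sizes(
    dataset: Sequence[AnnotationSet],
    sides: Sequence[int],
    categories: Iterable[TasselCategory] = (
        TasselCategory.TASSEL_N,
        TasselCategory.TASSEL_S,
    ),
) -> list[tuple[int, list[AnnotationSet]]]:
    """One standardized dataset per candidate square side (the box-size
    tuning enumeration; e.g. 50..500 step 50, refined 50..300 step 10)."""
    if len(sides) == 0:
        raise ValueError("sides must be nonempty")
    if any(b >= a for a, b in zip(sides[1:], sides[:-1])):
        raise ValueError("sides must be strictly increasing")
    cats = set(categories)
    out: list[tuple[int, list[AnnotationSet]]] = []
    for side in sides:
        targets: dict[TasselCategory, int | None] = {
            c: (side if c in cats else None) for c in TasselCategory
        }
        out.append((side, [standardize_boxes(a, targets) for a in dataset]))
    return out


@dataclass(frozen=True)
class DatasetStats:
    """Per-category and pooled box statistics (areas in px^2, ratios min/max)."""

    table: pd.DataFrame  # index: N, S, L, All; columns below

    COLUMNS = (
        "count",
        "proportion",
        "area_mean",
        "area_sd",
        "ratio_mean",
        "ratio_sd",
        "side_mean",
    )

    def row(self, key: str) -> pd.Series:
        return self.table.loc[key]


def dataset_stats(dataset: Sequence[AnnotationSet]) -> DatasetStats:
    """Count, area mean/SD, length-width-ratio mean/SD, and proportions per
    category plus a pooled "All" row. SDs are population SDs (ddof=0)."""
    rows = [
        (b.category.short_name, b.area, b.aspect_ratio, math.sqrt(b.area))
        for anns in dataset
        for b in anns.boxes
    ]
    if not rows:
        raise ValueError("dataset contains no annotation boxes")
    df = pd.DataFrame(rows, columns=["cat", "area", "ratio", "side"])
    total = len(df)
    records = {}
    for key, sub in [(c.short_name, df[df["cat"] == c.short_name]) for c in TasselCategory] + [
        ("All", df)
    ]:
        if len(sub) == 0:
            records[key] = dict.fromkeys(DatasetStats.COLUMNS, 0.0)
            continue
        records[key] = {
            "count": float(len(sub)),
            "proportion": len(sub) / total,
            "area_mean": float(sub["area"].mean()),
            "area_sd": float(sub["area"].std(ddof=0)),
            "ratio_mean": float(sub["ratio"].mean()),
            "ratio_sd": float(sub["ratio"].std(ddof=0)),
            "side_mean": float(sub["side"].mean()),
        }
    table = pd.DataFrame.from_dict(records, orient="index")[list(DatasetStats.COLUMNS)]
    return DatasetStats(table=table)


def crop_annotations_to_block(
    anns: AnnotationSet, block: Block, min_visible_frac: float = 0.5
) -> AnnotationSet:
    """Boxes intersecting the block, clipped and shifted to block-local
    coordinates; boxes less visible than ``min_visible_frac`` are dropped."""
    if not 0.0 <= min_visible_frac <= 1.0:
        raise ValueError(f"min_visible_frac must be in [0, 1], got {min_visible_frac}")
    block_spec = ImageSpec(block.side_px, block.side_px, anns.image_spec.gsd_cm_per_px)
    kept: list[BBox] = []
    for b in anns.boxes:
        clipped = b.clipped(block.x0, block.y0, block.x1, block.y1)
        if clipped is None:
            continue
        if clipped.area / b.area < min_visible_frac:
            continue
        kept.append(clipped.translated(-block.x0, -block.y0))
    return AnnotationSet(
        image_id=f"{anns.image_id}_r{block.row_index}c{block.col_index}",
        image_spec=block_spec,
        boxes=tuple(kept),
    )


def split_dataset(
    image_ids: Sequence[str],
    seed: int,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> dict[str, str]:
    """Seeded train/val/test split by image (default 8:1:1)."""
    if not math.isclose(sum(ratios), 1.0):
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    order = list(image_ids)
    rng.shuffle(order)
    n = len(order)
    n_train = round(ratios[0] * n)
    n_val = round(ratios[1] * n)
    assignment: dict[str, str] = {}
    for i, image_id in enumerate(order):
        if i < n_train:
            assignment[image_id] = "train"
        elif i < n_train + n_val:
            assignment[image_id] = "val"
        else:
            assignment[image_id] = "test"
    return assignment
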