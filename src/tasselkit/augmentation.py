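"""Label-preserving data augmentation: rotation, random cropping,
brightness, shadow addition, and chromatic adjustment.

Images are ``uint8`` arrays of shape (H, W, 3). Photometric operations
never touch box coordinates; geometric operations transform boxes with
the image. All randomness is driven by the seed stored in the spec, so a
given (image, spec) pair is reproducible bit-exactly.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .annotations import AnnotationSet, BBox
from .geometry import ImageSpec

__all__ = ["AugmentationOp", "AugmentationSpec", "augment_one", "augment_dataset"]


class AugmentationOp(str, enum.Enum):
    ROTATE = "ROTATE"
    RANDOM_CROP = "RANDOM_CROP"
    BRIGHTNESS = "BRIGHTNESS"
    SHADOW = "SHADOW"
    CHROMA = "CHROMA"


@dataclass(frozen=True)
class AugmentationSpec:
    op: AugmentationOp
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def params_json(self) -> str:
        return json.dumps(dict(self.params), sort_keys=True)


def _rotate_box_90k(b: BBox, k: int, width: int, height: int) -> BBox:
    """Box under k*90-degree clockwise rotation, pixel-center convention."""
    k = k % 4
    if k == 0:
        return b
    if k == 1:  # (cx, cy) -> (H-1-cy, cx), sides swap
        return BBox(b.category, height - 1 - b.cy, b.cx, b.h, b.w)
    if k == 2:
        return BBox(b.category, width - 1 - b.cx, height - 1 - b.cy, b.w, b.h)
    return BBox(b.category, b.cy, width - 1 - b.cx, b.h, b.w)  # k == 3


def _rotate_box_arbitrary(b: BBox, angle_deg: float, width: int, height: int) -> BBox | None:
    """Map the four corners through a rotation about the image center and
    refit the axis-aligned hull (slightly inflates non-axis boxes)."""
    theta = math.radians(angle_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    ocx, ocy = (width - 1) / 2.0, (height - 1) / 2.0
    xs, ys = [], []
    for px, py in (
        (b.x_min, b.y_min),
        (b.x_min, b.y_max),
        (b.x_max, b.y_min),
        (b.x_max, b.y_max),
    ):
        dx, dy = px - ocx, py - ocy
        # clockwise rotation in screen coordinates (y down)
        xs.append(ocx + cos_t * dx - sin_t * dy)
        ys.append(ocy + sin_t * dx + cos_t * dy)
    hull = BBox(
        b.category,
        (min(xs) + max(xs)) / 2.0,
        (min(ys) + max(ys)) / 2.0,
        max(xs) - min(xs),
        max(ys) - min(ys),
    )
    return hull.clipped(0.0, 0.0, float(width), float(height))


def _apply_rotate(
    img: np.ndarray, anns: AnnotationSet, angle: float
) -> tuple[np.ndarray, AnnotationSet]:
    height, width = img.shape[:2]
    if angle % 90 == 0:
        k = int(angle // 90)
        out_img = np.ascontiguousarray(np.rot90(img, k=-k))
        boxes = tuple(_rotate_box_90k(b, k, width, height) for b in anns.boxes)
        out_h, out_w = out_img.shape[:2]
        spec = ImageSpec(out_w, out_h, anns.image_spec.gsd_cm_per_px)
        return out_img, AnnotationSet(anns.image_id, spec, boxes)
    pil = Image.fromarray(img).rotate(
        angle, resample=Image.BILINEAR, expand=False, fillcolor=(0, 0, 0)
    )
    # PIL rotates counter-clockwise for positive angles; the box mapping
    # above is clockwise, so negate.
    boxes = tuple(
        rb
        for b in anns.boxes
        if (rb := _rotate_box_arbitrary(b, -angle, width, height)) is not None
    )
    return np.asarray(pil), replace(anns, boxes=boxes)


def _apply_random_crop(
    img: np.ndarray,
    anns: AnnotationSet,
    frac: float,
    rng: np.random.Generator,
    center: bool = False,
    min_visible_frac: float = 0.5,
) -> tuple[np.ndarray, AnnotationSet]:
    height, width = img.shape[:2]
    cw, ch = int(round(width * frac)), int(round(height * frac))
    if cw < 1 or ch < 1:
        raise ValueError(f"crop fraction {frac} yields an empty window")
    if center:
        x0, y0 = (width - cw) // 2, (height - ch) // 2
    else:
        x0 = int(rng.integers(0, width - cw + 1))
        y0 = int(rng.integers(0, height - ch + 1))
    crop = img[y0 : y0 + ch, x0 : x0 + cw]
    out_img = np.asarray(
        Image.fromarray(crop).resize((width, height), resample=Image.BILINEAR)
    )
    sx, sy = width / cw, height / ch
    boxes: list[BBox] = []
    for b in anns.boxes:
        clipped = b.clipped(x0, y0, x0 + cw, y0 + ch)
        if clipped is None or clipped.area / b.area < min_visible_frac:
            continue
        boxes.append(
            BBox(
                b.category,
                (clipped.cx - x0) * sx,
                (clipped.cy - y0) * sy,
                clipped.w * sx,
                clipped.h * sy,
            )
        )
    return out_img, replace(anns, boxes=tuple(boxes))


def _apply_shadow(
    img: np.ndarray, rng: np.random.Generator, opacity: float, extent: float
) -> np.ndarray:
    """Darken a seeded random convex quadrilateral by ``opacity``."""
    height, width = img.shape[:2]
    cx = rng.uniform(0.2, 0.8) * width
    cy = rng.uniform(0.2, 0.8) * height
    radius = extent * min(width, height) / 2.0
    angles = np.sort(rng.uniform(0.0, 2.0 * math.pi, size=4))
    pts = [
        (cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in angles
    ]
    mask = Image.new("L", (width, height), 0)
    ImageDraw.Draw(mask).polygon(pts, fill=255)
    mask_arr = np.asarray(mask, dtype=bool)
    out = img.astype(np.float64)
    out[mask_arr] *= 1.0 - opacity
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_one(
    img: np.ndarray, anns: AnnotationSet, spec: AugmentationSpec
) -> tuple[np.ndarray, AnnotationSet]:
    """Apply one augmentation to an image and its boxes.

    Photometric ops (BRIGHTNESS, SHADOW, CHROMA) return boxes unchanged;
    ROTATE refits axis-aligned hulls; RANDOM_CROP rescales boxes back to
    the original frame size.
    """
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    op = spec.op
    if op is AugmentationOp.BRIGHTNESS:
        gain = float(p.get("gain", rng.uniform(0.7, 1.3)))
        out = np.clip(np.rint(img.astype(np.float64) * gain), 0, 255).astype(np.uint8)
        return out, anns
    if op is AugmentationOp.CHROMA:
        gains = p.get("gains")
        if gains is None:
            gains = rng.uniform(0.8, 1.2, size=3)
        gains = np.asarray(gains, dtype=np.float64)
        out = np.clip(np.rint(img.astype(np.float64) * gains), 0, 255).astype(np.uint8)
        return out, anns
    if op is AugmentationOp.SHADOW:
        opacity = float(p.get("opacity", rng.uniform(0.3, 0.6)))
        extent = float(p.get("extent", rng.uniform(0.3, 0.7)))
        return _apply_shadow(img, rng, opacity, extent), anns
    if op is AugmentationOp.ROTATE:
        angle = p.get("angle_deg")
        if angle is None:
            angle = float(rng.choice([90.0, 180.0, 270.0]))
        return _apply_rotate(img, anns, float(angle))
    if op is AugmentationOp.RANDOM_CROP:
        frac = float(p.get("fraction", rng.uniform(0.5, 0.9)))
        return _apply_random_crop(
            img, anns, frac, rng, center=bool(p.get("center", False))
        )
    raise ValueError(f"unknown augmentation op {op!r}")


def augment_dataset(
    dataset: Sequence[tuple[np.ndarray, AnnotationSet]],
    target_count: int,
    seed: int,
    ops: Sequence[AugmentationOp] = tuple(AugmentationOp),
) -> tuple[list[tuple[np.ndarray, AnnotationSet]], list[dict]]:
    """Grow a dataset to ``target_count`` items by sampling ops uniformly
    with replacement over sources (e.g. 800 sources -> 4,200 items means
    3,400 derived copies).

    Returns (augmented dataset, manifest). Originals come first and are
    retained untouched; every manifest record carries the source id, op,
    parameters, and per-item seed.
    """
    if not dataset:
        raise ValueError("source dataset is empty")
    if target_count < len(dataset):
        raise ValueError(
            f"target_count {target_count} is below the source count {len(dataset)}"
        )
    rng = np.random.default_rng(seed)
    out = list(dataset)
    manifest = [
        {
            "derived_id": anns.image_id,
            "source_id": anns.image_id,
            "op": "ORIGINAL",
            "params_json": "{}",
            "seed": seed,
        }
        for _, anns in dataset
    ]
    ops = list(ops)
    for i in range(target_count - len(dataset)):
        src_idx = int(rng.integers(0, len(dataset)))
        op = ops[int(rng.integers(0, len(ops)))]
        item_seed = int(rng.integers(0, 2**31 - 1))
        src_img, src_anns = dataset[src_idx]
        spec = AugmentationSpec(op=op, seed=item_seed)
        aug_img, aug_anns = augment_one(src_img, src_anns, spec)
        derived_id = f"{src_anns.image_id}_aug{i:05d}"
        aug_anns = replace(aug_anns, image_id=derived_id)
        out.append((aug_img, aug_anns))
        manifest.append(
            {
                "derived_id": derived_id,
                "source_id": src_anns.image_id,
                "op": op.value,
                "params_json": spec.params_json(),
                "seed": item_seed,
            }
        )
    return out, manifest
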