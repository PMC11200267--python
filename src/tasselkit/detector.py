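"""Detection contract: a truth-conditioned mock detector with a
controllable error model, plus import/export of external detection files.

The mock does no computer vision. It samples misses, category confusion,
localization jitter, confidence noise, and false positives on top of the
ground-truth boxes of a block, with the miss rate growing with the radial
distance of an object from the UAV-frame center — a surrogate for the
perspective-distortion degradation observed on real imagery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotations import AnnotationSet, BBox, TasselCategory, YoloFormatError
from .geometry import Block, BlockingPlan, ImageSpec

__all__ = [
    "Detection",
    "MockDetectorParams",
    "detect",
    "import_detections",
    "export_detections",
    "screen",
]


@dataclass(frozen=True)
class Detection:
    """One detected object in block-local coordinates, optionally remapped."""

    category: TasselCategory
    box: BBox
    confidence: float
    block_id: int | None = None
    global_cx: float | None = None
    global_cy: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class MockDetectorParams:
    """Error model of the mock detector.

    ``miss_rate_center`` is the per-category miss probability for an object
    at the frame center; ``miss_slope_per_1000px`` adds to it linearly with
    radial distance (per 1,000 px). The confusion matrix rows must be
    stochastic; row c gives the emitted-category distribution for a true
    category c.
    """

    miss_rate_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    miss_slope_per_1000px: float = 0.0
    false_positives_per_block: float = 0.0
    jitter_sd_px: float = 0.0
    confusion: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )
    confidence_base: float = 1.0
    confidence_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in self.miss_rate_center:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"miss rate {r} outside [0, 1]")
        if self.miss_slope_per_1000px < 0:
            raise ValueError("miss slope must be >= 0")
        if self.false_positives_per_block < 0:
            raise ValueError("false-positive rate must be >= 0")
        if self.jitter_sd_px < 0:
            raise ValueError("jitter SD must be >= 0")
        mat = np.asarray(self.confusion, dtype=float)
        if mat.shape != (3, 3) or not np.allclose(mat.sum(axis=1), 1.0):
            raise ValueError("confusion matrix must be 3x3 row-stochastic")

    def miss_probability(self, category: TasselCategory, radial_dist_px: float) -> float:
        p = (
            self.miss_rate_center[int(category)]
            + self.miss_slope_per_1000px * radial_dist_px / 1000.0
        )
        return min(max(p, 0.0), 1.0)


def _block_rng(params: MockDetectorParams, block: Block | None) -> np.random.Generator:
    if block is None:
        return np.random.default_rng(params.seed)
    return np.random.default_rng([params.seed, block.x0, block.y0, block.side_px])


def detect(
    truth: AnnotationSet,
    params: MockDetectorParams,
    block: Block | None = None,
    frame: ImageSpec | None = None,
    block_id: int | None = None,
) -> list[Detection]:
    """Simulate detections over one block's ground truth.

    ``truth`` is block-local (e.g. from ``crop_annotations_to_block``).
    ``block``/``frame`` supply the geometry for the radial miss term; when
    omitted the radial distance is taken as 0. Deterministic given
    (params.seed, block).
    """
    rng = _block_rng(params, block)
    if frame is not None:
        fcx, fcy = frame.center
    out: list[Detection] = []
    side = truth.image_spec.width_px
    for b in truth.boxes:
        if frame is not None and block is not None:
            gx, gy = block.x0 + b.cx, block.y0 + b.cy
            radial = math.hypot(gx - fcx, gy - fcy)
        else:
            radial = 0.0
        if rng.random() < params.miss_probability(b.category, radial):
            continue
        emitted = TasselCategory(
            int(rng.choice(3, p=np.asarray(params.confusion[int(b.category)])))
        )
        if params.jitter_sd_px > 0:
            dx, dy = rng.normal(0.0, params.jitter_sd_px, size=2)
        else:
            dx = dy = 0.0
        cx = min(max(b.cx + dx, 0.0), float(truth.image_spec.width_px))
        cy = min(max(b.cy + dy, 0.0), float(truth.image_spec.height_px))
        conf = params.confidence_base
        if params.confidence_noise_sd > 0:
            conf += rng.normal(0.0, params.confidence_noise_sd)
        conf = min(max(conf, 0.0), 1.0)
        out.append(
            Detection(
                category=emitted,
                box=BBox(emitted, cx, cy, b.w, b.h),
                confidence=conf,
                block_id=block_id,
            )
        )
    if params.false_positives_per_block > 0:
        n_fp = int(rng.poisson(params.false_positives_per_block))
        for _ in range(n_fp):
            cat = TasselCategory(int(rng.integers(0, 3)))
            cx = float(rng.uniform(0, truth.image_spec.width_px))
            cy = float(rng.uniform(0, truth.image_spec.height_px))
            w = h = 140.0
            conf = min(max(float(rng.uniform(0.0, params.confidence_base)), 0.0), 1.0)
            out.append(
                Detection(
                    category=cat,
                    box=BBox(cat, cx, cy, w, h),
                    confidence=conf,
                    block_id=block_id,
                )
            )
    return out


def export_detections(dets: Sequence[Detection], block_side: int) -> str:
    """6-column normalized detection TXT: ``class cx cy w h conf``."""
    lines = [
        f"{int(d.category)} "
        f"{d.box.cx / block_side:.6f} {d.box.cy / block_side:.6f} "
        f"{d.box.w / block_side:.6f} {d.box.h / block_side:.6f} "
        f"{d.confidence:.6f}"
        for d in dets
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def import_detections(
    text: str, block: Block, block_id: int | None = None, source: str = "<string>"
) -> list[Detection]:
    """Parse a per-block detection file (normalized to the block side)."""
    side = block.side_px
    out: list[Detection] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 6:
            raise YoloFormatError(
                f"{source}:{lineno}: expected 6 fields 'class cx cy w h conf', "
                f"got {len(parts)}"
            )
        try:
            cls = int(parts[0])
            cx, cy, w, h, conf = (float(v) for v in parts[1:])
        except ValueError as exc:
            raise YoloFormatError(f"{source}:{lineno}: non-numeric field ({exc})") from exc
        if cls not in (0, 1, 2):
            raise YoloFormatError(f"{source}:{lineno}: class code {cls} outside {{0, 1, 2}}")
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h), ("conf", conf)):
            if not 0.0 <= v <= 1.0:
                raise YoloFormatError(f"{source}:{lineno}: {name}={v} outside [0, 1]")
        cat = TasselCategory(cls)
        out.append(
            Detection(
                category=cat,
                box=BBox(cat, cx * side, cy * side, w * side, h * side),
                confidence=conf,
                block_id=block_id,
            )
        )
    return out


def import_plan_detections(
    texts: Sequence[str], plan: BlockingPlan
) -> dict[int, list[Detection]]:
    """Per-block detection files for a whole plan, keyed by block index."""
    if len(texts) != len(plan.blocks):
        raise ValueError(
            f"got {len(texts)} detection files for a plan of {len(plan.blocks)} blocks"
        )
    return {
        i: import_detections(t, b, block_id=i, source=f"block[{i}]")
        for i, (t, b) in enumerate(zip(texts, plan.blocks))
    }


def screen(dets: Sequence[Detection], confidence_threshold: float = 0.3) -> list[Detection]:
    """Keep detections with confidence >= threshold, order preserved."""
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {confidence_threshold}")
    return [d for d in dets if d.confidence >= confidence_threshold]
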