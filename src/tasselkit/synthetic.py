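"""Synthetic maize-canopy scenes with ground truth, and raster-free
annotation fixtures.

Scenes place plants on a jittered grid (25 cm plant / 60 cm row spacing by
default, i.e. 100 px / 240 px at 0.25 cm/px GSD), assign each plant a
tassel category from a stage-dependent mixture, and render a schematic
glyph per category:

* Tassel-N — dark whorl disc (tassel removed/absent),
* Tassel-S — compact bright blob (formed, not emerged),
* Tassel-L — branched star with a 0.75 length-width ratio template.

Truth boxes are fixed squares for N/S (default 140 px) and glyph-hugging
boxes for L. A perspective-distortion surrogate elongates L glyphs and
boxes proportionally to the distance from the frame center. Rendering is
deliberately schematic: the downstream detector contract is
truth-conditioned, so the acceptance surface is geometry and counting.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .annotations import AnnotationSet, BBox, TasselCategory
from .geometry import ImageSpec

__all__ = [
    "GrowthStage",
    "SceneConfig",
    "PlantRecord",
    "SceneTruth",
    "generate_scene",
    "generate_annotation_fixture",
    "STAGE_MIXTURES",
]


class GrowthStage(str, enum.Enum):
    SPIKELET = "spikelet"
    TASSELING = "tasseling"
    DETASSELED = "detasseled"


#: (N, S, L) mixtures. S dominates at spikelet with sporadic L; L dominates
#: at tasseling; after detasseling, female rows are mostly N while male rows
#: stay S/L (see DETASSELED_MALE_MIXTURE).
STAGE_MIXTURES: dict[GrowthStage, tuple[float, float, float]] = {
    GrowthStage.SPIKELET: (0.0, 0.9, 0.1),
    GrowthStage.TASSELING: (0.0, 0.25, 0.75),
    GrowthStage.DETASSELED: (0.9, 0.08, 0.02),
}

DETASSELED_MALE_MIXTURE: tuple[float, float, float] = (0.0, 0.5, 0.5)

# glyph templates in px at 0.25 cm/px; L's 90x120 gives the 0.75 ratio
GLYPH_N_RADIUS = 28.0
GLYPH_S_RADIUS = 22.0
GLYPH_L_W = 90.0
GLYPH_L_H = 120.0


@dataclass(frozen=True)
class SceneConfig:
    image: ImageSpec = ImageSpec(2048, 2048, 0.25)
    plant_spacing_cm: float = 25.0
    row_spacing_cm: float = 60.0
    stage: GrowthStage = GrowthStage.SPIKELET
    mixture: tuple[float, float, float] | None = None
    female_rows_per_male: int = 4
    occlusion_prob: float = 0.0
    position_jitter_px: float = 12.0
    elongation_coeff: float = 0.0
    square_box_side_px: int = 140
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plant_spacing_cm <= 0 or self.row_spacing_cm <= 0:
            raise ValueError("spacings must be positive")
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must be in [0, 1]")
        if self.elongation_coeff < 0:
            raise ValueError("elongation_coeff must be >= 0")
        if self.mixture is not None:
            m = np.asarray(self.mixture, dtype=float)
            if m.shape != (3,) or (m < 0).any() or not math.isclose(float(m.sum()), 1.0):
                raise ValueError(f"mixture must be a probability 3-vector, got {self.mixture}")
        gsd = self.image.gsd_cm_per_px
        plant_px = self.plant_spacing_cm / gsd
        row_px = self.row_spacing_cm / gsd
        if plant_px < GLYPH_L_W or row_px < GLYPH_L_H:
            raise ValueError(
                f"spacing ({plant_px:.0f} x {row_px:.0f} px) is smaller than the "
                f"largest glyph ({GLYPH_L_W:.0f} x {GLYPH_L_H:.0f} px)"
            )

    @property
    def plant_spacing_px(self) -> float:
        return self.plant_spacing_cm / self.image.gsd_cm_per_px

    @property
    def row_spacing_px(self) -> float:
        return self.row_spacing_cm / self.image.gsd_cm_per_px


@dataclass(frozen=True)
class PlantRecord:
    row: int
    position: int
    sex: str  # "F" or "M"
    category: TasselCategory
    cx: float
    cy: float
    occluded: bool


@dataclass(frozen=True)
class SceneTruth:
    annotations: AnnotationSet
    totals: dict[TasselCategory, int]
    plants: tuple[PlantRecord, ...]

    def __post_init__(self) -> None:
        counts = self.annotations.category_counts()
        if counts != self.totals:
            raise ValueError(f"totals {self.totals} disagree with boxes {counts}")


def _stage_mixture(cfg: SceneConfig, sex: str) -> tuple[float, float, float]:
    if cfg.mixture is not None:
        return cfg.mixture
    if cfg.stage is GrowthStage.DETASSELED and sex == "M":
        return DETASSELED_MALE_MIXTURE
    return STAGE_MIXTURES[cfg.stage]


def _elongation(cfg: SceneConfig, cx: float, cy: float) -> tuple[float, float]:
    """Per-axis stretch factors growing with distance from the frame center."""
    fcx, fcy = cfg.image.center
    ex = 1.0 + cfg.elongation_coeff * abs(cx - fcx) / 1000.0
    ey = 1.0 + cfg.elongation_coeff * abs(cy - fcy) / 1000.0
    return ex, ey


def _draw_plant(
    draw: ImageDraw.ImageDraw,
    cat: TasselCategory,
    cx: float,
    cy: float,
    ex: float,
    ey: float,
    rng: np.random.Generator,
) -> None:
    if cat is TasselCategory.TASSEL_N:
        r_x, r_y = GLYPH_N_RADIUS * ex, GLYPH_N_RADIUS * ey
        draw.ellipse(
            (cx - r_x, cy - r_y, cx + r_x, cy + r_y), fill=(35, 52, 28)
        )
        draw.ellipse(
            (cx - r_x / 2, cy - r_y / 2, cx + r_x / 2, cy + r_y / 2),
            fill=(22, 33, 18),
        )
    elif cat is TasselCategory.TASSEL_S:
        r_x, r_y = GLYPH_S_RADIUS * ex, GLYPH_S_RADIUS * ey
        draw.ellipse(
            (cx - r_x, cy - r_y, cx + r_x, cy + r_y), fill=(196, 205, 120)
        )
        draw.ellipse(
            (cx - r_x / 2, cy - r_y / 2, cx + r_x / 2, cy + r_y / 2),
            fill=(226, 230, 150),
        )
    else:  # TASSEL_L: branched star inside a GLYPH_L_W x GLYPH_L_H envelope
        hw, hh = GLYPH_L_W * ex / 2.0, GLYPH_L_H * ey / 2.0
        n_branches = 7
        for k in range(n_branches):
            ang = -math.pi / 2 + (k - n_branches // 2) * (math.pi / (n_branches + 1))
            length = 0.6 + 0.4 * float(rng.random())
            tip_x = cx + hw * length * math.sin(ang) * 1.6
            tip_y = cy - hh * length * max(math.cos(ang), 0.25)
            draw.line(
                (cx, cy + hh * 0.4, min(max(tip_x, cx - hw), cx + hw), tip_y),
                fill=(214, 186, 112),
                width=4,
            )
        draw.line((cx, cy - hh, cx, cy + hh), fill=(222, 196, 120), width=5)


def generate_scene(cfg: SceneConfig) -> tuple[np.ndarray, SceneTruth]:
    """Render one synthetic canopy frame and its ground truth.

    Deterministic given ``cfg.seed``: identical configs produce
    byte-identical rasters and labels.
    """
    rng = np.random.default_rng(cfg.seed)
    img = cfg.image
    width, height = img.width_px, img.height_px

    # mottled canopy background
    base = rng.normal(loc=0.0, scale=6.0, size=(height, width, 1))
    canvas = np.clip(
        np.array([62, 92, 48], dtype=np.float64) + base, 0, 255
    ).astype(np.uint8)
    pil = Image.fromarray(canvas)
    draw = ImageDraw.Draw(pil)

    plant_px = cfg.plant_spacing_px
    row_px = cfg.row_spacing_px
    margin_x = GLYPH_L_W
    margin_y = GLYPH_L_H
    n_rows = int((height - 2 * margin_y) // row_px) + 1
    n_cols = int((width - 2 * margin_x) // plant_px) + 1
    oy = (height - (n_rows - 1) * row_px) / 2.0
    ox = (width - (n_cols - 1) * plant_px) / 2.0

    plants: list[PlantRecord] = []
    boxes: list[BBox] = []
    cycle = cfg.female_rows_per_male + 1
    for r in range(n_rows):
        sex = "M" if (r % cycle) == cfg.female_rows_per_male else "F"
        mixture = np.asarray(_stage_mixture(cfg, sex), dtype=float)
        for c in range(n_cols):
            jx, jy = rng.uniform(-cfg.position_jitter_px, cfg.position_jitter_px, size=2)
            cx = float(np.clip(ox + c * plant_px + jx, margin_x, width - margin_x))
            cy = float(np.clip(oy + r * row_px + jy, margin_y, height - margin_y))
            cat = TasselCategory(int(rng.choice(3, p=mixture)))
            occluded = bool(rng.random() < cfg.occlusion_prob)
            plants.append(PlantRecord(r, c, sex, cat, cx, cy, occluded))
            ex, ey = _elongation(cfg, cx, cy)
            if occluded:
                # leaf patch covering the plant center; no truth box
                draw.ellipse(
                    (cx - 50, cy - 35, cx + 50, cy + 35), fill=(74, 110, 56)
                )
                continue
            _draw_plant(draw, cat, cx, cy, ex, ey, rng)
            if cat is TasselCategory.TASSEL_L:
                box = BBox(cat, cx, cy, GLYPH_L_W * ex, GLYPH_L_H * ey)
            else:
                side = float(cfg.square_box_side_px)
                box = BBox(cat, cx, cy, side, side)
            clipped = box.clipped(0.0, 0.0, float(width), float(height))
            if clipped is not None:
                boxes.append(clipped)

    anns = AnnotationSet(
        image_id=f"scene_{cfg.stage.value}_{cfg.seed}",
        image_spec=img,
        boxes=tuple(boxes),
    )
    truth = SceneTruth(
        annotations=anns,
        totals=anns.category_counts(),
        plants=tuple(plants),
    )
    return np.asarray(pil), truth


def scene_manifest(cfg: SceneConfig, truth: SceneTruth) -> str:
    """JSON manifest with config, seed, and per-category totals."""
    return json.dumps(
        {
            "image": {
                "width_px": cfg.image.width_px,
                "height_px": cfg.image.height_px,
                "gsd_cm_per_px": cfg.image.gsd_cm_per_px,
            },
            "stage": cfg.stage.value,
            "plant_spacing_cm": cfg.plant_spacing_cm,
            "row_spacing_cm": cfg.row_spacing_cm,
            "occlusion_prob": cfg.occlusion_prob,
            "elongation_coeff": cfg.elongation_coeff,
            "seed": cfg.seed,
            "totals": {c.short_name: truth.totals[c] for c in TasselCategory},
        },
        indent=2,
    )


def generate_annotation_fixture(
    n_images: int,
    boxes_per_image: int | tuple[int, int],
    category_mixture: tuple[float, float, float] = (0.4093, 0.3524, 0.2383),
    mean_area_px2: float = 5784.0,
    sd_area_px2: float = 0.0,
    image: ImageSpec = ImageSpec(1024, 1024, 0.25),
    l_aspect: float = 0.75,
    seed: int = 0,
) -> list[AnnotationSet]:
    """Raster-free annotation datasets for statistics and metric tests.

    Box areas are normal(mean, sd) resampled to positivity; N/S boxes are
    squares, L boxes use the ``l_aspect`` length-width ratio at the same
    area. Centers are placed so no box needs clipping. The default mixture
    and mean area mirror a manually annotated maize-tassel corpus.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    mix = np.asarray(category_mixture, dtype=float)
    if mix.shape != (3,) or (mix < 0).any() or not math.isclose(float(mix.sum()), 1.0):
        raise ValueError(f"category_mixture must be a probability 3-vector, got {category_mixture}")
    if mean_area_px2 <= 0 or sd_area_px2 < 0:
        raise ValueError("area distribution must have positive mean and SD >= 0")
    rng = np.random.default_rng(seed)
    out: list[AnnotationSet] = []
    for i in range(n_images):
        if isinstance(boxes_per_image, tuple):
            n_boxes = int(rng.integers(boxes_per_image[0], boxes_per_image[1] + 1))
        else:
            n_boxes = int(boxes_per_image)
        boxes: list[BBox] = []
        for _ in range(n_boxes):
            cat = TasselCategory(int(rng.choice(3, p=mix)))
            area = mean_area_px2
            if sd_area_px2 > 0:
                area = float(rng.normal(mean_area_px2, sd_area_px2))
                while area <= 0:
                    area = float(rng.normal(mean_area_px2, sd_area_px2))
            if cat is TasselCategory.TASSEL_L:
                # w*h = area with h/w = l_aspect (w the long side)
                w = math.sqrt(area / l_aspect)
                h = area / w
            else:
                w = h = math.sqrt(area)
            cx = float(rng.uniform(w / 2, image.width_px - w / 2))
            cy = float(rng.uniform(h / 2, image.height_px - h / 2))
            boxes.append(BBox(cat, cx, cy, w, h))
        out.append(
            AnnotationSet(image_id=f"fixture_{i:04d}", image_spec=image, boxes=tuple(boxes))
        )
    return out
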