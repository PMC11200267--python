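"""Blocking geometry for large UAV frames.

Center-anchored block patterns (2x2 and 3x3 overlapping, full
non-overlapping grid), generic sliding windows, and ground-footprint
arithmetic derived from the ground sampling distance (GSD).

Conventions: 0-based pixel coordinates, x rightward, y downward; a block
occupies the half-open extent ``[x0, x0+side) x [y0, y0+side)``. When a
centered arrangement cannot be placed symmetrically (odd parity) it is
shifted left/up by one pixel.
"""

from __future__ import annotations

import csv
import enum
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ImageSpec",
    "Block",
    "BlockingPattern",
    "BlockingPlan",
    "plan_pattern1",
    "plan_pattern2",
    "plan_pattern3",
    "plan_sliding",
    "footprint_m2",
    "block_area_fraction",
]


@dataclass(frozen=True)
class ImageSpec:
    """Pixel dimensions plus ground sampling distance of a frame."""

    width_px: int
    height_px: int
    gsd_cm_per_px: float = 0.25

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError(
                f"image dimensions must be >= 1, got "
                f"{self.width_px} x {self.height_px}"
            )
        if not self.gsd_cm_per_px > 0:
            raise ValueError(f"gsd_cm_per_px must be > 0, got {self.gsd_cm_per_px}")

    @property
    def center(self) -> tuple[float, float]:
        return self.width_px / 2.0, self.height_px / 2.0


@dataclass(frozen=True)
class Block:
    """One square crop window, fully inside its parent image."""

    x0: int
    y0: int
    side_px: int
    row_index: int = 0
    col_index: int = 0

    def __post_init__(self) -> None:
        if self.side_px <= 0:
            raise ValueError(f"side_px must be > 0, got {self.side_px}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"block origin must be non-negative, got ({self.x0}, {self.y0})")

    @property
    def x1(self) -> int:
        """Exclusive right edge."""
        return self.x0 + self.side_px

    @property
    def y1(self) -> int:
        """Exclusive bottom edge."""
        return self.y0 + self.side_px

    @property
    def center(self) -> tuple[float, float]:
        return self.x0 + self.side_px / 2.0, self.y0 + self.side_px / 2.0

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


class BlockingPattern(str, enum.Enum):
    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    SLIDING = "SLIDING"


@dataclass(frozen=True)
class BlockingPlan:
    """An ordered decomposition of a frame into square blocks."""

    pattern: BlockingPattern
    image: ImageSpec
    block_side_px: int
    overlap_px: int
    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        for b in self.blocks:
            if b.x1 > self.image.width_px or b.y1 > self.image.height_px:
                raise ValueError(
                    f"block at ({b.x0}, {b.y0}) side {b.side_px} exceeds "
                    f"{self.image.width_px} x {self.image.height_px} image"
                )

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    @property
    def union_bounds(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) bounding box of the union of blocks (x1/y1 exclusive)."""
        if not self.blocks:
            raise ValueError("empty plan has no union")
        x0 = min(b.x0 for b in self.blocks)
        y0 = min(b.y0 for b in self.blocks)
        x1 = max(b.x1 for b in self.blocks)
        y1 = max(b.y1 for b in self.blocks)
        return x0, y0, x1, y1

    @property
    def union_side_px(self) -> int:
        """Side of the union bounding square (patterns 1/2 unions are square)."""
        x0, y0, x1, y1 = self.union_bounds
        return max(x1 - x0, y1 - y0)

    def union_area_px2(self) -> int:
        """Exact pixel area of the union of blocks (sweep over unique rows)."""
        if not self.blocks:
            return 0
        ys = sorted({v for b in self.blocks for v in (b.y0, b.y1)})
        total = 0
        for ya, yb in zip(ys[:-1], ys[1:]):
            spans = sorted(
                (b.x0, b.x1) for b in self.blocks if b.y0 <= ya and b.y1 >= yb
            )
            covered = 0
            cur_lo: int | None = None
            cur_hi = 0
            for lo, hi in spans:
                if cur_lo is None:
                    cur_lo, cur_hi = lo, hi
                elif lo <= cur_hi:
                    cur_hi = max(cur_hi, hi)
                else:
                    covered += cur_hi - cur_lo
                    cur_lo, cur_hi = lo, hi
            if cur_lo is not None:
                covered += cur_hi - cur_lo
            total += covered * (yb - ya)
        return total

    def to_records(self) -> list[dict]:
        return [
            {
                "block_id": i,
                "row": b.row_index,
                "col": b.col_index,
                "x0": b.x0,
                "y0": b.y0,
                "side": b.side_px,
            }
            for i, b in enumerate(self.blocks)
        ]

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.DictWriter(
            buf, fieldnames=["block_id", "row", "col", "x0", "y0", "side"]
        )
        writer.writeheader()
        writer.writerows(self.to_records())
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {
                "pattern": self.pattern.value,
                "image": {
                    "width_px": self.image.width_px,
                    "height_px": self.image.height_px,
                    "gsd_cm_per_px": self.image.gsd_cm_per_px,
                },
                "block_side_px": self.block_side_px,
                "overlap_px": self.overlap_px,
                "blocks": self.to_records(),
            },
            indent=2,
        )


def _centered_origin(image_extent: int, union_extent: int) -> int:
    # Odd parity shifts the union left/up by one pixel.
    return (image_extent - union_extent) // 2


def _centered_grid(
    img: ImageSpec,
    k: int,
    block_side: int,
    overlap: int,
    pattern: BlockingPattern,
) -> BlockingPlan:
    if not 0 <= overlap < block_side:
        raise ValueError(
            f"overlap must satisfy 0 <= overlap < block_side, got "
            f"overlap={overlap}, block_side={block_side}"
        )
    union = k * block_side - (k - 1) * overlap
    limit = min(img.width_px, img.height_px)
    if union > limit:
        raise ValueError(
            f"{k}x{k} arrangement needs a {union} px square but the image "
            f"offers only {limit} px on its short side"
        )
    ox = _centered_origin(img.width_px, union)
    oy = _centered_origin(img.height_px, union)
    stride = block_side - overlap
    blocks = tuple(
        Block(ox + c * stride, oy + r * stride, block_side, row_index=r, col_index=c)
        for r in range(k)
        for c in range(k)
    )
    return BlockingPlan(pattern, img, block_side, overlap, blocks)


def plan_pattern1(
    img: ImageSpec, block_side: int = 1024, overlap: int = 200
) -> BlockingPlan:
    """2x2 overlapping blocks centered on the image center.

    The union is a square of side ``2*block_side - overlap``; adjacent
    blocks overlap by exactly ``overlap`` pixels.
    """
    return _centered_grid(img, 2, block_side, overlap, BlockingPattern.P1)


def plan_pattern2(
    img: ImageSpec, block_side: int = 1024, overlap: int = 200
) -> BlockingPlan:
    """3x3 overlapping blocks centered on the image center.

    The union is a square of side ``3*block_side - 2*overlap``; the middle
    block is centered on the image center (up to odd-parity shift).
    """
    return _centered_grid(img, 3, block_side, overlap, BlockingPattern.P2)


def plan_pattern3(
    img: ImageSpec, block_side: int = 1024, anchor: str = "center"
) -> BlockingPlan:
    """Complete non-overlapping grid: floor(W/b) x floor(H/b) blocks.

    With ``anchor="center"`` (default) leftover margins are split evenly,
    the extra pixel going to the right/bottom; ``anchor="topleft"`` pins
    the grid to the image origin.
    """
    if block_side > min(img.width_px, img.height_px):
        raise ValueError(
            f"block_side {block_side} exceeds the image short side "
            f"{min(img.width_px, img.height_px)}"
        )
    if anchor not in ("center", "topleft"):
        raise ValueError(f"anchor must be 'center' or 'topleft', got {anchor!r}")
    cols = img.width_px // block_side
    rows = img.height_px // block_side
    if anchor == "center":
        ox = (img.width_px - cols * block_side) // 2
        oy = (img.height_px - rows * block_side) // 2
    else:
        ox = oy = 0
    blocks = tuple(
        Block(
            ox + c * block_side,
            oy + r * block_side,
            block_side,
            row_index=r,
            col_index=c,
        )
        for r in range(rows)
        for c in range(cols)
    )
    return BlockingPlan(BlockingPattern.P3, img, block_side, 0, blocks)


def plan_sliding(img: ImageSpec, block_side: int, overlap: int) -> BlockingPlan:
    """Row-major sliding windows with stride ``block_side - overlap``.

    The last row/column snaps inward so every block is in-bounds; every
    image pixel is covered.
    """
    if not 0 <= overlap < block_side:
        raise ValueError(
            f"overlap must satisfy 0 <= overlap < block_side, got "
            f"overlap={overlap}, block_side={block_side}"
        )
    if block_side > min(img.width_px, img.height_px):
        raise ValueError(
            f"block_side {block_side} exceeds the image short side "
            f"{min(img.width_px, img.height_px)}"
        )
    stride = block_side - overlap

    def starts(extent: int) -> list[int]:
        out = list(range(0, extent - block_side + 1, stride))
        if out[-1] != extent - block_side:
            out.append(extent - block_side)
        return out

    xs = starts(img.width_px)
    ys = starts(img.height_px)
    blocks = tuple(
        Block(x, y, block_side, row_index=r, col_index=c)
        for r, y in enumerate(ys)
        for c, x in enumerate(xs)
    )
    return BlockingPlan(BlockingPattern.SLIDING, img, block_side, overlap, blocks)


def footprint_m2(img: ImageSpec) -> float:
    """Ground area of a frame in square meters at its GSD."""
    return (img.width_px * img.gsd_cm_per_px / 100.0) * (
        img.height_px * img.gsd_cm_per_px / 100.0
    )


def block_area_fraction(plan: BlockingPlan) -> float:
    """Fraction of the image area covered by the union of the plan's blocks."""
    return plan.union_area_px2() / (plan.image.width_px * plan.image.height_px)
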