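"""Remapping block-local detections to frame coordinates and merging the
redundant objects produced by overlapping blocks.

Merging is category-wise single-linkage clustering on center distance at a
fixed radius (default 50 px): detections of one category whose centers are
chained within the radius collapse to one fused object at the
confidence-weighted mean center. A one-pass greedy variant is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .annotations import TasselCategory
from .detector import Detection
from .geometry import Block, BlockingPlan

__all__ = ["FusedObject", "to_global", "merge_redundant", "fuse_plan"]

DEFAULT_MERGE_RADIUS_PX = 50.0


@dataclass(frozen=True)
class FusedObject:
    category: TasselCategory
    global_cx: float
    global_cy: float
    confidence: float
    member_count: int
    member_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.member_count < 1:
            raise ValueError("a fused object needs at least one member")


def to_global(det: Detection, block: Block) -> Detection:
    """Attach frame coordinates: global center = local center + block origin."""
    if block is None:
        raise ValueError("detection has no block to remap from")
    return replace(
        det,
        global_cx=det.box.cx + block.x0,
        global_cy=det.box.cy + block.y0,
    )


def _single_linkage_clusters(pts: np.ndarray, radius: float) -> list[list[int]]:
    """Connected components of the 'within radius' graph (union-find)."""
    n = len(pts)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(pts)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _greedy_clusters(pts: np.ndarray, radius: float) -> list[list[int]]:
    """One-pass greedy: each point joins the first seed within radius."""
    seeds: list[int] = []
    clusters: list[list[int]] = []
    for i in range(len(pts)):
        for ci, s in enumerate(seeds):
            if float(np.hypot(*(pts[i] - pts[s]))) <= radius:
                clusters[ci].append(i)
                break
        else:
            seeds.append(i)
            clusters.append([i])
    return clusters


def merge_redundant(
    dets: Sequence[Detection],
    radius_px: float = DEFAULT_MERGE_RADIUS_PX,
    method: str = "single_linkage",
) -> list[FusedObject]:
    """Cluster same-category detections whose centers lie within
    ``radius_px`` and emit one fused object per cluster.

    Requires global coordinates. The fused center is the
    confidence-weighted mean; the representative confidence is the cluster
    max. Output is deterministic regardless of input order: detections are
    canonically ordered by (confidence desc, x, y) before clustering.
    """
    if radius_px < 0:
        raise ValueError(f"radius must be >= 0, got {radius_px}")
    if method not in ("single_linkage", "greedy"):
        raise ValueError(f"method must be 'single_linkage' or 'greedy', got {method!r}")
    for d in dets:
        if d.global_cx is None or d.global_cy is None:
            raise ValueError("all detections must be in global coordinates; run to_global")

    fused: list[FusedObject] = []
    indexed = list(enumerate(dets))
    for cat in TasselCategory:
        members = [
            (i, d) for i, d in indexed if d.category == cat
        ]
        if not members:
            continue
        members.sort(key=lambda t: (-t[1].confidence, t[1].global_cx, t[1].global_cy, t[0]))
        pts = np.array([[d.global_cx, d.global_cy] for _, d in members], dtype=float)
        cluster_fn = _single_linkage_clusters if method == "single_linkage" else _greedy_clusters
        for idxs in cluster_fn(pts, radius_px):
            group = sorted(idxs)
            confs = np.array([members[i][1].confidence for i in group])
            weights = confs if confs.sum() > 0 else np.ones_like(confs)
            centers = pts[group]
            cx, cy = np.average(centers, axis=0, weights=weights)
            fused.append(
                FusedObject(
                    category=cat,
                    global_cx=float(cx),
                    global_cy=float(cy),
                    confidence=float(confs.max()),
                    member_count=len(group),
                    member_ids=tuple(members[i][0] for i in group),
                )
            )
    fused.sort(key=lambda f: (int(f.category), f.global_cx, f.global_cy))
    return fused


def fuse_plan(
    dets_by_block: Mapping[int, Sequence[Detection]],
    plan: BlockingPlan,
    radius_px: float = DEFAULT_MERGE_RADIUS_PX,
    method: str = "single_linkage",
) -> tuple[dict[TasselCategory, int], list[FusedObject]]:
    """Remap every block's detections to frame coordinates, merge
    redundancies, and return per-category fused counts plus the objects."""
    global_dets: list[Detection] = []
    for block_idx, block_dets in sorted(dets_by_block.items()):
        if block_idx < 0 or block_idx >= len(plan.blocks):
            raise ValueError(f"block index {block_idx} outside plan of {len(plan.blocks)}")
        block = plan.blocks[block_idx]
        global_dets.extend(to_global(d, block) for d in block_dets)
    fused = merge_redundant(global_dets, radius_px=radius_px, method=method)
    counts = {c: 0 for c in TasselCategory}
    for f in fused:
        counts[f.category] += 1
    return counts, fused
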