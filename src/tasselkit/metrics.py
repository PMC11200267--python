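"""Detection and counting metrics.

Box-level: IoU, greedy confidence-ordered matching at an IoU threshold,
precision/recall/accuracy, average precision (all-points interpolation),
and mAP over categories.

Count-level, over per-image per-category predicted vs ground-truth counts:

    ED    mean over images of sqrt(sum_c (P_c - G_c)^2)
    ACC   mean over images of sum(P) / sum(G)
    RMSE  sqrt(mean over images of (sum(G) - sum(P))^2)
    MAE   mean |sum(G) - sum(P)|
    MPAE  mean |sum(G) - sum(P)| / sum(G)
    MDR   mean (sum(P) - sum(G)) / sum(G)

ACC - 1 == MDR holds algebraically for any input; MPAE == |MDR| whenever
every image's deviation shares one sign. Images with zero ground truth
are excluded from the ratio metrics (the exclusion count is reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotations import AnnotationSet, BBox, TasselCategory
from .detector import Detection

__all__ = [
    "MatchResult",
    "CountSummary",
    "PRCurve",
    "iou",
    "match",
    "precision_recall_accuracy",
    "average_precision",
    "pr_curve",
    "map_at_50",
    "count_metrics",
    "CountMetrics",
]


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two axis-aligned boxes, in [0, 1]."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN bookkeeping from matching detections against ground truth."""

    tp: dict[TasselCategory, int]
    fp: dict[TasselCategory, int]
    fn: dict[TasselCategory, int]
    #: per category, detection (confidence, is_tp) sorted confidence-descending
    labeled: dict[TasselCategory, list[tuple[float, bool]]]
    #: matched (detection_index, truth_index, iou) triples
    pairs: list[tuple[int, int, float]]

    @property
    def tp_total(self) -> int:
        return sum(self.tp.values())

    @property
    def fp_total(self) -> int:
        return sum(self.fp.values())

    @property
    def fn_total(self) -> int:
        return sum(self.fn.values())


def match(
    dets: Sequence[Detection],
    truth: Sequence[BBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy category-strict one-to-one matching, confidence-descending.

    Each detection claims the unmatched same-category truth box with the
    highest IoU >= threshold; leftover detections are FP, leftover truths
    FN. Both inputs must share one coordinate frame.
    """
    tp = {c: 0 for c in TasselCategory}
    fp = {c: 0 for c in TasselCategory}
    fn = {c: 0 for c in TasselCategory}
    labeled: dict[TasselCategory, list[tuple[float, bool]]] = {c: [] for c in TasselCategory}
    pairs: list[tuple[int, int, float]] = []
    truth_used = [False] * len(truth)

    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    for di in order:
        d = dets[di]
        best_iou, best_ti = 0.0, -1
        for ti, t in enumerate(truth):
            if truth_used[ti] or t.category != d.category:
                continue
            v = iou(d.box, t)
            if v > best_iou:
                best_iou, best_ti = v, ti
        if best_ti >= 0 and best_iou >= iou_threshold:
            truth_used[best_ti] = True
            tp[d.category] += 1
            labeled[d.category].append((d.confidence, True))
            pairs.append((di, best_ti, best_iou))
        else:
            fp[d.category] += 1
            labeled[d.category].append((d.confidence, False))
    for ti, t in enumerate(truth):
        if not truth_used[ti]:
            fn[t.category] += 1
    return MatchResult(tp=tp, fp=fp, fn=fn, labeled=labeled, pairs=pairs)


def precision_recall_accuracy(m: MatchResult) -> tuple[float, float, float]:
    """(P, R, Acc) pooled over categories; TN is fixed at 0 for open-world
    detection so Acc = TP/(TP+FP+FN). 0/0 cases return 0."""
    tp, fp, fn = m.tp_total, m.fp_total, m.fn_total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return precision, recall, accuracy


def average_precision(
    labeled: Sequence[tuple[float, bool]], truth_count: int
) -> float:
    """All-points interpolated AP: area under the precision envelope over
    recall, sweeping the confidence threshold across every detection."""
    if truth_count <= 0:
        raise ValueError("AP is undefined with zero ground-truth boxes")
    if not labeled:
        return 0.0
    order = sorted(labeled, key=lambda t: -t[0])
    tps = np.cumsum([1 if is_tp else 0 for _, is_tp in order])
    fps = np.cumsum([0 if is_tp else 1 for _, is_tp in order])
    recall = tps / truth_count
    precision = tps / (tps + fps)
    # precision envelope: running max from the right
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, envelope):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def average_precision_11pt(
    labeled: Sequence[tuple[float, bool]], truth_count: int
) -> float:
    """11-point interpolated AP variant (recall levels 0, 0.1, ..., 1)."""
    if truth_count <= 0:
        raise ValueError("AP is undefined with zero ground-truth boxes")
    if not labeled:
        return 0.0
    order = sorted(labeled, key=lambda t: -t[0])
    tps = np.cumsum([1 if is_tp else 0 for _, is_tp in order])
    fps = np.cumsum([0 if is_tp else 1 for _, is_tp in order])
    recall = tps / truth_count
    precision = tps / (tps + fps)
    total = 0.0
    for level in np.linspace(0.0, 1.0, 11):
        mask = recall >= level
        total += float(precision[mask].max()) if mask.any() else 0.0
    return total / 11.0


@dataclass(frozen=True)
class PRCurve:
    """Per-category PR points and APs, plus the category-mean mAP."""

    recall: dict[TasselCategory, np.ndarray]
    precision: dict[TasselCategory, np.ndarray]
    ap: dict[TasselCategory, float]
    map50: float


def pr_curve(m: MatchResult, truth_counts: Mapping[TasselCategory, int]) -> PRCurve:
    recalls: dict[TasselCategory, np.ndarray] = {}
    precisions: dict[TasselCategory, np.ndarray] = {}
    aps: dict[TasselCategory, float] = {}
    for cat in TasselCategory:
        n_truth = truth_counts.get(cat, 0)
        labeled = sorted(m.labeled[cat], key=lambda t: -t[0])
        tps = np.cumsum([1 if is_tp else 0 for _, is_tp in labeled])
        fps = np.cumsum([0 if is_tp else 1 for _, is_tp in labeled])
        recalls[cat] = tps / n_truth if n_truth else np.zeros_like(tps, dtype=float)
        precisions[cat] = np.where(tps + fps > 0, tps / np.maximum(tps + fps, 1), 0.0)
        if n_truth:
            aps[cat] = average_precision(labeled, n_truth)
    return PRCurve(
        recall=recalls,
        precision=precisions,
        ap=aps,
        map50=map_at_50(list(aps.values())),
    )


def map_at_50(aps: Sequence[float]) -> float:
    """Unweighted mean of per-category APs."""
    if len(aps) == 0:
        raise ValueError("mAP needs at least one defined AP")
    return float(np.mean(aps))


@dataclass(frozen=True)
class CountSummary:
    """Per-image, per-category predicted and ground-truth counts.

    ``predicted`` and ``ground_truth`` are (n_images, n_categories) arrays.
    """

    predicted: np.ndarray
    ground_truth: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.predicted)
        g = np.asarray(self.ground_truth)
        if p.shape != g.shape or p.ndim != 2:
            raise ValueError(
                f"predicted {p.shape} and ground_truth {g.shape} must be equal 2-D shapes"
            )
        if p.shape[0] < 1:
            raise ValueError("need at least one image")
        if (p < 0).any() or (g < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_images(self) -> int:
        return self.predicted.shape[0]

    @property
    def n_categories(self) -> int:
        return self.predicted.shape[1]


@dataclass(frozen=True)
class CountMetrics:
    ed: float
    ed_per_category: tuple[float, ...]
    acc: float
    rmse: float
    mae: float
    mpae: float
    mdr: float
    n_images_used: int
    n_images_excluded: int

    def as_dict(self) -> dict[str, float]:
        return {
            "ED": self.ed,
            "ACC": self.acc,
            "MDR": self.mdr,
            "RMSE": self.rmse,
            "MAE": self.mae,
            "MPAE": self.mpae,
        }


def count_metrics(cs: CountSummary) -> CountMetrics:
    """Count-level performance of predicted vs ground-truth counts.

    Images whose total ground truth is zero are excluded (ratio metrics
    are undefined there); the exclusion count is carried in the result.
    """
    pred = np.asarray(cs.predicted, dtype=float)
    gt = np.asarray(cs.ground_truth, dtype=float)
    gt_tot = gt.sum(axis=1)
    keep = gt_tot > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("every image has zero ground truth; count metrics undefined")
    pred, gt, gt_tot = pred[keep], gt[keep], gt_tot[keep]
    pred_tot = pred.sum(axis=1)
    diff = pred - gt
    diff_tot = pred_tot - gt_tot

    ed = float(np.mean(np.sqrt((diff**2).sum(axis=1))))
    ed_per_cat = tuple(float(v) for v in np.mean(np.abs(diff), axis=0))
    acc = float(np.mean(pred_tot / gt_tot))
    rmse = float(np.sqrt(np.mean(diff_tot**2)))
    mae = float(np.mean(np.abs(diff_tot)))
    mpae = float(np.mean(np.abs(diff_tot) / gt_tot))
    mdr = float(np.mean(diff_tot / gt_tot))
    return CountMetrics(
        ed=ed,
        ed_per_category=ed_per_cat,
        acc=acc,
        rmse=rmse,
        mae=mae,
        mpae=mpae,
        mdr=mdr,
        n_images_used=int(keep.sum()),
        n_images_excluded=n_excluded,
    )
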