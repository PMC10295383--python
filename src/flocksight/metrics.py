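"""Detection evaluation: IoU, greedy matching, precision-recall, AP/mAP,
recall at a fixed precision, and size stratification.

All boxes use the COCO convention: ``(x, y, w, h)`` with a top-left origin,
0-based continuous coordinates, and area ``w * h``.  Evaluation follows the
COCO protocol: greedy one-to-one matching in descending score order,
101-point interpolated average precision, and mAP averaged over the ten IoU
thresholds 0.50, 0.55, ..., 0.95.  Crowd-flagged ground truths act as ignore
regions: they are never counted as false negatives and a detection that only
overlaps a crowd region is neither a true nor a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BoundingBox",
    "Detection",
    "GroundTruth",
    "MatchResult",
    "PRCurve",
    "EvalResult",
    "iou",
    "match_detections",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "recall_at_precision",
    "size_partition",
    "IOU_THRESHOLDS",
    "SMALL_LIMIT",
]

#: COCO mAP IoU grid [0.50:0.05:0.95].
IOU_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))

#: Side length (px) below which a target counts as "small" (area < 40*40).
SMALL_LIMIT: float = 40.0


class InvalidBoxError(ValueError):
    """Raised for boxes with non-positive width/height or non-finite coords."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box ``(x, y, w, h)``, COCO xywh convention."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        vals = (self.x, self.y, self.w, self.h)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidBoxError(f"non-finite box coordinates: {vals}")
        if self.w <= 0 or self.h <= 0:
            raise InvalidBoxError(f"non-positive box size: w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def as_xyxy(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.x + self.w, self.y + self.h)


@dataclass(frozen=True)
class Detection:
    """A scored predicted box on one frame."""

    box: BoundingBox
    score: float
    frame_id: int = 0
    category: str = "waterbird"

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass(frozen=True)
class GroundTruth:
    """An annotated box; ``crowd`` marks an ignore region covering a group."""

    box: BoundingBox
    frame_id: int = 0
    crowd: bool = False
    id: int = 0


@dataclass
class MatchResult:
    """TP/FP/FN tallies and the detection -> ground-truth assignment.

    ``assignment[i]`` is the matched ground-truth ``id`` for detection index
    ``i``, or ``None`` if unmatched.  Detections whose only match is a crowd
    region are tallied under ``n_ignored`` (neither TP nor FP), so
    ``tp + fp + n_ignored == len(dets)`` and ``tp + fn == #non-crowd gts``.
    """

    tp: int
    fp: int
    fn: int
    assignment: dict[int, int | None] = field(default_factory=dict)
    n_ignored: int = 0


@dataclass
class PRCurve:
    """Score-ordered precision/recall points (thresholds descending)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        self.recall = np.asarray(self.recall, dtype=float)
        if not (len(self.thresholds) == len(self.precision) == len(self.recall)):
            raise ValueError("threshold/precision/recall arrays must align")


@dataclass
class EvalResult:
    """AP per IoU threshold, their mean, and recall at a precision floor."""

    ap_per_iou: dict[float, float]
    map_value: float
    recall_at_p85_all: float
    recall_at_p85_small: float
    recall_at_p85_other: float
    precision_target: float = 0.85

    def to_dict(self) -> dict:
        return {
            "ap_per_iou": {f"{k:.2f}": v for k, v in self.ap_per_iou.items()},
            "mAP": self.map_value,
            "recall_at_precision": {
                "target": self.precision_target,
                "all": self.recall_at_p85_all,
                "small": self.recall_at_p85_small,
                "other": self.recall_at_p85_other,
            },
        }


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    if a == b:
        return 1.0
    ax0, ay0, ax1, ay1 = a.as_xyxy()
    bx0, by0, bx1, by1 = b.as_xyxy()
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    # clamp: float round-off can push identical boxes a hair above 1
    return min(inter / (a.area + b.area - inter), 1.0)


def _sorted_det_indices(dets: Sequence[Detection]) -> list[int]:
    # descending score; ties broken by input order (stable sort)
    return sorted(range(len(dets)), key=lambda i: -dets[i].score)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    iou_thresh: float,
) -> MatchResult:
    """Greedy one-to-one matching of detections to ground truths.

    Detections are visited in descending score order (ties by input order);
    each claims the unmatched non-crowd ground truth with the highest IoU,
    provided that IoU >= ``iou_thresh`` (IoU ties broken by lower gt id).
    A detection left unmatched that overlaps a crowd region at or above the
    threshold is ignored rather than counted as a false positive.
    """
    if not (0.0 < iou_thresh <= 1.0):
        raise ValueError(f"iou_thresh must be in (0, 1], got {iou_thresh}")

    real_gts = [g for g in gts if not g.crowd]
    crowd_gts = [g for g in gts if g.crowd]
    matched_gt: set[int] = set()
    assignment: dict[int, int | None] = {}
    tp = fp = n_ignored = 0

    for i in _sorted_det_indices(dets):
        det = dets[i]
        best_iou, best_gt = 0.0, None
        for g in real_gts:
            if g.id in matched_gt:
                continue
            v = iou(det.box, g.box)
            if v > best_iou or (v == best_iou and best_gt is not None
                                and v > 0 and g.id < best_gt.id):
                best_iou, best_gt = v, g
        if best_gt is not None and best_iou >= iou_thresh:
            matched_gt.add(best_gt.id)
            assignment[i] = best_gt.id
            tp += 1
            continue
        # unmatched: check crowd/ignore overlap before calling it FP
        if any(iou(det.box, c.box) >= iou_thresh for c in crowd_gts):
            assignment[i] = None
            n_ignored += 1
        else:
            assignment[i] = None
            fp += 1

    fn = len(real_gts) - tp
    return MatchResult(tp=tp, fp=fp, fn=fn, assignment=assignment,
                       n_ignored=n_ignored)


def _tp_flags(
    dets: Sequence[Detection], gts: Sequence[GroundTruth], iou_thresh: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-detection TP / ignore flags in descending-score order.

    Greedy matching is prefix-consistent: matching only the top-k detections
    gives the same assignments as the first k steps of the full greedy pass,
    so one pass yields the whole PR sweep.
    Returns (is_tp, is_ignored, n_real_gts) aligned to descending score.
    """
    order = _sorted_det_indices(dets)
    full = match_detections(dets, gts, iou_thresh)
    crowd_gts = [g for g in gts if g.crowd]
    is_tp = np.zeros(len(dets), dtype=bool)
    is_ign = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        if full.assignment.get(i) is not None:
            is_tp[rank] = True
        elif any(iou(dets[i].box, c.box) >= iou_thresh for c in crowd_gts):
            is_ign[rank] = True
    n_real = sum(1 for g in gts if not g.crowd)
    return is_tp, is_ign, n_real


def pr_curve(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    iou_thresh: float,
) -> PRCurve:
    """Precision/recall swept over every distinct detection score.

    At each threshold, precision = TP/(TP+FP) and recall = TP/(TP+FN) over
    the detections scoring at or above it.  Requires at least one non-crowd
    ground truth (recall is undefined otherwise).
    """
    n_real = sum(1 for g in gts if not g.crowd)
    if n_real == 0:
        raise ValueError("pr_curve requires at least one non-crowd ground truth")
    if len(dets) == 0:
        return PRCurve(np.array([]), np.array([]), np.array([]))

    order = _sorted_det_indices(dets)
    scores = np.array([dets[i].score for i in order])
    is_tp, is_ign, _ = _tp_flags(dets, gts, iou_thresh)

    keep = ~is_ign
    scores_k = scores[keep]
    tp_cum = np.cumsum(is_tp[keep].astype(int))
    fp_cum = np.cumsum((~is_tp[keep]).astype(int))

    # one PR point per distinct score: the last (most inclusive) index at it
    if len(scores_k) == 0:
        return PRCurve(np.array([]), np.array([]), np.array([]))
    _, last_idx = np.unique(scores_k[::-1], return_index=True)
    cut = len(scores_k) - 1 - last_idx  # ascending score -> positions
    cut = np.sort(cut)

    thresholds = scores_k[cut]
    tp_at = tp_cum[cut].astype(float)
    fp_at = fp_cum[cut].astype(float)
    with np.errstate(invalid="ignore"):
        precision = np.where(tp_at + fp_at > 0, tp_at / (tp_at + fp_at), 0.0)
    recall = tp_at / n_real
    return PRCurve(thresholds, precision, recall)


def average_precision(curve: PRCurve, mode: str = "coco101") -> float:
    """Area under the precision-recall curve.

    ``mode='coco101'`` (default): mean over the 101-point recall grid
    {0, 0.01, ..., 1} of the maximum precision among points with recall >= r.
    ``mode='trapezoid'``: exact trapezoidal area over the envelope, for
    cross-checks.
    """
    if len(curve.recall) == 0:
        return 0.0
    rec = np.asarray(curve.recall, dtype=float)
    pre = np.asarray(curve.precision, dtype=float)

    if mode == "coco101":
        grid = np.linspace(0.0, 1.0, 101)
        ap = 0.0
        for r in grid:
            mask = rec >= r - 1e-12
            ap += float(pre[mask].max()) if mask.any() else 0.0
        return ap / 101.0
    if mode == "trapezoid":
        # monotone precision envelope, then trapezoid over recall
        order = np.argsort(rec)
        r_s, p_s = rec[order], pre[order]
        env = np.maximum.accumulate(p_s[::-1])[::-1]
        r_full = np.concatenate([[0.0], r_s])
        p_full = np.concatenate([[env[0]], env])
        return float(np.trapezoid(p_full, r_full))
    raise ValueError(f"unknown AP mode: {mode!r}")


def recall_at_precision(curve: PRCurve, target: float = 0.85) -> float:
    """Best recall achieved by any operating point with precision >= target.

    Returns 0 when no point reaches the target precision.
    """
    if not (0.0 < target < 1.0):
        raise ValueError(f"target must be in (0, 1), got {target}")
    if len(curve.recall) == 0:
        return 0.0
    mask = curve.precision >= target
    return float(curve.recall[mask].max()) if mask.any() else 0.0


def size_partition(
    boxes: Iterable[BoundingBox],
    small_limit: float = SMALL_LIMIT,
    criterion: str = "area",
) -> tuple[list[BoundingBox], list[BoundingBox]]:
    """Split boxes into (small, other) strata.

    ``criterion='area'`` (default): small iff ``w*h < small_limit**2``,
    the COCO-style area rule.  ``criterion='dims'``: small iff both sides
    are strictly below ``small_limit``.
    """
    if small_limit <= 0:
        raise ValueError("small_limit must be positive")
    small: list[BoundingBox] = []
    other: list[BoundingBox] = []
    for b in boxes:
        if criterion == "area":
            is_small = b.area < small_limit * small_limit
        elif criterion == "dims":
            is_small = b.w < small_limit and b.h < small_limit
        else:
            raise ValueError(f"unknown size criterion: {criterion!r}")
        (small if is_small else other).append(b)
    return small, other


def _is_small(box: BoundingBox, small_limit: float, criterion: str) -> bool:
    s, _ = size_partition([box], small_limit, criterion)
    return bool(s)


def _stratum_recall(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    keep_small: bool,
    iou_thresh: float,
    precision_target: float,
    small_limit: float,
    criterion: str,
) -> float:
    """Recall at the precision floor with gts restricted to one size stratum.

    Out-of-stratum ground truths become ignore regions so detections that hit
    them are dropped from the precision denominator (COCO area-range rule).
    """
    restricted: list[GroundTruth] = []
    for g in gts:
        in_stratum = _is_small(g.box, small_limit, criterion) == keep_small
        if g.crowd or not in_stratum:
            restricted.append(GroundTruth(g.box, g.frame_id, crowd=True, id=g.id))
        else:
            restricted.append(g)
    if not any(not g.crowd for g in restricted):
        return float("nan")
    curve = pr_curve(dets, restricted, iou_thresh)
    return recall_at_precision(curve, precision_target)


def mean_ap(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    precision_target: float = 0.85,
    recall_iou: float = 0.5,
    small_limit: float = SMALL_LIMIT,
    size_criterion: str = "area",
    ap_mode: str = "coco101",
) -> EvalResult:
    """Full evaluation: AP over IoU 0.50-0.95, mAP, and stratified recall.

    ``recall_at_p85`` figures are computed on the PR curve at ``recall_iou``
    (0.5 by default), overall and per size stratum.  Detections and ground
    truths are grouped by ``frame_id`` internally; matching never crosses
    frames.
    """
    frame_ids = sorted({d.frame_id for d in dets} | {g.frame_id for g in gts})
    ap_per_iou: dict[float, float] = {}

    def curve_at(thr: float, gt_list: Sequence[GroundTruth]) -> PRCurve:
        # pool detections over frames: offset gt ids per frame to keep them
        # unique, then run a single global sweep
        pooled_dets: list[Detection] = []
        pooled_gts: list[GroundTruth] = []
        for k, fid in enumerate(frame_ids):
            off = 1_000_000 * (k + 1)
            for d in dets:
                if d.frame_id == fid:
                    pooled_dets.append(d)
            for g in gt_list:
                if g.frame_id == fid:
                    pooled_gts.append(
                        GroundTruth(g.box, g.frame_id, g.crowd, g.id + off)
                    )
        return _pooled_pr(pooled_dets, pooled_gts, thr)

    for thr in IOU_THRESHOLDS:
        curve = curve_at(float(thr), list(gts))
        ap_per_iou[float(thr)] = average_precision(curve, mode=ap_mode)

    map_value = float(np.mean(list(ap_per_iou.values())))

    base = curve_at(recall_iou, list(gts))
    r_all = recall_at_precision(base, precision_target)

    def strat(keep_small: bool) -> float:
        restricted = []
        for g in gts:
            in_s = _is_small(g.box, small_limit, size_criterion) == keep_small
            if g.crowd or not in_s:
                restricted.append(GroundTruth(g.box, g.frame_id, True, g.id))
            else:
                restricted.append(g)
        if not any(not g.crowd for g in restricted):
            return float("nan")
        return recall_at_precision(curve_at(recall_iou, restricted),
                                   precision_target)

    return EvalResult(
        ap_per_iou=ap_per_iou,
        map_value=map_value,
        recall_at_p85_all=r_all,
        recall_at_p85_small=strat(True),
        recall_at_p85_other=strat(False),
        precision_target=precision_target,
    )


def _pooled_pr(
    dets: Sequence[Detection], gts: Sequence[GroundTruth], iou_thresh: float
) -> PRCurve:
    """PR sweep over multi-frame pools; matching stays within each frame."""
    n_real = sum(1 for g in gts if not g.crowd)
    if n_real == 0:
        raise ValueError("no non-crowd ground truths to evaluate against")
    if len(dets) == 0:
        return PRCurve(np.array([]), np.array([]), np.array([]))

    # per-frame greedy match, then merge flags by global score order
    flags: list[tuple[float, int, bool, bool]] = []  # (score, order, tp, ign)
    by_frame: dict[int, tuple[list[Detection], list[GroundTruth]]] = {}
    for d in dets:
        by_frame.setdefault(d.frame_id, ([], []))[0].append(d)
    for g in gts:
        by_frame.setdefault(g.frame_id, ([], []))[1].append(g)

    global_order = 0
    for fid in sorted(by_frame):
        f_dets, f_gts = by_frame[fid]
        if not f_dets:
            continue
        res = match_detections(f_dets, f_gts, iou_thresh)
        crowd = [g for g in f_gts if g.crowd]
        for i, d in enumerate(f_dets):
            is_tp = res.assignment.get(i) is not None
            is_ign = (not is_tp) and any(
                iou(d.box, c.box) >= iou_thresh for c in crowd
            )
            flags.append((d.score, global_order, is_tp, is_ign))
            global_order += 1

    flags.sort(key=lambda t: (-t[0], t[1]))
    kept = [(s, tp) for s, _, tp, ign in flags if not ign]
    if not kept:
        return PRCurve(np.array([]), np.array([]), np.array([]))
    scores = np.array([s for s, _ in kept])
    tps = np.array([tp for _, tp in kept], dtype=int)
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(1 - tps)

    _, last_idx = np.unique(scores[::-1], return_index=True)
    cut = np.sort(len(scores) - 1 - last_idx)
    thresholds = scores[cut]
    tp_at, fp_at = tp_cum[cut].astype(float), fp_cum[cut].astype(float)
    precision = np.where(tp_at + fp_at > 0, tp_at / (tp_at + fp_at), 0.0)
    recall = tp_at / n_real
    return PRCurve(thresholds, precision, recall)
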