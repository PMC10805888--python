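"""Bounding-box detection evaluation: IoU, greedy matching, interpolated AP.

Average precision follows the all-point interpolation used by the modern
COCO-style protocol: detections pooled over frames are sorted by confidence,
precision/recall are accumulated, precision is replaced by its running
maximum to the right (``p_interp(r) = max_{r' >= r} p(r')``) and AP is the
area under the resulting step curve,
``AP = sum_n (r_{n+1} - r_n) * p_interp(r_{n+1})`` with recall measured from
zero.  AP is averaged over IoU thresholds 0.50:0.05:0.95 and additionally
stratified by the ground-truth polyp-size category (small/medium/large).

Matching is greedy per frame: detections in descending confidence order
each claim the unmatched ground-truth box of highest IoU provided
IoU >= threshold (one-to-one).  Confidence ties are broken by larger best
IoU, then by input order, making evaluation bit-for-bit reproducible.

Size-stratified AP restricts the ground truth to one stratum; a detection
enters a stratum's curve only through the ground-truth box it matched
(unmatched false positives, and detections matched in other strata, count
against the unstratified AP only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import BoundingBox, InvalidInstanceError, SIZE_CATEGORIES

__all__ = [
    "BoundingBox",
    "Detection",
    "GroundTruthBox",
    "MatchedDetection",
    "PRCurve",
    "APResult",
    "DEFAULT_IOU_THRESHOLDS",
    "iou",
    "match_detections",
    "build_pr_curve",
    "interpolated_ap",
    "evaluate_detection",
    "read_detections_csv",
    "write_detections_csv",
    "read_coco_detections",
    "write_coco_detections",
    "read_coco_ground_truth",
    "write_coco_ground_truth",
]

#: COCO-style IoU threshold grid 0.50, 0.55, ..., 0.95.
DEFAULT_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    """A predicted polyp box with confidence, attached to a frame."""

    frame_id: str
    bbox: BoundingBox
    confidence: float
    label: str = "polyp"

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruthBox:
    """A ground-truth polyp box with its size stratum."""

    frame_id: str
    bbox: BoundingBox
    size_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.size_category is not None and self.size_category not in SIZE_CATEGORIES:
            raise ValueError(f"unknown size category {self.size_category!r}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint or degenerate pairs."""
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    return inter / union


@dataclass(frozen=True)
class MatchedDetection:
    """Outcome for one detection after greedy matching (processing order)."""

    det_index: int  # index into the input detection list
    confidence: float
    is_tp: bool
    gt_index: Optional[int]  # matched ground-truth index, None for FP
    best_iou: float


@dataclass
class MatchResult:
    matches: list[MatchedDetection]
    n_missed_gt: int


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthBox],
    iou_threshold: float,
) -> MatchResult:
    """Greedy one-to-one matching of a single frame's detections to its GTs.

    Detections are processed in descending confidence (ties: larger best IoU,
    then input order); each claims the unmatched ground truth of highest IoU
    when that IoU >= ``iou_threshold``, otherwise it is a false positive.
    """
    frames = {d.frame_id for d in dets} | {g.frame_id for g in gts}
    if len(frames) > 1:
        raise ValueError(f"match_detections operates on a single frame, got {sorted(frames)}")
    iou_mat = np.zeros((len(dets), len(gts)))
    for i, d in enumerate(dets):
        for j, g in enumerate(gts):
            iou_mat[i, j] = iou(d.bbox, g.bbox)
    best = iou_mat.max(axis=1) if len(gts) else np.zeros(len(dets))
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, -best[i], i))
    taken = np.zeros(len(gts), dtype=bool)
    matches: list[MatchedDetection] = []
    for i in order:
        j_best: Optional[int] = None
        iou_best = 0.0
        for j in range(len(gts)):
            if taken[j]:
                continue
            v = iou_mat[i, j]
            if v > iou_best:
                iou_best = v
                j_best = j
        if j_best is not None and iou_best >= iou_threshold:
            taken[j_best] = True
            matches.append(MatchedDetection(i, dets[i].confidence, True, j_best, iou_best))
        else:
            matches.append(MatchedDetection(i, dets[i].confidence, False, None, best[i]))
    return MatchResult(matches=matches, n_missed_gt=int((~taken).sum()))


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall at each unique recall value, with interpolation.

    ``recalls`` are strictly increasing; ``precisions`` hold the raw precision
    at the last detection achieving each recall; ``p_interp`` is the running
    maximum of precision to the right, so it is non-increasing in recall.
    """

    recalls: np.ndarray
    precisions: np.ndarray
    p_interp: np.ndarray
    n_gt: int


def build_pr_curve(scored: Sequence[tuple[float, bool]], n_gt: int) -> PRCurve:
    """Build a PR curve from ``(confidence, is_tp)`` pairs pooled over frames.

    Pairs must already be in evaluation order (descending confidence with a
    deterministic tie-break).  ``n_gt`` must be positive; the n_gt == 0 case
    is handled by the caller (AP undefined, stratum excluded).
    """
    if n_gt <= 0:
        raise ValueError("PR curve requires at least one ground-truth instance")
    flags = np.array([tp for _, tp in scored], dtype=bool)
    tps = np.cumsum(flags)
    fps = np.cumsum(~flags)
    recall = tps / n_gt
    precision = np.where(tps + fps > 0, tps / np.maximum(tps + fps, 1), 0.0)
    # keep the best precision achieved at each unique recall value
    uniq: dict[float, float] = {}
    for r, p in zip(recall, precision):
        uniq[float(r)] = max(uniq.get(float(r), 0.0), float(p))
    rs = np.array(sorted(uniq))
    ps = np.array([uniq[r] for r in rs])
    p_interp = np.maximum.accumulate(ps[::-1])[::-1] if len(ps) else ps
    return PRCurve(recalls=rs, precisions=ps, p_interp=p_interp, n_gt=n_gt)


def interpolated_ap(curve: PRCurve) -> float:
    """Area under the interpolated PR step curve, recall measured from 0."""
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(curve.recalls, curve.p_interp):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


@dataclass
class APResult:
    """AP per IoU threshold plus size-stratified AP/AR summaries.

    Stratum entries are ``None`` when the stratum has no ground truth
    (undefined, excluded from averages).
    """

    ap_per_threshold: dict[float, float]
    ap_mean: float
    ap_small: Optional[float]
    ap_medium: Optional[float]
    ap_large: Optional[float]
    ar: float
    ar_small: Optional[float]
    ar_medium: Optional[float]
    ar_large: Optional[float]
    n_gt: int
    n_det: int

    def ap_by_category(self) -> dict[str, Optional[float]]:
        return {
            "mean": self.ap_mean,
            "small": self.ap_small,
            "medium": self.ap_medium,
            "large": self.ap_large,
        }


def _pooled_curve(
    per_frame: Mapping[str, MatchResult],
    dets_by_frame: Mapping[str, list[tuple[int, Detection]]],
    n_gt: int,
) -> Optional[PRCurve]:
    if n_gt == 0:
        return None
    pool: list[tuple[float, float, str, int, bool]] = []
    for fid, res in per_frame.items():
        for m in res.matches:
            pool.append((m.confidence, m.best_iou, fid, m.det_index, m.is_tp))
    pool.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    return build_pr_curve([(c, tp) for c, _, _, _, tp in pool], n_gt)


def evaluate_detection(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthBox],
    thresholds: Sequence[float] = DEFAULT_IOU_THRESHOLDS,
) -> APResult:
    """Pooled AP over IoU thresholds with size-stratified AP and AR.

    Detections and ground truths are grouped by ``frame_id``; frames with no
    ground truth contribute false positives only, frames with no detections
    contribute misses.  AR is the mean over thresholds of the final (maximum)
    recall.  Raises if there is no ground truth anywhere.
    """
    if not gts:
        raise ValueError("evaluate_detection requires at least one ground-truth box")
    frames = sorted({d.frame_id for d in dets} | {g.frame_id for g in gts})
    dets_by_frame: dict[str, list[tuple[int, Detection]]] = {f: [] for f in frames}
    for i, d in enumerate(dets):
        dets_by_frame[d.frame_id].append((i, d))
    gts_by_frame: dict[str, list[tuple[int, GroundTruthBox]]] = {f: [] for f in frames}
    for j, g in enumerate(gts):
        gts_by_frame[g.frame_id].append((j, g))

    strata = {c: [j for j, g in enumerate(gts) if g.size_category == c] for c in SIZE_CATEGORIES}
    n_gt_stratum = {c: len(v) for c, v in strata.items()}

    ap_per_threshold: dict[float, float] = {}
    recalls_all: list[float] = []
    ap_stratum: dict[str, list[float]] = {c: [] for c in SIZE_CATEGORIES}
    ar_stratum: dict[str, list[float]] = {c: [] for c in SIZE_CATEGORIES}

    for t in thresholds:
        per_frame: dict[str, MatchResult] = {}
        # map global det index -> (confidence, best_iou, global matched gt index)
        matched_gt: dict[int, int] = {}
        for fid in frames:
            local_dets = [d for _, d in dets_by_frame[fid]]
            local_gts = [g for _, g in gts_by_frame[fid]]
            res = match_detections(local_dets, local_gts, t)
            # re-key detection/gt indices to global indices
            remapped = []
            for m in res.matches:
                gidx = dets_by_frame[fid][m.det_index][0]
                gt_global = gts_by_frame[fid][m.gt_index][0] if m.gt_index is not None else None
                remapped.append(
                    MatchedDetection(gidx, m.confidence, m.is_tp, gt_global, m.best_iou)
                )
                if gt_global is not None:
                    matched_gt[gidx] = gt_global
            per_frame[fid] = MatchResult(remapped, res.n_missed_gt)

        curve = _pooled_curve(per_frame, dets_by_frame, len(gts))
        assert curve is not None
        ap_per_threshold[float(t)] = interpolated_ap(curve)
        recalls_all.append(float(curve.recalls[-1]) if len(curve.recalls) else 0.0)

        for cat in SIZE_CATEGORIES:
            n_gt_c = n_gt_stratum[cat]
            if n_gt_c == 0:
                continue
            members = set(strata[cat])
            pool = []
            for fid, res in per_frame.items():
                for m in res.matches:
                    if m.is_tp and m.gt_index in members:
                        pool.append((m.confidence, m.best_iou, fid, m.det_index, True))
            pool.sort(key=lambda tt: (-tt[0], -tt[1], tt[2], tt[3]))
            if pool:
                c_curve = build_pr_curve([(c, tp) for c, _, _, _, tp in pool], n_gt_c)
                ap_stratum[cat].append(interpolated_ap(c_curve))
                ar_stratum[cat].append(float(c_curve.recalls[-1]))
            else:
                ap_stratum[cat].append(0.0)
                ar_stratum[cat].append(0.0)

    def _opt_mean(vals: list[float], present: bool) -> Optional[float]:
        return float(np.mean(vals)) if present else None

    return APResult(
        ap_per_threshold=ap_per_threshold,
        ap_mean=float(np.mean(list(ap_per_threshold.values()))),
        ap_small=_opt_mean(ap_stratum["small"], n_gt_stratum["small"] > 0),
        ap_medium=_opt_mean(ap_stratum["medium"], n_gt_stratum["medium"] > 0),
        ap_large=_opt_mean(ap_stratum["large"], n_gt_stratum["large"] > 0),
        ar=float(np.mean(recalls_all)),
        ar_small=_opt_mean(ar_stratum["small"], n_gt_stratum["small"] > 0),
        ar_medium=_opt_mean(ar_stratum["medium"], n_gt_stratum["medium"] > 0),
        ar_large=_opt_mean(ar_stratum["large"], n_gt_stratum["large"] > 0),
        n_gt=len(gts),
        n_det=len(dets),
    )


# ---------------------------------------------------------------------------
# I/O: plain CSV and a COCO-dialect JSON for interoperability.

def write_detections_csv(dets: Sequence[Detection], path: str | Path) -> None:
    rows = [
        {
            "frame_id": d.frame_id,
            "x": d.bbox.x,
            "y": d.bbox.y,
            "w": d.bbox.w,
            "h": d.bbox.h,
            "confidence": d.confidence,
        }
        for d in dets
    ]
    pd.DataFrame(rows, columns=["frame_id", "x", "y", "w", "h", "confidence"]).to_csv(
        path, index=False
    )


def read_detections_csv(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path)
    return [
        Detection(
            frame_id=str(r["frame_id"]),
            bbox=BoundingBox(float(r["x"]), float(r["y"]), float(r["w"]), float(r["h"])),
            confidence=float(r["confidence"]),
        )
        for r in df.to_dict("records")
    ]


def write_coco_detections(dets: Sequence[Detection], path: str | Path) -> None:
    payload = [
        {
            "image_id": d.frame_id,
            "category_id": 1,
            "bbox": [d.bbox.x, d.bbox.y, d.bbox.w, d.bbox.h],
            "score": d.confidence,
        }
        for d in dets
    ]
    Path(path).write_text(json.dumps(payload))


def read_coco_detections(path: str | Path) -> list[Detection]:
    payload = json.loads(Path(path).read_text())
    return [
        Detection(
            frame_id=str(r["image_id"]),
            bbox=BoundingBox(*r["bbox"]),
            confidence=float(r["score"]),
        )
        for r in payload
    ]


def write_coco_ground_truth(
    gts: Sequence[GroundTruthBox],
    frame_sizes: Mapping[str, tuple[int, int]],
    path: str | Path,
) -> None:
    images = [
        {"id": fid, "height": hw[0], "width": hw[1]} for fid, hw in sorted(frame_sizes.items())
    ]
    anns = [
        {
            "id": i + 1,
            "image_id": g.frame_id,
            "category_id": 1,
            "bbox": [g.bbox.x, g.bbox.y, g.bbox.w, g.bbox.h],
            "area": g.bbox.area,
            "iscrowd": 0,
            **({"size_category": g.size_category} if g.size_category else {}),
        }
        for i, g in enumerate(gts)
    ]
    payload = {
        "images": images,
        "annotations": anns,
        "categories": [{"id": 1, "name": "polyp"}],
    }
    Path(path).write_text(json.dumps(payload))


def read_coco_ground_truth(path: str | Path) -> list[GroundTruthBox]:
    payload = json.loads(Path(path).read_text())
    return [
        GroundTruthBox(
            frame_id=str(a["image_id"]),
            bbox=BoundingBox(*a["bbox"]),
            size_category=a.get("size_category"),
        )
        for a in payload["annotations"]
    ]
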