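"""Per-frame binary segmentation metrics and per-split aggregation.

Area-based scores come from the pixel confusion table: Dice
``DSC = 2tp / (2tp + fp + fn)``, Jaccard ``JC = tp / (tp + fp + fn)``,
positive predictive value ``p = tp / (tp + fp)``, recall
``r = tp / (tp + fn)``, accuracy ``Acc = (tp + tn) / N`` and the
recall-weighted ``F2 = 5pr / (4p + r)``.

The boundary-distance score is the average Hausdorff distance between the
ground-truth and predicted point sets,
``H_d(G, E) = ( mean_g min_e d(g,e) + mean_e min_g d(g,e) ) / 2``
with Euclidean ``d``.  By default the point sets are the mask *boundary*
pixels (foreground pixels with a background 8-neighbour, image border
counting as background); a flag switches to all foreground pixels.  Raw
distances are normalised to [0, 1] by the maximum over the evaluated test
set, and ``1 - H_d`` is reported so that larger is better.

Empty-mask conventions (test sets contain genuine no-polyp frames): when
both masks are empty the frame is a perfect prediction (DSC = JC = p = r =
F2 = 1, H_d = 0); when exactly one is empty the overlap scores degenerate to
0 and H_d takes a penalty equal to the image diagonal.  These frames are
kept in split means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "SegScores",
    "confusion_counts",
    "area_scores",
    "boundary_points",
    "average_hausdorff",
    "normalise_hausdorff",
    "score_frame",
    "evaluate_segmentation",
    "aggregate_split",
    "SEG_METRICS",
]

SEG_METRICS = ("DSC", "JC", "PPV", "Rec", "Acc", "F2", "Hd_raw", "Hd_norm", "one_minus_Hd")

_FULL_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel truth table of one frame; counts sum to the frame area."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SegScores:
    """All per-frame segmentation scores; Hd_norm is filled per test set."""

    DSC: float
    JC: float
    PPV: float
    Rec: float
    Acc: float
    F2: float
    Hd_raw: float
    Hd_norm: Optional[float] = None
    one_minus_Hd: Optional[float] = None


def confusion_counts(gt: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Exact pixel tabulation; masks must share one shape."""
    gt = np.asarray(gt).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if gt.shape != pred.shape:
        raise ValueError(f"mask shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    tp = int(np.count_nonzero(gt & pred))
    fp = int(np.count_nonzero(~gt & pred))
    fn = int(np.count_nonzero(gt & ~pred))
    tn = int(gt.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def area_scores(c: ConfusionCounts) -> SegScores:
    """Overlap scores from a confusion table, empty-mask conventions applied."""
    n_gt = c.tp + c.fn
    n_pred = c.tp + c.fp
    acc = (c.tp + c.tn) / c.total if c.total else 1.0
    if n_gt == 0 and n_pred == 0:
        return SegScores(DSC=1.0, JC=1.0, PPV=1.0, Rec=1.0, Acc=acc, F2=1.0, Hd_raw=0.0)
    dsc = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    jc = c.tp / (c.tp + c.fp + c.fn)
    p = c.tp / n_pred if n_pred else 0.0
    r = c.tp / n_gt if n_gt else 0.0
    f2 = 5 * p * r / (4 * p + r) if (4 * p + r) > 0 else 0.0
    return SegScores(DSC=dsc, JC=jc, PPV=p, Rec=r, Acc=acc, F2=f2, Hd_raw=np.nan)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(n, 2) array of (row, col) boundary pixels of a binary mask.

    A foreground pixel is boundary when any of its 8 neighbours (pixels
    outside the image counting as background) is background.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    interior = ndimage.binary_erosion(mask, structure=_FULL_3X3, border_value=0)
    return np.argwhere(mask & ~interior)


def average_hausdorff(
    g_points: np.ndarray,
    e_points: np.ndarray,
    empty_penalty: float = 0.0,
) -> float:
    """Symmetric average Hausdorff distance between two pixel point sets.

    Both directed mean nearest-neighbour distances are averaged and halved.
    When both sets are empty the distance is 0; when exactly one is empty
    the configured ``empty_penalty`` (conventionally the image diagonal) is
    returned.
    """
    g = np.asarray(g_points, dtype=float).reshape(-1, 2)
    e = np.asarray(e_points, dtype=float).reshape(-1, 2)
    if len(g) == 0 and len(e) == 0:
        return 0.0
    if len(g) == 0 or len(e) == 0:
        return float(empty_penalty)
    d_ge = cKDTree(e).query(g)[0]
    d_eg = cKDTree(g).query(e)[0]
    return float((d_ge.mean() + d_eg.mean()) / 2.0)


def normalise_hausdorff(per_frame_hd: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Divide raw distances by their maximum over the test set.

    Returns ``(hd_norm, one_minus_hd)``.  An all-zero input (every frame
    perfect) normalises to zeros.
    """
    hd = np.asarray(per_frame_hd, dtype=float)
    if hd.size == 0:
        raise ValueError("normalise_hausdorff requires at least one frame")
    m = hd.max()
    norm = hd / m if m > 0 else np.zeros_like(hd)
    return norm, 1.0 - norm


def score_frame(
    gt: np.ndarray,
    pred: np.ndarray,
    mode: str = "boundary",
) -> SegScores:
    """All per-frame scores for one mask pair (Hd_norm left unset).

    ``mode`` selects the Hausdorff point sets: ``"boundary"`` (default) or
    ``"all"`` foreground pixels.  The empty-set Hausdorff penalty is the
    image diagonal.
    """
    counts = confusion_counts(gt, pred)
    scores = area_scores(counts)
    if mode == "boundary":
        g_pts, e_pts = boundary_points(gt), boundary_points(pred)
    elif mode == "all":
        g_pts = np.argwhere(np.asarray(gt).astype(bool))
        e_pts = np.argwhere(np.asarray(pred).astype(bool))
    else:
        raise ValueError(f"unknown Hausdorff mode {mode!r}")
    h, w = np.asarray(gt).shape
    scores.Hd_raw = average_hausdorff(g_pts, e_pts, empty_penalty=float(np.hypot(h, w)))
    return scores


def evaluate_segmentation(
    gt_masks: Mapping[str, np.ndarray],
    pred_masks: Mapping[str, np.ndarray],
    splits: Mapping[str, str],
    mode: str = "boundary",
) -> pd.DataFrame:
    """Score every frame and normalise H_d over the whole evaluated set.

    ``gt_masks`` and ``pred_masks`` map frame_id to binary mask; ``splits``
    maps frame_id to its split label.  A missing prediction counts as an
    all-background mask (the frame is still scored).  Returns a tidy frame
    table with one row per frame and columns ``frame_id, split`` + scores,
    sorted by frame_id; the normalisation maximum is taken over all frames
    of this call, i.e. the full test set being evaluated.
    """
    rows = []
    for fid in sorted(gt_masks):
        gt = gt_masks[fid]
        pred = pred_masks.get(fid)
        if pred is None:
            pred = np.zeros_like(np.asarray(gt), dtype=bool)
        s = score_frame(gt, pred, mode=mode)
        rows.append(
            {
                "frame_id": fid,
                "split": splits[fid],
                "DSC": s.DSC,
                "JC": s.JC,
                "PPV": s.PPV,
                "Rec": s.Rec,
                "Acc": s.Acc,
                "F2": s.F2,
                "Hd_raw": s.Hd_raw,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no frames to evaluate")
    norm, one_minus = normalise_hausdorff(df["Hd_raw"].to_numpy())
    df["Hd_norm"] = norm
    df["one_minus_Hd"] = one_minus
    return df


def aggregate_split(frame_scores: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-frame mean and sd of every metric, per split.

    Sample sd (ddof = 1); a single-frame split reports sd 0.
    """
    metrics = [c for c in SEG_METRICS if c in frame_scores.columns]
    grouped = frame_scores.groupby("split")[metrics]
    mean = grouped.mean()
    sd = grouped.std(ddof=1).fillna(0.0)
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    out.columns = [f"{m}_{stat}" for stat, m in out.columns]
    return out
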