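"""Tolerance-gated generalisability deviation (dev_g) between data splits.

The deviation score compares a method's metrics on the *seen* reference
split (``data3``, seen-centre WLE sequences) against each *unseen* split
(``data1`` NBI, ``data2`` unseen-centre single frames, ``data4``
unseen-centre sequences).  For detection the categories are the AP family
``{mean, small, medium, large}`` with a 10% tolerance band; for
segmentation they are ``{DSC, F2, p, r, H_d}`` with a 5% band.

Two readings of the band condition are provided:

* ``gated`` (default): a category contributes ``|seen_k - unseen_k|`` only
  when the unseen score falls *outside* ``[seen_k (1 - tl), seen_k (1 + tl)]``;
  scores inside the band are treated as stable and contribute 0.
* ``literal``: the plain mean absolute deviation over categories (no gate).

Gated deviation is never larger than literal deviation.  The overall dev_g
of a method is the unweighted mean of its per-pair deviations
(data1-3, data2-3, data4-3) and does not depend on the mode choice given
the per-pair values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DETECTION_CATEGORIES",
    "SEGMENTATION_CATEGORIES",
    "REFERENCE_SPLIT",
    "UNSEEN_SPLITS",
    "SplitScores",
    "DeviationConfig",
    "DeviationResult",
    "detection_config",
    "segmentation_config",
    "pairwise_deviation",
    "overall_devg",
    "deviation_result",
]

DETECTION_CATEGORIES = ("mean", "small", "medium", "large")
SEGMENTATION_CATEGORIES = ("DSC", "F2", "p", "r", "H_d")

#: Seen-centre sequence split used as the base for all comparisons.
REFERENCE_SPLIT = "data3"
UNSEEN_SPLITS = ("data1", "data2", "data4")


@dataclass(frozen=True)
class SplitScores:
    """One split's metric vector, keyed by deviation category."""

    split: str
    scores: Mapping[str, float]

    def __getitem__(self, k: str) -> float:
        return self.scores[k]


@dataclass(frozen=True)
class DeviationConfig:
    """Tolerance band and category set for one task's deviation score."""

    tolerance: float
    categories: tuple[str, ...]
    mode: str = "gated"

    def __post_init__(self) -> None:
        if not (0.0 <= self.tolerance < 1.0):
            raise ValueError(f"tolerance must be in [0, 1), got {self.tolerance}")
        if self.mode not in ("gated", "literal"):
            raise ValueError(f"mode must be 'gated' or 'literal', got {self.mode!r}")


def detection_config(mode: str = "gated", tolerance: float = 0.1) -> DeviationConfig:
    """Detection-task deviation: AP categories, 10% tolerance."""
    return DeviationConfig(tolerance=tolerance, categories=DETECTION_CATEGORIES, mode=mode)


def segmentation_config(mode: str = "gated", tolerance: float = 0.05) -> DeviationConfig:
    """Segmentation-task deviation: DSC/F2/p/r/H_d categories, 5% tolerance."""
    return DeviationConfig(tolerance=tolerance, categories=SEGMENTATION_CATEGORIES, mode=mode)


def pairwise_deviation(
    seen: SplitScores, unseen: SplitScores, cfg: DeviationConfig
) -> float:
    """Deviation of one unseen split from the seen reference split."""
    for which, s in (("seen", seen), ("unseen", unseen)):
        missing = [k for k in cfg.categories if k not in s.scores]
        if missing:
            raise KeyError(f"{which} split {s.split!r} missing categories {missing}")
    total = 0.0
    for k in cfg.categories:
        s, u = float(seen[k]), float(unseen[k])
        diff = abs(s - u)
        if cfg.mode == "literal":
            total += diff
        else:
            lo, hi = s * (1.0 - cfg.tolerance), s * (1.0 + cfg.tolerance)
            if not (lo <= u <= hi):
                total += diff
    return total / len(cfg.categories)


def overall_devg(pair_devs: Sequence[float]) -> float:
    """Unweighted mean of per-pair deviations (reported to 3 decimals)."""
    if len(pair_devs) == 0:
        raise ValueError("overall_devg requires at least one pair deviation")
    return float(np.mean(pair_devs))


@dataclass(frozen=True)
class DeviationResult:
    """Per-pair deviations of one method plus their mean."""

    per_pair: Mapping[str, float]  # e.g. {"dev_g_1-3": ..., "dev_g_2-3": ..., "dev_g_4-3": ...}
    overall: float
    mode: str
    tolerance: float

    def to_row(self) -> dict[str, float]:
        return {**dict(self.per_pair), "dev_g": self.overall}


def deviation_result(
    split_scores: Mapping[str, SplitScores],
    cfg: DeviationConfig,
    reference: str = REFERENCE_SPLIT,
    unseen: Sequence[str] = UNSEEN_SPLITS,
) -> DeviationResult:
    """Deviations of every unseen split w.r.t. the reference, plus overall.

    ``split_scores`` maps split label to its :class:`SplitScores`; every
    split in ``unseen`` plus the reference must be present.
    """
    if reference not in split_scores:
        raise KeyError(f"reference split {reference!r} missing from scores")
    per_pair: dict[str, float] = {}
    for u in unseen:
        if u not in split_scores:
            raise KeyError(f"unseen split {u!r} missing from scores")
        label = f"dev_g_{u.removeprefix('data')}-{reference.removeprefix('data')}"
        per_pair[label] = pairwise_deviation(split_scores[reference], split_scores[u], cfg)
    return DeviationResult(
        per_pair=per_pair,
        overall=overall_devg(list(per_pair.values())),
        mode=cfg.mode,
        tolerance=cfg.tolerance,
    )
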