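"""Leaderboard ranking, elimination rules, and per-frame statistical tests.

Each criterion (e.g. average score, deviation score, inference time) is
ranked independently with direction awareness (rank 1 = best; exact ties
take the average of the tied positions).  Inference time may first be
*banded* into coarse categories (< 50 ms, 50-100 ms, > 100 ms by default)
so that small timing differences do not dominate.  Per-criterion ranks are
averaged per team, optionally rounded (half away from zero), and the final
leaderboard is the dense rank of the (rounded) means; residual ties are
broken by a designated criterion (the challenge used the segmentation
score).  Teams can be eliminated before ranking for inference time above a
cut-off (2 s) or scores below a floor derived from the baseline's
worst-split result.

For per-frame method comparison a Friedman test on within-frame ranks with
a Nemenyi post-hoc (studentized-range distribution) is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Criterion",
    "RankTable",
    "EliminationResult",
    "FriedmanNemenyiResult",
    "rank_criterion",
    "band_values",
    "aggregate_ranks",
    "eliminate",
    "friedman_nemenyi",
    "DEFAULT_TIME_BANDS_MS",
    "DEFAULT_TIME_LIMIT_MS",
]

#: Time band edges in ms: bands are <= 50, (50, 100], > 100.
DEFAULT_TIME_BANDS_MS = (50.0, 100.0)
#: Elimination cut-off for reported inference time.
DEFAULT_TIME_LIMIT_MS = 2000.0


@dataclass(frozen=True)
class Criterion:
    """One leaderboard column: a value per team and a direction."""

    name: str
    direction: str  # "higher_better" | "lower_better"
    values: Mapping[str, float]
    band_edges: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.band_edges is not None and list(self.band_edges) != sorted(set(self.band_edges)):
            raise ValueError("band edges must be strictly increasing")


def rank_criterion(c: Criterion) -> dict[str, float]:
    """Rank teams on one criterion; rank 1 is best, ties averaged."""
    teams = list(c.values)
    if len(teams) < 2:
        raise ValueError("ranking requires at least two teams")
    vals = np.array([float(c.values[t]) for t in teams])
    bad = [t for t, v in zip(teams, vals) if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite criterion value for teams {bad}")
    if c.direction == "higher_better":
        vals = -vals
    ranks = stats.rankdata(vals, method="average")
    return {t: float(r) for t, r in zip(teams, ranks)}


def band_values(c: Criterion, edges: Sequence[float] = DEFAULT_TIME_BANDS_MS) -> Criterion:
    """Replace a lower-better criterion's values by band indices 1..len+1.

    A value exactly on an edge falls in the lower band (<= edge).
    """
    if c.direction != "lower_better":
        raise ValueError("banding is defined for lower_better criteria only")
    edges_arr = np.asarray(sorted(edges), dtype=float)
    banded = {
        t: float(np.searchsorted(edges_arr, float(v), side="left") + 1)
        for t, v in c.values.items()
    }
    return Criterion(
        name=f"{c.name}_banded",
        direction="lower_better",
        values=banded,
        band_edges=tuple(edges_arr),
    )


@dataclass
class RankTable:
    """Per-criterion ranks, their mean, and the final dense ranking."""

    per_criterion: dict[str, dict[str, float]]
    mean_rank: dict[str, float]
    rounded_mean: Optional[dict[str, float]]
    final_rank: dict[str, int]
    unresolved_ties: list[tuple[str, ...]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_criterion)
        df["mean_rank"] = pd.Series(self.mean_rank)
        if self.rounded_mean is not None:
            df["rounded_mean"] = pd.Series(self.rounded_mean)
        df["final_rank"] = pd.Series(self.final_rank)
        return df.sort_values("final_rank")


def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def aggregate_ranks(
    criteria: Sequence[Criterion],
    round_means: bool = False,
    tiebreak_criterion: Optional[Criterion] = None,
) -> RankTable:
    """Average per-criterion ranks and densely rank the (rounded) means.

    All criteria must cover an identical team set.  With ``round_means`` the
    per-team mean rank is rounded half away from zero before the final dense
    ranking, mirroring the challenge procedure.  Ties in the final key are
    broken by ``tiebreak_criterion`` when given; ties it cannot break are
    reported in ``unresolved_ties`` and share a rank.
    """
    if not criteria:
        raise ValueError("aggregate_ranks requires at least one criterion")
    teams = sorted(criteria[0].values)
    for c in criteria:
        if sorted(c.values) != teams:
            raise ValueError(f"criterion {c.name!r} covers a different team set")
    per_criterion = {c.name: rank_criterion(c) for c in criteria}
    mean_rank = {t: float(np.mean([per_criterion[c.name][t] for c in criteria])) for t in teams}
    if round_means:
        key = {t: _round_half_away(mean_rank[t]) for t in teams}
        rounded: Optional[dict[str, float]] = {t: float(key[t]) for t in teams}
    else:
        key = dict(mean_rank)
        rounded = None

    tb_rank: dict[str, float] = {}
    if tiebreak_criterion is not None:
        tb_rank = rank_criterion(tiebreak_criterion)

    composite = {t: (key[t], tb_rank.get(t, 0.0)) for t in teams}
    distinct = sorted(set(composite.values()))
    final_rank = {t: distinct.index(composite[t]) + 1 for t in teams}

    unresolved: list[tuple[str, ...]] = []
    by_final: dict[int, list[str]] = {}
    for t, r in final_rank.items():
        by_final.setdefault(r, []).append(t)
    for r, group in sorted(by_final.items()):
        if len(group) > 1:
            unresolved.append(tuple(sorted(group)))
    return RankTable(
        per_criterion=per_criterion,
        mean_rank=mean_rank,
        rounded_mean=rounded,
        final_rank=final_rank,
        unresolved_ties=unresolved,
    )


@dataclass
class EliminationResult:
    survivors: list[str]
    eliminated: dict[str, list[str]]  # team -> reasons


def eliminate(
    teams: Sequence[str],
    scores: Mapping[str, Mapping[str, float]],
    baseline_worst_scores: Mapping[str, float],
    time_ms: Mapping[str, float],
    time_limit_ms: float = DEFAULT_TIME_LIMIT_MS,
    relative_margin: float = 0.10,
    floors: Optional[Mapping[str, float]] = None,
) -> EliminationResult:
    """Apply the challenge elimination rules.

    A team is removed when its reported inference time exceeds
    ``time_limit_ms`` (2 s), or when any task score falls more than
    ``relative_margin`` (10%) below the baseline's worst-split score for
    that task.  Explicit ``floors`` (e.g. ``{"AP": 0.10, "DSC": 0.50}``)
    override the derived thresholds per task.
    """
    derived = {task: v * (1.0 - relative_margin) for task, v in baseline_worst_scores.items()}
    if floors:
        derived.update(floors)
    survivors: list[str] = []
    eliminated: dict[str, list[str]] = {}
    for t in teams:
        reasons: list[str] = []
        if time_ms.get(t, 0.0) > time_limit_ms:
            reasons.append("time")
        for task, floor in derived.items():
            v = scores.get(t, {}).get(task)
            if v is not None and v < floor:
                reasons.append(f"score floor:{task}")
        if reasons:
            eliminated[t] = reasons
        else:
            survivors.append(t)
    return EliminationResult(survivors=survivors, eliminated=eliminated)


@dataclass
class FriedmanNemenyiResult:
    statistic: float
    pvalue: float
    mean_ranks: pd.Series
    pairwise_pvalues: pd.DataFrame


def friedman_nemenyi(
    per_frame_scores: pd.DataFrame | np.ndarray,
    methods: Optional[Sequence[str]] = None,
) -> FriedmanNemenyiResult:
    """Friedman chi-square over within-frame ranks + Nemenyi post-hoc.

    ``per_frame_scores`` is frames x methods with no missing cells.  The
    Nemenyi pairwise p-value for methods i, j uses the studentized-range
    distribution: ``q = |R_i - R_j| / sqrt(k(k+1) / (12 n))`` with survival
    function ``SF(q; k, inf)``.  Identical columns yield statistic 0 and
    p-values 1 (the no-evidence limit scipy reports as NaN).
    """
    if isinstance(per_frame_scores, pd.DataFrame):
        data = per_frame_scores.to_numpy(dtype=float)
        names = list(per_frame_scores.columns) if methods is None else list(methods)
    else:
        data = np.asarray(per_frame_scores, dtype=float)
        names = list(methods) if methods is not None else [f"m{i}" for i in range(data.shape[1])]
    n, k = data.shape
    if k < 3:
        raise ValueError("Friedman test requires at least 3 methods")
    if n < 2:
        raise ValueError("Friedman test requires at least 2 frames")
    if not np.isfinite(data).all():
        raise ValueError("missing or non-finite cells are not allowed (no imputation)")

    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    mean_ranks = pd.Series(ranks.mean(axis=0), index=names)

    with np.errstate(invalid="ignore"):
        stat, p = stats.friedmanchisquare(*(data[:, j] for j in range(k)))
    if not np.isfinite(stat):  # all-tied degenerate case
        stat, p = 0.0, 1.0

    se = math.sqrt(k * (k + 1) / (12.0 * n))
    pw = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks.iloc[i] - mean_ranks.iloc[j]) / se
            pv = float(np.clip(stats.studentized_range.sf(q, k, np.inf), 0.0, 1.0))
            pw[i, j] = pw[j, i] = pv
    pairwise = pd.DataFrame(pw, index=names, columns=names)
    return FriedmanNemenyiResult(
        statistic=float(stat), pvalue=float(p), mean_ranks=mean_ranks, pairwise_pvalues=pairwise
    )
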