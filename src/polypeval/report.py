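"""End-to-end evaluation runs and leaderboard report generation.

`run_evaluation` ties the modules together: it loads a manifest plus ground
truth, evaluates every team's segmentation masks and/or detection boxes per
test split, computes deviation scores against the seen reference split
(data3), ranks teams per criterion, and writes a machine-readable report.

Per-split aggregation conventions (the toolkit's own choices, echoed in the
report metadata):

* the per-split *segmentation score* is the unweighted mean of the split's
  per-frame means of DSC, F2, PPV, Rec and 1 - H_d (all higher-better);
* the per-split *detection score* is the split's AP averaged over IoU
  thresholds (AP_mean); the headline "average detection" is its mean over
  the four test splits;
* ranking criteria are the per-split scores (seen split excluded for the
  score family), the overall deviation, and banded inference time; both
  rounded and unrounded rank aggregation are reported.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    FrameRecord,
    PolypInstance,
    read_instances_csv,
    read_manifest_csv,
    read_mask,
    validate_manifest,
)
from .detection import Detection, GroundTruthBox, evaluate_detection, read_detections_csv
from .generalisability import (
    REFERENCE_SPLIT,
    UNSEEN_SPLITS,
    DeviationConfig,
    DeviationResult,
    SplitScores,
    deviation_result,
    segmentation_config,
)
from .ranking import Criterion, RankTable, aggregate_ranks, band_values
from .segmentation import aggregate_split, evaluate_segmentation

__all__ = [
    "TeamInputs",
    "RunConfig",
    "LeaderboardReport",
    "run_evaluation",
    "load_gt_masks",
    "seg_split_scores",
    "det_split_scores",
]

TEST_SPLITS_ORDER = ("data1", "data2", "data3", "data4")
SEG_SCORE_COMPONENTS = ("DSC", "F2", "PPV", "Rec", "one_minus_Hd")


@dataclass
class TeamInputs:
    """File references for one team's submission."""

    name: str
    pred_mask_dir: Optional[Path] = None
    detections_path: Optional[Path] = None
    time_ms: Optional[float] = None


@dataclass
class RunConfig:
    """One reproducible evaluation run."""

    task: str  # "detection" | "segmentation" | "both"
    manifest_path: Path
    instances_path: Path
    gt_mask_dir: Optional[Path]
    teams: list[TeamInputs]
    out_dir: Optional[Path] = None
    mode: str = "gated"
    det_tolerance: float = 0.1
    seg_tolerance: float = 0.05
    hausdorff_mode: str = "boundary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("detection", "segmentation", "both"):
            raise ValueError(f"unknown task {self.task!r}")
        if not self.teams:
            raise ValueError("at least one team is required")


@dataclass
class LeaderboardReport:
    """All tables produced by one run, plus metadata sufficient to re-run."""

    seg_frame_scores: dict[str, pd.DataFrame]
    seg_split_tables: dict[str, pd.DataFrame]
    det_split_tables: dict[str, pd.DataFrame]
    deviations: pd.DataFrame
    rank_tables: dict[str, pd.DataFrame]
    team_errors: dict[str, str]
    metadata: dict

    def to_json_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "seg_split_tables": {t: _df_records(df) for t, df in self.seg_split_tables.items()},
            "det_split_tables": {t: _df_records(df) for t, df in self.det_split_tables.items()},
            "deviations": _df_records(self.deviations),
            "rank_tables": {name: _df_records(df) for name, df in self.rank_tables.items()},
            "team_errors": self.team_errors,
        }

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for team, df in self.seg_frame_scores.items():
            df.to_csv(out_dir / f"seg_frames_{team}.csv", index=False)
        for team, df in self.seg_split_tables.items():
            df.to_csv(out_dir / f"seg_splits_{team}.csv")
        for team, df in self.det_split_tables.items():
            df.to_csv(out_dir / f"det_splits_{team}.csv", index=False)
        if not self.deviations.empty:
            self.deviations.to_csv(out_dir / "deviations.csv", index=False)
        for name, df in self.rank_tables.items():
            df.to_csv(out_dir / f"rank_{name}.csv")
        (out_dir / "report.json").write_text(json.dumps(self.to_json_dict(), indent=1))


def _df_records(df: pd.DataFrame) -> list[dict]:
    return json.loads(df.reset_index().to_json(orient="records"))


def load_gt_masks(
    records: Sequence[FrameRecord], mask_dir: Path
) -> dict[str, np.ndarray]:
    masks = {}
    for rec in records:
        rel = rec.mask_path or f"masks/{rec.frame_id}.png"
        path = mask_dir / Path(rel).name
        masks[rec.frame_id] = read_mask(path)
    return masks


def seg_split_scores(split_table: pd.DataFrame) -> dict[str, SplitScores]:
    """Deviation categories {DSC, F2, p, r, H_d} per split from the mean table."""
    out = {}
    for split, row in split_table.iterrows():
        out[str(split)] = SplitScores(
            split=str(split),
            scores={
                "DSC": row["DSC_mean"],
                "F2": row["F2_mean"],
                "p": row["PPV_mean"],
                "r": row["Rec_mean"],
                "H_d": row["Hd_norm_mean"],
            },
        )
    return out


def det_split_scores(per_split: Mapping[str, "object"]) -> dict[str, SplitScores]:
    """AP categories per split; a stratum missing anywhere is dropped everywhere."""
    cats = {"mean", "small", "medium", "large"}
    tables = {s: r.ap_by_category() for s, r in per_split.items()}
    common = [c for c in ("mean", "small", "medium", "large")
              if all(tables[s][c] is not None for s in tables)]
    return {
        s: SplitScores(split=s, scores={c: tables[s][c] for c in common}) for s in tables
    }


def _seg_score(split_table: pd.DataFrame, split: str) -> float:
    row = split_table.loc[split]
    return float(np.mean([row[f"{m}_mean"] for m in SEG_SCORE_COMPONENTS]))


def run_evaluation(cfg: RunConfig) -> LeaderboardReport:
    """Evaluate every team on the test splits and build the leaderboard.

    Per-team input failures are recorded in ``team_errors`` without aborting
    the run for the remaining teams.  Output is deterministic given inputs.
    """
    records = read_manifest_csv(cfg.manifest_path)
    instances = read_instances_csv(cfg.instances_path)
    validate_manifest(records, instances)
    test_records = [r for r in records if r.split in TEST_SPLITS_ORDER]
    splits = {r.frame_id: r.split for r in test_records}
    test_ids = set(splits)
    gt_boxes = [
        GroundTruthBox(frame_id=i.frame_id, bbox=i.bbox, size_category=i.size_category)
        for i in instances
        if i.frame_id in test_ids
    ]

    do_seg = cfg.task in ("segmentation", "both")
    do_det = cfg.task in ("detection", "both")
    gt_masks: dict[str, np.ndarray] = {}
    if do_seg:
        if cfg.gt_mask_dir is None:
            raise ValueError("segmentation evaluation requires gt_mask_dir")
        gt_masks = load_gt_masks(test_records, Path(cfg.gt_mask_dir))

    seg_frame_scores: dict[str, pd.DataFrame] = {}
    seg_split_tables: dict[str, pd.DataFrame] = {}
    det_split_tables: dict[str, pd.DataFrame] = {}
    dev_rows: list[dict] = []
    seg_scores_by_split: dict[str, dict[str, float]] = {}
    det_avg: dict[str, float] = {}
    seg_dev_overall: dict[str, float] = {}
    det_dev_overall: dict[str, float] = {}
    times: dict[str, float] = {}
    team_errors: dict[str, str] = {}

    for team in cfg.teams:
        try:
            if team.time_ms is not None:
                times[team.name] = team.time_ms
            if do_seg:
                pred_dir = Path(team.pred_mask_dir)  # type: ignore[arg-type]
                pred_masks = {}
                for fid in gt_masks:
                    p = pred_dir / f"{fid}.png"
                    if p.exists():
                        pred_masks[fid] = read_mask(p)
                frame_df = evaluate_segmentation(
                    gt_masks, pred_masks, splits, mode=cfg.hausdorff_mode
                )
                split_table = aggregate_split(frame_df)
                seg_frame_scores[team.name] = frame_df
                seg_split_tables[team.name] = split_table
                dev = deviation_result(
                    seg_split_scores(split_table),
                    segmentation_config(mode=cfg.mode, tolerance=cfg.seg_tolerance),
                )
                seg_dev_overall[team.name] = dev.overall
                dev_rows.extend(_dev_rows(team.name, "segmentation", dev))
                seg_scores_by_split[team.name] = {
                    s: _seg_score(split_table, s)
                    for s in TEST_SPLITS_ORDER
                    if s in split_table.index
                }
            if do_det:
                dets = read_detections_csv(team.detections_path)  # type: ignore[arg-type]
                dets = [d for d in dets if d.frame_id in test_ids]
                per_split = {}
                rows = []
                for s in TEST_SPLITS_ORDER:
                    s_gts = [g for g in gt_boxes if splits[g.frame_id] == s]
                    if not s_gts:
                        continue
                    s_dets = [d for d in dets if splits[d.frame_id] == s]
                    res = evaluate_detection(s_dets, s_gts)
                    per_split[s] = res
                    rows.append(
                        {
                            "split": s,
                            "AP_mean": res.ap_mean,
                            "AP_small": res.ap_small,
                            "AP_medium": res.ap_medium,
                            "AP_large": res.ap_large,
                            "AR": res.ar,
                            "n_gt": res.n_gt,
                            "n_det": res.n_det,
                        }
                    )
                det_split_tables[team.name] = pd.DataFrame(rows)
                det_avg[team.name] = float(np.mean([r.ap_mean for r in per_split.values()]))
                # strata missing everywhere are dropped from the category set
                split_scores = det_split_scores(per_split)
                cats = tuple(next(iter(split_scores.values())).scores)
                dev = deviation_result(
                    split_scores,
                    DeviationConfig(
                        tolerance=cfg.det_tolerance, categories=cats, mode=cfg.mode
                    ),
                )
                det_dev_overall[team.name] = dev.overall
                dev_rows.extend(_dev_rows(team.name, "detection", dev))
        except (OSError, ValueError, KeyError) as exc:
            team_errors[team.name] = f"{type(exc).__name__}: {exc}"

    rank_tables: dict[str, pd.DataFrame] = {}
    if do_seg and len(seg_scores_by_split) >= 2:
        rank_tables.update(
            _seg_rank_tables(seg_scores_by_split, seg_dev_overall, times)
        )
    if do_det and len(det_avg) >= 2:
        rank_tables.update(_det_rank_tables(det_avg, det_dev_overall, times))

    deviations = pd.DataFrame(dev_rows)
    metadata = {
        "toolkit_version": __version__,
        "config": _config_dict(cfg),
        "n_test_frames": len(test_records),
        "n_test_instances": len(gt_boxes),
        "reference_split": REFERENCE_SPLIT,
    }
    report = LeaderboardReport(
        seg_frame_scores=seg_frame_scores,
        seg_split_tables=seg_split_tables,
        det_split_tables=det_split_tables,
        deviations=deviations,
        rank_tables=rank_tables,
        team_errors=team_errors,
        metadata=metadata,
    )
    if cfg.out_dir is not None:
        report.write(Path(cfg.out_dir))
    return report


def _dev_rows(team: str, task: str, dev: DeviationResult) -> list[dict]:
    rows = [
        {"team": team, "task": task, "pair": pair, "mode": dev.mode,
         "tolerance": dev.tolerance, "deviation": v}
        for pair, v in dev.per_pair.items()
    ]
    rows.append(
        {"team": team, "task": task, "pair": "overall", "mode": dev.mode,
         "tolerance": dev.tolerance, "deviation": dev.overall}
    )
    return rows


def _rank_variants(name: str, criteria: list[Criterion], tiebreak: Optional[Criterion]) -> dict:
    out = {}
    for label, rounded in (("unrounded", False), ("rounded", True)):
        table = aggregate_ranks(criteria, round_means=rounded, tiebreak_criterion=tiebreak)
        out[f"{name}_{label}"] = table.to_frame()
    return out


def _seg_rank_tables(
    scores_by_split: Mapping[str, Mapping[str, float]],
    dev_overall: Mapping[str, float],
    times: Mapping[str, float],
) -> dict[str, pd.DataFrame]:
    teams = sorted(scores_by_split)
    score_splits = [s for s in TEST_SPLITS_ORDER if s != REFERENCE_SPLIT]
    crit_scores = [
        Criterion(
            name=f"seg_{s}",
            direction="higher_better",
            values={t: scores_by_split[t][s] for t in teams},
        )
        for s in score_splits
        if all(s in scores_by_split[t] for t in teams)
    ]
    tables = _rank_variants("seg_score", crit_scores, None)
    criteria = list(crit_scores)
    if all(t in dev_overall for t in teams):
        criteria.append(
            Criterion(name="dev_g", direction="lower_better",
                      values={t: dev_overall[t] for t in teams})
        )
    if all(t in times for t in teams):
        criteria.append(
            band_values(
                Criterion(name="time_ms", direction="lower_better",
                          values={t: times[t] for t in teams})
            )
        )
    tiebreak = crit_scores[0] if crit_scores else None
    tables.update(_rank_variants("seg_overall", criteria, tiebreak))
    return tables


def _det_rank_tables(
    avg_det: Mapping[str, float],
    dev_overall: Mapping[str, float],
    times: Mapping[str, float],
) -> dict[str, pd.DataFrame]:
    teams = sorted(avg_det)
    criteria = [
        Criterion(name="avg_det", direction="higher_better",
                  values={t: avg_det[t] for t in teams})
    ]
    if all(t in dev_overall for t in teams):
        criteria.append(
            Criterion(name="dev_g", direction="lower_better",
                      values={t: dev_overall[t] for t in teams})
        )
    if all(t in times for t in teams):
        criteria.append(
            Criterion(name="time_ms", direction="lower_better",
                      values={t: times[t] for t in teams})
        )
    return _rank_variants("det_overall", criteria, criteria[0])


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)

    def conv(v):
        if isinstance(v, Path):
            return str(v)
        if isinstance(v, list):
            return [conv(x) for x in v]
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        return v

    return conv(d)
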