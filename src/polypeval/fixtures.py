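"""Seeded synthetic challenge fixtures: masks, boxes, manifest, predictions.

The generator emulates the *structure* of a multi-centre colonoscopy
benchmark — six centres, two modalities, single-frame and sequence test
splits, and a null/small/medium/large polyp-size mixture on 540x720 frames —
without any appearance model.  Polyps are star-shaped blobs: ellipses whose
radius is modulated by a low-order Fourier series,
``r(theta) = 1 + sum_m a_m cos(m theta + phi_m)`` for m = 2..4, with the
total amplitude bounded so the shape stays simply connected.  Sequences
evolve by a Gaussian random walk of blob centre and log-scale with
reflecting frame boundaries.

Predictions are simulated by perturbing the ground-truth blobs: each
instance is independently missed with some probability, survivors are
jittered in position, scale and boundary shape, and spurious blobs are
added at a Poisson rate.  Detection confidences follow
``base - penalty * (1 - IoU) + noise``.  A per-split severity multiplier
scales every perturbation, which is how split-level domain shift (and hence
a known positive deviation score) is injected; random draws are made before
severity scaling, so runs with the same seed and different severities are
coupled.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import (
    REFERENCE_SIZE,
    BoundingBox,
    FrameRecord,
    PolypInstance,
    categorize_polyp_size,
    write_instances_csv,
    write_manifest_csv,
    write_mask,
)
from .detection import Detection, GroundTruthBox, iou, write_detections_csv

__all__ = [
    "SceneSpec",
    "PerturbationSpec",
    "GroundTruthFixture",
    "PredictionSet",
    "ChallengeFixture",
    "generate_ground_truth",
    "simulate_predictions",
    "generate_challenge_fixture",
]

#: sqrt-area sampling bands per size category (native px; at the default
#: reference-resolution frame these align with the 100/200 categorisation
#: landmarks, with a few px margin so rasterisation never flips the
#: category).  Recorded categories are always recomputed from the rendered
#: tight box, so non-default frame sizes stay self-consistent.
_SIZE_BANDS = {"small": (36.0, 94.0), "medium": (106.0, 194.0), "large": (206.0, 270.0)}
_SEQUENCE_SPLITS = ("data3", "data4")
_UNSEEN_CENTRE_SPLITS = ("data2", "data4")


class InfeasibleSpecError(ValueError):
    """The requested scene cannot be realised (e.g. polyp larger than frame)."""


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth scene parameters; defaults mirror the challenge layout.

    ``split_counts`` defaults to the challenge's frame counts (3242 training
    frames; test quotas 135/86/124/432 for data1-data4).  The null-frame
    probability (~0.17) and the small/medium/large mixture (0.37/0.40/0.23)
    match the published per-size instance tallies.
    """

    frame_hw: tuple[int, int] = REFERENCE_SIZE
    split_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "train": 3242,
            "data1": 135,
            "data2": 86,
            "data3": 124,
            "data4": 432,
        }
    )
    null_frame_prob: float = 0.17
    extra_polyp_rate: float = 0.12
    size_mixture: tuple[float, float, float] = (0.37, 0.40, 0.23)
    seq_len_range: tuple[int, int] = (10, 30)
    train_sequence_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.size_mixture), 1.0, abs_tol=1e-9):
            raise ValueError("size mixture must sum to 1")
        if not (0.0 <= self.null_frame_prob <= 1.0):
            raise ValueError("null_frame_prob must be in [0, 1]")
        if any(n < 0 for n in self.split_counts.values()):
            raise ValueError("split counts must be non-negative")


@dataclass(frozen=True)
class PerturbationSpec:
    """Prediction error model; ``severity`` multiplies all rates per split."""

    miss_prob: float = 0.08
    spurious_rate: float = 0.10
    boundary_noise_px: float = 2.0
    offset_sd_px: float = 10.0
    scale_noise_sd: float = 0.05
    conf_base: float = 0.9
    conf_iou_penalty: float = 0.5
    conf_noise_sd: float = 0.05
    severity: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_prob <= 1.0):
            raise ValueError("miss_prob must be a probability")
        for name in ("spurious_rate", "boundary_noise_px", "offset_sd_px", "scale_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def identity(cls, seed: int = 0) -> "PerturbationSpec":
        """The zero-perturbation model: predictions equal the ground truth."""
        return cls(
            miss_prob=0.0,
            spurious_rate=0.0,
            boundary_noise_px=0.0,
            offset_sd_px=0.0,
            scale_noise_sd=0.0,
            conf_noise_sd=0.0,
            seed=seed,
        )

    def severity_for(self, split: str) -> float:
        return float(self.severity.get(split, 1.0))


@dataclass
class _Blob:
    """Parametric blob: centre, semi-axes, Fourier boundary modulation."""

    cy: float
    cx: float
    ry: float
    rx: float
    amps: np.ndarray  # amplitudes for harmonics m = 2, 3, 4
    phases: np.ndarray

    def copy(self) -> "_Blob":
        return _Blob(self.cy, self.cx, self.ry, self.rx, self.amps.copy(), self.phases.copy())


_THETA = np.linspace(0.0, 2.0 * np.pi, 721)


def _modulation(amps: np.ndarray, phases: np.ndarray, theta: np.ndarray) -> np.ndarray:
    out = np.ones_like(theta)
    for m, (a, ph) in enumerate(zip(amps, phases), start=2):
        out += a * np.cos(m * theta + ph)
    return out


def _blob_extent(blob: _Blob) -> tuple[float, float]:
    """Tight half-extents (hy, hx) of the blob outline around its centre."""
    b = _modulation(blob.amps, blob.phases, _THETA)
    x = blob.rx * b * np.cos(_THETA)
    y = blob.ry * b * np.sin(_THETA)
    return float(np.abs(y).max()), float(np.abs(x).max())


def _render_blob(blob: _Blob, shape: tuple[int, int]) -> Optional[tuple[slice, slice, np.ndarray]]:
    """Rasterise one blob; returns (row slice, col slice, patch) or None."""
    h, w = shape
    hy, hx = _blob_extent(blob)
    y0 = max(0, int(math.floor(blob.cy - hy)) - 1)
    y1 = min(h, int(math.ceil(blob.cy + hy)) + 2)
    x0 = max(0, int(math.floor(blob.cx - hx)) - 1)
    x1 = min(w, int(math.ceil(blob.cx + hx)) + 2)
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = (xx - blob.cx) / blob.rx
    v = (yy - blob.cy) / blob.ry
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    patch = rho <= _modulation(blob.amps, blob.phases, theta)
    if not patch.any():
        return None
    return slice(y0, y1), slice(x0, x1), patch


def _patch_bbox(ys: slice, xs: slice, patch: np.ndarray) -> BoundingBox:
    rows = np.any(patch, axis=1).nonzero()[0]
    cols = np.any(patch, axis=0).nonzero()[0]
    y0, y1 = int(rows[0]) + ys.start, int(rows[-1]) + ys.start + 1
    x0, x1 = int(cols[0]) + xs.start, int(cols[-1]) + xs.start + 1
    return BoundingBox(x=float(x0), y=float(y0), w=float(x1 - x0), h=float(y1 - y0))


def _sample_blob(
    rng: np.random.Generator,
    category: str,
    frame_hw: tuple[int, int],
) -> _Blob:
    """Sample a blob whose tight box lands inside the requested size band."""
    h, w = frame_hw
    lo, hi = _SIZE_BANDS[category]
    s = rng.uniform(lo, hi)  # sqrt of the target box area, native px
    q = math.exp(rng.uniform(math.log(0.75), math.log(4.0 / 3.0)))  # aspect w/h
    target_w = s * math.sqrt(q)
    target_h = s / math.sqrt(q)
    if target_w >= w - 6 or target_h >= h - 6:
        raise InfeasibleSpecError(
            f"{category} polyp (box {target_h:.0f}x{target_w:.0f}) does not fit a {h}x{w} frame"
        )
    amps = rng.uniform(0.0, 0.08, size=3)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    blob = _Blob(cy=0.0, cx=0.0, ry=target_h / 2.0, rx=target_w / 2.0, amps=amps, phases=phases)
    # Half-extents scale linearly with the semi-axes, so one correction makes
    # the outline's tight box hit the target exactly (up to rasterisation).
    hy, hx = _blob_extent(blob)
    blob.ry *= (target_h / 2.0) / hy
    blob.rx *= (target_w / 2.0) / hx
    hy, hx = _blob_extent(blob)
    blob.cy = rng.uniform(hy + 2.0, h - hy - 3.0)
    blob.cx = rng.uniform(hx + 2.0, w - hx - 3.0)
    return blob


@dataclass
class GroundTruthFixture:
    """In-memory ground truth bundle produced by :func:`generate_ground_truth`."""

    spec: SceneSpec
    records: list[FrameRecord]
    masks: dict[str, np.ndarray]
    instances: list[PolypInstance]
    blobs: dict[str, list[_Blob]]

    def splits(self) -> dict[str, str]:
        return {r.frame_id: r.split for r in self.records}

    def ground_truth_boxes(self) -> list[GroundTruthBox]:
        return [
            GroundTruthBox(frame_id=i.frame_id, bbox=i.bbox, size_category=i.size_category)
            for i in self.instances
        ]


def _frame_blobs(
    rng: np.random.Generator, spec: SceneSpec, categories: Sequence[str]
) -> list[_Blob]:
    return [_sample_blob(rng, c, spec.frame_hw) for c in categories]


def _realise_frame(
    fid: str,
    split: str,
    centre: str,
    modality: str,
    blobs: list[_Blob],
    spec: SceneSpec,
    fixture: GroundTruthFixture,
    sequence_id: Optional[str] = None,
    frame_index: Optional[int] = None,
) -> None:
    h, w = spec.frame_hw
    mask = np.zeros((h, w), dtype=bool)
    kept: list[_Blob] = []
    for blob in blobs:
        rendered = _render_blob(blob, (h, w))
        if rendered is None:
            continue
        ys, xs, patch = rendered
        mask[ys, xs] |= patch
        bbox = _patch_bbox(ys, xs, patch)
        category = categorize_polyp_size(bbox, (h, w))
        fixture.instances.append(PolypInstance(frame_id=fid, bbox=bbox, size_category=category))
        kept.append(blob)
    fixture.records.append(
        FrameRecord(
            frame_id=fid,
            centre_id=centre,
            modality=modality,
            split=split,
            sequence_id=sequence_id,
            frame_index=frame_index,
            height_px=h,
            width_px=w,
            mask_path=f"masks/{fid}.png",
        )
    )
    fixture.masks[fid] = mask
    fixture.blobs[fid] = kept


def _walk_blob(rng: np.random.Generator, blob: _Blob, frame_hw: tuple[int, int]) -> _Blob:
    """One random-walk step of a sequence blob, reflecting at frame edges."""
    h, w = frame_hw
    nxt = blob.copy()
    nxt.cy += rng.normal(0.0, 8.0)
    nxt.cx += rng.normal(0.0, 8.0)
    nxt.ry *= math.exp(rng.normal(0.0, 0.03))
    nxt.rx *= math.exp(rng.normal(0.0, 0.03))
    nxt.ry = min(nxt.ry, h / 2.5)
    nxt.rx = min(nxt.rx, w / 2.5)
    hy, hx = _blob_extent(nxt)
    lo_y, hi_y = hy + 2.0, h - hy - 3.0
    lo_x, hi_x = hx + 2.0, w - hx - 3.0
    if lo_y < hi_y:
        nxt.cy = _reflect(nxt.cy, lo_y, hi_y)
    if lo_x < hi_x:
        nxt.cx = _reflect(nxt.cx, lo_x, hi_x)
    return nxt


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    t = (v - lo) % (2.0 * span)
    return lo + (t if t <= span else 2.0 * span - t)


def _split_centre_modality(rng: np.random.Generator, split: str) -> tuple[str, str]:
    if split in _UNSEEN_CENTRE_SPLITS:
        centre = "C6"
    else:
        centre = f"C{rng.integers(1, 6)}"
    modality = "NBI" if split == "data1" else "WLE"
    return centre, modality


def generate_ground_truth(spec: SceneSpec) -> GroundTruthFixture:
    """Generate manifest, masks and instances for every requested split.

    Fully reproducible from ``spec.seed``: the same spec yields byte-identical
    masks and manifest.  Splits ``data3``/``data4`` (and a configurable
    fraction of ``train``) are organised as sequences whose blobs evolve by
    a bounded random walk; ``data1``/``data2`` are single frames.
    """
    rng = np.random.default_rng(spec.seed)
    fixture = GroundTruthFixture(spec=spec, records=[], masks={}, instances=[], blobs={})
    cats = np.array(["small", "medium", "large"])

    def sample_categories() -> list[str]:
        n = 1 + int(rng.poisson(spec.extra_polyp_rate))
        return list(rng.choice(cats, size=n, p=spec.size_mixture))

    for split, count in spec.split_counts.items():
        if count == 0:
            continue
        if split in _SEQUENCE_SPLITS:
            n_seq_frames = count
            n_single = 0
        elif split == "train":
            n_seq_frames = int(round(count * spec.train_sequence_fraction))
            n_single = count - n_seq_frames
        else:
            n_seq_frames = 0
            n_single = count

        for i in range(n_single):
            fid = f"{split}-f{i:05d}"
            centre, modality = _split_centre_modality(rng, split)
            blobs = [] if rng.random() < spec.null_frame_prob else _frame_blobs(
                rng, spec, sample_categories()
            )
            _realise_frame(fid, split, centre, modality, blobs, spec, fixture)

        produced = 0
        k = 0
        while produced < n_seq_frames:
            length = int(rng.integers(spec.seq_len_range[0], spec.seq_len_range[1] + 1))
            length = min(length, n_seq_frames - produced)
            sid = f"{split}-s{k:03d}"
            centre, modality = _split_centre_modality(rng, split)
            null_seq = rng.random() < spec.null_frame_prob
            blobs = [] if null_seq else _frame_blobs(rng, spec, sample_categories())
            for j in range(length):
                fid = f"{sid}-{j:03d}"
                _realise_frame(
                    fid, split, centre, modality, blobs, spec, fixture,
                    sequence_id=sid, frame_index=j,
                )
                blobs = [_walk_blob(rng, b, spec.frame_hw) for b in blobs]
            produced += length
            k += 1
    return fixture


@dataclass
class PredictionSet:
    """Simulated per-team predictions: masks plus scored detections."""

    pspec: PerturbationSpec
    masks: dict[str, np.ndarray]
    detections: list[Detection]


def simulate_predictions(
    fixture: GroundTruthFixture, pspec: PerturbationSpec
) -> PredictionSet:
    """Perturb the ground truth into plausible predictions.

    Every random draw happens before severity scaling, so the same seed with
    two different severity maps gives coupled error realisations; with the
    :meth:`PerturbationSpec.identity` model the output equals the ground
    truth exactly.
    """
    rng = np.random.default_rng(pspec.seed)
    h, w = fixture.spec.frame_hw
    pred_masks: dict[str, np.ndarray] = {}
    detections: list[Detection] = []
    boxes_by_frame: dict[str, list[PolypInstance]] = {}
    for inst in fixture.instances:
        boxes_by_frame.setdefault(inst.frame_id, []).append(inst)
    for rec in fixture.records:
        fid = rec.frame_id
        sev = pspec.severity_for(rec.split)
        gt_boxes = boxes_by_frame.get(fid, [])
        mask = np.zeros((h, w), dtype=bool)
        pred_blobs: list[_Blob] = []
        for blob in fixture.blobs[fid]:
            u = rng.random()
            d_cy, d_cx = rng.normal(0.0, 1.0, size=2)
            d_log_ry, d_log_rx = rng.normal(0.0, 1.0, size=2)
            d_amps = rng.normal(0.0, 1.0, size=3)
            if u < min(1.0, pspec.miss_prob * sev):
                continue
            nb = blob.copy()
            nb.cy += d_cy * pspec.offset_sd_px * sev
            nb.cx += d_cx * pspec.offset_sd_px * sev
            nb.ry *= math.exp(d_log_ry * pspec.scale_noise_sd * sev)
            nb.rx *= math.exp(d_log_rx * pspec.scale_noise_sd * sev)
            mean_r = (nb.ry + nb.rx) / 2.0
            if mean_r > 0 and pspec.boundary_noise_px > 0:
                nb.amps = nb.amps + d_amps * (pspec.boundary_noise_px * sev / mean_r)
                total = np.abs(nb.amps).sum()
                if total > 0.45:  # keep the outline star-shaped
                    nb.amps *= 0.45 / total
            pred_blobs.append(nb)
        n_spurious = int(rng.poisson(pspec.spurious_rate * sev))
        for _ in range(n_spurious):
            cat = "small" if rng.random() < 0.7 else "medium"
            pred_blobs.append(_sample_blob(rng, cat, (h, w)))
        for nb in pred_blobs:
            rendered = _render_blob(nb, (h, w))
            conf_noise = rng.normal(0.0, 1.0)
            if rendered is None:
                continue
            ys, xs, patch = rendered
            mask[ys, xs] |= patch
            bbox = _patch_bbox(ys, xs, patch)
            best_iou = max((iou(bbox, g.bbox) for g in gt_boxes), default=0.0)
            conf = pspec.conf_base - pspec.conf_iou_penalty * (1.0 - best_iou)
            conf += conf_noise * pspec.conf_noise_sd
            detections.append(
                Detection(frame_id=fid, bbox=bbox, confidence=float(np.clip(conf, 0.0, 1.0)))
            )
        pred_masks[fid] = mask
    return PredictionSet(pspec=pspec, masks=pred_masks, detections=detections)


@dataclass
class ChallengeFixture:
    """A full train + data1-data4 bundle with one simulated submission."""

    gt: GroundTruthFixture
    pred: PredictionSet
    out_dir: Optional[Path] = None


def generate_challenge_fixture(
    spec: SceneSpec,
    pspec: PerturbationSpec,
    out_dir: Optional[str | Path] = None,
    team: str = "synthetic",
) -> ChallengeFixture:
    """Ground truth plus one simulated team, optionally written to disk.

    The on-disk tree matches the manifest conventions::

        out/manifest.csv              out/masks/<frame_id>.png
        out/instances.csv             out/pred/<team>/masks/<frame_id>.png
        out/fixture.json              out/pred/<team>/detections.csv
    """
    gt = generate_ground_truth(spec)
    pred = simulate_predictions(gt, pspec)
    out_path: Optional[Path] = None
    if out_dir is not None:
        out_path = Path(out_dir)
        (out_path / "masks").mkdir(parents=True, exist_ok=True)
        team_dir = out_path / "pred" / team
        (team_dir / "masks").mkdir(parents=True, exist_ok=True)
        write_manifest_csv(gt.records, out_path / "manifest.csv")
        write_instances_csv(gt.instances, out_path / "instances.csv")
        for fid, mask in gt.masks.items():
            write_mask(mask, out_path / "masks" / f"{fid}.png")
        for fid, mask in pred.masks.items():
            write_mask(mask, team_dir / "masks" / f"{fid}.png")
        write_detections_csv(pred.detections, team_dir / "detections.csv")
        descriptor = {
            "scene_spec": _spec_dict(spec),
            "perturbation_spec": _spec_dict(pspec),
            "team": team,
            "n_frames": len(gt.records),
            "n_instances": len(gt.instances),
        }
        (out_path / "fixture.json").write_text(json.dumps(descriptor, indent=1))
    return ChallengeFixture(gt=gt, pred=pred, out_dir=out_path)


def _spec_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
        elif isinstance(v, Mapping):
            d[k] = dict(v)
    return d
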