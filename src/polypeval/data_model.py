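"""Manifest, polyp-size taxonomy, and file I/O for challenge-style datasets.

A dataset is described by two plain tables plus a directory of binary masks:

* a *manifest* with one row per frame (centre, modality, split, optional
  sequence membership, frame geometry, file references), and
* an *instance table* with one row per ground-truth polyp bounding box.

The test data is partitioned into four splits probing generalisation:
``data1`` (unseen modality, NBI), ``data2`` (unseen-centre single frames,
C6), ``data3`` (seen-centre sequences, the reference split) and ``data4``
(unseen-centre sequences, C6).  Polyp instances are sized on frames rescaled
to a common 540x720 reference resolution and classed as small / medium /
large; frames without any polyp are *null* frames.

Coordinate conventions: 0-based pixel coordinates, x rightward, y downward;
boxes are ``(x, y, w, h)`` covering the half-open region
``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CENTRES",
    "MODALITIES",
    "SPLITS",
    "TEST_SPLITS",
    "REFERENCE_SIZE",
    "SMALL_MAX_AREA",
    "LARGE_MIN_AREA",
    "ValidationError",
    "InvalidInstanceError",
    "QuotaError",
    "BoundingBox",
    "FrameRecord",
    "PolypInstance",
    "ManifestSummary",
    "categorize_polyp_size",
    "validate_manifest",
    "summarize_manifest",
    "compose_round",
    "read_manifest_csv",
    "write_manifest_csv",
    "read_instances_csv",
    "write_instances_csv",
    "read_manifest_json",
    "write_manifest_json",
    "read_mask",
    "write_mask",
]

CENTRES = ("C1", "C2", "C3", "C4", "C5", "C6")
MODALITIES = ("WLE", "NBI")
SPLITS = ("train", "data1", "data2", "data3", "data4")
TEST_SPLITS = ("data1", "data2", "data3", "data4")

#: Common resolution polyp sizes are referred to before categorisation.
REFERENCE_SIZE = (540, 720)

#: Area (px^2, at reference resolution) below which a box is "small".
SMALL_MAX_AREA = 100 * 100
#: Area (px^2, at reference resolution) above which a box is "large".
LARGE_MIN_AREA = 200 * 200

SIZE_CATEGORIES = ("small", "medium", "large")

MANIFEST_COLUMNS = [
    "frame_id",
    "centre_id",
    "modality",
    "split",
    "sequence_id",
    "frame_index",
    "height_px",
    "width_px",
    "image_path",
    "mask_path",
]
INSTANCE_COLUMNS = ["frame_id", "x", "y", "w", "h", "size_category"]


class ValidationError(ValueError):
    """A manifest or instance table violates a structural invariant."""


class InvalidInstanceError(ValidationError):
    """A polyp instance is geometrically invalid (e.g. non-positive box)."""


class QuotaError(ValidationError):
    """A round-composition quota exceeds the frames available in a split."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box ``(x, y, w, h)`` over ``[x, x+w) x [y, y+h)``."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w < 0 or self.h < 0:
            raise InvalidInstanceError(
                f"box width/height must be non-negative, got w={self.w}, h={self.h}"
            )

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


@dataclass(frozen=True)
class FrameRecord:
    """Identity and geometry of one video frame in the dataset."""

    frame_id: str
    centre_id: str
    modality: str
    split: str
    height_px: int
    width_px: int
    sequence_id: Optional[str] = None
    frame_index: Optional[int] = None
    image_path: Optional[str] = None
    mask_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.centre_id not in CENTRES:
            raise ValidationError(f"unknown centre {self.centre_id!r} for frame {self.frame_id!r}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r} for frame {self.frame_id!r}")
        if self.split not in SPLITS:
            raise ValidationError(f"unknown split {self.split!r} for frame {self.frame_id!r}")
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValidationError(f"non-positive frame size for frame {self.frame_id!r}")
        if (self.sequence_id is None) != (self.frame_index is None):
            raise ValidationError(
                f"frame {self.frame_id!r}: sequence_id and frame_index must be given together"
            )
        if self.frame_index is not None and self.frame_index < 0:
            raise ValidationError(f"frame {self.frame_id!r}: negative frame_index")
        # Split-level constraints of the challenge design.
        if self.split == "data1" and self.modality != "NBI":
            raise ValidationError(f"frame {self.frame_id!r}: data1 is the NBI split")
        if self.split in ("data2", "data4") and self.centre_id != "C6":
            raise ValidationError(f"frame {self.frame_id!r}: {self.split} is restricted to centre C6")
        if self.split == "data3" and (self.centre_id == "C6" or self.modality != "WLE"):
            raise ValidationError(
                f"frame {self.frame_id!r}: data3 holds WLE frames from seen centres C1-C5"
            )

    @property
    def size(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass(frozen=True)
class PolypInstance:
    """One ground-truth polyp box attached to a frame."""

    frame_id: str
    bbox: BoundingBox
    size_category: str

    def __post_init__(self) -> None:
        if self.size_category not in SIZE_CATEGORIES:
            raise ValidationError(
                f"unknown size category {self.size_category!r} on frame {self.frame_id!r}"
            )


def categorize_polyp_size(
    bbox: BoundingBox,
    native_size: tuple[int, int],
    reference_size: tuple[int, int] = REFERENCE_SIZE,
    rule: str = "area",
) -> str:
    """Classify a polyp box as ``small``/``medium``/``large``.

    The box is first rescaled from its native frame resolution to
    ``reference_size`` with independent per-axis scale factors.  Under the
    default ``"area"`` rule the scaled box area ``a`` is compared with the
    100x100 and 200x200 pixel landmarks: small when ``a < 100**2``, large
    when ``a > 200**2``, medium otherwise (both landmarks inclusive to
    medium).  The alternative ``"side"`` rule classifies per side instead:
    small when both scaled sides are < 100 px, large when both are > 200 px.

    Parameters
    ----------
    bbox
        Box in native-resolution pixels; must have positive width and height.
    native_size, reference_size
        ``(height, width)`` of the native frame and of the reference frame.
    rule
        ``"area"`` (default) or ``"side"``.
    """
    if bbox.w <= 0 or bbox.h <= 0:
        raise InvalidInstanceError(f"cannot size a degenerate box {bbox.as_tuple()}")
    nh, nw = native_size
    rh, rw = reference_size
    if nh <= 0 or nw <= 0:
        raise InvalidInstanceError(f"non-positive native frame size {native_size}")
    sw = bbox.w * (rw / nw)
    sh = bbox.h * (rh / nh)
    if rule == "area":
        a = sw * sh
        if a < SMALL_MAX_AREA:
            return "small"
        if a > LARGE_MIN_AREA:
            return "large"
        return "medium"
    if rule == "side":
        if sw < 100 and sh < 100:
            return "small"
        if sw > 200 and sh > 200:
            return "large"
        return "medium"
    raise ValueError(f"unknown size rule {rule!r}")


@dataclass(frozen=True)
class ManifestSummary:
    """Aggregate counts over a manifest plus its instance table."""

    frames_per_split: Mapping[str, int]
    frames_per_centre: Mapping[str, int]
    instances_per_size: Mapping[str, int]
    null_frames: int

    @property
    def total_frames(self) -> int:
        return sum(self.frames_per_split.values())

    @property
    def total_instances(self) -> int:
        return sum(self.instances_per_size.values())


def validate_manifest(
    records: Sequence[FrameRecord],
    instances: Sequence[PolypInstance] = (),
    size_rule: str = "area",
) -> None:
    """Check cross-record invariants; raise :class:`ValidationError` on failure.

    Per-record invariants (split/centre/modality constraints) are enforced at
    construction; this adds frame-id uniqueness, (sequence_id, frame_index)
    uniqueness, instance referential integrity, in-bounds boxes and
    consistency of stored size categories with :func:`categorize_polyp_size`.
    """
    seen_ids: set[str] = set()
    seen_seq: set[tuple[str, int]] = set()
    by_id: dict[str, FrameRecord] = {}
    for rec in records:
        if rec.frame_id in seen_ids:
            raise ValidationError(f"duplicate frame_id {rec.frame_id!r}")
        seen_ids.add(rec.frame_id)
        by_id[rec.frame_id] = rec
        if rec.sequence_id is not None:
            key = (rec.sequence_id, rec.frame_index)
            if key in seen_seq:
                raise ValidationError(f"duplicate (sequence_id, frame_index) {key}")
            seen_seq.add(key)
    dangling = sorted({inst.frame_id for inst in instances} - seen_ids)
    if dangling:
        raise ValidationError(f"instances reference unknown frames: {dangling}")
    for inst in instances:
        rec = by_id[inst.frame_id]
        b = inst.bbox
        if b.x < 0 or b.y < 0 or b.x2 > rec.width_px or b.y2 > rec.height_px:
            raise ValidationError(
                f"instance box {b.as_tuple()} outside frame {inst.frame_id!r} "
                f"({rec.height_px}x{rec.width_px})"
            )
        expected = categorize_polyp_size(b, rec.size, rule=size_rule)
        if expected != inst.size_category:
            raise ValidationError(
                f"instance on frame {inst.frame_id!r} stored as {inst.size_category!r} "
                f"but categorises as {expected!r}"
            )


def summarize_manifest(
    records: Sequence[FrameRecord], instances: Sequence[PolypInstance]
) -> ManifestSummary:
    """Per-split/per-centre frame counts, per-size instance counts, null frames."""
    known = {rec.frame_id for rec in records}
    dangling = sorted({inst.frame_id for inst in instances} - known)
    if dangling:
        raise ValidationError(f"instances reference unknown frames: {dangling}")
    frames_per_split = {s: 0 for s in SPLITS}
    frames_per_centre = {c: 0 for c in CENTRES}
    for rec in records:
        frames_per_split[rec.split] += 1
        frames_per_centre[rec.centre_id] += 1
    instances_per_size = {s: 0 for s in SIZE_CATEGORIES}
    frames_with_polyp: set[str] = set()
    for inst in instances:
        instances_per_size[inst.size_category] += 1
        frames_with_polyp.add(inst.frame_id)
    null_frames = len(known) - len(frames_with_polyp)
    return ManifestSummary(
        frames_per_split={s: n for s, n in frames_per_split.items() if n},
        frames_per_centre={c: n for c, n in frames_per_centre.items() if n},
        instances_per_size=instances_per_size,
        null_frames=null_frames,
    )


def compose_round(
    records: Sequence[FrameRecord],
    round_id: int,
    per_split_quota: Mapping[str, int],
    seed: int = 0,
) -> list[FrameRecord]:
    """Select a deterministic test subset honouring per-split quotas.

    Frames within each split are ordered by ``frame_id``; when a quota is
    smaller than the split a seeded sample without replacement is drawn
    (seed combined with the split index, so the subset depends only on
    manifest content, quotas and seed).  The challenge rounds used quotas of
    50+50+50 (round 1), 88+86+124 (round 2) and 135+86+124+432 (round 3).
    """
    if round_id not in (1, 2, 3):
        raise ValueError(f"round_id must be 1, 2 or 3, got {round_id}")
    by_split: dict[str, list[FrameRecord]] = {}
    for rec in records:
        by_split.setdefault(rec.split, []).append(rec)
    chosen: list[FrameRecord] = []
    for split, quota in per_split_quota.items():
        avail = sorted(by_split.get(split, []), key=lambda r: r.frame_id)
        if quota > len(avail):
            raise QuotaError(
                f"quota {quota} for split {split!r} exceeds available {len(avail)} frames"
            )
        if quota == len(avail):
            picked = avail
        else:
            rng = np.random.default_rng([seed, SPLITS.index(split)])
            idx = sorted(rng.choice(len(avail), size=quota, replace=False))
            picked = [avail[i] for i in idx]
        chosen.extend(picked)
    return chosen


# ---------------------------------------------------------------------------
# Serialisation: CSV (canonical) and JSON mirror, plus 8-bit PNG masks.

def write_manifest_csv(records: Sequence[FrameRecord], path: str | Path) -> None:
    df = pd.DataFrame([_record_row(rec) for rec in records], columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest_csv(path: str | Path) -> list[FrameRecord]:
    df = pd.read_csv(path, dtype={"sequence_id": "string"})
    return [_row_record(row) for row in df.to_dict("records")]


def write_instances_csv(instances: Sequence[PolypInstance], path: str | Path) -> None:
    rows = [
        {
            "frame_id": i.frame_id,
            "x": i.bbox.x,
            "y": i.bbox.y,
            "w": i.bbox.w,
            "h": i.bbox.h,
            "size_category": i.size_category,
        }
        for i in instances
    ]
    pd.DataFrame(rows, columns=INSTANCE_COLUMNS).to_csv(path, index=False)


def read_instances_csv(path: str | Path) -> list[PolypInstance]:
    df = pd.read_csv(path)
    return [
        PolypInstance(
            frame_id=str(r["frame_id"]),
            bbox=BoundingBox(float(r["x"]), float(r["y"]), float(r["w"]), float(r["h"])),
            size_category=str(r["size_category"]),
        )
        for r in df.to_dict("records")
    ]


def write_manifest_json(
    records: Sequence[FrameRecord],
    instances: Sequence[PolypInstance],
    path: str | Path,
) -> None:
    payload = {
        "frames": [_record_row(rec) for rec in records],
        "instances": [
            {
                "frame_id": i.frame_id,
                "x": i.bbox.x,
                "y": i.bbox.y,
                "w": i.bbox.w,
                "h": i.bbox.h,
                "size_category": i.size_category,
            }
            for i in instances
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_manifest_json(path: str | Path) -> tuple[list[FrameRecord], list[PolypInstance]]:
    payload = json.loads(Path(path).read_text())
    records = [_row_record(row) for row in payload["frames"]]
    instances = [
        PolypInstance(
            frame_id=row["frame_id"],
            bbox=BoundingBox(row["x"], row["y"], row["w"], row["h"]),
            size_category=row["size_category"],
        )
        for row in payload["instances"]
    ]
    return records, instances


def read_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel 8-bit mask PNG; any nonzero pixel is polyp."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    arr = (np.asarray(mask).astype(bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def _record_row(rec: FrameRecord) -> dict:
    return {
        "frame_id": rec.frame_id,
        "centre_id": rec.centre_id,
        "modality": rec.modality,
        "split": rec.split,
        "sequence_id": rec.sequence_id,
        "frame_index": rec.frame_index,
        "height_px": rec.height_px,
        "width_px": rec.width_px,
        "image_path": rec.image_path,
        "mask_path": rec.mask_path,
    }


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA:
        return None
    s = str(v)
    return s if s and s.lower() != "nan" else None


def _row_record(row: Mapping) -> FrameRecord:
    seq = _opt_str(row.get("sequence_id"))
    fi = row.get("frame_index")
    if fi is None or (isinstance(fi, float) and math.isnan(fi)):
        frame_index = None
    else:
        frame_index = int(fi)
    return FrameRecord(
        frame_id=str(row["frame_id"]),
        centre_id=str(row["centre_id"]),
        modality=str(row["modality"]),
        split=str(row["split"]),
        sequence_id=seq,
        frame_index=frame_index,
        height_px=int(row["height_px"]),
        width_px=int(row["width_px"]),
        image_path=_opt_str(row.get("image_path")),
        mask_path=_opt_str(row.get("mask_path")),
    )
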