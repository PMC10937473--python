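"""Frames, calibration, keypoint annotations and dataset splitting.

Coordinates are 0-based pixel indices at native image resolution, origin at
the top-left pixel center, x increasing rightward (columns), y increasing
downward (rows).  Per-axis pixel spacing (cm/px) is carried on every frame so
anisotropic calibration survives resizing.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "KeypointName",
    "FrameRecord",
    "Annotation",
    "Dataset",
    "AnnotationFormatError",
    "read_annotations",
    "write_annotations",
    "split_dataset",
]


class KeypointName(enum.IntEnum):
    """The four caliper landmarks, in anatomical order along the measurement axis.

    Anterior/posterior borders of the interventricular septum, then of the LV
    free wall.  The integer order is fixed and meaningful: consecutive pairs
    delimit the IVS, LV internal diameter and free-wall calipers.
    """

    SEPT_ANT = 0
    SEPT_POST = 1
    FW_ANT = 2
    FW_POST = 3


class Phase(str, enum.Enum):
    ED = "ED"
    ES = "ES"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class FrameRecord:
    """One image frame with its calibration metadata."""

    study_id: str
    frame_id: str
    image_path: str
    height_px: int
    width_px: int
    spacing_x_cm: float
    spacing_y_cm: float
    phase: Phase = Phase.UNKNOWN

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError(f"frame {self.frame_id}: non-positive dimensions")
        if self.spacing_x_cm <= 0 or self.spacing_y_cm <= 0:
            raise ValueError(f"frame {self.frame_id}: non-positive pixel spacing")


@dataclass(frozen=True)
class Annotation:
    """One rater's four (possibly missing) keypoints on one frame."""

    frame_id: str
    rater_id: str
    repeat_index: int
    points: Mapping[KeypointName, tuple[float, float] | None]

    def __post_init__(self) -> None:
        if self.repeat_index < 1:
            raise ValueError("repeat_index must be >= 1")
        pts = {k: (None if self.points.get(k) is None else tuple(map(float, self.points[k])))
               for k in KeypointName}
        object.__setattr__(self, "points", pts)

    def present(self) -> list[KeypointName]:
        return [k for k in KeypointName if self.points[k] is not None]

    def is_complete(self) -> bool:
        return len(self.present()) == 4


@dataclass
class Dataset:
    """Frames plus annotations; every annotation must resolve to a frame."""

    frames: list[FrameRecord] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.frame_id for f in self.frames]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate frame_id in dataset")
        known = set(ids)
        dangling = sorted({a.frame_id for a in self.annotations} - known)
        if dangling:
            raise ValueError(f"annotations reference unknown frame_id(s): {dangling}")

    def frame(self, frame_id: str) -> FrameRecord:
        for f in self.frames:
            if f.frame_id == frame_id:
                return f
        raise KeyError(frame_id)

    def annotations_for(self, frame_id: str) -> list[Annotation]:
        return [a for a in self.annotations if a.frame_id == frame_id]

    @property
    def study_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.frames:
            seen.setdefault(f.study_id, None)
        return list(seen)


class AnnotationFormatError(ValueError):
    """Malformed annotation file; carries the 1-based offending line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


_REQUIRED_KEYS = (
    "study_id", "frame_id", "image_path", "height_px", "width_px",
    "spacing_x_cm", "spacing_y_cm", "phase", "rater_id", "repeat_index", "points",
)


def _frame_from_obj(obj: dict) -> FrameRecord:
    return FrameRecord(
        study_id=str(obj["study_id"]),
        frame_id=str(obj["frame_id"]),
        image_path=str(obj["image_path"]),
        height_px=int(obj["height_px"]),
        width_px=int(obj["width_px"]),
        spacing_x_cm=float(obj["spacing_x_cm"]),
        spacing_y_cm=float(obj["spacing_y_cm"]),
        phase=Phase(obj["phase"]),
    )


def read_annotations(path: str | Path) -> Dataset:
    """Read a JSON-lines annotation file.

    One object per line carrying both frame metadata and one rater's points.
    ``rater_id: null`` lines register a frame without contributing an
    annotation (so frames with no labels round-trip).  Missing points are
    explicit nulls and come back as ``None``.
    """
    frames: dict[str, FrameRecord] = {}
    annotations: list[Annotation] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise AnnotationFormatError(line_no, f"invalid JSON ({exc.msg})") from exc
            missing = [k for k in _REQUIRED_KEYS if k not in obj]
            if missing:
                raise AnnotationFormatError(line_no, f"missing key(s) {missing}")
            try:
                frame = _frame_from_obj(obj)
            except (ValueError, KeyError) as exc:
                raise AnnotationFormatError(line_no, str(exc)) from exc
            prior = frames.get(frame.frame_id)
            if prior is not None and prior != frame:
                raise AnnotationFormatError(
                    line_no, f"inconsistent metadata for frame {frame.frame_id!r}")
            frames[frame.frame_id] = frame
            if obj["rater_id"] is None:
                continue
            raw_pts = obj["points"] or {}
            pts: dict[KeypointName, tuple[float, float] | None] = {}
            for name in KeypointName:
                v = raw_pts.get(name.name)
                if v is None:
                    pts[name] = None
                else:
                    x, y = float(v[0]), float(v[1])
                    if not (0 <= x < frame.width_px and 0 <= y < frame.height_px):
                        raise AnnotationFormatError(
                            line_no, f"{name.name} ({x}, {y}) outside frame bounds")
                    pts[name] = (x, y)
            try:
                annotations.append(Annotation(
                    frame_id=frame.frame_id,
                    rater_id=str(obj["rater_id"]),
                    repeat_index=int(obj["repeat_index"]),
                    points=pts,
                ))
            except ValueError as exc:
                raise AnnotationFormatError(line_no, str(exc)) from exc
    return Dataset(frames=list(frames.values()), annotations=annotations)


def _annotation_obj(frame: FrameRecord, ann: Annotation | None) -> dict:
    obj = {
        "study_id": frame.study_id,
        "frame_id": frame.frame_id,
        "image_path": frame.image_path,
        "height_px": frame.height_px,
        "width_px": frame.width_px,
        "spacing_x_cm": frame.spacing_x_cm,
        "spacing_y_cm": frame.spacing_y_cm,
        "phase": frame.phase.value,
        "rater_id": None,
        "repeat_index": 1,
        "points": None,
    }
    if ann is not None:
        obj["rater_id"] = ann.rater_id
        obj["repeat_index"] = ann.repeat_index
        obj["points"] = {k.name: (None if ann.points[k] is None else list(ann.points[k]))
                         for k in KeypointName}
    return obj


def write_annotations(dataset: Dataset, path: str | Path) -> None:
    """Write JSON-lines re-readable by :func:`read_annotations`.

    Coordinates are serialised with :func:`repr` (shortest round-trip decimal),
    so they survive write/read bit-identically.
    """
    by_frame: dict[str, list[Annotation]] = {f.frame_id: [] for f in dataset.frames}
    for a in dataset.annotations:
        by_frame[a.frame_id].append(a)
    with open(path, "w", encoding="utf-8") as fh:
        for frame in dataset.frames:
            anns = by_frame[frame.frame_id]
            if not anns:
                fh.write(json.dumps(_annotation_obj(frame, None)) + "\n")
            for ann in anns:
                fh.write(json.dumps(_annotation_obj(frame, ann)) + "\n")


def split_dataset(
    dataset: Dataset,
    train_fraction: float,
    seed: int,
    granularity: str = "study",
) -> tuple[Dataset, Dataset]:
    """Deterministic train/test split.

    ``granularity="study"`` (default) keeps every frame of one study on the
    same side, preventing leakage of near-duplicate frames from a single scan;
    ``"frame"`` splits frames independently.  The train side receives
    ``floor(train_fraction * n_units)`` units.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    if granularity not in ("study", "frame"):
        raise ValueError(f"unknown granularity {granularity!r}")
    rng = np.random.default_rng(seed)
    if granularity == "study":
        units = dataset.study_ids
        if len(units) < 2:
            raise ValueError("need at least 2 studies to split at study level")
        order = list(np.array(units, dtype=object)[rng.permutation(len(units))])
        n_train = math.floor(train_fraction * len(order))
        train_units = set(order[:n_train])
        in_train = lambda f: f.study_id in train_units  # noqa: E731
    else:
        units = [f.frame_id for f in dataset.frames]
        if len(units) < 2:
            raise ValueError("need at least 2 frames to split at frame level")
        order = list(np.array(units, dtype=object)[rng.permutation(len(units))])
        n_train = math.floor(train_fraction * len(order))
        train_units = set(order[:n_train])
        in_train = lambda f: f.frame_id in train_units  # noqa: E731

    def subset(pred) -> Dataset:
        frames = [f for f in dataset.frames if pred(f)]
        ids = {f.frame_id for f in frames}
        anns = [a for a in dataset.annotations if a.frame_id in ids]
        return Dataset(frames=frames, annotations=anns)

    return subset(in_train), subset(lambda f: not in_train(f))
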