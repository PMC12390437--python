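"""Core domain types and file I/O.

The toolkit monitors birds moving through an electrical water-bath stunning
line.  Everything downstream — tracking, evaluation, the digital twin — works
on a handful of small record types defined here:

* :class:`BoundingBox` / :class:`Detection` / :class:`GroundTruthBox` for the
  vision side (boxes are stored center-format, continuous coordinates,
  image origin top-left);
* :class:`EEGTrace` for brainwave recordings (time in seconds, amplitude in
  millivolts);
* :class:`VisualJudgement` for the behavioural consciousness checklist;
* :class:`TwinEvent` for the digital twin's timestamped event stream.

I/O round-trips are exact: writing a list of records and reading it back
yields equal records for every supported dialect.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STUNNED",
    "UNSTUNNED",
    "CLASS_NAMES",
    "BoundingBox",
    "Detection",
    "GroundTruthBox",
    "EEGTrace",
    "VisualJudgement",
    "TwinEvent",
    "ValidationError",
    "ParseError",
    "read_detections",
    "write_detections",
    "read_eeg",
    "write_eeg",
    "read_events",
    "write_events",
    "read_ground_truth_coco",
    "write_ground_truth_coco",
]

STUNNED = "stunned"
UNSTUNNED = "unstunned"
CLASS_NAMES = (STUNNED, UNSTUNNED)

DETECTION_CSV_COLUMNS = ["frame", "label", "cx", "cy", "w", "h", "score"]


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. non-positive box width)."""


class ParseError(ValueError):
    """A file could not be parsed under the requested dialect."""


def _canonical_label(label: str) -> str:
    low = str(label).strip().lower()
    if low not in CLASS_NAMES:
        raise ValidationError(
            f"unknown class {label!r}: expected one of {CLASS_NAMES}"
        )
    return low


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in center format (cx, cy, w, h), pixels.

    Coordinates are continuous (sub-pixel); the image origin is top-left.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "w", "h"):
            val = getattr(self, name)
            if not math.isfinite(val):
                raise ValidationError(f"box field {name!r} is not finite: {val!r}")
        if self.w <= 0:
            raise ValidationError(f"box width w must be > 0, got {self.w}")
        if self.h <= 0:
            raise ValidationError(f"box height h must be > 0, got {self.h}")

    @property
    def x1(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "BoundingBox":
        return cls((x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        """From COCO top-left (x, y, w, h)."""
        return cls(x + w / 2.0, y + h / 2.0, w, h)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.w, self.h)


@dataclass(frozen=True)
class Detection:
    """One detector output: box + confidence + predicted class at a frame."""

    box: BoundingBox
    score: float
    label: str
    frame: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", _canonical_label(self.label))
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score must lie in [0, 1], got {self.score}")
        if self.frame < 0:
            raise ValidationError(f"frame must be non-negative, got {self.frame}")


@dataclass(frozen=True)
class GroundTruthBox:
    """An annotated box with a stable object identity for tracking tests."""

    box: BoundingBox
    label: str
    frame: int
    object_id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", _canonical_label(self.label))
        if self.frame < 0:
            raise ValidationError(f"frame must be non-negative, got {self.frame}")


@dataclass(frozen=True)
class EEGTrace:
    """A brainwave recording: strictly increasing time (s), amplitude (mV)."""

    t: np.ndarray
    v: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("t and v must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValidationError("EEG trace contains non-finite values")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("EEG time column must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    def __len__(self) -> int:
        return int(self.t.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EEGTrace):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.v, other.v)
            and self.sample_rate == other.sample_rate
        )


@dataclass(frozen=True)
class VisualJudgement:
    """Behavioural consciousness checklist for one bird after the bath."""

    raise_head: bool
    open_eyes: bool
    move_wing: bool
    weight: float  # kg
    voltage: float  # V

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError(f"weight must be > 0 kg, got {self.weight}")
        if self.voltage < 0:
            raise ValidationError(f"voltage must be >= 0 V, got {self.voltage}")


_STAGES = ("idle", "reception", "stunning", "cutting", "plucking")


@dataclass(frozen=True)
class TwinEvent:
    """One digital-twin tick: stage index 0-4, applied voltage, stun flag.

    ``stunned_flag`` is ``None`` outside the stunning stage (no EEG signal
    to threshold), otherwise the 12 mV monitor verdict at that instant.
    """

    t: float
    bird_id: str
    stage_index: int
    voltage: float
    stunned_flag: bool | None

    def __post_init__(self) -> None:
        if self.stage_index not in (0, 1, 2, 3, 4):
            raise ValidationError(
                f"stage_index must be in 0..4, got {self.stage_index}"
            )

    @property
    def stage_name(self) -> str:
        return _STAGES[self.stage_index]


# ---------------------------------------------------------------------------
# Detection I/O (CSV and COCO-style JSON)
# ---------------------------------------------------------------------------

def read_detections(path: str | Path, dialect: str = "csv") -> list[Detection]:
    """Read detections from ``path`` in the named dialect.

    Dialects: ``"csv"`` (columns frame, label, cx, cy, w, h, score) or
    ``"coco-json"`` (COCO-style ``annotations`` with top-left boxes and a
    ``score`` per annotation).  Record order is preserved.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_detections_csv(path)
    if dialect == "coco-json":
        return _read_detections_coco(path)
    raise ValueError(f"unknown dialect {dialect!r}: expected 'csv' or 'coco-json'")


def _read_detections_csv(path: Path) -> list[Detection]:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file with no header") from exc
    missing = [c for c in DETECTION_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out: list[Detection] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1 = header
        try:
            box = BoundingBox(float(row.cx), float(row.cy), float(row.w), float(row.h))
            out.append(
                Detection(box=box, score=float(row.score), label=str(row.label),
                          frame=int(row.frame))
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"{path}: line {i}: {exc}") from exc
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return out


def write_detections(detections: Sequence[Detection], path: str | Path,
                     dialect: str = "csv") -> None:
    path = Path(path)
    if dialect == "csv":
        rows = [
            {
                "frame": d.frame, "label": d.label,
                "cx": d.box.cx, "cy": d.box.cy, "w": d.box.w, "h": d.box.h,
                "score": d.score,
            }
            for d in detections
        ]
        pd.DataFrame(rows, columns=DETECTION_CSV_COLUMNS).to_csv(path, index=False)
    elif dialect == "coco-json":
        _write_detections_coco(detections, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _coco_categories() -> list[dict]:
    return [{"id": i + 1, "name": name} for i, name in enumerate(CLASS_NAMES)]


def _read_detections_coco(path: Path) -> list[Detection]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    cats = {c["id"]: c["name"] for c in doc.get("categories", _coco_categories())}
    frames = {img["id"]: int(img.get("frame", img["id"])) for img in doc.get("images", [])}
    out: list[Detection] = []
    for k, ann in enumerate(doc.get("annotations", [])):
        try:
            x, y, w, h = (float(u) for u in ann["bbox"])
            box = BoundingBox.from_xywh(x, y, w, h)
            label = cats[ann["category_id"]]
            frame = frames.get(ann["image_id"], int(ann["image_id"]))
            out.append(Detection(box=box, score=float(ann.get("score", 1.0)),
                                 label=label, frame=frame))
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: annotation {k}: missing/bad field {exc}") from exc
    return out


def _write_detections_coco(detections: Sequence[Detection], path: Path) -> None:
    frames = sorted({d.frame for d in detections})
    images = [{"id": f, "frame": f} for f in frames]
    cat_id = {name: i + 1 for i, name in enumerate(CLASS_NAMES)}
    annotations = []
    for k, d in enumerate(detections):
        x, y, w, h = d.box.to_xywh()
        annotations.append(
            {
                "id": k + 1,
                "image_id": d.frame,
                "category_id": cat_id[d.label],
                "bbox": [x, y, w, h],
                "score": d.score,
                "area": w * h,
                "iscrowd": 0,
            }
        )
    doc = {"images": images, "annotations": annotations,
           "categories": _coco_categories()}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_ground_truth_coco(path: str | Path) -> list[GroundTruthBox]:
    """Read annotations (COCO-style JSON) as ground-truth boxes.

    ``object_id`` is taken from the annotation's ``track_id`` field when
    present, else from the annotation id.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    cats = {c["id"]: c["name"] for c in doc.get("categories", _coco_categories())}
    frames = {img["id"]: int(img.get("frame", img["id"])) for img in doc.get("images", [])}
    out: list[GroundTruthBox] = []
    for k, ann in enumerate(doc.get("annotations", [])):
        try:
            x, y, w, h = (float(u) for u in ann["bbox"])
            out.append(
                GroundTruthBox(
                    box=BoundingBox.from_xywh(x, y, w, h),
                    label=cats[ann["category_id"]],
                    frame=frames.get(ann["image_id"], int(ann["image_id"])),
                    object_id=int(ann.get("track_id", ann.get("id", k))),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: annotation {k}: missing/bad field {exc}") from exc
    return out


def write_ground_truth_coco(gt: Sequence[GroundTruthBox], path: str | Path) -> None:
    frames = sorted({g.frame for g in gt})
    images = [{"id": f, "frame": f} for f in frames]
    cat_id = {name: i + 1 for i, name in enumerate(CLASS_NAMES)}
    annotations = []
    for k, g in enumerate(gt):
        x, y, w, h = g.box.to_xywh()
        annotations.append(
            {
                "id": k + 1,
                "image_id": g.frame,
                "category_id": cat_id[g.label],
                "bbox": [x, y, w, h],
                "track_id": g.object_id,
                "area": w * h,
                "iscrowd": 0,
            }
        )
    doc = {"images": images, "annotations": annotations,
           "categories": _coco_categories()}
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# EEG I/O
# ---------------------------------------------------------------------------

def read_eeg(path: str | Path) -> EEGTrace:
    """Read a two-column CSV (time_s, amplitude_mV) into an :class:`EEGTrace`.

    The sample rate is inferred from the median spacing of the time column.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    for col in ("time_s", "amplitude_mV"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    try:
        t = frame["time_s"].to_numpy(dtype=float)
        v = frame["amplitude_mV"].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from exc
    if t.size >= 2:
        dt = np.diff(t)
        if not np.all(dt > 0):
            bad = int(np.argmin(dt > 0)) + 2
            raise ValidationError(
                f"{path}: time column not strictly increasing at line {bad}"
            )
        rate = 1.0 / float(np.median(dt))
    else:
        rate = 1.0
    return EEGTrace(t=t, v=v, sample_rate=rate)


def write_eeg(trace: EEGTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.t, "amplitude_mV": trace.v}).to_csv(
        Path(path), index=False
    )


# ---------------------------------------------------------------------------
# Twin event stream (JSON Lines — the file-level stand-in for MQTT)
# ---------------------------------------------------------------------------

def write_events(events: Sequence[TwinEvent], path: str | Path) -> None:
    """Write twin events as JSON Lines; events must be time-ordered."""
    times = [e.t for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError("events must be time-ordered")
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps(dataclasses.asdict(e)) + "\n")


def read_events(path: str | Path) -> list[TwinEvent]:
    out: list[TwinEvent] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                out.append(
                    TwinEvent(
                        t=float(rec["t"]),
                        bird_id=str(rec["bird_id"]),
                        stage_index=int(rec["stage_index"]),
                        voltage=float(rec["voltage"]),
                        stunned_flag=rec["stunned_flag"],
                    )
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ParseError(f"{path}: line {i}: {exc}") from exc
    return out
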