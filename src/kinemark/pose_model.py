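"""Domain types and JSON I/O for pose-landmark and joint-angle time series.

The pipeline consumes per-frame 2D landmarks as produced by a standard
33-point pose estimator: coordinates are normalized to the frame
(origin top-left, x in fractions of width, y in fractions of height with
y increasing *downward*), and each landmark carries a visibility
confidence in [0, 1]. Only the eight lower-limb landmarks
(HIP / KNEE / ANKLE / FOOT_INDEX, left and right — indices 23–28 and
31–32 of the 33-point topology) participate in angle computation; any
other names present in an input file are tolerated and recorded in the
sequence metadata.

File schemas (UTF-8 JSON, fixed key order):

Landmark sequence::

    {"fps": float|null, "width_px": int|null, "height_px": int|null,
     "metadata": {...},
     "frames": [{"t": 0.0, "lm": {"LEFT_HIP": {"x": .5, "y": .4, "v": .99}, ...}}, ...]}

Angle series (written as a list under ``"series"``)::

    {"series": [{"joint": "knee", "side": "left", "convention": "raw_eq1",
                 "filtered": true, "filter_spec": {...}|null,
                 "samples": [{"t": 0.0, "deg": 12.3, "origin": "observed"}, ...]}]}
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "LANDMARK_VOCABULARY",
    "DEFAULT_VISIBILITY_THRESHOLD",
    "Landmark2D",
    "PoseFrame",
    "PoseSequence",
    "AngleSample",
    "JointAngleSeries",
    "PoseValidationError",
    "read_pose_json",
    "write_pose_json",
    "read_angles_json",
    "write_angles_json",
    "validate_sequence",
]

#: Lower-limb landmark vocabulary (33-point topology indices 23-28, 31-32).
LANDMARK_VOCABULARY = frozenset(
    f"{side}_{part}"
    for side in ("LEFT", "RIGHT")
    for part in ("HIP", "KNEE", "ANKLE", "FOOT_INDEX")
)

#: A landmark below this visibility counts as missing (conventional midpoint).
DEFAULT_VISIBILITY_THRESHOLD = 0.5


class PoseValidationError(ValueError):
    """Raised when an input file or sequence violates a documented invariant."""


class Landmark2D(BaseModel):
    """One named point in normalized image coordinates.

    ``x``/``y`` may be non-finite only when the point is effectively
    missing (visibility below the missing-threshold). ``interpolated``
    is in-memory provenance set by gap filling; it is not serialized.
    """

    model_config = ConfigDict(frozen=True)

    x: float
    y: float
    visibility: float = Field(ge=0.0, le=1.0)
    interpolated: bool = False

    @model_validator(mode="after")
    def _finite_when_visible(self) -> "Landmark2D":
        if self.visibility >= DEFAULT_VISIBILITY_THRESHOLD:
            if not (math.isfinite(self.x) and math.isfinite(self.y)):
                raise ValueError(
                    f"non-finite coordinates ({self.x}, {self.y}) on a visible landmark"
                )
        return self


class PoseFrame(BaseModel):
    """All landmarks observed at one timestamp (seconds)."""

    model_config = ConfigDict(frozen=True)

    timestamp: float = Field(ge=0.0)
    landmarks: dict[str, Landmark2D]

    @field_validator("landmarks")
    @classmethod
    def _known_names(cls, v: dict[str, Landmark2D]) -> dict[str, Landmark2D]:
        unknown = set(v) - LANDMARK_VOCABULARY
        if unknown:
            raise ValueError(f"unknown landmark names: {sorted(unknown)}")
        return v


class PoseSequence(BaseModel):
    """An ordered landmark recording: the pipeline's raw input."""

    frames: list[PoseFrame] = Field(min_length=1)
    frame_width_px: Optional[int] = Field(default=None, gt=0)
    frame_height_px: Optional[int] = Field(default=None, gt=0)
    nominal_fps: Optional[float] = Field(default=None, gt=0)
    metadata: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _strictly_increasing(self) -> "PoseSequence":
        ts = [f.timestamp for f in self.frames]
        for i in range(1, len(ts)):
            if ts[i] <= ts[i - 1]:
                raise ValueError(
                    f"timestamps not strictly increasing at frame {i}: "
                    f"{ts[i - 1]} -> {ts[i]}"
                )
        return self

    @property
    def timestamps(self) -> list[float]:
        return [f.timestamp for f in self.frames]


class AngleSample(BaseModel):
    """One joint angle observation in degrees (arccos range [0, 180])."""

    model_config = ConfigDict(frozen=True)

    timestamp: float
    value_deg: float = Field(ge=0.0, le=180.0)
    origin: str = "observed"

    @field_validator("origin")
    @classmethod
    def _origin_vocab(cls, v: str) -> str:
        if v not in ("observed", "interpolated"):
            raise ValueError(f"origin must be 'observed' or 'interpolated', got {v!r}")
        return v


class JointAngleSeries(BaseModel):
    """A per-frame angle trace for one joint, with processing provenance."""

    joint: str
    side: str
    samples: list[AngleSample]
    filtered: bool = False
    filter_spec: Optional[dict] = None
    convention: str = "raw_eq1"

    @field_validator("joint")
    @classmethod
    def _joint_vocab(cls, v: str) -> str:
        if v not in ("hip", "knee", "ankle"):
            raise ValueError(f"joint must be hip/knee/ankle, got {v!r}")
        return v

    @field_validator("side")
    @classmethod
    def _side_vocab(cls, v: str) -> str:
        if v not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {v!r}")
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "JointAngleSeries":
        ts = [s.timestamp for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("angle samples must have strictly increasing timestamps")
        return self

    def values(self) -> list[float]:
        return [s.value_deg for s in self.samples]

    def timestamps(self) -> list[float]:
        return [s.timestamp for s in self.samples]


# ---------------------------------------------------------------------------
# JSON I/O


def read_pose_json(path: str | Path) -> PoseSequence:
    """Read a landmark-sequence JSON file.

    Unknown landmark names are dropped from frames and recorded under
    ``metadata["unknown_landmarks"]``. Invariant violations (non-monotone
    timestamps, visibility outside [0, 1], malformed fields) raise
    :class:`PoseValidationError` naming the offending field.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise PoseValidationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(raw, dict) or "frames" not in raw:
        raise PoseValidationError(f"{path}: missing top-level 'frames' field")

    unknown: set[str] = set()
    frames: list[PoseFrame] = []
    for i, fr in enumerate(raw["frames"]):
        try:
            t = float(fr["t"])
            lm_raw = fr.get("lm", {})
        except (KeyError, TypeError, ValueError) as exc:
            raise PoseValidationError(f"frame {i}: malformed ('t'/'lm'): {exc}") from exc
        landmarks = {}
        for name, p in lm_raw.items():
            if name not in LANDMARK_VOCABULARY:
                unknown.add(name)
                continue
            try:
                landmarks[name] = Landmark2D(
                    x=float(p["x"]), y=float(p["y"]), visibility=float(p["v"])
                )
            except Exception as exc:
                raise PoseValidationError(f"frame {i}, landmark {name}: {exc}") from exc
        try:
            frames.append(PoseFrame(timestamp=t, landmarks=landmarks))
        except Exception as exc:
            raise PoseValidationError(f"frame {i}: {exc}") from exc

    metadata = dict(raw.get("metadata") or {})
    if unknown:
        metadata["unknown_landmarks"] = sorted(unknown)
    try:
        return PoseSequence(
            frames=frames,
            frame_width_px=raw.get("width_px"),
            frame_height_px=raw.get("height_px"),
            nominal_fps=raw.get("fps"),
            metadata=metadata,
        )
    except Exception as exc:
        raise PoseValidationError(f"{path}: {exc}") from exc


def write_pose_json(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence in the documented schema (deterministic key order)."""
    doc = {
        "fps": seq.nominal_fps,
        "width_px": seq.frame_width_px,
        "height_px": seq.frame_height_px,
        "metadata": seq.metadata,
        "frames": [
            {
                "t": f.timestamp,
                "lm": {
                    name: {"x": lm.x, "y": lm.y, "v": lm.visibility}
                    for name, lm in sorted(f.landmarks.items())
                },
            }
            for f in seq.frames
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def write_angles_json(series: list[JointAngleSeries], path: str | Path) -> None:
    """Serialize one or more angle series; read-back reproduces values to 1e-9°."""
    if not series:
        raise ValueError("series list must be non-empty")
    doc = {
        "series": [
            {
                "joint": s.joint,
                "side": s.side,
                "convention": s.convention,
                "filtered": s.filtered,
                "filter_spec": s.filter_spec,
                "samples": [
                    {"t": a.timestamp, "deg": a.value_deg, "origin": a.origin}
                    for a in s.samples
                ],
            }
            for s in series
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")


def read_angles_json(path: str | Path) -> list[JointAngleSeries]:
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise PoseValidationError(f"{path}: not valid JSON: {exc}") from exc
    out = []
    for s in raw.get("series", []):
        out.append(
            JointAngleSeries(
                joint=s["joint"],
                side=s["side"],
                convention=s["convention"],
                filtered=s["filtered"],
                filter_spec=s.get("filter_spec"),
                samples=[
                    AngleSample(timestamp=a["t"], value_deg=a["deg"], origin=a["origin"])
                    for a in s["samples"]
                ],
            )
        )
    return out


# ---------------------------------------------------------------------------


def is_missing(
    frame: PoseFrame, name: str, threshold: float = DEFAULT_VISIBILITY_THRESHOLD
) -> bool:
    """A landmark is missing when absent or below the visibility threshold."""
    lm = frame.landmarks.get(name)
    return lm is None or lm.visibility < threshold


def validate_sequence(
    seq: PoseSequence,
    required: set[str] | frozenset[str],
    threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> dict[str, int]:
    """Count, per required landmark, the frames where it is missing.

    Reporting only — the input is never mutated. Names outside the
    lower-limb vocabulary raise :class:`PoseValidationError`.
    """
    bad = set(required) - LANDMARK_VOCABULARY
    if bad:
        raise PoseValidationError(f"required names not in vocabulary: {sorted(bad)}")
    return {
        name: sum(is_missing(f, name, threshold) for f in seq.frames)
        for name in sorted(required)
    }
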