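"""Per-frame joint angles from landmark vectors.

Every angle is the unsigned angle between two segment vectors,

    theta = arccos( clamp(u . v / (|u| |v|), -1, 1) ) * 180 / pi,

with the cosine clamped to [-1, 1] so rounding can never produce NaN.
The three sagittal-plane joints are defined as:

* **hip** — thigh vector (hip → knee) against the fixed vertical axis
  (0, −1). Coordinates follow the pose-estimator convention (origin
  top-left, y increasing downward), so (0, −1) points *up-image*: a
  thigh hanging straight down reads 180° under the raw arccos
  (``raw_eq1``) and 0° under the clinical ``flexion`` convention
  (180° − raw), which measures deviation from upright posture. Both
  conventions are exposed; every sign ambiguity in 2D flows from this
  choice of axis, hence the explicit parameter.
* **knee** — thigh vector (hip → knee) against shank vector
  (knee → ankle); 0° is a straight leg, growing with flexion.
* **ankle** — shank vector (knee → ankle) against foot vector
  (ankle → toe); dorsiflexion/plantarflexion.

When the frame's pixel dimensions are known, normalized coordinates are
mapped to the aspect-corrected plane (x·width, y·height) before taking
vectors — angles measured in raw normalized space are distorted for
non-square frames. Without dimensions the raw coordinates are used and
a warning is logged once per sequence.

Zero-length segment vectors (coincident landmarks) indicate tracking
failure; the frame raises :class:`DegenerateGeometryError` rather than
silently reading 0°, and the batch pipeline skips and logs it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .pose_model import (
    AngleSample,
    JointAngleSeries,
    PoseFrame,
    PoseSequence,
)
from .preprocess import (
    FilterSpec,
    butterworth_lowpass,
    interpolate_gaps,
    median_fs,
    resample_uniform,
)

__all__ = [
    "Vector2",
    "JOINT_LANDMARKS",
    "DegenerateGeometryError",
    "MissingLandmarkError",
    "angle_between",
    "hip_angle",
    "knee_angle",
    "ankle_angle",
    "compute_angle_series",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9

#: Landmarks each joint needs, in proximal-to-distal order (side prefix added).
JOINT_LANDMARKS = {
    "hip": ("HIP", "KNEE"),
    "knee": ("HIP", "KNEE", "ANKLE"),
    "ankle": ("KNEE", "ANKLE", "FOOT_INDEX"),
}


class DegenerateGeometryError(ValueError):
    """Coincident landmarks produced a zero-length segment vector."""


class MissingLandmarkError(KeyError):
    """A landmark required by the joint definition is absent from the frame."""


@dataclass(frozen=True)
class Vector2:
    dx: float
    dy: float

    @property
    def norm(self) -> float:
        return math.hypot(self.dx, self.dy)


#: The fixed vertical reference axis: up-image in y-down coordinates.
VERTICAL_UP = Vector2(0.0, -1.0)


def angle_between(u: Vector2, v: Vector2) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180]."""
    nu, nv = u.norm, v.norm
    if nu <= _EPS or nv <= _EPS:
        raise DegenerateGeometryError(
            f"zero-length vector (|u|={nu:.3g}, |v|={nv:.3g})"
        )
    c = (u.dx * v.dx + u.dy * v.dy) / (nu * nv)
    c = min(1.0, max(-1.0, c))
    return math.degrees(math.acos(c))


def _point(
    frame: PoseFrame,
    name: str,
    width: Optional[float],
    height: Optional[float],
) -> tuple[float, float]:
    lm = frame.landmarks.get(name)
    if lm is None:
        raise MissingLandmarkError(f"{name} absent at t={frame.timestamp}")
    if width is not None and height is not None:
        return lm.x * width, lm.y * height
    return lm.x, lm.y


def _segment(
    frame: PoseFrame,
    a: str,
    b: str,
    width: Optional[float],
    height: Optional[float],
) -> Vector2:
    ax, ay = _point(frame, a, width, height)
    bx, by = _point(frame, b, width, height)
    return Vector2(bx - ax, by - ay)


def hip_angle(
    frame: PoseFrame,
    side: str = "left",
    convention: str = "raw_eq1",
    width: Optional[float] = None,
    height: Optional[float] = None,
) -> float:
    """Angle of the thigh (hip → knee) to the vertical axis (0, −1)."""
    s = side.upper()
    thigh = _segment(frame, f"{s}_HIP", f"{s}_KNEE", width, height)
    raw = angle_between(thigh, VERTICAL_UP)
    if convention == "raw_eq1":
        return raw
    if convention == "flexion":
        return 180.0 - raw
    raise ValueError(f"unknown convention {convention!r}")


def knee_angle(
    frame: PoseFrame,
    side: str = "left",
    width: Optional[float] = None,
    height: Optional[float] = None,
) -> float:
    """Angle between thigh (hip → knee) and shank (knee → ankle); 0° = straight."""
    s = side.upper()
    thigh = _segment(frame, f"{s}_HIP", f"{s}_KNEE", width, height)
    shank = _segment(frame, f"{s}_KNEE", f"{s}_ANKLE", width, height)
    return angle_between(thigh, shank)


def ankle_angle(
    frame: PoseFrame,
    side: str = "left",
    width: Optional[float] = None,
    height: Optional[float] = None,
) -> float:
    """Angle between shank (knee → ankle) and foot (ankle → toe)."""
    s = side.upper()
    shank = _segment(frame, f"{s}_KNEE", f"{s}_ANKLE", width, height)
    foot = _segment(frame, f"{s}_ANKLE", f"{s}_FOOT_INDEX", width, height)
    return angle_between(shank, foot)


def _frame_angle(
    frame: PoseFrame,
    joint: str,
    side: str,
    convention: str,
    width: Optional[float],
    height: Optional[float],
) -> float:
    if joint == "hip":
        return hip_angle(frame, side, convention, width, height)
    if joint == "knee":
        return knee_angle(frame, side, width, height)
    if joint == "ankle":
        return ankle_angle(frame, side, width, height)
    raise ValueError(f"unknown joint {joint!r}")


def compute_angle_series(
    seq: PoseSequence,
    joints: Sequence[str] = ("hip", "knee", "ankle"),
    side: str = "left",
    convention: str = "raw_eq1",
    filter_spec: Optional[FilterSpec] = None,
    apply_filter: bool = False,
    fs_hz: Optional[float] = None,
    visibility_threshold: float = 0.5,
) -> list[JointAngleSeries]:
    """Full per-joint pipeline: interpolate gaps → angles → resample → filter.

    With ``apply_filter`` (or an explicit ``filter_spec``) the angle
    trace is resampled onto a uniform grid — median observed frame rate
    unless ``fs_hz`` overrides — then Butterworth-smoothed. Without it,
    raw per-frame angles on the original timestamps are returned.
    A resampled sample is flagged ``interpolated`` when its nearest
    source frame used gap-filled landmarks. Frames with degenerate
    geometry are skipped and logged with their timestamp.
    """
    if seq.frame_width_px is None or seq.frame_height_px is None:
        logger.warning(
            "frame dimensions unknown; computing angles on raw normalized "
            "coordinates (distorted for non-square frames)"
        )
        w = h = None
    else:
        w, h = float(seq.frame_width_px), float(seq.frame_height_px)

    required = {
        f"{side.upper()}_{part}" for j in joints for part in JOINT_LANDMARKS[j]
    }
    seq = interpolate_gaps(seq, sorted(required), visibility_threshold)

    out: list[JointAngleSeries] = []
    for joint in joints:
        names = [f"{side.upper()}_{p}" for p in JOINT_LANDMARKS[joint]]
        ts: list[float] = []
        vals: list[float] = []
        interp: list[bool] = []
        for frame in seq.frames:
            try:
                deg = _frame_angle(frame, joint, side, convention, w, h)
            except DegenerateGeometryError as exc:
                logger.warning("skipping %s at t=%s: %s", joint, frame.timestamp, exc)
                continue
            ts.append(frame.timestamp)
            vals.append(deg)
            interp.append(any(frame.landmarks[n].interpolated for n in names))

        if not ts:
            raise DegenerateGeometryError(f"no computable frames for joint {joint}")

        do_filter = apply_filter or filter_spec is not None
        if do_filter:
            rate = fs_hz or (filter_spec.fs_hz if filter_spec else None) or median_fs(ts)
            spec = filter_spec or FilterSpec(fs_hz=rate)
            if spec.fs_hz != rate:
                spec = spec.model_copy(update={"fs_hz": rate})
            grid, gvals = resample_uniform(ts, vals, spec.fs_hz)
            fvals = np.clip(butterworth_lowpass(gvals, spec), 0.0, 180.0)
            src = np.asarray(ts)
            nearest = np.searchsorted(src, grid)
            nearest = np.clip(nearest, 0, len(ts) - 1)
            left = np.clip(nearest - 1, 0, len(ts) - 1)
            use_left = np.abs(src[left] - grid) < np.abs(src[nearest] - grid)
            nearest = np.where(use_left, left, nearest)
            samples = [
                AngleSample(
                    timestamp=float(t),
                    value_deg=float(vv),
                    origin="interpolated" if interp[k] else "observed",
                )
                for t, vv, k in zip(grid, fvals, nearest)
            ]
            out.append(
                JointAngleSeries(
                    joint=joint,
                    side=side,
                    convention=convention,
                    filtered=True,
                    filter_spec=spec.model_dump(),
                    samples=samples,
                )
            )
        else:
            samples = [
                AngleSample(
                    timestamp=t,
                    value_deg=v,
                    origin="interpolated" if flag else "observed",
                )
                for t, v, flag in zip(ts, vals, interp)
            ]
            out.append(
                JointAngleSeries(
                    joint=joint,
                    side=side,
                    convention=convention,
                    filtered=False,
                    samples=samples,
                )
            )
    return out
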