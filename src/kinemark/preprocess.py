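"""Gap interpolation, uniform resampling, and Butterworth smoothing.

Pose landmarks drop out whenever the estimator loses a point (occlusion,
motion blur, frame edges). Missing runs are filled by straight-line
interpolation in time between the last valid and next valid coordinate,
per coordinate; leading/trailing runs, which have no bracket on one
side, are held at the nearest valid value.

Capture runs at a variable 15–20 Hz, while a fixed-cutoff digital filter
needs a constant sampling rate, so angle traces are linearly resampled
onto a uniform grid (median observed rate by default) before smoothing
with a 4th-order Butterworth low-pass at 6 Hz — the biomechanics
convention for suppressing frame-to-frame jitter while preserving
physiological motion. The default is zero-phase (forward–backward)
filtering: offline analysis should not carry phase lag; the single-pass
``causal`` mode mirrors what a streaming deployment would apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import signal

from .pose_model import (
    DEFAULT_VISIBILITY_THRESHOLD,
    LANDMARK_VOCABULARY,
    Landmark2D,
    PoseFrame,
    PoseSequence,
    PoseValidationError,
    is_missing,
)

__all__ = [
    "GapRecord",
    "FilterSpec",
    "detect_gaps",
    "interpolate_gaps",
    "resample_uniform",
    "butterworth_lowpass",
    "median_fs",
]


@dataclass(frozen=True)
class GapRecord:
    """A maximal run of missing frames for one landmark.

    ``bracketing_valid`` holds the (left, right) valid frame indices when
    both exist; a leading/trailing run has ``None`` on the open side.
    """

    landmark: str
    start_index: int
    end_index: int  # inclusive
    bracketing_valid: tuple[Optional[int], Optional[int]]

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")

    @property
    def bracketed(self) -> bool:
        left, right = self.bracketing_valid
        return left is not None and right is not None


class FilterSpec(BaseModel):
    """Butterworth low-pass parameters (order 4, 6 Hz cutoff by default)."""

    order: int = Field(default=4, gt=0)
    cutoff_hz: float = Field(default=6.0, gt=0)
    fs_hz: float = Field(gt=0)
    mode: str = "zero_phase"

    @model_validator(mode="after")
    def _check(self) -> "FilterSpec":
        if self.cutoff_hz >= self.fs_hz / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must be below Nyquist {self.fs_hz / 2} Hz"
            )
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError("mode must be 'zero_phase' or 'causal'")
        return self

    @property
    def min_samples(self) -> int:
        # shortest series the zero-phase edge handling supports
        return 3 * (self.order + 1)


def detect_gaps(
    seq: PoseSequence,
    landmark: str,
    threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> list[GapRecord]:
    """Locate maximal missing runs of one landmark across a sequence."""
    if landmark not in LANDMARK_VOCABULARY:
        raise PoseValidationError(f"{landmark!r} not in landmark vocabulary")
    missing = [is_missing(f, landmark, threshold) for f in seq.frames]
    n = len(missing)
    gaps: list[GapRecord] = []
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and missing[j + 1]:
            j += 1
        left = i - 1 if i > 0 else None
        right = j + 1 if j + 1 < n else None
        gaps.append(GapRecord(landmark, i, j, (left, right)))
        i = j + 1
    return gaps


def interpolate_gaps(
    seq: PoseSequence,
    required: Sequence[str] | None = None,
    threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
) -> PoseSequence:
    """Fill missing landmark runs by per-coordinate linear interpolation.

    Bracketed gaps get the straight-line fill in timestamp,
    ``v(t) = v0 + (v1 - v0) * (t - t0) / (t1 - t0)``; unbracketed
    leading/trailing runs are held at the nearest valid value. Filled
    landmarks are flagged ``interpolated`` and given visibility 1.0;
    observed landmarks pass through untouched, so the operation is
    idempotent.
    """
    names = list(required) if required is not None else sorted(
        {n for f in seq.frames for n in f.landmarks}
    )
    ts = np.asarray(seq.timestamps)
    filled: dict[int, dict[str, Landmark2D]] = {i: {} for i in range(len(seq.frames))}

    for name in names:
        if name not in LANDMARK_VOCABULARY:
            raise PoseValidationError(f"{name!r} not in landmark vocabulary")
        valid_idx = [
            i for i, f in enumerate(seq.frames) if not is_missing(f, name, threshold)
        ]
        if len(valid_idx) < 2:
            raise PoseValidationError(
                f"landmark {name} has {len(valid_idx)} valid frame(s); "
                "need >= 2 to interpolate"
            )
        vt = ts[valid_idx]
        vx = np.array([seq.frames[i].landmarks[name].x for i in valid_idx])
        vy = np.array([seq.frames[i].landmarks[name].y for i in valid_idx])
        for gap in detect_gaps(seq, name, threshold):
            for i in range(gap.start_index, gap.end_index + 1):
                # np.interp holds edge values on unbracketed runs
                x = float(np.interp(ts[i], vt, vx))
                y = float(np.interp(ts[i], vt, vy))
                filled[i][name] = Landmark2D(
                    x=x, y=y, visibility=1.0, interpolated=True
                )

    frames = []
    for i, f in enumerate(seq.frames):
        if filled[i]:
            frames.append(
                PoseFrame(timestamp=f.timestamp, landmarks={**f.landmarks, **filled[i]})
            )
        else:
            frames.append(f)
    return PoseSequence(
        frames=frames,
        frame_width_px=seq.frame_width_px,
        frame_height_px=seq.frame_height_px,
        nominal_fps=seq.nominal_fps,
        metadata=seq.metadata,
    )


def median_fs(timestamps: Sequence[float]) -> float:
    """Median instantaneous frame rate of a timestamp vector."""
    dt = np.diff(np.asarray(timestamps, dtype=float))
    if dt.size == 0:
        raise ValueError("need >= 2 timestamps to estimate a frame rate")
    return float(1.0 / np.median(dt))


def resample_uniform(
    timestamps: Sequence[float],
    values: Sequence[float],
    fs_hz: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto the uniform grid t0, t0 + 1/fs, ... <= t_last."""
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 samples to resample")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    n = int(np.floor((t[-1] - t[0]) * fs_hz + 1e-9)) + 1
    grid = t[0] + np.arange(n) / fs_hz
    return grid, np.interp(grid, t, v)


def butterworth_lowpass(values: Sequence[float], spec: FilterSpec) -> np.ndarray:
    """Apply the Butterworth low-pass to a uniformly sampled series.

    ``zero_phase`` runs the filter forward then backward (no phase lag,
    squared magnitude response), with Gustafsson initial conditions so
    the forward-backward and backward-forward passes agree exactly —
    this makes the operator precisely time-reversal symmetric, which
    simple edge padding only approximates. ``causal`` is a single
    forward pass started at the DC steady state of the first sample.
    """
    x = np.asarray(values, dtype=float)
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.fs_hz)
    if spec.mode == "causal":
        if x.size < 2:
            raise ValueError("series too short to filter")
        zi = signal.lfilter_zi(b, a) * x[0]  # start at steady state for the DC level
        y, _ = signal.lfilter(b, a, x, zi=zi)
        return y
    if x.size <= spec.min_samples:
        raise ValueError(
            f"series length {x.size} <= {spec.min_samples}; too short to filter"
        )
    return signal.filtfilt(b, a, x, method="gust")
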