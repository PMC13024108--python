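"""Synthetic fixtures with known ground truth.

Two generators support validation of the pipeline end to end:

* :func:`simulate_motion` poses a sagittal-plane lower-limb chain
  (hip fixed; thigh/shank/foot segments of plausible on-screen
  proportions) driven by a raised-cosine flexion profile, projects the
  joints to y-down normalized coordinates, and returns both the
  landmark sequence and the analytic angle ground truth. The raised
  cosine is C¹-smooth and slow relative to the 6 Hz filter cutoff, so
  smoothing passes it essentially unchanged — degradations (coordinate
  noise, visibility dropout, frame-interval jitter) are therefore the
  only things a recovery test can fail on.

* :func:`simulate_two_way_table` draws paired clinical/algorithm values
  from a two-way model ``x_ij = mu + subject_i + offset_j + e_ij`` with
  known variance components, echoing the population ICC(A,1)
  ``subject_sd² / (subject_sd² + rater_offset²/2 + error_sd²)`` in the
  output metadata.

All randomness flows from the spec's single seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .agreement import PairedMeasurements
from .pose_model import Landmark2D, PoseFrame, PoseSequence

__all__ = [
    "SyntheticMotionSpec",
    "SyntheticTruth",
    "simulate_motion",
    "degrade_sequence",
    "simulate_two_way_table",
]

# plausible on-screen segment proportions for a full-body ~2.5 m capture
THIGH_LEN = 0.22
SHANK_LEN = 0.20
FOOT_LEN = 0.07

_HIP_ORIGIN = (0.45, 0.35)
_FRAME_PX = 1080  # square frame: aspect correction is a pure scale


class SyntheticMotionSpec(BaseModel):
    """Parameters of one simulated flexion-extension recording."""

    joint: str = "knee"
    peak_deg: float = Field(default=90.0, gt=0, lt=180)
    n_reps: int = Field(default=3, ge=1)
    rep_period_s: float = Field(default=3.0, gt=0)
    fps_hz: float = Field(default=18.0, gt=0)
    duration_s: float | None = None
    noise_sd_norm: float = Field(default=0.0, ge=0)
    dropout_prob: float = Field(default=0.0, ge=0, lt=1)
    jitter_frac: float = Field(default=0.15, ge=0, lt=0.5)
    side: str = "left"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticMotionSpec":
        if self.joint not in ("hip", "knee"):
            raise ValueError("joint must be 'hip' or 'knee'")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        return self

    @property
    def total_duration_s(self) -> float:
        return self.duration_s or self.n_reps * self.rep_period_s


@dataclass(frozen=True)
class SyntheticTruth:
    """Analytic ground truth accompanying a simulated sequence."""

    timestamps: np.ndarray
    angles_deg: dict[str, np.ndarray]  # joint -> truth series (flexion for hip)
    repetition_peaks: list[float]
    spec: SyntheticMotionSpec = field(repr=False, default=None)


def _flexion_profile(t: np.ndarray, peak_deg: float, period_s: float) -> np.ndarray:
    """Raised-cosine repetitions: 0 at rep boundaries, peak at mid-rep."""
    phase = (t % period_s) / period_s
    return peak_deg * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


def _jittered_timestamps(spec: SyntheticMotionSpec, rng: np.random.Generator) -> np.ndarray:
    n = int(np.floor(spec.total_duration_s * spec.fps_hz)) + 1
    dt = (1.0 / spec.fps_hz) * (1.0 + spec.jitter_frac * rng.uniform(-1, 1, size=n - 1))
    return np.concatenate([[0.0], np.cumsum(dt)])


def simulate_motion(spec: SyntheticMotionSpec) -> tuple[PoseSequence, SyntheticTruth]:
    """Generate a landmark sequence plus its analytic angle ground truth.

    The chain hangs from a fixed hip. For ``joint='knee'`` the thigh
    stays vertical and the shank swings forward by the flexion profile;
    for ``joint='hip'`` the whole straight leg rotates forward (a leg
    raise). The foot is held at 90° to the shank throughout. Truth hip
    angles use the clinical flexion convention (0° = upright thigh).
    """
    rng = np.random.default_rng(spec.seed)
    t = _jittered_timestamps(spec, rng)
    theta = np.radians(_flexion_profile(t, spec.peak_deg, spec.rep_period_s))

    hx, hy = _HIP_ORIGIN
    if spec.joint == "hip":
        thigh_dir = np.stack([np.sin(theta), np.cos(theta)], axis=1)
        shank_dir = thigh_dir  # straight knee
    else:
        thigh_dir = np.tile([0.0, 1.0], (len(t), 1))  # vertical, down-image
        shank_dir = np.stack([np.sin(theta), np.cos(theta)], axis=1)

    knee = np.array([hx, hy]) + THIGH_LEN * thigh_dir
    ankle = knee + SHANK_LEN * shank_dir
    # foot perpendicular to shank, pointing "forward" (rotate shank by -90°)
    foot_dir = np.stack([shank_dir[:, 1], -shank_dir[:, 0]], axis=1)
    toe = ankle + FOOT_LEN * foot_dir

    pts = np.stack([np.tile([hx, hy], (len(t), 1)), knee, ankle, toe], axis=1)
    if pts.min() < 0.0 or pts.max() > 1.0:
        raise ValueError(
            "simulated chain leaves the unit frame; reduce peak_deg or move the hip"
        )

    prefix = spec.side.upper()
    names = [f"{prefix}_{p}" for p in ("HIP", "KNEE", "ANKLE", "FOOT_INDEX")]
    frames = [
        PoseFrame(
            timestamp=float(ti),
            landmarks={
                name: Landmark2D(x=float(p[0]), y=float(p[1]), visibility=1.0)
                for name, p in zip(names, pt)
            },
        )
        for ti, pt in zip(t, pts)
    ]
    seq = PoseSequence(
        frames=frames,
        frame_width_px=_FRAME_PX,
        frame_height_px=_FRAME_PX,
        nominal_fps=spec.fps_hz,
        metadata={"synthetic": True, "joint": spec.joint, "side": spec.side,
                  "peak_deg": spec.peak_deg, "n_reps": spec.n_reps},
    )
    if spec.noise_sd_norm > 0 or spec.dropout_prob > 0:
        seq = degrade_sequence(
            seq, spec.noise_sd_norm, spec.dropout_prob,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    deg = np.degrees(theta)
    truth_angles = {
        "hip": deg if spec.joint == "hip" else np.zeros_like(deg),
        "knee": deg if spec.joint == "knee" else np.zeros_like(deg),
        "ankle": np.full_like(deg, 90.0),
    }
    truth = SyntheticTruth(
        timestamps=t,
        angles_deg=truth_angles,
        repetition_peaks=[spec.peak_deg] * spec.n_reps,
        spec=spec,
    )
    return seq, truth


def degrade_sequence(
    seq: PoseSequence,
    noise_sd_norm: float,
    dropout_prob: float,
    seed: int,
) -> PoseSequence:
    """Add i.i.d. Gaussian coordinate noise and Bernoulli visibility dropout."""
    if noise_sd_norm < 0:
        raise ValueError("noise sd must be non-negative")
    if not (0 <= dropout_prob < 1):
        raise ValueError("dropout_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    frames = []
    for f in seq.frames:
        lms = {}
        for name, lm in f.landmarks.items():
            x, y, v = lm.x, lm.y, lm.visibility
            if noise_sd_norm > 0:
                x += float(rng.normal(0, noise_sd_norm))
                y += float(rng.normal(0, noise_sd_norm))
            if dropout_prob > 0 and rng.random() < dropout_prob:
                v = 0.0
            lms[name] = Landmark2D(x=x, y=y, visibility=v)
        frames.append(PoseFrame(timestamp=f.timestamp, landmarks=lms))
    return PoseSequence(
        frames=frames,
        frame_width_px=seq.frame_width_px,
        frame_height_px=seq.frame_height_px,
        nominal_fps=seq.nominal_fps,
        metadata={**seq.metadata, "degraded": True},
    )


def simulate_two_way_table(
    n_subjects: int,
    subject_sd: float,
    rater_offset: float = 0.0,
    error_sd: float = 1.0,
    mu: float = 90.0,
    seed: int = 0,
) -> PairedMeasurements:
    """Paired values from ``x_ij = mu + subject_i + offset_j + e_ij``.

    The clinical rater gets −offset/2 and the algorithm +offset/2, so the
    expected bias (algorithm − clinical) equals ``rater_offset``. The
    population ICC(A,1) implied by the components is recorded under
    ``metadata['population_icc']``.
    """
    if n_subjects < 3:
        raise ValueError("need >= 3 subjects")
    if subject_sd <= 0 or error_sd < 0:
        raise ValueError("sds must be positive (subject) / non-negative (error)")
    rng = np.random.default_rng(seed)
    s = rng.normal(0, subject_sd, size=n_subjects)
    e = rng.normal(0, error_sd, size=(n_subjects, 2))
    clinical = mu + s - rater_offset / 2 + e[:, 0]
    algorithm = mu + s + rater_offset / 2 + e[:, 1]
    # fixed column effects ±offset/2: theta_c^2 = sum(c_j^2)/(k-1) = offset^2/2
    pop_icc = subject_sd**2 / (subject_sd**2 + rater_offset**2 / 2 + error_sd**2)
    return PairedMeasurements(
        subjects=[f"S{i + 1:02d}" for i in range(n_subjects)],
        clinical_deg=clinical,
        algorithm_deg=algorithm,
        metadata={
            "population_icc": pop_icc,
            "mu": mu,
            "subject_sd": subject_sd,
            "rater_offset": rater_offset,
            "error_sd": error_sd,
        },
    )
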