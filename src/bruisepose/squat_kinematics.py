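"""Squat trajectory ingestion, range of motion, and matched-flexion isolation.

Trajectories are per-frame joint-parameter tables of the kind produced by
dynamic Roentgen stereophotogrammetric analysis (RSA): for every radiographic
frame, the five knee parameters of the tibia relative to the femur.  The
comparison analysis needs two things from a trajectory: the per-parameter
range of motion over the whole trial, and the single (sub-frame,
interpolated) pose at which the squat passes through a given flexion angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FlexionOutOfRange, FormatError, InvariantViolation, PhaseNotFound
from .knee_frames import JointPose, pose_from_parameters

__all__ = [
    "TRAJECTORY_COLUMNS",
    "KinematicTrajectory",
    "RangeOfMotion",
    "read_trajectory",
    "write_trajectory",
    "compute_rom",
    "matched_flexion_pose",
    "moving_average_filter",
]

TRAJECTORY_COLUMNS = ("frame", "time_s", "flexion_deg", "vv_deg", "ie_deg", "ap_mm", "pd_mm")
#: joint parameters carried by a trajectory, in reporting order
PARAMETERS = ("flexion", "vv", "ie", "ap", "pd")
_PARAM_COL = {
    "flexion": "flexion_deg",
    "vv": "vv_deg",
    "ie": "ie_deg",
    "ap": "ap_mm",
    "pd": "pd_mm",
}


@dataclass
class KinematicTrajectory:
    """Ordered per-frame joint poses of one motion trial."""

    frames: pd.DataFrame
    subject_id: str = ""
    task: str = "single_leg_squat"

    def __post_init__(self) -> None:
        df = self.frames
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"trajectory missing column(s) {missing}")
        if len(df) < 2:
            raise InvariantViolation("trajectory needs at least 2 frames")
        values = df[list(TRAJECTORY_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise InvariantViolation("trajectory contains non-finite values")
        t = df["time_s"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise InvariantViolation("time_s must be strictly increasing")
        self.frames = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frames)

    def parameter(self, name: str) -> np.ndarray:
        return self.frames[_PARAM_COL[name]].to_numpy(dtype=float)

    def pose_at_index(self, i: int) -> JointPose:
        row = self.frames.iloc[i]
        return pose_from_parameters(
            flexion=float(row["flexion_deg"]),
            vv=float(row["vv_deg"]),
            ie=float(row["ie_deg"]),
            ap=float(row["ap_mm"]),
            pd=float(row["pd_mm"]),
        )


@dataclass(frozen=True)
class RangeOfMotion:
    """Per-parameter extrema over one trajectory."""

    limits: dict[str, tuple[float, float]] = field(default_factory=dict)

    def minimum(self, name: str) -> float:
        return self.limits[name][0]

    def maximum(self, name: str) -> float:
        return self.limits[name][1]

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {k: {"min": lo, "max": hi} for k, (lo, hi) in self.limits.items()}


def read_trajectory(path: str | Path, subject_id: str = "") -> KinematicTrajectory:
    """Read a trajectory CSV with the documented header.

    Raises `FormatError` naming the offending column or line on malformed
    input, `InvariantViolation` on non-monotone time or non-finite values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in TRAJECTORY_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    return KinematicTrajectory(df, subject_id=subject_id or path.stem)


def write_trajectory(trajectory: KinematicTrajectory, path: str | Path) -> None:
    """Write the trajectory CSV (full float precision, lossless round trip)."""
    df = trajectory.frames[list(TRAJECTORY_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.17g")


def compute_rom(trajectory: KinematicTrajectory) -> RangeOfMotion:
    """Exact per-parameter extrema over all frames."""
    limits = {}
    for name in PARAMETERS:
        v = trajectory.parameter(name)
        limits[name] = (float(v.min()), float(v.max()))
    return RangeOfMotion(limits)


def _phase_slice(flexion: np.ndarray, phase: str) -> slice:
    peak = int(np.argmax(flexion))
    if phase == "descent":
        if peak == 0:
            raise PhaseNotFound("trajectory has no descent (flexion-increasing) phase")
        return slice(0, peak + 1)
    if phase == "ascent":
        if peak >= len(flexion) - 1:
            raise PhaseNotFound("trajectory has no ascent (flexion-decreasing) phase")
        return slice(peak, len(flexion))
    if phase == "first":
        return slice(0, len(flexion))
    raise ValueError(f"phase must be 'descent', 'ascent' or 'first', got {phase!r}")


def matched_flexion_pose(
    trajectory: KinematicTrajectory,
    target_flexion: float,
    phase: str = "descent",
) -> JointPose:
    """Squat pose at a given flexion angle.

    If a frame matches ``target_flexion`` exactly it is returned unchanged;
    otherwise all parameters are linearly interpolated between the two frames
    bracketing the *first* crossing of the target within the requested phase
    (descent by default — the loading phase analogous to injury).
    """
    flexion = trajectory.parameter("flexion")
    if not (flexion.min() <= target_flexion <= flexion.max()):
        raise FlexionOutOfRange(
            f"target flexion {target_flexion:.2f} deg outside trajectory range "
            f"[{flexion.min():.2f}, {flexion.max():.2f}]"
        )
    sl = _phase_slice(flexion, phase)
    f = flexion[sl]
    offset = sl.start or 0

    exact = np.flatnonzero(f == target_flexion)
    if exact.size:
        return trajectory.pose_at_index(offset + int(exact[0]))

    sign = np.sign(f - target_flexion)
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if crossings.size == 0:
        raise FlexionOutOfRange(
            f"target flexion {target_flexion:.2f} deg not crossed during the {phase} phase"
        )
    i = offset + int(crossings[0])
    f0, f1 = flexion[i], flexion[i + 1]
    alpha = (target_flexion - f0) / (f1 - f0)
    params = {}
    for name in ("vv", "ie", "ap", "pd"):
        v = trajectory.parameter(name)
        params[name] = float((1 - alpha) * v[i] + alpha * v[i + 1])
    return pose_from_parameters(flexion=float(target_flexion), **params)


def moving_average_filter(trajectory: KinematicTrajectory, window: int = 5) -> KinematicTrajectory:
    """Optional centered moving-average smoothing (off by default upstream).

    RSA noise is sub-millimetric, so the pipeline never smooths implicitly.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    df = trajectory.frames.copy()
    for name in PARAMETERS:
        col = _PARAM_COL[name]
        df[col] = df[col].rolling(window, center=True, min_periods=1).mean()
    return KinematicTrajectory(df, subject_id=trajectory.subject_id, task=trajectory.task)
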