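"""Per-trial measures extracted from reach trajectories.

Movement onset is the first sample farther than 2.25 cm from the start-dot
center; the trial ends at the first sample within 0.75 cm of the target
center.  Directional error is the signed angle (degrees, clockwise/rightward
positive) between the onset-to-target vector and the onset-to-position-at-
peak-velocity vector.  On channel trials the lateral wall force at peak
velocity, divided by peak speed, gives the normalized force readout of the
motor memory (N s/m; compensation of a clockwise field is negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import (END_THRESHOLD_M, ONSET_THRESHOLD_M, TARGET, Trajectory)

#: Movement times in this closed window count as successful (on-time) trials.
SUCCESS_WINDOW_MS = (350.0, 450.0)

#: Peak speeds below this floor make the normalized force readout unreliable.
MIN_PEAK_SPEED = 0.05

#: Slack absorbing floating-point representation error at threshold crossings.
_EPS = 1e-12


class MetricsError(ValueError):
    pass


@dataclass
class TrialRecord:
    """Extracted measures for one trial."""

    movement_time_ms: float
    peak_velocity: float
    t_peak_ms: float
    directional_error_deg: float
    force_at_pv: float          # NaN on non-channel trials
    success: bool
    failure_flag: bool


def _distances_from(traj: Trajectory, point) -> np.ndarray:
    d = traj.pos - np.asarray(point)
    return np.hypot(d[:, 0], d[:, 1])


def detect_onset(traj: Trajectory, threshold: float = ONSET_THRESHOLD_M) -> float | None:
    """Time (ms) of the first sample beyond ``threshold`` from the start center.

    Returns None when the threshold is never crossed (failed trial).
    """
    crossed = np.flatnonzero(_distances_from(traj, (0.0, 0.0)) > threshold - _EPS)
    return float(traj.t_ms[crossed[0]]) if crossed.size else None


def detect_end(traj: Trajectory, threshold: float = END_THRESHOLD_M) -> float | None:
    """Time (ms) of the first sample within ``threshold`` of the target center."""
    crossed = np.flatnonzero(_distances_from(traj, TARGET) < threshold + _EPS)
    return float(traj.t_ms[crossed[0]]) if crossed.size else None


def peak_velocity(traj: Trajectory) -> tuple[float, float]:
    """(peak speed m/s, time of peak ms); ties resolved to the earliest sample."""
    speed = np.hypot(traj.vel[:, 0], traj.vel[:, 1])
    idx = int(np.argmax(speed))
    return float(speed[idx]), float(traj.t_ms[idx])


def directional_error(traj: Trajectory, onset_ms: float | None = None) -> float:
    """Signed angle (degrees) between onset->target and onset->peak-velocity position.

    Positive is clockwise (rightward of the straight line for a forward
    reach); antisymmetric under mirroring the trajectory about the x = 0
    line.
    """
    if onset_ms is None:
        onset_ms = detect_onset(traj)
    if onset_ms is None:
        raise MetricsError("movement onset never detected")
    i_on = int(np.searchsorted(traj.t_ms, onset_ms))
    _, t_pk = peak_velocity(traj)
    i_pk = int(np.searchsorted(traj.t_ms, t_pk))
    p_on = traj.pos[i_on]
    v1 = np.asarray(TARGET) - p_on
    v2 = traj.pos[i_pk] - p_on
    n2 = math.hypot(*v2)
    if n2 == 0.0:
        raise MetricsError("zero-length onset-to-peak-velocity vector")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = float(v1 @ v2)
    # clockwise (rightward) positive
    return math.degrees(math.atan2(-cross, dot))


def force_at_peak_velocity(traj: Trajectory,
                           min_speed: float = MIN_PEAK_SPEED) -> float:
    """Wall force at peak velocity normalized by peak speed (N s/m).

    Only defined on channel (EC/IEC) trials; NaN otherwise.  Raises when the
    peak speed is below the reliability floor.
    """
    if traj.phase not in ("EC", "IEC"):
        return float("nan")
    speed, t_pk = peak_velocity(traj)
    if speed < min_speed:
        raise MetricsError(f"peak speed {speed:.3f} m/s below floor {min_speed}")
    i_pk = int(np.searchsorted(traj.t_ms, t_pk))
    return float(traj.wall_force[i_pk] / speed)


def classify_success(movement_time_ms: float,
                     window=SUCCESS_WINDOW_MS) -> bool:
    """True when the movement time lies in the closed on-time window."""
    lo, hi = window
    return lo <= movement_time_ms <= hi


def trial_record(traj: Trajectory) -> dict:
    """Extract all per-trial measures into a flat dict.

    Failed trials (thresholds never crossed, timeout, or degenerate peak
    speed) carry ``failure_flag=True`` with NaN measures; they are excluded
    from block means and success counts downstream.  The private
    ``_lateral_dev_at_pv_m`` entry feeds the learner in trajectory-mode
    simulation and is stripped before export.
    """
    onset = detect_onset(traj)
    end = detect_end(traj)
    failed = traj.failed or onset is None or end is None
    record = {
        "movement_time_ms": np.nan, "peak_velocity": np.nan,
        "directional_error_deg": np.nan, "force_at_pv": np.nan,
        "success": False, "failure_flag": True, "_lateral_dev_at_pv_m": np.nan,
    }
    if failed:
        return record
    speed, t_pk = peak_velocity(traj)
    try:
        de = directional_error(traj, onset_ms=onset)
        fpv = force_at_peak_velocity(traj)
    except MetricsError:
        return record
    mt = end - onset
    i_pk = int(np.searchsorted(traj.t_ms, t_pk))
    record.update({
        "movement_time_ms": mt, "peak_velocity": speed,
        "directional_error_deg": de, "force_at_pv": fpv,
        "success": classify_success(mt), "failure_flag": False,
        "_lateral_dev_at_pv_m": float(traj.pos[i_pk, 0]),
    })
    return record
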