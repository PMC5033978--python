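"""Synthetic cohorts for a curl-field reaching experiment with error clamps.

The arm/robot system is a planar point mass driven by a motor command with
three parts: an inverse-dynamics feedforward that tracks a minimum-jerk
reference to the target, a PD feedback correction around that reference, and
a learned lateral compensation ``-z * g_field * vy`` that anticipates the
clockwise curl field.  ``z`` is the behavioral compensation state (z = 1 is
full compensation) produced by a two-state learner: a fast process that
learns and forgets quickly and a slow process that learns little per trial
but retains strongly.

Trial environments
------------------
null (FAM/N)   no environment force
curl (FF)      F = B v with B = [[0, g], [-g, 0]]; pushes rightward for a
               forward reach
channel (EC/IEC)  stiff spring-damper wall confining the hand to the straight
               start-target line; the lateral force the hand exerts on the
               wall reads out the learned compensation

What the learner sees
---------------------
On field and null trials the error signal is the signed lateral hand
deviation at peak velocity (normalized by reach length).  On error-clamp
trials the hand moves straight, so the only usable error is visual: the
mismatch between the trajectory predicted from the current compensation
state and the rendered feedback.  That mismatch scales with the adapted
state itself, and with the feedback condition: an expanding arc carries no
direction information (gain 0), a veridical straight cursor carries the full
mismatch (gain 1), and a cursor curved 1 cm leftward injects an additional
offset error on top of it.

Two cohort fidelity tiers share the same learner: ``mode="trajectory"``
integrates 1 kHz trajectories and extracts metrics from them, while
``mode="fast"`` generates per-trial measures directly from the learner state
plus noise, for inexpensive statistical experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import ProtocolConfig, Schedule, TrialSpec, build_schedule

REACH_LENGTH_M = 0.15          # start-to-target distance
ONSET_THRESHOLD_M = 0.0225     # movement considered started beyond this distance
END_THRESHOLD_M = 0.0075       # trial ends within this distance of the target
TARGET = (0.0, REACH_LENGTH_M)

GROUPS = ("arc", "cursor", "augmented")


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class FieldParams:
    """Velocity-dependent curl field, F = B v, clockwise for g_field > 0."""

    g_field: float = 15.0        # N per m/s
    rotation_sense: str = "clockwise"


@dataclass
class ChannelParams:
    """Virtual spring-damper wall used on error-clamp trials."""

    stiffness: float = 5000.0    # N/m
    damping: float = 30.0        # N per m/s


@dataclass
class ControllerParams:
    """Point-mass plant and reach controller.

    ``kp`` doubles as the arm's effective lateral stiffness; it is kept an
    order of magnitude below the channel stiffness so that on clamp trials
    the wall, not the arm, absorbs the compensatory push.  The minimum-jerk
    reference duration is derived from ``target_movement_time_ms`` so that
    the *measured* movement time (onset threshold to target acquisition)
    lands on the instructed 400 ms.
    """

    mass: float = 1.0                    # kg
    kp: float = 200.0                    # N/m
    kd: float = 15.0                     # N per m/s
    target_movement_time_ms: float = 400.0
    timeout_ms: float = 1200.0
    dt_ms: float = 1.0
    trial_duration_jitter: float = 0.10      # lognormal sd, per trial
    participant_duration_sd: float = 0.05    # lognormal sd, per participant


@dataclass
class LearnerParams:
    """Two-state trial-to-trial learner and its noise model.

    ``clamp_error_gain`` scales the visually available mismatch on
    error-clamp trials per feedback condition; the curved-cursor condition
    additionally experiences the cursor-minus-straight-line offset as error.
    ``ff_error_scale`` is the lateral deviation (fraction of reach length) a
    fully naive participant shows in the field; ``ec_error_scale`` converts
    the predicted-trajectory mismatch into learner error units.
    """

    retention_fast: float = 0.92
    retention_slow: float = 0.996
    learn_fast: float = 0.08
    learn_slow: float = 0.01
    clamp_error_gain: dict = field(
        default_factory=lambda: {"arc": 0.0, "cursor": 1.0, "augmented": 1.1}
    )
    ff_error_scale: float = 0.20
    ec_error_scale: float = 1.8
    augmented_max_dev_m: float = 0.01     # leftward cursor bulge at mid-reach
    state_noise_sd_fast: float = 0.02
    state_noise_sd_slow: float = 0.002
    #: Trial-to-trial motor noise expressed on the force-at-peak-velocity
    #: scale (N s/m); the trajectory tier converts it to a lateral force bias.
    motor_noise_sd: float = 1.5
    #: Relative (lognormal) spread of learning rates across participants.
    participant_jitter_rel: float = 0.10

    def __post_init__(self):
        if not (0 < self.retention_fast < self.retention_slow < 1):
            raise ValueError("need 0 < retention_fast < retention_slow < 1")
        if not (self.learn_fast > self.learn_slow > 0):
            raise ValueError("need learn_fast > learn_slow > 0")


@dataclass
class ParticipantState:
    """Latent compensation state; the behavioral readout is z = z_fast + z_slow."""

    z_fast: float = 0.0
    z_slow: float = 0.0

    @property
    def z(self) -> float:
        return self.z_fast + self.z_slow


@dataclass
class Trajectory:
    """One trial's 1 kHz time series.

    Positions are in meters with the origin at the start-dot center, +y
    toward the target and +x rightward.  ``wall_force`` is the lateral force
    the hand exerts on the channel wall (NaN on non-channel trials).
    """

    t_ms: np.ndarray
    pos: np.ndarray            # (n, 2)
    vel: np.ndarray            # (n, 2)
    env_force: np.ndarray      # (n, 2) environment force on the hand
    wall_force: np.ndarray     # (n,)
    phase: str
    feedback: str
    failed: bool = False       # timeout without target acquisition


# --------------------------------------------------------------------------
# primitive force laws
# --------------------------------------------------------------------------

def curl_force(vel, params: FieldParams):
    """Curl-field force on the hand: (Fx, Fy) = (g*vy, -g*vx).

    Perpendicular to the velocity, magnitude g*|v|; for a forward reach
    (vy > 0) it pushes rightward, i.e. clockwise.
    """
    vx, vy = vel
    g = params.g_field
    return (g * vy, -g * vx)


def channel_force(lateral_pos: float, lateral_vel: float,
                  params: ChannelParams) -> float:
    """Restoring force of the virtual channel on the hand (x component).

    The wall force recorded in a Trajectory is the negation of this value
    (force of the hand on the wall).
    """
    return -(params.stiffness * lateral_pos + params.damping * lateral_vel)


def augmented_cursor_x(y_hand: float, max_dev: float = 0.01,
                       reach_len: float = REACH_LENGTH_M) -> float:
    """Lateral cursor position of the curved (error-augmenting) feedback.

    The cursor follows the circular arc through (0, 0), (-max_dev,
    reach_len/2) and (0, reach_len): no deviation at the endpoints and
    ``max_dev`` to the left (negative x) at mid-reach.  ``y_hand`` outside
    the reach is clamped to the nearer endpoint.
    """
    y = min(max(y_hand, 0.0), reach_len)
    half = reach_len / 2.0
    cx = (half * half - max_dev * max_dev) / (2.0 * max_dev)
    radius = cx + max_dev
    return cx - math.sqrt(radius * radius - (y - half) ** 2)


# --------------------------------------------------------------------------
# minimum-jerk reference
# --------------------------------------------------------------------------

def _min_jerk_fraction(s: float) -> float:
    return s * s * s * (10.0 - 15.0 * s + 6.0 * s * s)


def _measured_mt_fraction() -> float:
    """Fraction of the reference duration between the onset and end thresholds.

    The onset (2.25 cm from start) and end (0.75 cm from target) thresholds
    cut the minimum-jerk profile at fixed phase fractions; movement time as
    measured is that fraction of the full reference duration.
    """
    from scipy.optimize import brentq

    lo = ONSET_THRESHOLD_M / REACH_LENGTH_M
    hi = 1.0 - END_THRESHOLD_M / REACH_LENGTH_M
    s_on = brentq(lambda s: _min_jerk_fraction(s) - lo, 0.0, 1.0)
    s_off = brentq(lambda s: _min_jerk_fraction(s) - hi, 0.0, 1.0)
    return s_off - s_on


MEASURED_MT_FRACTION = _measured_mt_fraction()


def reference_kinematics(t_s: float, duration_s: float,
                         reach_len: float = REACH_LENGTH_M):
    """Minimum-jerk reference position/velocity/acceleration along +y at time t."""
    if t_s >= duration_s:
        return reach_len, 0.0, 0.0
    s = t_s / duration_s
    pos = reach_len * _min_jerk_fraction(s)
    vel = reach_len / duration_s * 30.0 * s * s * (1.0 - s) ** 2
    acc = reach_len / duration_s ** 2 * (60.0 * s - 180.0 * s * s + 120.0 * s ** 3)
    return pos, vel, acc


# --------------------------------------------------------------------------
# single-trial physics
# --------------------------------------------------------------------------

def simulate_trial(state: ParticipantState | float, spec: TrialSpec,
                   field_params: FieldParams | None = None,
                   channel_params: ChannelParams | None = None,
                   controller: ControllerParams | None = None,
                   lateral_bias_n: float = 0.0,
                   duration_scale: float = 1.0) -> Trajectory:
    """Integrate one reach at 1 kHz (semi-implicit Euler).

    ``state`` may be a ParticipantState or a bare compensation value z.
    ``lateral_bias_n`` is a per-trial constant motor-noise force (N);
    ``duration_scale`` multiplies the reference duration (timing noise).
    The trial ends when the hand comes within 0.75 cm of the target center,
    or is flagged failed at the timeout.
    """
    field_params = field_params or FieldParams()
    channel_params = channel_params or ChannelParams()
    controller = controller or ControllerParams()

    z = state.z if isinstance(state, ParticipantState) else float(state)
    g = field_params.g_field
    m = controller.mass
    dt = controller.dt_ms / 1000.0
    duration_s = (controller.target_movement_time_ms / 1000.0
                  / MEASURED_MT_FRACTION) * duration_scale
    n_max = int(round(controller.timeout_ms / controller.dt_ms)) + 1
    channel = spec.phase in ("EC", "IEC")
    curl = spec.phase == "FF"

    t_ms = np.empty(n_max)
    pos = np.empty((n_max, 2))
    vel = np.empty((n_max, 2))
    env = np.empty((n_max, 2))
    wall = np.full(n_max, np.nan)

    x = y = vx = vy = 0.0
    end_x, end_y = TARGET
    failed = True
    n = n_max
    for i in range(n_max):
        t = i * dt
        ry, rvy, ray = reference_kinematics(t, duration_s)

        # environment force on the hand
        if curl:
            fx_env, fy_env = g * vy, -g * vx
        elif channel:
            fx_env = channel_force(x, vx, channel_params)
            fy_env = 0.0
        else:
            fx_env = fy_env = 0.0

        t_ms[i] = i * controller.dt_ms
        pos[i] = (x, y)
        vel[i] = (vx, vy)
        env[i] = (fx_env, fy_env)
        if channel:
            wall[i] = -fx_env

        dxt, dyt = x - end_x, y - end_y
        if dxt * dxt + dyt * dyt < END_THRESHOLD_M ** 2:
            failed = False
            n = i + 1
            break

        # motor command: inverse dynamics along the reference, PD correction,
        # learned lateral compensation, constant motor-noise bias
        fx_cmd = controller.kp * (0.0 - x) + controller.kd * (0.0 - vx)
        fy_cmd = m * ray + controller.kp * (ry - y) + controller.kd * (rvy - vy)
        fx_cmd += -z * g * vy + lateral_bias_n

        ax = (fx_cmd + fx_env) / m
        ay = (fy_cmd + fy_env) / m
        vx += ax * dt
        vy += ay * dt
        x += vx * dt
        y += vy * dt

    return Trajectory(
        t_ms=t_ms[:n], pos=pos[:n], vel=vel[:n], env_force=env[:n],
        wall_force=wall[:n], phase=spec.phase, feedback=spec.feedback,
        failed=failed,
    )


# --------------------------------------------------------------------------
# trial-to-trial learning
# --------------------------------------------------------------------------

def experienced_error(spec: TrialSpec, z: float, params: LearnerParams,
                      measured_dev_norm: float | None = None) -> float:
    """Signed lateral error available to the learner on this trial.

    Field and null trials: the actual normalized lateral deviation at peak
    velocity if supplied, else its state-based expectation ((1 - z) of the
    naive deviation in the field; -z of it in the null field, where the
    residual compensation itself curves the reach).  Error-clamp trials: the
    feedback-gated visual mismatch, which grows with the adapted state, plus
    the curved-cursor offset for the error-augmenting condition.  The arc
    condition carries no directional information, so its error is zero.
    """
    if spec.phase in ("FAM", "N", "FF"):
        if measured_dev_norm is not None:
            return measured_dev_norm
        base = params.ff_error_scale
        return (1.0 - z) * base if spec.phase == "FF" else -z * base
    gain = params.clamp_error_gain[spec.feedback]
    offset = 0.0
    if spec.feedback == "augmented":
        offset = params.augmented_max_dev_m / REACH_LENGTH_M
    return -gain * params.ec_error_scale * (z + offset)


def _step(state: ParticipantState, error: float, params: LearnerParams,
          noise_fast: float = 0.0, noise_slow: float = 0.0) -> ParticipantState:
    zf = (params.retention_fast * state.z_fast
          + params.learn_fast * error + noise_fast)
    zs = (params.retention_slow * state.z_slow
          + params.learn_slow * error + noise_slow)
    # keep the summed state in a physiologically plausible band
    total = zf + zs
    if total > 1.5:
        scale = 1.5 / total
        zf, zs = zf * scale, zs * scale
    elif total < -0.5:
        scale = -0.5 / total
        zf, zs = zf * scale, zs * scale
    return ParticipantState(z_fast=zf, z_slow=zs)


def update_state(state: ParticipantState, spec: TrialSpec, error: float,
                 params: LearnerParams,
                 rng: np.random.Generator | None = None) -> ParticipantState:
    """One learner step: z_i <- retention_i * z_i + learn_i * error + noise."""
    nf = ns = 0.0
    if rng is not None:
        nf = rng.normal(0.0, params.state_noise_sd_fast)
        ns = rng.normal(0.0, params.state_noise_sd_slow)
    return _step(state, error, params, nf, ns)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    field_params: FieldParams = field(default_factory=FieldParams)
    channel: ChannelParams = field(default_factory=ChannelParams)
    controller: ControllerParams = field(default_factory=ControllerParams)
    learner: LearnerParams = field(default_factory=LearnerParams)
    groups: tuple = GROUPS
    n_per_group: int = 15
    #: Directional-error amplitude (degrees) of a fully naive reach in the
    #: field; used by the fast tier's direct metric generator.
    fast_de_scale_deg: float = 21.0
    fast_de_noise_deg: float = 3.0


RECORD_COLUMNS = [
    "group", "participant", "global_index", "phase", "block_label",
    "within_block_index", "feedback", "movement_time_ms", "peak_velocity",
    "directional_error_deg", "force_at_pv", "success", "failure_flag",
]


def _participant_learner(base: LearnerParams, rng: np.random.Generator) -> LearnerParams:
    """Per-participant multiplicative jitter on learning parameters."""
    rel = base.participant_jitter_rel
    jit = lambda: math.exp(rng.normal(0.0, rel)) if rel > 0 else 1.0
    return LearnerParams(
        retention_fast=base.retention_fast,
        retention_slow=base.retention_slow,
        learn_fast=min(base.learn_fast * jit(), 0.5),
        learn_slow=min(base.learn_slow * jit(), base.learn_fast * 0.5),
        clamp_error_gain=dict(base.clamp_error_gain),
        ff_error_scale=base.ff_error_scale * jit(),
        ec_error_scale=base.ec_error_scale * jit(),
        augmented_max_dev_m=base.augmented_max_dev_m,
        state_noise_sd_fast=base.state_noise_sd_fast,
        state_noise_sd_slow=base.state_noise_sd_slow,
        motor_noise_sd=base.motor_noise_sd,
        participant_jitter_rel=base.participant_jitter_rel,
    )


def _simulate_participant_fast(schedule: Schedule, learner: LearnerParams,
                               config: CohortConfig,
                               rng: np.random.Generator) -> list[dict]:
    """Metric-level tier: per-trial measures straight from the learner state."""
    g = config.field_params.g_field
    ctrl = config.controller
    n = len(schedule)
    mt_nominal = ctrl.target_movement_time_ms
    part_factor = math.exp(rng.normal(0.0, ctrl.participant_duration_sd))
    mt_factors = np.exp(rng.normal(0.0, ctrl.trial_duration_jitter, n)) * part_factor
    fpv_noise = rng.normal(0.0, learner.motor_noise_sd, n)
    de_noise = rng.normal(0.0, config.fast_de_noise_deg, n)
    state_noise = np.column_stack([
        rng.normal(0.0, learner.state_noise_sd_fast, n),
        rng.normal(0.0, learner.state_noise_sd_slow, n),
    ])
    pv_nominal = 1.875 * REACH_LENGTH_M / (mt_nominal / 1000.0 / MEASURED_MT_FRACTION)

    state = ParticipantState()
    rows = []
    for i, spec in enumerate(schedule):
        z = state.z
        mt = mt_nominal * mt_factors[i]
        pv = pv_nominal / mt_factors[i]
        if spec.is_channel:
            fpv = -z * g + fpv_noise[i]
            de = 0.2 * de_noise[i]
        else:
            fpv = np.nan
            lvl = (1.0 - z) if spec.phase == "FF" else -z
            de = lvl * config.fast_de_scale_deg + de_noise[i]
        rows.append({
            "global_index": spec.global_index, "phase": spec.phase,
            "block_label": spec.block_label,
            "within_block_index": spec.within_block_index,
            "feedback": spec.feedback, "movement_time_ms": mt,
            "peak_velocity": pv, "directional_error_deg": de,
            "force_at_pv": fpv, "success": 350.0 <= mt <= 450.0,
            "failure_flag": False,
        })
        err = experienced_error(spec, z, learner)
        state = _step(state, err, learner, state_noise[i, 0], state_noise[i, 1])
    return rows


def _simulate_participant_trajectories(schedule: Schedule, learner: LearnerParams,
                                       config: CohortConfig,
                                       rng: np.random.Generator,
                                       trajectory_sink=None) -> list[dict]:
    """Trajectory tier: integrate each reach, extract measures from kinematics."""
    from . import metrics

    ctrl = config.controller
    n = len(schedule)
    part_factor = math.exp(rng.normal(0.0, ctrl.participant_duration_sd))
    mt_factors = np.exp(rng.normal(0.0, ctrl.trial_duration_jitter, n)) * part_factor
    pv_nominal = 1.875 * REACH_LENGTH_M / (
        ctrl.target_movement_time_ms / 1000.0 / MEASURED_MT_FRACTION)
    bias_scale = learner.motor_noise_sd * pv_nominal
    biases = rng.normal(0.0, bias_scale, n)
    state_noise = np.column_stack([
        rng.normal(0.0, learner.state_noise_sd_fast, n),
        rng.normal(0.0, learner.state_noise_sd_slow, n),
    ])

    state = ParticipantState()
    rows = []
    for i, spec in enumerate(schedule):
        z = state.z
        traj = simulate_trial(
            state, spec, config.field_params, config.channel, ctrl,
            lateral_bias_n=biases[i], duration_scale=mt_factors[i],
        )
        record = metrics.trial_record(traj)
        record.update({
            "global_index": spec.global_index, "phase": spec.phase,
            "block_label": spec.block_label,
            "within_block_index": spec.within_block_index,
            "feedback": spec.feedback,
        })
        rows.append(record)
        if trajectory_sink is not None:
            trajectory_sink(spec, traj)

        if spec.is_channel or record["failure_flag"]:
            dev_norm = None
        else:
            dev_norm = record["_lateral_dev_at_pv_m"] / REACH_LENGTH_M
        err = experienced_error(spec, z, learner, measured_dev_norm=dev_norm)
        state = _step(state, err, learner, state_noise[i, 0], state_noise[i, 1])
    for r in rows:
        r.pop("_lateral_dev_at_pv_m", None)
    return rows


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    mode: str = "fast", trajectory_sink=None) -> pd.DataFrame:
    """Generate a full cohort: one row per trial per participant.

    Each participant draws an independent RNG stream from
    (seed, group index, participant index), so cohorts are reproducible and
    participants are statistically independent.  The schedule is identical
    for every participant and every seed; only its feedback label varies by
    group.
    """
    config = config or CohortConfig()
    if mode not in ("fast", "trajectory"):
        raise ValueError(f"unknown cohort mode {mode!r}")
    frames = []
    for g_idx, group in enumerate(config.groups):
        schedule = build_schedule(config.protocol, feedback=group)
        for p_idx in range(config.n_per_group):
            rng = np.random.default_rng([int(seed), g_idx, p_idx])
            learner = _participant_learner(config.learner, rng)
            if mode == "fast":
                rows = _simulate_participant_fast(schedule, learner, config, rng)
            else:
                rows = _simulate_participant_trajectories(
                    schedule, learner, config, rng, trajectory_sink)
            frame = pd.DataFrame(rows)
            frame.insert(0, "participant", f"{group}-{p_idx + 1:02d}")
            frame.insert(0, "group", group)
            frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return table[RECORD_COLUMNS]


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Flatten a Trajectory to the per-trial CSV layout."""
    return pd.DataFrame({
        "t_ms": traj.t_ms,
        "x_m": traj.pos[:, 0], "y_m": traj.pos[:, 1],
        "vx": traj.vel[:, 0], "vy": traj.vel[:, 1],
        "fx_env": traj.env_force[:, 0], "fy_env": traj.env_force[:, 1],
        "wall_force_N": traj.wall_force,
    })
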