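import numpy as np
import pytest
from hypothesis import settings

from clampdecay.protocol import ProtocolConfig
from clampdecay.simulate import CohortConfig, Trajectory, simulate_cohort

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """One default fast-tier cohort (3 x 15 participants, full schedule)."""
    return simulate_cohort(seed=1, mode="fast")


@pytest.fixture(scope="session")
def mini_protocol():
    """A drastically shortened session for trajectory-tier tests."""
    return ProtocolConfig(
        familiarization_trials=4, n1_null_trials=6, n1_iec_trials=1,
        n_ff_blocks=2, ff_trials_per_block=5, iec_per_ff_block=1,
        n_ec_blocks=2, ec_block_trials=6, n2_null_trials=4,
        expected_total=None, expected_blocks=None,
    )


def make_ramp_trajectory(duration_ms=400, speed=0.375, phase="N",
                         feedback="cursor", x_offset_fn=None):
    """Straight constant-velocity reach: y(t) = speed * t, 1 kHz samples."""
    n = duration_ms + 1
    t = np.arange(n, dtype=float)
    y = speed * t / 1000.0
    x = np.zeros(n) if x_offset_fn is None else np.array([x_offset_fn(yy) for yy in y])
    pos = np.column_stack([x, y])
    vel = np.column_stack([np.gradient(x, t / 1000.0), np.full(n, speed)])
    return Trajectory(
        t_ms=t, pos=pos, vel=vel, env_force=np.zeros((n, 2)),
        wall_force=np.full(n, np.nan), phase=phase, feedback=feedback,
    )
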