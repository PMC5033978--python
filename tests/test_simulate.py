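import numpy as np
import pytest

from clampdecay.protocol import TrialSpec
from clampdecay.simulate import (ChannelParams, CohortConfig, FieldParams,
                                 LearnerParams, ParticipantState,
                                 augmented_cursor_x, channel_force, curl_force,
                                 experienced_error, simulate_cohort,
                                 simulate_trial, update_state)


def ec_spec(feedback="cursor"):
    return TrialSpec(1, "EC", "EC1", 1, feedback)


class TestForceLaws:
    @pytest.mark.parametrize("vel, expected", [
        ((0.0, 0.0), (0.0, 0.0)),
        ((0.0, 0.5), (7.5, 0.0)),
        ((0.1, 0.0), (0.0, -1.5)),
    ])
    def test_curl_examples(self, vel, expected):
        assert curl_force(vel, FieldParams()) == pytest.approx(expected)

    def test_curl_orthogonal_with_magnitude_g_speed(self):
        rng = np.random.default_rng(7)
        params = FieldParams()
        for _ in range(1000):
            v = rng.normal(0, 0.5, 2)
            f = np.array(curl_force(v, params))
            assert abs(f @ v) < 1e-12
            assert np.hypot(*f) == pytest.approx(15.0 * np.hypot(*v), rel=1e-12)

    @pytest.mark.parametrize("pos, vel, expected", [
        (0.0, 0.0, 0.0),
        (0.001, 0.01, -5.3),
        (-0.001, 0.0, 5.0),
    ])
    def test_channel_examples(self, pos, vel, expected):
        assert channel_force(pos, vel, ChannelParams()) == pytest.approx(expected)

    def test_augmented_cursor_arc(self):
        assert augmented_cursor_x(0.0) == pytest.approx(0.0, abs=1e-12)
        assert augmented_cursor_x(0.15) == pytest.approx(0.0, abs=1e-12)
        assert augmented_cursor_x(0.075) == pytest.approx(-0.01)
        # leftward everywhere in between, clamped outside the reach
        ys = np.linspace(0.01, 0.14, 20)
        assert all(augmented_cursor_x(y) < 0 for y in ys)
        assert augmented_cursor_x(-0.3) == pytest.approx(0.0, abs=1e-12)
        assert augmented_cursor_x(0.5) == pytest.approx(0.0, abs=1e-12)


class TestLearner:
    def test_retention_only_update(self):
        params = LearnerParams()
        state = update_state(ParticipantState(0.1, 0.4), ec_spec("arc"), 0.0, params)
        assert state.z_fast == pytest.approx(0.92 * 0.1)
        assert state.z_slow == pytest.approx(0.996 * 0.4)

    def test_arc_feedback_carries_no_error(self):
        assert experienced_error(ec_spec("arc"), 0.7, LearnerParams()) == 0.0

    def test_cursor_clamp_error_opposes_adapted_state(self):
        err = experienced_error(ec_spec("cursor"), 0.5, LearnerParams())
        assert err < 0

    def test_repeated_cursor_clamps_decay_strictly_toward_zero(self):
        params = LearnerParams()
        state = ParticipantState(0.08, 0.18)
        zs = [state.z]
        for _ in range(30):
            err = experienced_error(ec_spec("cursor"), state.z, params)
            state = update_state(state, ec_spec("cursor"), err, params)
            zs.append(state.z)
        diffs = np.diff(zs)
        assert all(d < 0 for d in diffs[:20])
        assert zs[-1] < 0.25 * zs[0]

    @pytest.mark.parametrize("gain_lo, gain_hi", [(0.0, 1.0), (0.5, 1.5)])
    def test_larger_clamp_gain_decays_faster(self, gain_lo, gain_hi):
        finals = []
        for gain in (gain_lo, gain_hi):
            params = LearnerParams(clamp_error_gain={
                "arc": gain, "cursor": gain, "augmented": gain})
            state = ParticipantState(0.08, 0.18)
            for _ in range(30):
                err = experienced_error(ec_spec("cursor"), state.z, params)
                state = update_state(state, ec_spec("cursor"), err, params)
            finals.append(state.z)
        assert finals[1] < finals[0]


class TestTrialPhysics:
    def test_unopposed_field_pushes_rightward(self):
        traj = simulate_trial(0.0, TrialSpec(1, "FF", "FF1", 1, "cursor"))
        assert traj.pos[:, 0].max() > 0.005
        assert not traj.failed

    def test_naive_clamp_trial_has_no_wall_force(self):
        traj = simulate_trial(0.0, ec_spec())
        assert np.nanmax(np.abs(traj.wall_force)) < 0.1

    def test_adapted_clamp_readout_matches_feedforward(self):
        traj = simulate_trial(0.5, ec_spec())
        speed = np.hypot(traj.vel[:, 0], traj.vel[:, 1])
        i_pk = int(np.argmax(speed))
        expected = -0.5 * 15.0 * traj.vel[i_pk, 1]
        assert traj.wall_force[i_pk] == pytest.approx(expected, rel=0.05)

    def test_channel_confines_hand_below_3mm(self):
        for z in (0.0, 0.3, 0.6, 0.9):
            traj = simulate_trial(z, ec_spec())
            assert np.abs(traj.pos[:, 0]).max() < 0.003

    def test_trial_is_deterministic(self):
        a = simulate_trial(0.4, ec_spec())
        b = simulate_trial(0.4, ec_spec())
        np.testing.assert_array_equal(a.pos, b.pos)
        np.testing.assert_array_equal(a.wall_force, b.wall_force)

    def test_sampling_grid_is_1khz(self):
        traj = simulate_trial(0.2, ec_spec())
        assert np.all(np.diff(traj.t_ms) == 1.0)


class TestCohort:
    def test_default_cohort_has_45_participants(self, default_cohort):
        counts = default_cohort.groupby("group")["participant"].nunique()
        assert counts.to_dict() == {"arc": 15, "augmented": 15, "cursor": 15}
        per_participant = default_cohort.groupby("participant").size()
        assert (per_participant == 809).all()

    def test_same_seed_reproduces_table_exactly(self):
        cfg = CohortConfig(n_per_group=2)
        a = simulate_cohort(cfg, seed=3, mode="fast")
        b = simulate_cohort(cfg, seed=3, mode="fast")
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_seeds_change_noise_but_not_schedule(self):
        cfg = CohortConfig(n_per_group=2)
        a = simulate_cohort(cfg, seed=3, mode="fast")
        b = simulate_cohort(cfg, seed=4, mode="fast")
        for col in ("global_index", "phase", "block_label",
                    "within_block_index", "feedback"):
            assert (a[col] == b[col]).all()
        ec_a = a.loc[a.phase == "EC", "force_at_pv"]
        ec_b = b.loc[b.phase == "EC", "force_at_pv"]
        assert not np.allclose(ec_a, ec_b)

    def test_channel_trials_carry_force_others_do_not(self, default_cohort):
        channel = default_cohort["phase"].isin(["EC", "IEC"])
        assert default_cohort.loc[channel, "force_at_pv"].notna().all()
        assert default_cohort.loc[~channel, "force_at_pv"].isna().all()

    def test_trajectory_tier_mini_cohort(self, mini_protocol):
        cfg = CohortConfig(protocol=mini_protocol, groups=("arc", "cursor"),
                           n_per_group=2)
        rec = simulate_cohort(cfg, seed=0, mode="trajectory")
        assert rec["participant"].nunique() == 4
        channel = rec["phase"].isin(["EC", "IEC"])
        ok = ~rec["failure_flag"]
        assert (rec.loc[channel & ok, "force_at_pv"].abs() < 20).all()
        assert rec.loc[ok, "movement_time_ms"].between(100, 1200).all()
        # adaptation leaves a compensatory (negative) clamp force after learning
        last_ec = rec[(rec.block_label == "EC1") & ok]
        assert last_ec["force_at_pv"].mean() < 0
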