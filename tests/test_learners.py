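"""Learners: sensory/reward errors, ILC update, re-aiming, feedback, exploration."""

import numpy as np
import pytest

from vmrsim.learners import (
    LearnerParams,
    LearnerState,
    SENSORY_NOISE_VAR,
    combine,
    default_p_max,
    explore_binary,
    feedback_command,
    reward_error,
    rotate_commands,
    sensory_error,
    update_reward,
    update_sensorimotor,
)
from vmrsim.plant import min_jerk_trajectory, simulate_trial
from vmrsim.protocol import TrialSpec

NO_LEARN = dict(L=((0.0,) * 4,) * 2, p=0.0, feedback_on=False)


def _run_one(plant, beta=0.0, params=None):
    state = LearnerState(plant, params or LearnerParams(**NO_LEARN))
    spec = TrialSpec(beta, beta, "perturbed" if beta else "baseline")
    return state, simulate_trial(state, spec, plant)


class TestSensoryError:
    def test_on_path_error_is_zero(self, plant, desired):
        _, trial = _run_one(plant)
        err = sensory_error(desired, trial)
        assert np.abs(err.polar).max() < 1e-9
        assert np.abs(err.metric).max() < 1e-9

    def test_rotation_gives_constant_angle_error(self, plant, desired):
        """A straight hand reach seen through a 30-degree rotation has a
        -30 degree cursor-angle error at every sample with d > 0."""
        _, trial = _run_one(plant, beta=30.0)
        err = sensory_error(desired, trial)
        moved = trial.cursor[:, 0] > 1e-6
        np.testing.assert_allclose(err.polar[moved, 2], -30.0, atol=1e-9)

    def test_noise_variances_match_spec(self, plant, desired, rng):
        _, trial = _run_one(plant)
        draws = np.concatenate([
            sensory_error(desired, trial, noise_on=True, rng=rng).polar
            for _ in range(300)
        ])  # ~12k samples per channel
        var = draws.var(axis=0)
        np.testing.assert_allclose(var, SENSORY_NOISE_VAR, rtol=0.1)


class TestRewardError:
    def test_perfect_endpoint_gives_zero(self, plant, desired):
        _, trial = _run_one(plant)
        assert reward_error(sensory_error(desired, trial), trial, "endpoint").value \
            == pytest.approx(0.0, abs=1e-12)

    def test_endpoint_value_hand_arithmetic(self, plant, desired):
        # e_gamma(end) = -30 deg at d = 0.10 m -> 2 * (-pi/6) * 0.1
        _, trial = _run_one(plant, beta=30.0)
        v = reward_error(sensory_error(desired, trial), trial, "endpoint").value
        assert v == pytest.approx(2 * np.radians(-30.0) * 0.10, rel=1e-6)

    def test_integrated_is_distance_weighted_mean(self, plant, desired):
        _, trial = _run_one(plant, beta=30.0)
        err = sensory_error(desired, trial)
        got = reward_error(err, trial, "integrated").value
        want = np.mean(2 * np.radians(err.polar[1:, 2]) * trial.cursor[1:, 0])
        assert got == pytest.approx(want, rel=1e-12)

    def test_binary_threshold_on_magnitude(self, plant, desired):
        _, trial = _run_one(plant)
        err = sensory_error(desired, trial)
        r = plant.target_radius
        # synthetic endpoint angular errors produce |e_RW| of 0.5 r and 2 r
        for scale, expect in ((0.5, 0.0), (2.0, 1.0)):
            e = err.polar.copy()
            e[-1, 2] = np.degrees(scale * r / (2 * trial.cursor[-1, 0]))
            fake = sensory_error(desired, trial)
            fake = type(fake)(e, fake.metric)
            assert reward_error(fake, trial, "binary").value == expect

    def test_unknown_mode_rejected(self, plant, desired):
        _, trial = _run_one(plant)
        with pytest.raises(ValueError, match="unknown reward mode"):
            reward_error(sensory_error(desired, trial), trial, "nope")


class TestSensorimotorUpdate:
    def test_zero_gain_never_learns(self, plant):
        state, trial = _run_one(plant, beta=30.0)
        state.finish_trial(trial)
        assert np.all(state.u_sm == 0.0)

    def test_forgetting_decay_without_error(self, plant):
        lp = LearnerParams()
        state = LearnerState(plant, lp)
        state.u_sm = np.ones((plant.k_end, 2))
        state.last_error = None
        u = update_sensorimotor(state, lp)
        np.testing.assert_allclose(u, 0.995)

    def test_scalar_recursion_fixed_point(self):
        """u+ = b u + g e with constant e converges to g e / (1 - b);
        oracle: brute-force iteration."""
        b, g, e = 0.995, 0.02, -0.5
        u = 0.0
        for _ in range(10_000):
            u = b * u + g * e
        assert u == pytest.approx(g * e / (1 - b), rel=1e-6)

    def test_motor_noise_variance(self, plant, rng):
        lp = LearnerParams(L=((0.0,) * 4,) * 2)
        state = LearnerState(plant, lp)
        state.last_error = None
        draws = np.concatenate([
            update_sensorimotor(state, lp, motor_noise=True, rng=rng)
            for _ in range(300)
        ])
        np.testing.assert_allclose(draws.var(axis=0), lp.motor_noise_var, rtol=0.1)


class TestRewardUpdate:
    def test_p_zero_keeps_fallback(self, plant):
        lp = LearnerParams(L=((0.0,) * 4,) * 2, p=0.0, reward_mode="endpoint",
                           feedback_on=False)
        state = LearnerState(plant, lp)
        for _ in range(5):
            trial = simulate_trial(state, TrialSpec(30.0, 30.0, "perturbed"), plant)
            state.finish_trial(trial)
        np.testing.assert_array_equal(state.u_rw, state.u0)

    def test_geometric_convergence_matches_closed_form(self, plant):
        """Noise-free end-point learning: the cursor endpoint angle decays
        with the per-trial ratio of the equivalent scalar recursion
        aim' = aim + p * 2 * radians(-(aim+beta)) * D."""
        p, beta, D = 0.5, 30.0, plant.target_distance
        lp = LearnerParams(L=((0.0,) * 4,) * 2, p=p, reward_mode="endpoint",
                           feedback_on=False)
        state = LearnerState(plant, lp)
        angles = []
        for _ in range(12):
            trial = simulate_trial(state, TrialSpec(beta, beta, "perturbed"), plant)
            angles.append(trial.cursor[-1, 2])
            state.finish_trial(trial)
        aim = 0.0
        for i, got in enumerate(angles):
            assert got == pytest.approx(np.degrees(aim) + beta, abs=1e-6)
            aim = aim + p * 2 * np.radians(-(np.degrees(aim) + beta)) * D

    def test_deadaptation_cue_resets_to_fallback(self, plant):
        lp = LearnerParams(L=((0.0,) * 4,) * 2, p=0.5, reward_mode="endpoint",
                           feedback_on=False)
        state = LearnerState(plant, lp)
        for _ in range(30):
            trial = simulate_trial(state, TrialSpec(30.0, 30.0, "perturbed"), plant)
            state.finish_trial(trial)
        assert abs(np.degrees(state.aim)) > 20.0
        state.start_trial(0.0, "deadaptation")
        trial = simulate_trial(state, TrialSpec(0.0, 0.0, "deadaptation"), plant)
        assert abs(trial.cursor[-1, 2]) < 1e-9      # straight again


class TestBinaryExploration:
    def _state(self, plant, p_max=None):
        lp = LearnerParams(L=((0.0,) * 4,) * 2, reward_mode="binary",
                           feedback_on=False, p_max=p_max)
        return LearnerState(plant, lp)

    def test_success_freezes_commands(self, plant, rng):
        state = self._state(plant)
        spec = TrialSpec(0.0, 0.0, "baseline")
        t1 = simulate_trial(state, spec, plant)
        assert t1.hit
        state.finish_trial(t1, rng=rng)
        t2 = simulate_trial(state, spec, plant)
        np.testing.assert_array_equal(t1.commands, t2.commands)

    def test_no_exploration_without_range(self, plant, rng):
        state = self._state(plant, p_max=0.0)
        spec = TrialSpec(30.0, 30.0, "perturbed")
        ends = []
        for _ in range(5):
            tr = simulate_trial(state, spec, plant)
            ends.append(tr.cursor[-1, 2])
            state.finish_trial(tr, rng=rng)
        assert np.ptp(ends) == 0.0  # endpoint error never changes

    def test_failure_draws_around_memory(self, plant, rng):
        state = self._state(plant)
        spec = TrialSpec(30.0, 30.0, "perturbed")
        tr = simulate_trial(state, spec, plant)
        assert not tr.hit
        state.finish_trial(tr, rng=rng)
        assert state.aim_memory == 0.0
        assert abs(state.aim) <= default_p_max()
        assert state.aim != 0.0

    def test_acquisition_rate_over_seeds(self, plant):
        """Most seeded exploration runs find and keep the target within 50
        perturbed trials (analytic per-trial hit chance ~8/90 per draw)."""
        wins = 0
        n = 60
        for seed in range(n):
            rng = np.random.default_rng(seed)
            state = self._state(plant)
            spec = TrialSpec(30.0, 30.0, "perturbed")
            hit_at = None
            for t in range(50):
                tr = simulate_trial(state, spec, plant)
                state.finish_trial(tr, rng=rng)
                if tr.hit:
                    hit_at = t
                    break
            wins += hit_at is not None
        assert wins / n >= 0.95


class TestFeedback:
    def test_zero_before_delay_elapses(self, plant):
        lp = LearnerParams()
        err = np.ones((plant.k_end + 1, 4))
        for k in range(lp.delay_steps(plant) + 1):
            assert np.all(feedback_command(err, lp, k, plant) == 0.0)

    def test_delayed_proportional_on_position(self, plant):
        lp = LearnerParams()
        e = np.tile([0.1, 0.0, -0.2, 0.0], (plant.k_end + 1, 1))
        out = feedback_command(e, lp, 20, plant)
        np.testing.assert_allclose(out, [0.45 * 0.1, 0.45 * -0.2])

    def test_zero_gain_matrix(self, plant):
        lp = LearnerParams(C=((0.0,) * 4,) * 2)
        e = np.ones((plant.k_end + 1, 4))
        assert np.all(feedback_command(e, lp, 30, plant) == 0.0)

    def test_disabled_when_no_vision(self, plant):
        lp = LearnerParams(feedback_on=False)
        e = np.ones((plant.k_end + 1, 4))
        assert np.all(feedback_command(e, lp, 30, plant) == 0.0)


class TestCombine:
    def test_sum_matches_arithmetic(self, rng):
        a, b, c = rng.normal(size=(3, 40, 2))
        np.testing.assert_array_equal(combine(a, b, c), a + b + c)

    def test_rotation_by_zero_is_identity(self, u0):
        np.testing.assert_allclose(rotate_commands(u0, 0.0), u0)
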