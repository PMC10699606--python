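"""Trial-to-trial learning: sensorimotor adaptation, reward learning, feedback.

Three command sources sum into the motor command of each step
(``u = u_RW + u_SM + u_FB``):

* **Sensorimotor adaptation** -- iterative learning control (ILC): the
  feedforward command is revised from one trial to the next from the
  previous trial's sensory prediction error, with a forgetting factor
  ``b``::

      u_SM_j(k) = b * u_SM_{j-1}(k) + L @ e_{j-1}(k + 1)  (+ motor noise)

  The one-step error anticipation makes the scheme non-causal in trial
  time, which is what lets a per-step gain matrix contract the error
  across iterations. This pathway models implicit adaptation: it updates
  the internal model and is blind to the perturbation cue, so it produces
  aftereffects on both catch and de-adaptation trials.

* **Explicit reward learning** -- a scalar reward prediction error (the
  end-point arc miss, its whole-movement integrated form, or a binary
  hit/miss) re-aims the planned movement direction::

      aim_j = aim_{j-1} + p * e_RW_{j-1}
      u_RW_j = R(aim_j) @ u_0

  i.e. the reward command sequence is the fallback command of the
  unperturbed straight reach rotated to the new aim, so a reward-learned
  movement is a straight reach at the re-aimed angle (``u_RW_1 = u_0``,
  aim 0). Because this pathway is an explicit strategy, a cue announcing
  that the perturbation is gone resets the aim to zero and the commands
  to the fallback ``u_0`` -- hence no aftereffect on de-adaptation
  trials.

* **Feedback control** -- within-trial delayed error feedback
  ``u_FB(k) = C @ e(k - delay_steps)``, active only when sensory
  information is available during the movement.

The sensory error is exposed in the polar cursor frame (deg for angular
components, matching how the perturbation is specified); the gain matrices
``L`` and ``C`` act on the error expressed in metric cursor coordinates
``[e_along, e_along_dot, e_lateral, e_lateral_dot]`` (m, m/s), the frame
in which the reward error's arc-length units also live.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .plant import (
    DesiredTrajectory,
    PlantParams,
    Trial,
    inverse_dynamics,
    min_jerk_trajectory,
)

__all__ = [
    "SENSORY_NOISE_VAR",
    "MOTOR_NOISE_VAR",
    "L_SENSORIMOTOR",
    "L_EPE_COMBINED",
    "C_FEEDBACK",
    "SensoryError",
    "RewardError",
    "LearnerParams",
    "LearnerState",
    "sensory_error",
    "reward_error",
    "update_sensorimotor",
    "update_reward",
    "explore_binary",
    "feedback_command",
    "combine",
    "default_p_max",
    "rotate_commands",
    "scaled",
]

_D2R = np.pi / 180.0

#: Sensory-noise variances on the polar error channels
#: (distance m^2, radial velocity m^2/s^2, angle deg^2, angular velocity deg^2/s^2).
SENSORY_NOISE_VAR = (0.002, 0.004, 0.3, 0.05)

#: Motor-noise variances on the two force channels (N^2): radial, angular.
MOTOR_NOISE_VAR = (0.02, 0.8)

#: Sensorimotor adaptation gains: rows -> (f_d, f_gamma), columns ->
#: (e_along, e_along_dot, e_lateral, e_lateral_dot).
L_SENSORIMOTOR = ((0.02, 0.9, 0.0, 0.0), (0.0, 0.0, 0.02, 0.9))

#: Sensorimotor gains of the combined end-point-error regime (note the
#: asymmetric lateral velocity gain, kept as published).
L_EPE_COMBINED = ((0.0012, 0.96, 0.0, 0.0), (0.0, 0.0, 0.0012, 0.096))

#: Feedback gains (position-only PD degenerate).
C_FEEDBACK = ((0.45, 0.0, 0.0, 0.0), (0.0, 0.0, 0.45, 0.0))


@dataclass(frozen=True)
class SensoryError:
    """Per-step cursor error of one trial, desired minus observed.

    ``polar`` has columns (e_d m, e_d_dot m/s, e_gamma deg, e_gamma_dot
    deg/s); ``metric`` the same error in metric cursor coordinates. Both
    have ``k_end + 1`` rows.
    """

    polar: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        if self.polar.shape != self.metric.shape or self.polar.shape[1] != 4:
            raise ValueError("error arrays must be (k_end + 1, 4) and congruent")


@dataclass(frozen=True)
class RewardError:
    """Scalar reward prediction error.

    ``value`` is signed with arc-length units (m) for the integrated and
    end-point modes, or 0/1 for the binary mode (0 = rewarded).
    """

    value: float
    mode: Literal["integrated", "endpoint", "binary"]


def default_p_max(params: PlantParams | None = None,
                  max_reaim_deg: float = 45.0) -> float:
    """Exploration half-range (radians of re-aim per unit binary error):
    a single draw can re-aim the reach by up to ``max_reaim_deg``."""
    return float(np.radians(max_reaim_deg))


def rotate_commands(u: np.ndarray, aim_rad: float) -> np.ndarray:
    """Command sequence of the same reach planned at polar angle ``aim``.

    Rotates each (f_d, f_gamma) force vector by ``aim`` (positive
    rightward), so the straight-reach fallback becomes a straight reach
    towards a re-aimed target.
    """
    c, s = np.cos(aim_rad), np.sin(aim_rad)
    out = np.empty_like(u)
    out[:, 0] = c * u[:, 0] - s * u[:, 1]
    out[:, 1] = s * u[:, 0] + c * u[:, 1]
    return out


@dataclass(frozen=True)
class LearnerParams:
    """All tunable constants of the three learning pathways.

    ``L``/``C`` are 2x4 gain matrices on the metric error; ``b`` the
    sensorimotor forgetting factor; ``p`` the explicit reward learning
    rate; ``delay_s`` the feedback reaction time; ``reward_mode`` selects
    which reward error drives explicit re-aiming (``None``
    disables it); ``p_max`` the half-range of the uniform exploration draw
    in the binary regime (``None`` -> sized for a 45 deg re-aim);
    ``anticipation_steps`` the non-causal error shift of the ILC update.
    """

    L: tuple = L_SENSORIMOTOR
    C: tuple = C_FEEDBACK
    b: float = 0.995
    p: float = 0.0
    delay_s: float = 0.3
    feedback_on: bool = True
    reward_mode: Literal["integrated", "endpoint", "binary", None] = None
    p_max: float | None = None
    anticipation_steps: int = 1
    sensory_noise_var: tuple = SENSORY_NOISE_VAR
    motor_noise_var: tuple = MOTOR_NOISE_VAR

    def __post_init__(self) -> None:
        if not (0 < self.b <= 1):
            raise ValueError("forgetting factor b must be in (0, 1]")
        if self.delay_s < 0:
            raise ValueError("feedback delay must be non-negative")
        L = np.asarray(self.L, float)
        C = np.asarray(self.C, float)
        if L.shape != (2, 4) or C.shape != (2, 4):
            raise ValueError("L and C must be 2x4 matrices")
        if not (np.all(np.isfinite(L)) and np.all(np.isfinite(C))):
            raise ValueError("gain matrices must be finite")

    @property
    def L_matrix(self) -> np.ndarray:
        return np.asarray(self.L, float)

    @property
    def C_matrix(self) -> np.ndarray:
        return np.asarray(self.C, float)

    def delay_steps(self, params: PlantParams) -> int:
        return int(round(self.delay_s / params.dt))


@dataclass
class LearnerState:
    """Across-trial memory of the learner.

    Holds the sensorimotor command sequence ``u_sm``, the explicit aim
    angle and its reward command sequence ``u_rw`` (the fallback ``u0``
    rotated to the aim), the binary-regime success memory (the last
    rewarded aim), and the previous trial's errors. ``feedforward()`` and
    ``feedback`` satisfy the interface that
    :func:`vmrsim.plant.simulate_trial` expects.
    """

    plant: PlantParams
    params: LearnerParams
    u_sm: np.ndarray = field(init=False)
    u_rw: np.ndarray = field(init=False)
    u0: np.ndarray = field(init=False)
    aim: float = field(init=False, default=0.0)
    aim_memory: float = field(init=False, default=0.0)
    last_error: SensoryError | None = field(init=False, default=None)
    last_reward: RewardError | None = field(init=False, default=None)
    last_hit: bool | None = field(init=False, default=None)
    desired: DesiredTrajectory = field(init=False, repr=False)

    def __post_init__(self) -> None:
        K = self.plant.k_end
        self.desired = min_jerk_trajectory(self.plant)
        self.u0 = inverse_dynamics(self.desired, self.plant)
        self.u_sm = np.zeros((K, 2))
        self.u_rw = self.u0.copy()
        self.aim = 0.0
        self.aim_memory = 0.0

    def feedforward(self) -> np.ndarray:
        return combine(self.u_rw, self.u_sm, 0.0)

    @property
    def feedback(self):
        if not self.params.feedback_on:
            return None
        return self.params.C_matrix, self.params.delay_steps(self.plant)

    # -- across-trial orchestration -------------------------------------

    def start_trial(self, cue: float, role: str) -> None:
        """Apply cue semantics before a trial is executed.

        A de-adaptation cue (perturbation announced absent after learning)
        resets the explicit pathway to the fallback commands and discards
        the accumulated reward corrections; the implicit pathway is
        untouched. Catch trials carry the old cue, so nothing is reset.
        """
        if role == "deadaptation":
            self.aim = 0.0
            self.aim_memory = 0.0
            self.u_rw = self.u0.copy()

    def finish_trial(self, trial: Trial, rng: np.random.Generator | None = None,
                     motor_noise: bool = False) -> None:
        """Consume a completed trial: store errors, update both pathways."""
        self.last_error = SensoryError(trial.sensory_error.copy(),
                                       trial.metric_error.copy())
        self.last_hit = trial.hit
        if self.params.reward_mode is not None:
            self.last_reward = reward_error(
                self.last_error, trial, self.params.reward_mode,
                target_radius=self.plant.target_radius)
        self.u_sm = update_sensorimotor(self, self.params,
                                        motor_noise=motor_noise, rng=rng)
        if self.params.reward_mode == "binary":
            self.u_rw = explore_binary(self, self.params, rng)
        elif self.params.reward_mode is not None:
            self.u_rw = update_reward(self, self.params)


def sensory_error(
    desired: DesiredTrajectory,
    trial: Trial,
    noise_on: bool = False,
    rng: np.random.Generator | None = None,
    noise_var: tuple = SENSORY_NOISE_VAR,
) -> SensoryError:
    """Per-step error between the desired and the observed cursor.

    The error is computed in visual (cursor) coordinates: under a
    visuomotor rotation a straight hand reach yields a constant angular
    error of ``-beta`` degrees. With ``noise_on`` Gaussian noise with the
    configured per-channel variances is added to the polar error and
    propagated to the metric form.
    """
    cur = trial.cursor
    pol = np.column_stack([
        desired.d - cur[:, 0],
        desired.d_dot - cur[:, 1],
        desired.gamma - cur[:, 2],
        desired.gamma_dot - cur[:, 3],
    ])
    if pol.shape[0] != desired.d.shape[0]:
        raise ValueError("trial length does not match the desired trajectory")
    if noise_on:
        if rng is None:
            raise ValueError("rng required when noise_on")
        pol = pol + rng.normal(0.0, np.sqrt(noise_var), size=pol.shape)
    from .plant import _metric_error_from_polar

    return SensoryError(pol, _metric_error_from_polar(pol, desired))


def reward_error(
    err: SensoryError,
    trial: Trial,
    mode: Literal["integrated", "endpoint", "binary"],
    target_radius: float | None = None,
) -> RewardError:
    """Scalar reward prediction error of one trial.

    * ``integrated``: mean over steps of ``2 * e_gamma(l) * d(l)`` with the
      angular error in radians and ``d`` the observed cursor distance --
      an arc-length-weighted angular miss (m).
    * ``endpoint``: the same product at the final step only.
    * ``binary``: 0 if ``|endpoint value| <= r`` else 1, with ``r`` the
      target radius.
    """
    e_gamma_rad = err.polar[:, 2] * _D2R
    d_cursor = trial.cursor[:, 0]
    if mode == "integrated":
        v = float(np.mean(2.0 * e_gamma_rad[1:] * d_cursor[1:]))
    elif mode in ("endpoint", "binary"):
        v = float(2.0 * e_gamma_rad[-1] * d_cursor[-1])
        if mode == "binary":
            r = trial.params.target_radius if target_radius is None else target_radius
            return RewardError(0.0 if abs(v) <= r else 1.0, "binary")
    else:
        raise ValueError(f"unknown reward mode: {mode!r}")
    return RewardError(v, mode)


def update_sensorimotor(
    state: LearnerState,
    params: LearnerParams,
    motor_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Next trial's sensorimotor command sequence (ILC with forgetting).

    ``u_sm(k) <- b * u_sm(k) + L @ e(k + s)`` with ``s`` the anticipation
    shift (the final step reuses the last available error sample). Before
    the first trial ``u_sm`` is all zeros; with ``L = 0`` it therefore
    stays zero, and with zero error it shrinks by ``b`` per trial.
    """
    K = state.plant.k_end
    u = params.b * state.u_sm
    if state.last_error is not None:
        idx = np.minimum(np.arange(K) + params.anticipation_steps, K)
        u = u + state.last_error.metric[idx] @ params.L_matrix.T
    if motor_noise:
        if rng is None:
            raise ValueError("rng required for motor noise")
        u = u + rng.normal(0.0, np.sqrt(params.motor_noise_var), size=u.shape)
    return u


def update_reward(state: LearnerState, params: LearnerParams) -> np.ndarray:
    """Next trial's explicit reward command sequence.

    Advances the aim by ``p * e_RW`` (radians; the reward error carries
    the signed arc-length miss) and returns the fallback commands rotated
    to the new aim -- the movement is re-planned towards a shifted
    target. With ``p = 0`` the aim, and hence the sequence, stays at the
    fallback forever. Updates ``state.aim``.
    """
    if state.last_reward is not None and params.p != 0.0:
        state.aim = state.aim + params.p * state.last_reward.value
    return rotate_commands(state.u0, state.aim)


def explore_binary(
    state: LearnerState,
    params: LearnerParams,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Binary-reward exploration with success memory.

    Success (the previous reach hit the target) commits that trial's aim
    to memory and replays its commands unchanged. Failure draws a fresh
    re-aim ``p ~ Uniform(-p_max, p_max)`` (radians) applied to the stored
    memory aim (the last rewarded aim; straight ahead before any
    success) -- the binary error magnitude of 1 replaces the graded
    end-point error in the explicit update. Updates ``state.aim`` and
    ``state.aim_memory``.
    """
    if state.last_hit:
        state.aim_memory = state.aim
        return rotate_commands(state.u0, state.aim)
    p_max = default_p_max(state.plant) if params.p_max is None else params.p_max
    if p_max == 0.0:
        state.aim = state.aim_memory
        return rotate_commands(state.u0, state.aim)
    if rng is None:
        raise ValueError("rng required for binary exploration")
    state.aim = state.aim_memory + rng.uniform(-p_max, p_max)
    return rotate_commands(state.u0, state.aim)


def feedback_command(
    err_history: np.ndarray,
    params: LearnerParams,
    k: int,
    plant: PlantParams,
) -> np.ndarray:
    """Delayed within-trial feedback command at step ``k``.

    ``C @ e(k - delay_steps)`` on the metric error history of the current
    trial; the zero vector while ``k <= delay_steps`` or when feedback is
    disabled (no sensory information during the movement).
    """
    ds = params.delay_steps(plant)
    if not params.feedback_on or k <= ds:
        return np.zeros(2)
    return params.C_matrix @ np.asarray(err_history)[k - ds]


def combine(u_rw, u_sm, u_fb) -> np.ndarray:
    """Componentwise sum of the three command contributions (no clipping)."""
    return np.asarray(u_rw) + np.asarray(u_sm) + np.asarray(u_fb)


def scaled(params: LearnerParams, L_scale: float) -> LearnerParams:
    """Copy of ``params`` with the sensorimotor gain matrix scaled."""
    L = tuple(tuple(v * L_scale for v in row) for row in params.L)
    return replace(params, L=L)
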