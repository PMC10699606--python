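"""Point-mass arm plant for visuomotor-rotation reaching.

The hand is a point mass moving in the horizontal plane. Reaches start at
the origin and aim at a target straight ahead at distance ``D`` along the
+y axis. Two force channels drive the mass: ``f_d`` along the target axis
and ``f_gamma`` perpendicular to it (the lateral/tangential channel that a
visuomotor rotation recruits). Integration is forward Euler in Cartesian
coordinates; the state is reported in polar form
``(d, d_dot, gamma, gamma_dot)`` -- radial distance (m), radial velocity
(m/s), polar angle (deg, positive rightward/clockwise of straight ahead)
and angular velocity (deg/s) -- which is the frame in which perturbations
and kinematic metrics are expressed.

A visuomotor rotation of ``beta`` degrees rotates the displayed cursor
about the start position, i.e. adds ``beta`` to the observed polar angle
while leaving radial quantities untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "PlantParams",
    "ArmState",
    "ControlVector",
    "Observation",
    "DesiredTrajectory",
    "Trial",
    "InstabilityError",
    "step",
    "observe",
    "min_jerk_trajectory",
    "inverse_dynamics",
    "simulate_trial",
]

_R2D = 180.0 / np.pi
_D2R = np.pi / 180.0


class InstabilityError(RuntimeError):
    """Raised when a simulated trial diverges (non-finite or runaway state)."""


@dataclass(frozen=True)
class PlantParams:
    """Physical and discretization constants of the reaching plant.

    Parameters
    ----------
    m : float
        Point mass in kg. The printed learning gains are interpreted
        relative to unit mass.
    dt : float
        Integration step in seconds.
    k_end : int
        Number of time steps per trial; trial duration is ``k_end * dt``.
    target_distance : float
        Reach amplitude D in metres.
    target_radius : float
        Radius of the target disc in metres (hit window).
    d_min : float
        Pole guard radius in metres: below this distance the polar angular
        velocity is reported against ``d_min`` instead of ``d`` to avoid
        the coordinate singularity at the start position.
    """

    m: float = 1.0
    dt: float = 0.02
    k_end: int = 40
    target_distance: float = 0.10
    target_radius: float = 0.007
    d_min: float = 0.005

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if self.k_end < 2:
            raise ValueError("k_end must be at least 2")
        for name in ("m", "target_distance", "target_radius", "d_min"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")

    @property
    def duration(self) -> float:
        return self.k_end * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.k_end + 1) * self.dt


class ArmState(NamedTuple):
    """Plant state at one time step, polar frame (m, m/s, deg, deg/s)."""

    d: float
    d_dot: float
    gamma: float
    gamma_dot: float


class ControlVector(NamedTuple):
    """Force command at one time step: along-axis and lateral channels (N)."""

    f_d: float
    f_gamma: float


class Observation(NamedTuple):
    """Cursor state: plant state with the visuomotor rotation applied."""

    d: float
    d_dot: float
    gamma: float
    gamma_dot: float


def _polar_to_cart(d, d_dot, gamma, gamma_dot):
    """Exact polar -> Cartesian map; gamma in degrees, x lateral, y ahead."""
    g = np.asarray(gamma) * _D2R
    gd = np.asarray(gamma_dot) * _D2R
    sin, cos = np.sin(g), np.cos(g)
    x = d * sin
    y = d * cos
    vx = d_dot * sin + d * gd * cos
    vy = d_dot * cos - d * gd * sin
    return x, vx, y, vy


def _cart_to_polar(x, vx, y, vy, d_min: float):
    d = np.hypot(x, y)
    gamma = np.degrees(np.arctan2(x, y))
    d_safe = np.maximum(d, 1e-12)
    d_dot = (x * vx + y * vy) / d_safe
    d_lever = np.maximum(d, d_min)
    gamma_dot = np.degrees((vx * y - vy * x) / d_lever**2)
    return d, d_dot, gamma, gamma_dot


def step(state: ArmState, control: ControlVector, params: PlantParams) -> ArmState:
    """Advance the plant one time step under the given force command.

    Semi-implicit (symplectic) Euler point-mass update in Cartesian
    coordinates -- velocities first, then positions::

        vx+ = vx + dt * f_gamma / m        x+ = x + dt * vx+
        vy+ = vy + dt * f_d / m            y+ = y + dt * vy+

    reported back in polar form. On the target axis (gamma = 0) this gives
    ``d_dot+ = d_dot + dt*f_d/m`` and ``d+ = d + dt*d_dot+`` (so a coasting
    state drifts by ``dt*d_dot`` per step). The velocity-first ordering
    makes the straight-reach inverse dynamics exact from rest. The input
    state is not mutated.
    """
    vals = np.array(tuple(state) + tuple(control), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite plant state or control: {state}, {control}")
    x, vx, y, vy = _polar_to_cart(*state)
    dt, m = params.dt, params.m
    vx2 = vx + dt * control.f_gamma / m
    vy2 = vy + dt * control.f_d / m
    x2 = x + dt * vx2
    y2 = y + dt * vy2
    return ArmState(*(float(v) for v in _cart_to_polar(x2, vx2, y2, vy2, params.d_min)))


def observe(state: ArmState, beta: float) -> Observation:
    """Apply the visuomotor rotation: the cursor angle is the hand angle
    plus ``beta`` degrees; radial quantities and rates are unchanged."""
    return Observation(state.d, state.d_dot, state.gamma + beta, state.gamma_dot)


@dataclass(frozen=True)
class DesiredTrajectory:
    """Reference cursor trajectory: a straight reach along the target axis.

    Arrays have ``k_end + 1`` samples (k = 0 .. k_end). ``d``/``d_dot``
    follow the minimum-jerk profile; the angular channels are identically
    zero (straight ahead).
    """

    params: PlantParams
    d: np.ndarray
    d_dot: np.ndarray
    gamma: np.ndarray
    gamma_dot: np.ndarray

    @property
    def xy(self) -> np.ndarray:
        """(k_end+1, 2) Cartesian positions [x, y] in metres."""
        return np.column_stack([np.zeros_like(self.d), self.d])


def min_jerk_trajectory(params: PlantParams) -> DesiredTrajectory:
    """Minimum-jerk straight reach from the origin to the target.

    Positions follow d(t) = D (10 tau^3 - 15 tau^4 + 6 tau^5), tau = t/T
    (analytic peak speed (15/8) D/T at midpoint). Velocities are the
    discrete backward differences of the sampled positions (start at
    rest), so that the semi-implicit-Euler plant reproduces the positions
    exactly when fed the inverse-dynamics commands.
    """
    T = params.duration
    tau = params.times / T
    D = params.target_distance
    d = D * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    d_dot = np.insert(np.diff(d) / params.dt, 0, 0.0)
    zeros = np.zeros_like(d)
    return DesiredTrajectory(params, d, d_dot, zeros, zeros.copy())


def inverse_dynamics(desired: DesiredTrajectory, params: PlantParams) -> np.ndarray:
    """Feedforward command sequence u_0 reproducing the desired reach.

    Returns an (k_end, 2) array of [f_d, f_gamma] per step. For the
    straight minimum-jerk reach the lateral channel is identically zero and
    f_d(k) = m * (d_dot(k+1) - d_dot(k)) / dt, so that replaying u_0
    open-loop from rest with no rotation reproduces the desired positions
    to round-off.
    """
    if desired.d.shape != (params.k_end + 1,):
        raise ValueError(
            f"desired trajectory has {desired.d.shape[0]} samples, "
            f"expected {params.k_end + 1}"
        )
    u = np.zeros((params.k_end, 2))
    u[:, 0] = params.m * np.diff(desired.d_dot) / params.dt
    return u


@dataclass
class Trial:
    """One completed reach: commands, hand states, cursor observations.

    State arrays have ``k_end + 1`` rows (polar columns d, d_dot, gamma,
    gamma_dot); ``commands`` has ``k_end`` rows ([f_d, f_gamma]).
    ``sensory_error`` is the per-step cursor error in the polar frame
    (desired minus observed; deg for angle), possibly noisy if sensory
    noise was enabled. ``metric_error`` is the same error expressed in
    metric cursor coordinates [e_along, e_along_dot, e_lat, e_lat_dot]
    (m, m/s) -- the frame the learning and feedback gains act on.
    """

    beta: float
    cue: float
    role: str
    commands: np.ndarray
    states: np.ndarray
    cursor: np.ndarray
    sensory_error: np.ndarray
    metric_error: np.ndarray
    params: PlantParams = field(repr=False)

    def __post_init__(self) -> None:
        if self.role == "catch" and not (self.beta == 0 and self.cue != 0):
            raise ValueError("catch trials must have beta = 0 and a nonzero cue")
        if self.role == "deadaptation" and not (self.beta == 0 and self.cue == 0):
            raise ValueError("de-adaptation trials must have beta = 0 and cue = 0")

    @property
    def hand_xy(self) -> np.ndarray:
        x, _, y, _ = _polar_to_cart(*self.states.T)
        return np.column_stack([x, y])

    @property
    def cursor_xy(self) -> np.ndarray:
        x, _, y, _ = _polar_to_cart(*self.cursor.T)
        return np.column_stack([x, y])

    @property
    def hit(self) -> bool:
        """End point of the cursor within the target disc."""
        end = self.cursor_xy[-1] - np.array([0.0, self.params.target_distance])
        return bool(np.hypot(*end) <= self.params.target_radius)


def _metric_error_from_polar(err_polar: np.ndarray, desired: DesiredTrajectory) -> np.ndarray:
    """Convert a polar-frame cursor error sequence to metric coordinates.

    Reconstructs the (possibly noise-perturbed) cursor implied by the error
    and differences it from the desired Cartesian trajectory, so noise on
    the polar error propagates consistently to the learner's frame.
    """
    cd = desired.d - err_polar[:, 0]
    cdd = desired.d_dot - err_polar[:, 1]
    cg = desired.gamma - err_polar[:, 2]
    cgd = desired.gamma_dot - err_polar[:, 3]
    x, vx, y, vy = _polar_to_cart(cd, cdd, cg, cgd)
    _, dvx, dy, dvy = 0.0, np.zeros_like(x), desired.d, desired.d_dot
    return np.column_stack([dy - y, dvy - vy, 0.0 - x, dvx - vx])


def simulate_trial(
    learner_state,
    trial_spec,
    params: PlantParams,
    *,
    sensory_noise_sd: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> Trial:
    """Roll the plant through one trial under a learner's commands.

    ``learner_state`` must provide ``feedforward()`` returning the
    (k_end, 2) feedforward command array (reward + sensorimotor components)
    and a ``feedback`` attribute that is either ``None`` or a pair
    ``(C, delay_steps)`` with C a (2, 4) gain matrix on the metric error.
    The feedback command at step k is ``C @ e(k - delay_steps)`` and zero
    while ``k <= delay_steps`` (no sensory information has arrived yet).

    ``trial_spec`` carries ``beta`` (imposed rotation, deg), ``cue``
    (declared rotation, deg) and ``role``. If ``sensory_noise_sd`` (four
    per-channel standard deviations in the polar error units) is given,
    Gaussian noise is added to the stored per-step sensory error and hence
    to what feedback control and subsequent learning see.
    """
    K = params.k_end
    desired = min_jerk_trajectory(params)
    u_ff = np.asarray(learner_state.feedforward(), dtype=float)
    if u_ff.shape != (K, 2):
        raise ValueError(f"feedforward commands must be ({K}, 2), got {u_ff.shape}")
    fb = getattr(learner_state, "feedback", None)
    if fb is not None:
        C, delay_steps = np.asarray(fb[0], dtype=float), int(fb[1])

    beta = float(trial_spec.beta)
    cb, sb = np.cos(beta * _D2R), np.sin(beta * _D2R)
    noise_sd = None if sensory_noise_sd is None else np.asarray(sensory_noise_sd, float)
    if noise_sd is not None and rng is None:
        raise ValueError("rng is required when sensory noise is enabled")

    hand = np.zeros((K + 1, 4))            # x, vx, y, vy
    err_polar = np.zeros((K + 1, 4))
    err_metric = np.zeros((K + 1, 4))
    commands = np.zeros((K, 2))

    def record_errors(k: int) -> None:
        x, vx, y, vy = hand[k]
        cx, cvx = cb * x + sb * y, cb * vx + sb * vy
        cy, cvy = -sb * x + cb * y, -sb * vx + cb * vy
        cd, cdd, cg, cgd = _cart_to_polar(cx, cvx, cy, cvy, params.d_min)
        e = np.array([desired.d[k] - cd, desired.d_dot[k] - cdd,
                      desired.gamma[k] - cg, desired.gamma_dot[k] - cgd])
        if noise_sd is not None:
            e = e + rng.normal(0.0, noise_sd)
            ncd, ncdd = desired.d[k] - e[0], desired.d_dot[k] - e[1]
            ncg, ncgd = desired.gamma[k] - e[2], desired.gamma_dot[k] - e[3]
            nx, nvx, ny, nvy = _polar_to_cart(ncd, ncdd, ncg, ncgd)
        else:
            nx, nvx, ny, nvy = cx, cvx, cy, cvy
        err_polar[k] = e
        err_metric[k] = [desired.d[k] - ny, desired.d_dot[k] - nvy, -nx, -nvx]

    record_errors(0)
    dt, m = params.dt, params.m
    bound = 50.0 * params.target_distance
    for k in range(K):
        f = u_ff[k].copy()
        if fb is not None and k > delay_steps:
            f += C @ err_metric[k - delay_steps]
        commands[k] = f
        x, vx, y, vy = hand[k]
        nvx = vx + dt * f[1] / m
        nvy = vy + dt * f[0] / m
        hand[k + 1] = [x + dt * nvx, nvx, y + dt * nvy, nvy]
        if not np.all(np.isfinite(hand[k + 1])) or np.max(np.abs(hand[k + 1][[0, 2]])) > bound:
            gains = "feedback gain C" if fb is not None else "feedforward commands"
            raise InstabilityError(
                f"trial diverged at step {k + 1} (|state| > {bound:g} m); "
                f"check the learning gains L/p and {gains}"
            )
        record_errors(k + 1)

    x, vx, y, vy = hand.T
    states = np.column_stack(_cart_to_polar(x, vx, y, vy, params.d_min))
    cursor = states.copy()
    cursor[:, 2] += beta
    return Trial(
        beta=beta,
        cue=float(trial_spec.cue),
        role=str(trial_spec.role),
        commands=commands,
        states=states,
        cursor=cursor,
        sensory_error=err_polar,
        metric_error=err_metric,
        params=params,
    )
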