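"""Reach-kinematics metrics: filtering, segmentation, path area, angle.

Works on 2-D cursor (or hand) trajectories from either the simulator or
motion capture. Conventions: coordinates in cm, the reach goes from the
start position at the origin towards a target on the +y axis at 10 cm;
positive x is rightward. Both signed metrics are positive for rightward
(clockwise) deviation; counter-clockwise-rotation trials are sign-flipped
before averaging so both directions can be pooled.

* **Cursor path area** (cm^2): signed area enclosed between the trajectory
  and the straight start-target chord. If the trajectory misses the
  target, the region is closed along the trial-end circle (radius 10 cm
  about the start) from the exit point to the target before integrating.
* **Cursor angle** (deg): direction of the displacement vector over the
  160 ms following movement onset (first sample at speed >= 0.025 m/s),
  relative to straight ahead. Captures the feedforward initial aim before
  feedback corrections arrive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import signal

from .plant import Trial

__all__ = [
    "Trajectory2D",
    "TrialMetrics",
    "IncompleteTrialError",
    "OnsetError",
    "lowpass_filter",
    "segment_trial",
    "cursor_path_area",
    "cursor_angle",
    "normalize_sign",
    "trial_to_trajectory",
    "make_fixture_trajectories",
]

TARGET_DISTANCE_CM = 10.0
TARGET_RADIUS_CM = 0.7
START_RADIUS_CM = 0.4
ONSET_SPEED_CM_S = 2.5     # 0.025 m/s
ANGLE_WINDOW_S = 0.160


class IncompleteTrialError(ValueError):
    """Trajectory never reaches the trial-end radius."""


class OnsetError(ValueError):
    """Speed never reaches the movement-onset threshold."""


@dataclass(frozen=True)
class Trajectory2D:
    """Uniformly sampled planar trajectory; t in s, x/y in cm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        if len(t) != len(self.x) or len(t) != len(self.y):
            raise ValueError("t, x, y must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def r(self) -> np.ndarray:
        """Distance from the start position (cm)."""
        return np.hypot(self.x, self.y)


@dataclass(frozen=True)
class TrialMetrics:
    """Signed kinematic metrics of one trial."""

    cursor_path_area: float
    cursor_angle: float
    hit: bool
    direction: Literal["cw", "ccw", "none"] = "none"


def trial_to_trajectory(trial: Trial, which: str = "cursor") -> Trajectory2D:
    """Cursor (or hand) path of a simulated trial as a cm trajectory."""
    xy = trial.cursor_xy if which == "cursor" else trial.hand_xy
    t = trial.params.times
    return Trajectory2D(t, xy[:, 0] * 100.0, xy[:, 1] * 100.0,
                        fs=1.0 / trial.params.dt)


def lowpass_filter(traj: Trajectory2D, cutoff_hz: float = 10.0,
                   order: int = 4) -> Trajectory2D:
    """Zero-phase Butterworth low-pass of both coordinates.

    Forward-backward filtering keeps the onset timing unbiased (phase lag
    would shift the cursor-angle window). The design is rate-aware; the
    sampling rate must exceed twice the cutoff.
    """
    if traj.fs <= 2 * cutoff_hz:
        raise ValueError(f"sampling rate {traj.fs} Hz too low for a "
                         f"{cutoff_hz} Hz cutoff")
    padlen = 3 * (order + 1)
    if len(traj) <= padlen:
        raise ValueError(f"trajectory too short to filter ({len(traj)} samples)")
    sos = signal.butter(order, cutoff_hz, fs=traj.fs, output="sos")
    return replace(traj,
                   x=signal.sosfiltfilt(sos, traj.x),
                   y=signal.sosfiltfilt(sos, traj.y))


def segment_trial(traj: Trajectory2D,
                  start_radius: float = START_RADIUS_CM,
                  end_radius: float | None = TARGET_DISTANCE_CM) -> Trajectory2D:
    """Clip the trajectory to the analysed movement.

    Returns the sub-trajectory from the first sample at/after the crossing
    of ``start_radius`` up to (and including) the first sample at/after the
    crossing of ``end_radius``. No sub-sample interpolation: the bias is
    below one sample. Raises :class:`IncompleteTrialError` if the movement
    never reaches the end radius; ``end_radius=None`` keeps the movement to
    its final sample instead.
    """
    r = traj.r
    started = np.nonzero(r >= start_radius)[0]
    i0 = int(started[0]) if len(started) else 0
    if end_radius is None:
        i1 = len(r) - 1
    else:
        tol = 1e-6 * end_radius      # round-off guard for reaches ending
        finished = np.nonzero(r[i0:] >= end_radius - tol)[0]
        if not len(finished):
            raise IncompleteTrialError(
                f"trajectory never crosses the {end_radius} cm radius")
        i1 = i0 + int(finished[0])
    sl = slice(i0, i1 + 1)
    return Trajectory2D(traj.t[sl], traj.x[sl], traj.y[sl], traj.fs)


def cursor_path_area(traj: Trajectory2D,
                     target_xy: tuple = (0.0, TARGET_DISTANCE_CM),
                     end_radius: float = TARGET_DISTANCE_CM) -> float:
    """Signed area (cm^2) between the path and the start-target chord.

    Computed as the line integral of x dy along the path (trapezoidal),
    which is the signed enclosed area once the boundary is closed: the
    chord back along the y-axis contributes nothing. A rightward bulge is
    positive. If the path's end point is not the target, the boundary is
    first closed along the trial-end circle from the exit point to the
    target (shorter arc), so end-point misses contribute the wedge between
    exit point and target.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 samples")
    x, y = traj.x, traj.y
    area = float(np.trapezoid(x, y))
    tx, ty = target_xy
    ex, ey = x[-1], y[-1]
    if np.hypot(ex - tx, ey - ty) > 1e-9:
        # close the region: project the exit point radially onto the
        # trial-end circle (no-op when the path ends on it), then follow
        # the shorter arc to the target
        r_end = np.hypot(ex, ey)
        if abs(r_end - end_radius) > 1e-9 and r_end > 0:
            s = end_radius / r_end
            area += float(ex * ey * (s**2 - 1.0) / 2.0)
        a0 = np.arctan2(ex, ey)
        a1 = np.arctan2(tx, ty)
        n = max(8, int(abs(a1 - a0) / 0.01))
        ang = np.linspace(a0, a1, n)
        area += float(np.trapezoid(end_radius * np.sin(ang),
                                   end_radius * np.cos(ang)))
    return area


def cursor_angle(traj: Trajectory2D,
                 v_threshold: float = ONSET_SPEED_CM_S,
                 window: float = ANGLE_WINDOW_S) -> float:
    """Initial movement direction (deg, positive rightward).

    Movement onset is the first sample whose finite-difference speed
    reaches ``v_threshold`` (cm/s); the angle is that of the displacement
    vector from onset to the sample ``window`` seconds later (clipped to
    the final sample), measured from the +y axis.
    """
    if len(traj) < 2:
        raise OnsetError("trajectory too short")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    speed = np.hypot(vx, vy)
    idx = np.nonzero(speed >= v_threshold)[0]
    if not len(idx):
        raise OnsetError(
            f"speed never reaches the onset threshold {v_threshold} cm/s")
    i0 = int(idx[0])
    i1 = min(i0 + int(round(window * traj.fs)), len(traj) - 1)
    if i1 == i0:
        raise OnsetError("no samples after movement onset")
    dx, dy = traj.x[i1] - traj.x[i0], traj.y[i1] - traj.y[i0]
    return float(np.degrees(np.arctan2(dx, dy)))


def normalize_sign(metrics: TrialMetrics,
                   direction: Literal["cw", "ccw", "none"] | None = None) -> TrialMetrics:
    """Flip both signed metrics on counter-clockwise-rotation trials so
    that cw and ccw runs are directly comparable; cw and unperturbed
    trials pass through unchanged. Applying the flip twice restores the
    original values."""
    direction = metrics.direction if direction is None else direction
    if direction == "ccw":
        return TrialMetrics(-metrics.cursor_path_area, -metrics.cursor_angle,
                            metrics.hit, direction)
    return replace(metrics, direction=direction)


def make_fixture_trajectories(
    kind: Literal["straight", "rotated", "curved_feedback", "noisy", "miss"],
    angle_deg: float = 0.0,
    noise_sd_cm: float = 0.05,
    detour_cm: float = 5.0,
    n: int = 1,
    fs: float = 30.0,
    duration: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[Trajectory2D]:
    """Synthetic 30 Hz reach trajectories with known ground truth.

    Emulates the task geometry (10 cm reach, 1.4 cm target) for metric
    validation: ``straight`` and ``rotated`` are minimum-jerk reaches at a
    fixed aim (area 0, angle = ``angle_deg``); ``curved_feedback`` starts
    rotated and curves back onto the target (a rightward semicircular
    detour of radius ``detour_cm`` when ``angle_deg`` is 0, with known
    area pi r^2 / 2); ``noisy`` adds white Gaussian position noise to a
    straight reach; ``miss`` is a rotated reach that ends off-target.
    """
    t = np.arange(int(round(duration * fs)) + 1) / fs
    tau = np.clip(t / duration, 0, 1)
    prof = TARGET_DISTANCE_CM * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    out = []
    for i in range(n):
        if kind in ("straight", "rotated", "miss"):
            a = np.radians(angle_deg)
            x, y = prof * np.sin(a), prof * np.cos(a)
            # a 'miss' overshoots the end radius so the closing arc applies
            if kind == "miss":
                x, y = 1.05 * x, 1.05 * y
        elif kind == "curved_feedback":
            # semicircular detour of radius detour_cm bulging rightward,
            # traversed at minimum-jerk arc speed; ends at (0, 2*detour_cm),
            # the target when detour_cm = 5. Enclosed area = pi r^2 / 2.
            r = detour_cm
            s = prof / TARGET_DISTANCE_CM * np.pi          # arc parameter
            x, y = r * np.sin(s), r - r * np.cos(s)
        elif kind == "noisy":
            x, y = np.zeros_like(prof), prof.copy()
            if rng is None:
                raise ValueError("rng required for noisy fixtures")
            x = x + rng.normal(0, noise_sd_cm, x.shape)
            y = y + rng.normal(0, noise_sd_cm, y.shape)
        else:
            raise ValueError(f"unknown fixture kind {kind!r}")
        out.append(Trajectory2D(t, x, y, fs))
    return out
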