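"""Trial schedules, the experiment runner and parameter sweeps.

The standard adaptation protocol (consistent perturbation direction) is 80
trials: 10 unperturbed baseline trials, a 60-trial perturbed block with
two catch trials (perturbation silently removed, cue unchanged) each
followed by four perturbed trials, and 10 de-adaptation trials
(perturbation removed and announced by the cue). Replicated runs use
independent, counter-derived RNG streams so any single replicate can be
reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .learners import LearnerParams, LearnerState, scaled
from .plant import PlantParams, Trial, simulate_trial

__all__ = [
    "TrialSpec",
    "Schedule",
    "SweepSpec",
    "SimulationResult",
    "build_part1_schedule",
    "build_part2_schedule",
    "run_experiment",
    "sweep",
    "trials_to_criterion",
]

ROTATION_DEG = 30.0


class TrialSpec(NamedTuple):
    """Specification of one trial: imposed rotation, cued rotation, role."""

    beta: float
    cue: float
    role: Literal["baseline", "perturbed", "catch", "deadaptation"]


@dataclass(frozen=True)
class Schedule:
    """Ordered list of trial specifications for a whole experiment."""

    trials: tuple
    name: str = "custom"

    def __post_init__(self) -> None:
        for t in self.trials:
            if t.role == "catch" and not (t.beta == 0 and t.cue != 0):
                raise ValueError("catch trials need beta = 0 and a nonzero cue")
            if t.role == "deadaptation" and not (t.beta == 0 and t.cue == 0):
                raise ValueError("de-adaptation trials need beta = 0 and cue = 0")
            if t.role == "baseline" and not (t.beta == 0 and t.cue == 0):
                raise ValueError("baseline trials need beta = 0 and cue = 0")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trials, columns=["beta", "cue", "role"]).assign(
            trial=np.arange(len(self.trials))
        )[["trial", "beta", "cue", "role"]]


def build_part1_schedule(
    direction: Literal["cw", "ccw"] = "cw",
    n_baseline: int = 10,
    n_block: int = 60,
    n_deadapt: int = 10,
    catch_positions: Sequence[int] = (43, 48),
    rotation: float = ROTATION_DEG,
) -> Schedule:
    """Consistent-direction adaptation schedule (80 trials by default).

    ``catch_positions`` are 1-based positions within the perturbed block;
    each catch trial is followed by at least four perturbed trials before
    the next event. Clockwise rotation is positive beta.
    """
    beta = rotation if direction == "cw" else -rotation
    for i, pos in enumerate(catch_positions[:-1]):
        if catch_positions[i + 1] - pos < 5:
            raise ValueError("catch trials must be at least 5 block positions apart")
    if catch_positions and max(catch_positions) > n_block - 4:
        raise ValueError("each catch trial must be followed by 4 perturbed trials")
    trials = [TrialSpec(0.0, 0.0, "baseline")] * n_baseline
    catch_set = set(catch_positions)
    for pos in range(1, n_block + 1):
        if pos in catch_set:
            trials.append(TrialSpec(0.0, beta, "catch"))
        else:
            trials.append(TrialSpec(beta, beta, "perturbed"))
    trials += [TrialSpec(0.0, 0.0, "deadaptation")] * n_deadapt
    return Schedule(tuple(trials), name=f"part1_{direction}")


def build_part2_schedule(
    seed: int = 0,
    n_each: int = 20,
    n_random: int = 100,
    rotation: float = ROTATION_DEG,
) -> Schedule:
    """Random-direction schedule: 20 cw + 20 ccw + 100 randomly ordered
    trials, the random pattern fixed by ``seed`` (plumbing; the adaptation
    analyses in this package target the consistent-direction protocol)."""
    rng = np.random.default_rng(seed)
    trials = [TrialSpec(rotation, rotation, "perturbed")] * n_each
    trials += [TrialSpec(-rotation, -rotation, "perturbed")] * n_each
    signs = rng.choice([-1.0, 1.0], size=n_random)
    trials += [TrialSpec(s * rotation, s * rotation, "perturbed") for s in signs]
    return Schedule(tuple(trials), name="part2")


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter sweep: name in {"L_scale", "p"}, grid of values."""

    parameter: Literal["L_scale", "p"]
    grid: tuple
    n_replicates: int = 50
    sensory_noise: bool = True
    motor_noise: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be non-empty")


@dataclass
class SimulationResult:
    """Per-trial kinematic metrics of a (replicated) simulated experiment.

    ``per_replicate`` is a long DataFrame with columns (replicate, trial,
    role, beta, cue, area_cm2, angle_deg, endpoint_cm, hit); ``mean`` is
    the replicate average per trial. ``trials`` optionally retains the
    full Trial records of the last replicate.
    """

    schedule: Schedule
    per_replicate: pd.DataFrame
    seed: int
    trials: list = field(default_factory=list, repr=False)
    sweep_value: float | None = None

    @property
    def mean(self) -> pd.DataFrame:
        num = ["beta", "cue", "area_cm2", "angle_deg", "endpoint_cm", "hit"]
        g = self.per_replicate.groupby("trial", sort=True)
        out = g[num].mean()
        out["role"] = g["role"].first()
        return out.reset_index()


def _trial_metrics(trial: Trial) -> tuple:
    """Cursor path area (cm^2), cursor angle (deg), signed lateral
    end-point error (cm) and hit flag of one simulated trial."""
    traj = _metrics.trial_to_trajectory(trial)
    try:
        seg = _metrics.segment_trial(traj)
    except _metrics.IncompleteTrialError:
        # transient trials may stop short of the end radius; analyse the
        # whole movement (the area closure projects onto the end circle)
        seg = _metrics.segment_trial(traj, end_radius=None)
    area = _metrics.cursor_path_area(seg)
    try:
        angle = _metrics.cursor_angle(seg)
    except _metrics.OnsetError:
        angle = np.nan
    endpoint_cm = float(trial.cursor_xy[-1, 0] * 100.0)
    return area, angle, endpoint_cm, trial.hit


def run_experiment(
    schedule: Schedule,
    learner: LearnerParams,
    plant: PlantParams | None = None,
    n_replicates: int = 1,
    seed: int = 0,
    sensory_noise: bool = False,
    motor_noise: bool = False,
    keep_trials: bool = False,
) -> SimulationResult:
    """Run the full across-trial loop, optionally replicated.

    Each replicate r uses the RNG stream ``SeedSequence(seed, spawn_key=(r,))``
    so the result is deterministic for a fixed seed and any single
    replicate can be re-run alone. Noise switches control the sensory
    noise on the per-step error (seen by feedback and learning) and the
    motor noise of the sensorimotor update.
    """
    plant = plant or PlantParams()
    rows = []
    kept: list = []
    noise_sd = np.sqrt(learner.sensory_noise_var) if sensory_noise else None
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        state = LearnerState(plant, learner)
        kept = []
        for i, spec in enumerate(schedule):
            state.start_trial(spec.cue, spec.role)
            trial = simulate_trial(
                state, spec, plant,
                sensory_noise_sd=noise_sd, rng=rng if sensory_noise else None,
            )
            area, angle, endpoint_cm, hit = _trial_metrics(trial)
            rows.append((r, i, spec.role, spec.beta, spec.cue,
                         area, angle, endpoint_cm, hit))
            if keep_trials:
                kept.append(trial)
            state.finish_trial(trial, rng=rng, motor_noise=motor_noise)
    df = pd.DataFrame(rows, columns=[
        "replicate", "trial", "role", "beta", "cue",
        "area_cm2", "angle_deg", "endpoint_cm", "hit"])
    return SimulationResult(schedule, df, seed, trials=kept)


def sweep(
    spec: SweepSpec,
    base: LearnerParams,
    schedule: Schedule | None = None,
    plant: PlantParams | None = None,
    seed: int = 0,
) -> list[SimulationResult]:
    """One replicate-averaged SimulationResult per grid value, all sharing
    the schedule and base configuration; grid order preserved."""
    schedule = schedule or build_part1_schedule()
    out = []
    for v in spec.grid:
        if spec.parameter == "L_scale":
            lp = scaled(base, float(v))
        elif spec.parameter == "p":
            lp = replace(base, p=float(v))
        else:
            raise ValueError(f"unknown sweep parameter {spec.parameter!r}")
        res = run_experiment(
            schedule, lp, plant,
            n_replicates=spec.n_replicates, seed=seed,
            sensory_noise=spec.sensory_noise, motor_noise=spec.motor_noise,
        )
        res.sweep_value = float(v)
        out.append(res)
    return out


def trials_to_criterion(result: SimulationResult, threshold_cm: float = 0.7) -> int:
    """Index (within the perturbed block, 0-based) of the first perturbed
    trial whose replicate-mean |end-point error| falls below the target
    radius; ``len(block)`` if never reached."""
    mean = result.mean
    block = mean[mean.role == "perturbed"].reset_index(drop=True)
    ok = np.abs(block.endpoint_cm.to_numpy()) < threshold_cm
    hits = np.nonzero(ok)[0]
    return int(hits[0]) if len(hits) else len(block)
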