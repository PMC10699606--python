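"""Run configuration, named presets and result serialization.

The five presets are the published simulation regimes:

========  ===========================================================
sm_only       implicit sensorimotor adaptation only (p = 0), with
              within-trial feedback control
epe_only      explicit end-point-error learning only (L = 0, p = 0.5,
              no feedback: no sensory information during the movement)
rwd_only      binary-reward exploration only (L = 0, no feedback)
err_combined  sensorimotor + explicit learning with full vision
              (printed L, p = 0.36, integrated reward error, feedback)
epe_combined  sensorimotor + explicit learning without vision
              (small printed L, p = 0.5, end-point error, no feedback)
========  ===========================================================
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .learners import (
    C_FEEDBACK,
    L_EPE_COMBINED,
    L_SENSORIMOTOR,
    LearnerParams,
)
from .plant import PlantParams
from .protocol import Schedule, SimulationResult, build_part1_schedule, build_part2_schedule

__all__ = ["RunConfig", "PRESETS", "load_config", "save_config", "write_results",
           "learner_from_config", "plant_from_config", "schedule_from_config"]

_ZERO = ((0.0,) * 4, (0.0,) * 4)

#: Learner keyword presets; L/C rows are (e_along, e_along_dot, e_lat, e_lat_dot).
PRESETS: dict[str, dict] = {
    "sm_only": dict(L=L_SENSORIMOTOR, C=C_FEEDBACK, p=0.0,
                    feedback_on=True, reward_mode=None),
    "epe_only": dict(L=_ZERO, C=C_FEEDBACK, p=0.5,
                     feedback_on=False, reward_mode="endpoint"),
    "rwd_only": dict(L=_ZERO, C=C_FEEDBACK, p=0.0,
                     feedback_on=False, reward_mode="binary"),
    "err_combined": dict(L=L_SENSORIMOTOR, C=C_FEEDBACK, p=0.36,
                         feedback_on=True, reward_mode="integrated"),
    "epe_combined": dict(L=L_EPE_COMBINED, C=C_FEEDBACK, p=0.5,
                         feedback_on=False, reward_mode="endpoint"),
}


class PlantConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    m: float = 1.0
    dt: float = 0.02
    k_end: int = 40
    target_distance: float = 0.10
    target_radius: float = 0.007
    d_min: float = 0.005


class LearnerConfig(BaseModel):
    """Explicit learner parameters; unset fields fall back to the preset."""

    model_config = ConfigDict(extra="forbid")
    L: list[list[float]] | None = None
    C: list[list[float]] | None = None
    b: float = 0.995
    p: float | None = None
    delay_s: float = 0.3
    feedback_on: bool | None = None
    reward_mode: Literal["integrated", "endpoint", "binary"] | None = None
    p_max: float | None = None
    anticipation_steps: int = 1


class RunConfig(BaseModel):
    """Full specification of a simulated experiment."""

    model_config = ConfigDict(extra="forbid")

    preset: str = "sm_only"
    learner: LearnerConfig = Field(default_factory=LearnerConfig)
    plant: PlantConfig = Field(default_factory=PlantConfig)
    schedule: str = "part1_cw"
    n_replicates: int = 1
    seed: int = 0
    sensory_noise: bool = False
    motor_noise: bool = False
    keep_trials: bool = False

    @field_validator("preset")
    @classmethod
    def _known_preset(cls, v: str) -> str:
        if v not in PRESETS:
            raise ValueError(f"unknown preset {v!r}; choose from {sorted(PRESETS)}")
        return v

    @field_validator("seed")
    @classmethod
    def _seed_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be a non-negative integer")
        return v

    @field_validator("schedule")
    @classmethod
    def _known_schedule(cls, v: str) -> str:
        if v not in ("part1_cw", "part1_ccw", "part2"):
            raise ValueError("schedule must be part1_cw, part1_ccw or part2")
        return v

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def plant_from_config(cfg: RunConfig) -> PlantParams:
    return PlantParams(**cfg.plant.model_dump())


def learner_from_config(cfg: RunConfig) -> LearnerParams:
    kw = dict(PRESETS[cfg.preset])
    lc = cfg.learner
    if lc.L is not None:
        kw["L"] = tuple(tuple(r) for r in lc.L)
    if lc.C is not None:
        kw["C"] = tuple(tuple(r) for r in lc.C)
    if lc.p is not None:
        kw["p"] = lc.p
    if lc.feedback_on is not None:
        kw["feedback_on"] = lc.feedback_on
    if lc.reward_mode is not None:
        kw["reward_mode"] = lc.reward_mode
    return LearnerParams(b=lc.b, delay_s=lc.delay_s, p_max=lc.p_max,
                         anticipation_steps=lc.anticipation_steps, **kw)


def schedule_from_config(cfg: RunConfig) -> Schedule:
    if cfg.schedule == "part2":
        return build_part2_schedule(seed=cfg.seed)
    return build_part1_schedule("cw" if cfg.schedule.endswith("cw") and
                                not cfg.schedule.endswith("ccw") else "ccw")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are
    rejected with a message naming the offending key."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


def write_results(result: SimulationResult, out_dir: str | Path,
                  cfg: RunConfig | None = None) -> dict[str, Path]:
    """Write metrics CSV (long format), optional trajectory CSV and a JSON
    run manifest. Deterministic runs re-created from the manifest
    reproduce the metrics CSV byte for byte."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    metrics_path = out / "metrics.csv"
    result.per_replicate.to_csv(metrics_path, index=False, float_format="%.10g")
    paths["metrics"] = metrics_path

    if result.trials:
        rows = []
        for i, tr in enumerate(result.trials):
            hand, cur = tr.hand_xy, tr.cursor_xy
            t = tr.params.times
            for k in range(len(t)):
                rows.append((i, k, t[k], tr.states[k, 0], tr.states[k, 2],
                             hand[k, 0], hand[k, 1], cur[k, 0], cur[k, 1]))
        traj = pd.DataFrame(rows, columns=[
            "trial_index", "k", "t", "d", "gamma", "x", "y",
            "cursor_x", "cursor_y"])
        traj_path = out / "trajectories.csv"
        traj.to_csv(traj_path, index=False, float_format="%.10g")
        paths["trajectories"] = traj_path

    manifest = {
        "package_version": __version__,
        "seed": int(result.seed),
        "n_trials": len(result.schedule),
        "schedule": result.schedule.name,
    }
    if cfg is not None:
        manifest["config"] = cfg.model_dump()
        manifest["config_hash"] = cfg.config_hash()
        manifest["preset"] = cfg.preset
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
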