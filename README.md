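# vmrsim — dual-error learning simulator for visuomotor rotation

`vmrsim` is a simulator and analysis toolkit for a classic question in
computational motor neuroscience: when a reaching movement is perturbed
by a visuomotor rotation (the cursor is rotated ±30° about the start
position), how do *implicit sensorimotor adaptation* (driven by sensory
prediction error) and *explicit reward learning* (driven by reward
prediction error — a signed end-point miss or a binary hit/miss)
combine to restore performance, and why do only some forms of learning
leave aftereffects when the perturbation is removed?

The model is a discrete-time point-mass reach (40 steps of 0.02 s,
10 cm target) driven by the sum of three commands

    u_j(k) = u_j^RW(k) + u_j^SM(k) + u_j^FB(k)

* **u^SM** — iterative learning control (ILC): the feedforward command
  is updated across trials from the previous trial's per-step sensory
  error *e*, with forgetting:
  `u^SM_j(k) = b·u^SM_{j−1}(k) + L·e_{j−1}(k+1)`, `b = 0.995`,
  `L = [[0.02, 0.9, 0, 0], [0, 0, 0.02, 0.9]]`. Cue-blind; produces
  aftereffects.
* **u^RW** — explicit re-aiming: a scalar reward error (end-point arc
  miss `2·e_γ(k_end)·d(k_end)`, its whole-movement mean, or a binary
  hit/miss with uniform ±45° exploration) shifts the planned movement
  direction: `aim_j = aim_{j−1} + p·e^RW_{j−1}`, and the command is the
  straight-reach fallback `u_0` rotated to the aim. Resettable by a cue;
  no aftereffect on announced washout.
* **u^FB** — within-trial delayed feedback, `C·e(k − 15)` (0.3 s
  reaction time), active only when the cursor is visible during the
  movement.

The package also implements the reach-kinematics metrics used to read
out adaptation — **cursor path area** (signed cm² between the cursor
path and the start–target chord, with an arc-closure rule for misses)
and **cursor angle** (initial movement direction over the 160 ms after
a 0.025 m/s onset) — the 80-trial adaptation protocol with catch and
de-adaptation trials, replicate-averaged experiment runs, and parameter
sweeps. See `docs/methods.md` for the model details and design
decisions.

## Worked example

Simulate the consistent-direction protocol with sensorimotor
adaptation only (full vision, `p = 0`):

```python
from vmrsim import build_part1_schedule, run_experiment
from vmrsim.config import RunConfig, learner_from_config

cfg = RunConfig(preset="sm_only", seed=0)
res = run_experiment(build_part1_schedule("cw"),
                     learner_from_config(cfg), seed=cfg.seed)
m = res.mean
print(m[m.trial.isin([0, 10, 14, 20, 40, 52, 70])]
      [["trial", "role", "area_cm2", "angle_deg", "hit"]])
```

which prints

```
 trial         role  area_cm2  angle_deg      hit
     0     baseline      0.00       0.00     1.00
    10    perturbed     26.13      30.00     0.00
    14    perturbed     14.18      20.44     0.00
    20    perturbed      4.45      10.74     0.00
    40    perturbed      0.78      -2.30     0.00
    52        catch    -24.35     -32.92     0.00
    70 deadaptation    -23.52     -28.38     0.00
```

Trial 10 is the first perturbed trial: the hand still moves straight,
so the cursor angle equals the imposed 30° rotation and the path area
is large and positive (rightward). Over the next trials the implicit
pathway rotates the movement the other way and the area collapses
towards zero. On the catch trial (52) the perturbation is silently
removed while the learned compensation persists — a large *negative*
aftereffect — and because implicit adaptation cannot be discarded
voluntarily, the announced de-adaptation trial (70) shows the same
aftereffect. Re-running with `preset="epe_only"` (end-point reward
learning) gives a comparable catch-trial aftereffect but a flat, zero
de-adaptation trial: the explicit aim resets when the cue announces
the perturbation is gone. That contrast is the central dissociation the
simulator reproduces.

The same runs are available from the shell:

```sh
vmr schedule --direction cw            # inspect the 80-trial protocol
vmr simulate -c config.yaml -o out/    # metrics.csv + manifest.json
vmr sweep -c config.yaml --parameter p --grid 0.25,0.5,1.0 -o sweep.csv
vmr fixtures --kind rotated --angle 20 --out fx.csv
vmr metrics --in fx.csv --out fx_metrics.csv --no-filter
```

where `config.yaml` can be as small as `preset: epe_only`.

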