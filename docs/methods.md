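# Model and methods

`vmrsim` simulates trial-to-trial motor adaptation to a visuomotor
rotation: a point-to-point reach whose displayed cursor is rotated by
±30° about the start position, learned over an 80-trial protocol by two
interacting processes — implicit sensorimotor adaptation and explicit
reward-based re-aiming — plus delayed within-trial feedback control.

## Plant

The hand is a point mass `m` (default 1 kg) in the horizontal plane.
Reaches start at the origin and aim at a target 10 cm straight ahead
(radius 0.7 cm). Two force channels act on the mass: `f_d` along the
target axis and `f_gamma` perpendicular to it. Integration is
semi-implicit (symplectic) Euler with `dt = 0.02 s` over `k_end = 40`
steps (0.8 s per movement):

    v+ = v + dt f / m,     x+ = x + dt v+

The state is reported in polar coordinates `(d, d_dot, gamma,
gamma_dot)` — distance from the start (m), its rate, the polar angle
(deg, positive rightward/clockwise), and its rate — because the
perturbation and the kinematic metrics are angular quantities. Two
deliberate numerical choices:

* **Velocity-first Euler.** With position-first (explicit) Euler the
  first commanded velocity sample cannot move the first position sample,
  so no command sequence can replay the sampled minimum-jerk plan
  exactly; velocity-first integration makes the inverse dynamics exact
  to round-off, which the open-loop fidelity test asserts at
  `1e-9 × D`.
* **Forces, not torques.** The lateral channel is a force producing
  lateral acceleration `f/m`, not a torque divided by a `1/(m d²)`
  inertia about the start. A torque formulation is singular at the
  start position (the reach begins at the pole, where the moment of
  inertia vanishes) and makes the closed learning loop either unstable
  or non-adaptive for the shipped gain matrices; the force formulation
  is regular everywhere, and for a 30° rotation the small-angle
  difference between "tangential" and "lateral" is negligible.
  `PlantParams.d_min` (5 mm) survives only as a pole guard when
  reporting the polar angular velocity near `d = 0`.

The visuomotor rotation adds `beta` to the observed polar angle — an
exact rigid rotation of the hand position about the start.

The desired movement is a straight minimum-jerk reach
`d(t) = D(10τ³ − 15τ⁴ + 6τ⁵)`, `τ = t/T`, sampled on the integration
grid; desired velocities are the backward differences of the sampled
positions (so the plan starts at rest and is exactly executable). The
fallback command `u_0` is its inverse dynamics; the lateral channel of
`u_0` is identically zero.

## Sensory error and the learning frame

The per-step sensory prediction error is the desired cursor state minus
the observed cursor state. It is exposed in the polar frame (`e_d`,
`e_d_dot`, `e_gamma` in degrees, `e_gamma_dot`), which is how the
perturbation is specified: a straight hand reach seen through a 30°
rotation has `e_gamma ≡ −30°`.

The gain matrices, however, act on the error expressed in **metric
cursor coordinates** `[e_along, e_along_dot, e_lat, e_lat_dot]` (m,
m/s) — the along-axis and lateral error of the cursor and their rates.
Two reasons. First, units: the reward error multiplies the angular
error (radians) by the distance, i.e. it is an arc length in metres;
using metres in the sensorimotor channel keeps one error currency
throughout. Second, well-posedness: the polar-angle target
(`gamma ≡ 0` with `gamma_dot ≡ 0`) is not reachable from `gamma(0)=0`
— compensating a rotation requires the angle to jump at the pole — so
an iteration penalising angular velocity can lock into a non-adapting
equilibrium, whereas the lateral error of the compensated movement
vanishes together with its rate. In the lateral frame the shipped gain
matrix yields a stable, smoothly converging iteration.

With sensory noise enabled, Gaussian noise with per-channel variances
(0.002 m², 0.004 m²/s², 0.3 deg², 0.05 deg²/s²) is added to the polar
error at every step and propagated into the metric frame, so feedback
control and subsequent learning both see the noisy percept.

## Sensorimotor adaptation (ILC)

The feedforward sensorimotor command is revised across trials by
iterative learning control with forgetting:

    u_SM_j(k) = b · u_SM_{j−1}(k) + L · e_{j−1}(k+1)   (+ motor noise)

with `b = 0.995` and `L = [[0.02, 0.9, 0, 0], [0, 0, 0.02, 0.9]]`
(position and velocity gains per channel). The error is taken one step
ahead of the command it corrects (`anticipation_steps = 1`,
configurable): a command at step `k` first affects the state at step
`k+1`, and this non-causal (in trial time) pairing is what gives the
iteration its contraction; with same-index errors every iteration
eigenvalue equals `b` and nothing is learned on the protocol's
timescale. Under the default geometry the per-trial error contraction
near the movement end is ≈ `b − 0.9·d·dt/m ≈ 0.8`; convergence is a
damped ring — the endpoint error overshoots by ~10° around trial 10 and
settles below 10% of its initial value well before trial 50, while the
cursor-path-area curve declines essentially monotonically, which is the
readout the protocol plots.

This pathway is cue-blind: it models implicit recalibration of the
internal model, so its compensation persists identically on catch
trials (perturbation silently removed) and de-adaptation trials
(removal announced) — the aftereffect.

Motor noise (`n_m`, variances 0.02 and 0.8 N² per channel) can be
injected into the update. Because the update is a `b ≈ 1` recursion,
white force noise of that magnitude accumulates to a stationary spread
of several newtons — an order of magnitude above the ~0.9 N signal —
and obliterates the learning curves, so replicate-averaged runs default
to sensory noise only; the switch and variances remain configurable.

## Explicit reward learning

The reward prediction error is a scalar per trial:

* integrated: `mean_k( 2·e_gamma(k)[rad] · d(k) )` — an
  arc-length-weighted angular miss (m);
* end-point: the same product at the final step only;
* binary: 0 (rewarded) if the end-point magnitude is within the target
  radius, else 1.

The explicit pathway maintains an **aim angle**:

    aim_j = aim_{j−1} + p · e_RW_{j−1},     u_RW_j = R(aim_j) · u_0

i.e. the reward command is the fallback command rotated — the same
reach re-planned towards a shifted target. Reward-learned movements are
therefore straight but angled, and the learned compensation lives in a
consciously accessible aim rather than in the internal model. A cue
announcing that the perturbation is gone resets the aim (and the
exploration memory) to zero: no aftereffect on de-adaptation trials,
full aftereffect on catch trials. With `p = 0.5` the endpoint error
decays geometrically with ratio `1 − 2 p D ≈ 0.9` per trial; the
iteration is stable for `p` below `1/D = 10`.

In the binary regime no graded error exists. A successful reach commits
its aim to memory and is replayed unchanged; after a failure a fresh
re-aim is drawn uniformly within ±45° (`p_max = π/4`) around the stored
memory aim (straight ahead before any success). The success signal is
the task's own reward — the cursor end point landing inside the
physical target disc (±4.0° at 10 cm). With these defaults a draw hits
the target with probability ≈ 8/90, so ≈ 99% of runs acquire the target
within 50 perturbed trials; exploration around a committed memory
(rather than a random walk over consecutive failures) is what makes
acquisition reliable.

## Feedback control

Within a trial, `u_FB(k) = C · e(k − 15)` with
`C = [[0.45, 0, 0, 0], [0, 0, 0.45, 0]]` acting on the metric error and
a 0.3 s (15-step) reaction delay; it is zero until the delay elapses
and in regimes without sensory information during the movement
(end-point-error and binary reward). Its contribution within a single
0.8 s movement is modest (the late-arriving correction strictly reduces
the endpoint error) and it shapes the curved single-trial corrections
seen in full-vision runs.

## Protocol and replication

The consistent-direction schedule has 80 trials: 10 baseline, a
60-trial perturbed block with catch trials at block positions 43 and 48
(each followed by four perturbed trials), and 10 de-adaptation trials.
Cue semantics: catch trials keep the perturbation cue (the learner is
not told), de-adaptation trials announce the removal. A
random-direction schedule builder (20 cw + 20 ccw + 100 random) is
provided as plumbing. Replicated runs draw replicate `r`'s RNG stream
from `SeedSequence(seed, spawn_key=(r,))`, so a fixed seed reproduces
results bitwise and any replicate can be re-run in isolation; the
shipped replicate count for sweeps is 50.

Shipped parameter presets: `sm_only` (printed `L`, `p = 0`, feedback
on), `epe_only` (`L = 0`, `p = 0.5`, no feedback), `rwd_only` (binary
exploration, no feedback), `err_combined` (printed `L`, `p = 0.36`,
integrated reward error, feedback on), `epe_combined`
(`L = [[0.0012, 0.96, 0, 0], [0, 0, 0.0012, 0.096]]` — the asymmetric
lateral velocity gain kept as published — `p = 0.5`, end-point error,
no feedback).

## Kinematic metrics

Trajectories are analysed in cm with the start at the origin and the
target at (0, 10):

* **Segmentation** from the first sample at/after the 0.4 cm radius to
  the first at/after the 10 cm radius (no sub-sample interpolation; the
  bias is below one sample at 30 Hz). Simulated transients that stop
  short of 10 cm are analysed to their final sample.
* **Cursor path area** (cm², rightward positive): line integral
  `∮ x dy` around the region bounded by the path and the start–target
  chord; if the path does not end on the target the boundary is closed
  by projecting the exit point radially onto the 10 cm trial-end circle
  and following the shorter arc to the target. For a semicircular
  detour of radius 5 cm the closed form is `π·5²/2 ≈ 39.27 cm²`.
* **Cursor angle** (deg): direction of the displacement vector over the
  160 ms after movement onset (first sample with speed ≥ 0.025 m/s),
  relative to straight ahead — the feedforward initial aim, before
  feedback corrections arrive.
* **Sign normalization**: counter-clockwise-rotation trials have both
  signed metrics negated (an involution) so the two directions pool.
* Recorded (30 Hz) trajectories pass through a zero-phase 4th-order
  Butterworth low-pass at 10 Hz (forward–backward, so onset timing is
  unbiased); noise-free simulated trajectories (50 Hz) skip the filter.

The synthetic fixture generator produces 30 Hz trajectories with known
ground truth (straight, rotated, semicircular detour, noisy, miss) on
the task geometry; it validates the metrics but shares none of their
code paths.

## What the simulations do and do not show

The synthetic protocol reproduces the structure of the behavioural
experiment — learning-curve decline, catch-trial aftereffects, the
catch/de-adaptation dissociation between implicit and explicit
learning, and exploration-driven acquisition under binary reward. It
does not emulate biomechanics beyond a point mass, trial-time
variability in movement duration, savings across blocks, or
use-dependent effects; passing tests say the model and metrics behave
as specified, not that human data would match quantitatively. Problem
sizes used by the test suite (80-trial protocols, single replicates for
deterministic checks, 50 replicates for noisy means, 200 seeds for the
exploration statistics) are the package's standard study conditions.

## Known limitations

* The sensorimotor iteration rings before settling; strictly monotone
  endpoint-error decline is not a property of this update law.
* The combined regimes share one error stream; there is no separate
  proprioceptive channel, so "no vision" regimes simply disable
  feedback and (optionally) noise rather than modelling degraded
  senses.
* `p` mixes units across regimes (rad/m for graded reward error, rad
  for binary), mirroring how the update is defined.
* The random-direction schedule is provided but not studied: the model
  as shipped has a single context and will not switch compensation
  cue-contingently.
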