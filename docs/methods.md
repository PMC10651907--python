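# Methods

This note documents the models, parameter choices and limitations behind
`activegaze`.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Task and coordinate conventions

Two polycube stimuli (connected face-glued unit cubes) sit on posts
0.4 m apart inside a 3.4 m × 4.3 m arena; an observer walks freely and
answers "same" or "different" (2AFC).  *Same* means geometric congruence
under the 24 proper rotations of the cubic lattice; mirror pairs count
as different because the stimuli are rigid physical objects.  Complexity
is keyed to block count: C_e (n = 7), C_m (n = 10), C_h (n = 18).

World frame: right-handed, x–y floor plane, z up, meters, origin at the
arena corner nearest the curtain.  Quaternions are (w, x, y, z) with
w ≥ 0.  The head frame's +x is "straight ahead".  Timestamps are
trial-relative float seconds (microsecond resolution), t = 0 at the
first head sample.

Stimulus factors per trial: complexity (balanced, 6 trials per level of
18), start position P_l / P_s / P_c (equidistant, in-line, oblique),
orientation difference 0/90/180° (applied about the post axis), and
sameness — the latter three uniform random per trial.

## Stream synchronization

Gaze (50 Hz, direction in the head frame) is the lower-rate,
event-defining stream, so head pose (120 Hz) is interpolated to gaze
timestamps: positions linearly, orientations by shortest-arc slerp.
Head gaps longer than 25 ms (three nominal periods) are not interpolated
across; affected gaze samples are dropped and counted.  Invalid gaze
rows are flagged, never silently removed.

## Fixation detection (I-VT)

Angular velocity per sample is the central difference — the angle
between the two neighbouring gaze directions over their time span
(one-sided at the trace ends).  This is the smallest-lag estimator at
50 Hz (a 40 ms window).  Velocity is computed on **world-frame**
directions by default so that VOR-like stabilization during walking
still reads as fixation; `frame="head"` is available.

Parameters (all in `FixationDetectorConfig`):

| parameter | default | rationale |
|---|---|---|
| velocity_threshold | 30 °/s | task definition of a fixation |
| min_duration | 60 ms | standard I-VT event treatment |
| max_gap | 75 ms | standard merge window |
| merge_max_angle | 0.5° | merged runs must point the same way |

The merge gap is counted as the *unclassified time strictly between two
runs*, and single-sample sub-threshold runs are ignored (they can never
be fixations and must not block a merge).  With the central-difference
estimator a single noisy outlier sample contaminates the velocity of
both neighbours; under these conventions the resulting split is repaired
by the merge step, while genuinely distinct fixations (≥ 2.4° apart)
never merge because of the direction condition.

## Target assignment

Bounding spheres stand in for the exact block meshes: at 0.8–2.5 m
viewing distance the angular discrepancy between sphere and mesh is
below the 1.42° tracker accuracy, which is also the assignment
tolerance — a fixation aimed at an object's limb should not be lost to
tracker error.  Angular miss of a sphere (radius r at distance d) for a
ray is `max(0, ∠(ray, center-direction) − asin(r/d))`; smallest miss
within tolerance wins, ties go to the nearer object, a ray origin inside
a sphere assigns that object with a warning.

## Trial measures

* **Response time**: answer time minus the start of the trial's first
  fixation (any label).
* **Head path**: anchored integration — displacement accumulates from an
  anchor and is added once it reaches `min_step = 2 mm` (10× the head
  tracker RMSE).  Naive sample-by-sample integration of 120 Hz noise
  would add meters of spurious path per minute; the anchored form is
  insensitive to it while exact on straight walks.
* **Grouping profile**: environment fixations are removed *without*
  splitting a run — a floor glance mid-inspection does not end an
  inspection episode (`split_on_environment=True` flips this).  Runs are
  binned 1..8 and >8; exact run lengths are retained so totals audit
  without bin midpoints.
* **Fixation ratio**: primary = more-fixated object; exact ties resolve
  to the object fixated first (deterministic and behaviorally motivated).
* **Normalized response time**: mean RT divided by block count, reported
  to 2 decimals.

## Inference layer

Continuous measures use classical repeated-measures ANOVA on
per-subject cell means (random factor assignment makes trial counts per
cell unequal, so means are taken first).  For k levels and m subjects,
F carries df = (k−1, (k−1)(m−1)): 47 subjects give (2, 92) for 3-level
factors and (5, 230) for the 6-block learning factor — the blocking of
18 trials into 6 consecutive blocks of 3 is inferred from that
denominator and is configurable.  No sphericity correction by default;
Greenhouse–Geisser via flag.  The n-way mode (main effects + two-way
interactions on the full per-subject cell-mean grid) delegates to
statsmodels' `AnovaRM`; incomplete grids raise an explicit
missing-design error rather than imputing.

Accuracy sits near ceiling, so it is modelled as binomial with logit
link, fixed factor effects (treatment coding) and a subject random
intercept.  The marginal likelihood integrates the intercept with
25-node Gauss–Hermite quadrature and is maximized with L-BFGS-B;
factors are tested with joint Wald χ² using the numerical Hessian.
This estimator is written in-package because no installed library
provides a frequentist binomial GLMM; its calibration (type-I error
≈ 5 %) and power (sign recovery of an odds-ratio-3 effect) are verified
by simulation in the test suite and the acceptance script.  Complete
separation (e.g. constant correctness) yields flagged results with a
warning, not a crash.

## Synthetic experiment generator

The generator emulates the *statistical* structure the pipeline
consumes; it is not a biomechanical model.  An agent starts at its
start position facing away from the stimuli, turns (120 °/s), walks
(0.9 m/s) to a vantage point, and inspects the objects through groups
of fixations whose sizes are drawn iid from a categorical distribution
over {1..8, >8} (drawing the *number* of groups first — stopping on a
cumulative fixation count would size-bias the last draw).  Between
groups the target object alternates; with probability 0.35 the agent
relocates, with probability 0.12 it glances at the floor.  Fixation
durations are log-normal (median 0.30 s, σ_log 0.35, clipped to
0.1–1.2 s).  Answers are drawn from per-complexity correctness
probabilities (0.961 / 0.9418 / 0.912); the mean object-fixation counts
per complexity (76.56 / 79.53 / 121.06) and the grouping-size
distribution are seeded from study-level aggregates.  These calibration
inputs are never used as recovery evidence: recovery tests compare
pipeline output against the *configured* values.

### Exactness by construction

Gaze is built directly on the 50 Hz grid.  Fixations are constant world
directions; transitions (saccades, scanning sweeps during walks) are
geodesic arcs whose per-sample steps lie in ~0.65–8°, i.e.
central-difference velocities of ~33–400 °/s, while the samples
adjacent to a fixation stay within 1.2° of it (below threshold at the
40 ms window).  Consecutive fixation targets are ≥ 2.4° apart.  Head
position/orientation change only inside motion intervals aligned to the
0.1 s grid shared by the 120 Hz and 50 Hz clocks, with linear/geodesic
interpolation inside — so slerp at gaze timestamps reproduces the
generating pose exactly.  Consequence: with noise off, detection
recovers every scheduled event, label, and time *exactly*, and the
zero-noise path check uses `min_step = 0` (the anchored integrator's
per-leg residual of < 2 mm is a thresholding artifact, not an error).

Stimulus geometry: per-complexity cell sizes (6 / 4.5 / 3.5 cm) and
bounding-box limits keep all complexity levels inside a shared
~12–18 cm envelope, as with the physical stimuli; bounding spheres are
floored at 10 cm.  Vantage points are sampled so each object subtends
≥ 2.8° angular radius and the two objects do not overlap angularly
(+1.5° margin) — from the in-line start position the objects are
angularly nested, so the agent always walks to a vantage before its
first fixation, as real observers must.

### Noise model

Gaze error is dominated by slowly varying calibration offset, modelled
as AR(1) (correlation time 1.5 s) on two tangential components plus
0.1° RMS white jitter, with the stationary mean angular error
calibrated to 1.42°.  White noise of that magnitude would drive the
central-difference velocity above 30 °/s inside true fixations —
incompatible with I-VT working on this hardware at all — so the drift
structure is both realistic and necessary.  Head position noise is
white and isotropic with 0.2 mm 3D RMSE; head orientation noise is off
by default.

### What the simulator does not emulate

Realistic saccade main-sequence dynamics (transitions move at modestly
super-threshold speeds so that event boundaries are grid-exact), gait
and posture, blinks and tracking dropouts (the `valid` flag is honored
by the pipeline but the generator emits none), depth-of-fixation
vergence, and any hypothesis-testing strategy in where the agent looks
(targets within an object are random cells).  Passing recovery tests
therefore certify the pipeline's geometry, event logic and bookkeeping
— not human realism of the scanpaths.

## Problem sizes

The acceptance script simulates one full experiment (47 × 18 = 846
trials) at calibrated noise for recovery and aggregate measures, 30
noiseless trials for the exactness block, 100 null simulations each for
ANOVA and GLMM type-I error, and 20 injected-effect fits for sign
recovery; the suite's statistical calibration test uses 200 null
simulations.  These sizes give binomial/multinomial intervals tight
enough for the checks they support while keeping a full run in minutes
on one core.

## Known limitations

* Bounding-sphere assignment cannot separate objects seen one behind
  the other; the simulator avoids such vantages, real data may not.
* The GLMM supports a single random intercept (no random slopes,
  no crossed grouping).
* `rm_anova` requires complete subject × level cells; with uniform
  random factor assignment a subject can miss a level (the pipeline
  reports such factors as flagged entries).
* The merge step operates on mean directions; extremely slow drift
  within a long fixation could defeat the 0.5° consistency check.
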