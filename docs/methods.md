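# Methods

## The question and the statistic

During constant-radius cornering, two classes of gaze target make
sharply different oculomotor predictions even though they sit close
together in the visual field:

* **Tangent point (TP)** — the point on the inside lane edge where the
  line of sight is tangential to the edge. On a circular trajectory its
  egocentric direction is constant (`|h| = 90° − arcsin(r/d)` for inner
  radius `r` and distance-from-center `d`), so perfect TP fixation
  predicts *no* horizontal eye movement.
* **Waypoint on the future path** — a world-fixed point the vehicle
  will pass over. By the inscribed-angle theorem its egocentric
  direction equals half the remaining arc angle, and therefore closes
  at exactly **half the vehicle's yaw rate** ω. Sequentially fixating
  waypoints produces optokinetic nystagmus (OKN): ~200–400 ms slow
  phases at horizontal velocity −½ω, interleaved with resetting quick
  phases.

The worked example: an observer at the start of a 90° arc fixating the
arc's endpoint sees it 45° from heading; over the traversal the vehicle
rotates 90° while the eye counter-rotates 45° — a 2:1 ratio that holds
for every on-path fixation point.

The discriminating statistic is computed fixation by fixation: for each
detected slow phase,

    Δ = ½·|mean yaw rate| − v_against

where `v_against` is the horizontal slow-phase velocity component
directed against the bend. Waypoint tracking ⇒ Δ ≈ 0; TP fixation ⇒
Δ ≈ ½|ω| (≈ 7 deg/s at 42 km/h on a 48 m radius). Δ is self-normalizing
across speeds and invariant under mirroring the bend's handedness. Its
orientation is chosen so that TP fixation comes out positive; the sign
convention is echoed into every report.

## Coordinate and sign conventions

Allocentric frame: right-handed planar x/y, angles CCW from +x,
radians internally and degrees at every interface. Egocentric
horizontal angles are positive to the right of heading; vertical angles
positive below the horizon (`arctan(eye_height / ground_distance)`,
eye height 1.2 m by default — any positive value preserves the
horizontal geometry). Yaw rate is clockwise-positive; with these two
choices the signed half-rate law `dα/dt = −½·ω` holds identically for
right- and left-hand bends, and in a right-hand bend the TP direction
is positive while slow-phase flow is negative (leftward). Segment
direction histograms measure 0° = vehicle-frame up, positive clockwise,
so the waypoint-tracking signature "left and down" falls in
(−180°, −90°).

The road model is planar: no gradient or superelevation. All bend
geometry is a parametric constant-radius arc; non-circular (clothoid)
bends are out of scope.

## Synthetic data: what it emulates and what it does not

The simulator reproduces the sensor suite of an instrumented-car study:
60 Hz remote eye tracking with a 0–1 quality signal, 100 Hz CAN speed
and yaw rate, 1 Hz GPS. A trial is a 40 m straight approach, a 50 m
entry, a constant-radius arc (default 48 m centerline, 135°, right
hand) and a short exit, driven at constant speed (default 11.67 m/s =
42 km/h, between-subject SD 1.1 m/s).

Gaze strategies:

* `waypoint` — slow phases of duration U(0.2, 0.4) s track a world-fixed
  point placed `preview_time` (default 2 s) ahead on the path; quick
  phases are 2–4-sample constant-velocity ramps (peak speed parameter,
  default 300 deg/s) to the next waypoint. During slow phases the
  noiseless horizontal velocity is exactly −½ω.
* `tp` — gaze pinned to the geometric tangent point (constant during
  the arc).
* `tp_okr` — TP fixation plus reflexive drift at `okr_gain` times the
  local optic-flow rate at the TP, reset by corrective saccades.

Sensor noise: per-axis white Gaussian noise (default SD 0.35°, a
typical precision for a remote automotive tracker), an AR(1) vibration
wander (coefficient 0.95, innovation 0.1°, stationary SD ≈ 0.32°)
emulating shake of a dashboard-mounted tracker, and blink-like quality
dropouts — geometric bursts of mean 8 samples (~133 ms) whose
burst-start rate is set so the stationary per-sample dropout
probability equals `dropout_prob` (default 0.02). Dropout bursts are
temporally correlated because real tracker losses (blinks, reflections)
are; modelling them as i.i.d. single samples would shred each cornering
phase into many short analysis windows, which no real recording does.

Per-subject heterogeneity: speeds and preview times are jittered
between subjects, and so are the oculomotor/tracker parameters
(slow-phase duration range midpoint ±0.03 s, noise SD and vibration SD
lognormal ±30%, dropout rate lognormal ±50%). The last group matters:
Δ deliberately cancels speed and preview, so a cohort varying only in
those would show essentially zero between-subject variance in the
statistic — unlike any real cohort — making subject-level confidence
intervals degenerate.

What the simulator does **not** model: scene rendering, head movement,
steering-control feedback (lane position enters only as a small
per-trial path-radius jitter), road gradient, traffic (exclusions exist
only as metadata flags). Passing tests therefore show that the
*analysis chain* recovers known ground truth under realistic sensor
noise — not that real drivers behave like the generator.

## Preprocessing

Quality criterion 0.2, strict `<` (a sample exactly at threshold is
retained); excluded samples are flagged with reason codes, never
deleted. CAN signals are merged to gaze timestamps by
nearest-preceding-sample selection, GPS by linear interpolation
(upsampling grids include the span endpoint so round trips of linear
signals are lossless; downsampling grids have `ceil(duration·rate)`
points). Each sample is assigned an along-route distance via Euclidean
nearest-neighbour matching to a prototype trial's interpolated track,
made non-decreasing by a running maximum; matches farther than 25 m
(our choice; the matching tolerance is not otherwise determined) are
flagged as alignment failures. Phases: entry = [onset − 50 m, onset),
cornering = [onset, onset + arc − 35 m] (closed end), approach before
entry; half-open conventions make labelling single-valued. The 35 m
exit cutoff is the distance driven in 3 s at 42 km/h, keeping both the
driver and the gaze target inside the constant-curvature section.

## Slow-phase detection

Gaze is partitioned into maximal linear segments by exact dynamic
programming: minimize `Σ SSE(per-axis LS lines, both axes summed) +
penalty·(number of segments)` over all partitions with ≥ 2-sample
segments, O(n²) with O(1) segment costs from prefix sums. Both axes
share breakpoints. Windows are contiguous runs of non-excluded samples
within one phase; windows shorter than 12 samples are skipped.

The penalty is data-driven: `c·σ̂²·log n` with `c = 4` and σ̂ the
RMS over axes of a robust noise estimate (median absolute first
difference / (0.6745·√2)), floored at 0.05° so noiseless traces still
receive a positive penalty. The constant was kept at 4 after a
calibration against simulated ground truth: smaller values fragment
true slow phases below the retention limit, larger values only worsen
quick-phase merging.

Classification: segments under 12 samples (200 ms at 60 Hz) are
discarded as too short for a reliable velocity estimate; retained
segments with fitted speed ≥ 50 deg/s (configurable; no canonical value
exists) are saccades, the rest slow phases. Genuine quick phases are
2–4 samples and thus always discarded — analysis proceeds on the
retained pursuits, with the 50 deg/s rule as a safety net.

**Transition guard.** At realistic noise, isolating a 2-sample quick
phase does not pay for an extra segment, so the optimal partition puts
the breakpoint *inside* the quick phase, attaching one transition
sample to each neighbouring slow phase. Because quick phases always
reset against the pursuit direction, those samples tilt fitted slopes
systematically toward zero (measured bias in Δ: +0.75 deg/s where the
truth is 0). Slow-phase velocity is therefore fitted on the segment
interior, excluding one guard sample at each end (configurable), and
the amplitude is the fitted line evaluated at the segment's extreme
times, preserving `speed = |amplitude| / duration`. This removes
essentially all of the bias (to +0.03 deg/s on clean cohorts). A small
positive residual (~+0.2–0.4 deg/s at cohort level) remains from the
rare segment that swallows an entire quick phase between two
truncated slow phases; it is visible in very large pooled samples but
well inside the per-subject variability.

Durations are reported as `t_end − t_start` of the detected samples, so
an n-sample segment spans (n−1)/60 s; the discard rule uses the sample
count. Breakpoint localization at a continuous slope knee is inherently
±1–2 samples at 0.3° noise (within ±1 sample of the knee the competing
models differ by less than the noise).

## Statistics

Δ is computed for slow phases inside the cornering phase only. Subject
means are unweighted means over a subject's slow phases within a
condition; group CIs use the t distribution with df = n−1. The
normal-vs-tp contrast is a paired two-sided t-test over common
subjects; normal-vs-control is an independent pooled-variance t-test
with df = n₁+n₂−2 computed from the actual group sizes; the pooled CI
concatenates normal and control subject means. No multiple-testing
correction is applied (two planned contrasts). Degenerate all-zero
paired differences report t = 0, p = 1.

Descriptives: per-sample gaze displacement from the geometric TP with
component-wise per-subject medians (robust to symmetric tracker noise);
relative-frequency direction histograms over equal-width bins on
(−180°, 180°] that sum to exactly 1; highest-density-region thresholds
of the 2-D slow-phase velocity cloud from a Gaussian KDE (Scott
bandwidth), where for mass p the returned level is the largest density
whose superlevel set holds at least fraction p of the samples — only
this enclosed-mass contract is tested, not the smoother itself.

Per-trial condition classification labels a trial `tp` when its mean Δ
exceeds half its own predicted TP value (½ × mean ½|ω|), i.e. the
midpoint of the two hypotheses.

## Problem sizes and determinism

Default cohorts are 7 subjects × 16 runs (plus a 17-subject control
cohort in the analysis drivers); one trial is ≈ 19 s of driving
(~1,140 gaze samples, ~420 in the analyzed cornering window). The whole
simulate–detect–analyze chain runs in well under a minute on one core.
All randomness flows from `numpy.random.default_rng` seeded per
subject/trial/stage from a single master seed; outputs are
byte-identical across reruns with the same seed, and every output file
carries the software version and a configuration hash.

## Known limitations

* The generator's strategies are pure; real drivers mix them, glance at
  mirrors and dashboards, and track with gain < 1, so real
  between-subject spread in Δ is larger than simulated.
* The quick-phase/slow-phase boundary treatment leaves a small positive
  Δ bias (see above); with tens of pooled subjects the pooled CI can
  exclude zero even under pure waypoint tracking.
* GPS alignment uses noiseless simulated positions; real GPS multipath
  error is not modelled.
* The `tp_okr` strategy's drift model (gain on local TP flow, frozen
  per slow phase) is an assumption; nothing in the pipeline depends on
  its details.
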