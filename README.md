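# curvegaze

Where do drivers look when steering through a bend — at the **tangent
point** (TP, the point where the line of sight grazes the inside lane
edge) or at **waypoints on the future path**? The two targets sit close
together in the visual field, so gaze-position heatmaps cannot separate
them. Their *motion* can: on a circular trajectory the TP keeps a
constant egocentric direction, while the line of sight to any
world-fixed point on the path rotates at exactly **half the vehicle's
yaw rate** ω. Waypoint tracking therefore produces optokinetic
nystagmus whose slow phases drift horizontally at −½ω; TP fixation
predicts none.

This package implements that analysis end to end for synthetic
instrumented-car data:

* **geometry** — closed-form cornering kinematics: TP direction
  (`|h| = 90° − arcsin(r/d)`), waypoint direction (½ × remaining arc,
  by the inscribed-angle theorem), and gaze-line rotation rates
  (−½ω for every on-path point).
* **synthetic** — a seeded simulator of 60 Hz gaze + 100 Hz CAN +
  1 Hz GPS trials under three strategies (waypoint, tp, tp + reflexive
  drift), with tracker noise, vibration wander, blink-like dropouts and
  a sample-exact ground-truth event log.
* **preprocess** — quality filtering (criterion 0.2), multirate
  resampling, position alignment to a prototype trial, and bend phases
  (entry = 50 m before curvature onset; cornering cut 35 m before the
  exit).
* **semdetect** — optimal piecewise-linear segmentation of the 2-D gaze
  trace by exact dynamic programming (SSE + penalty per segment),
  discarding segments under 12 samples (200 ms at 60 Hz) as too short
  for reliable velocity estimates.
* **oknstats** — the fixation-by-fixation statistic
  **Δ = ½·|yaw| − v_against** (waypoint tracking ⇒ Δ ≈ 0; TP fixation ⇒
  Δ ≈ ½|ω|), per-subject aggregation, 95% CIs, paired and independent
  t-tests, direction histograms, TP-displacement medians and
  enclosed-mass density thresholds.

The design mirrors the on-road experiment the method comes from:
7 subjects × 16 runs on a 48 m-radius ramp at ≈ 42 km/h, in alternating
blocks of normal driving and an explicit look-at-the-TP instruction,
plus an independent 17-subject control cohort.

## Worked example

```bash
python analysis/01_simulate.py --seed 0   # 248 trial CSVs under results/trials/
python analysis/02_detect.py              # results/segments.tsv
python analysis/03_analyze.py             # results/report.json + summary
```

The analysis step prints (seed 0):

```
slow phases analyzed: 4185
  normal   mean Δ = +0.32 deg/s, 95% CI [-0.09, +0.73]
  tp       mean Δ = +6.36 deg/s, 95% CI [+6.08, +6.63]
  control  mean Δ = +0.34 deg/s, 95% CI [+0.15, +0.54]
  normal vs tp (paired):   t(6) = -29.42, p = 1e-07
  normal vs control (ind): t(22) = -0.13, p = 0.9
  per-trial condition classification: 99.6% of 248 trials
```

Read: under normal driving the slow-phase velocity matches ½·yaw (Δ
centred on zero — the waypoint-tracking signature), while under the
TP-fixation instruction Δ sits at ½|ω| ≈ 6.5 deg/s because the
horizontal nystagmus disappears; the two conditions separate perfectly
within subjects, and normal driving is indistinguishable from the
uninstructed control cohort. Individual trials can be classified by
strategy from Δ alone with ≈ 99% accuracy.

The same pipeline is scriptable through a CLI
(`curvegaze simulate | detect | analyze | run-all`, all seeded and
byte-reproducible) and as a library (`simulate_cohort`,
`detect_cohort`, `analyze_segments`). File formats are documented in
`FORMATS.md`, the model and its assumptions in `docs/methods.md`.

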