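# File formats

All files are UTF-8 text with `.` as the decimal separator. Angles are
degrees, distances metres, rates deg/s, times seconds. Every generated
file starts with a provenance comment line
`# curvegaze <version> config=<hash>`; readers must skip `#` lines.

## Trial CSV (`trial_sSS_rRR.csv`)

Comma-separated, mandatory header row, one row per 60 Hz gaze sample.
CAN-bus signals (originally 100 Hz) are merged by nearest-preceding
sample; GPS (1 Hz) by linear interpolation.

| column     | meaning                                                    |
|------------|------------------------------------------------------------|
| t          | time from trial start (s)                                  |
| gh_deg     | horizontal gaze angle, positive right of heading (deg)     |
| gv_deg     | vertical gaze angle, positive below horizon (deg)          |
| quality    | tracker quality 0–1 (samples < 0.2 are excluded)           |
| speed_mps  | vehicle speed (m/s)                                        |
| yaw_dps    | yaw rate, clockwise positive (deg/s)                       |
| x_m, y_m   | planar position (m)                                        |
| subject    | subject id                                                 |
| trial      | run index within subject (1–16)                            |
| condition  | normal / tp / control                                      |
| tp_h_deg, tp_v_deg | ground-truth tangent-point direction (synthetic)   |

A sidecar `trial_sSS_rRR.json` carries trial metadata (bend geometry,
path radius, route distances, exclusion flags) and the ground-truth
event log: a list of `{start_s, end_s, kind, target}` with
`kind ∈ {slow_phase, saccade}`.

## Segments TSV (`segments.tsv`)

Tab-separated, one row per detected segment: `subject, trial,
condition, bend_id, handedness, phase, t_start, t_end, duration, n,
slope_h, slope_v, amp_h, amp_v, speed, direction, class, yaw_mean`.
`direction` is measured from vehicle-frame vertical (0° = up, positive
clockwise). `class ∈ {slow_phase, saccade, discarded}`.

## Report JSON (`report.json`)

Group results (per-subject mean Δ, group means, 95% CIs, paired and
independent t-tests, pooled CI), per-condition direction histograms and
velocity-density (HDR) thresholds, tangent-point displacement medians,
the per-trial condition classification, and an echo of every parameter
and sign convention used.

## Configuration JSON

`RunConfig` with sections `sim` (cohort design), `detect` (quality
threshold, penalty constant, minimum samples, saccade threshold,
transition guard) and `analysis` (bins, mass fractions, confidence
level); any omitted field takes its documented default.

## Manifest (`manifest.json`)

SHA-256 checksum of every file produced by a stage, plus the software
version, config hash and master seed; reruns with the same seed are
byte-identical.
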