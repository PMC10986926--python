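# armrep

Quantify repetitive arm movement from arm-worn inertial sensors: from raw
accelerometer/gyroscope streams to humeral elevation angles, movement
cycles, active/resting bouts, exposure metrics, validation against
video-rated intervals, and bilateral (dominant vs non-dominant) statistical
comparison. A synthetic-data simulator with exact ground truth makes every
stage verifiable without any recorded data.

## How it works

1. **Orientation** (`armrep.orientation`) — a magnetometer-free
   complementary filter fuses gyroscope and accelerometer into a
   sensor-to-world quaternion stream whose *inclination* is drift-free
   (heading carries no accuracy contract). A ≥ 1 s static arm-hang window
   calibrates the humeral long axis in the sensor frame; the humeral
   elevation angle is the angle between that axis and the vertical
   (0° = arm hanging, 180° = overhead).
2. **Cycle/bout detection** (`armrep.arm_core`) — the elevation trace is
   optionally low-pass filtered (zero-phase), reduced to an alternating
   extrema series, and pruned smallest-range-first until every adjacent
   range meets the movement threshold (default 10°). Each surviving maximum
   with valleys on both sides is one movement cycle (elevation event,
   optional idle, lowering event). Consecutive cycles separated by
   no-activity gaps ≤ 7 s share an active bout; longer gaps are resting
   bouts. Metrics (counts, totals, mean/SD/median/IQR of durations,
   cycles per bout, median/peak elevation per bout) are reported for all
   active bouts and for bouts longer than 10 s.
3. **Evaluation** (`armrep.evaluation`) — sample-wise accuracy /
   sensitivity / specificity against annotated intervals, stroke-count
   error, threshold sweeps, per-activity summaries.
4. **Stats** (`armrep.stats`) — paired two-sided Wilcoxon signed-rank tests
   (exact, tie-aware, for up to 25 effective pairs; normal approximation
   with tie/continuity corrections above) and side-by-side descriptive
   summaries.
5. **Synthesis** (`armrep.synth`) — programmable sessions built from
   raised-cosine cycles with exact ground-truth cycles/bouts, plus a
   forward IMU model (rotation in a fixed vertical plane) for end-to-end
   orientation tests.

## CLI

The console entry point is `arm`. Shared parameters may be given globally
(before the subcommand) or on the subcommands that use them.

```bash
# synthesize a session (elevation + raw IMU + ground truth)
arm simulate --spec spec.json --out-elev elev.csv --out-imu imu.csv \
    --out-truth truth.json --seed 7

# raw IMU -> elevation angles (static calibration window in seconds)
arm elevation --imu imu.csv --calib-start 0 --calib-end 2 --out elev.csv

# movement cycles at a threshold
arm detect --elev elev.csv --threshold-deg 10 --out cycles.csv

# full metric set
arm metrics --elev elev.csv --threshold-deg 10 --rest-gap-s 7 \
    --long-bout-s 10 --out metrics.json

# score against video-rated intervals
arm validate --elev elev.csv --ann ann.csv --threshold-deg 10 --out scores.json

# threshold sweep (5/10/15/20 degrees by default)
arm sweep --elev elev.csv --ann ann.csv --thresholds 5,10,15,20 --out sweep.csv

# bilateral comparison from a directory of <pid>_<dom|nondom>[_day].json
arm compare --metrics-dir metrics/ --out bilateral.csv
```

File formats (CSV, UTF-8, header mandatory):

- IMU: `time_s,ax_mps2,ay_mps2,az_mps2,gx_rads,gy_rads,gz_rads`
- annotations: `start_s,end_s,label` with label ∈
  {resting, propulsion, non_propulsion}
- elevation: `time_s,elevation_deg`

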