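# gaitfuse

A toolkit for two-IMU sagittal-plane joint-angle measurement, built
around five pieces:

- **`gaitfuse.synthetic`** — physics-based ground-truth generation
  (damped free-swinging pendulum, treadmill gait at configurable speed)
  and a measurement model that turns trajectories into noisy IMU
  streams (white noise, constant gyro bias, full-scale saturation at
  ±16 g / ±2000 dps) plus a noiseless high-rate reference angle series.
- **`gaitfuse.fusion`** — stationary gyro self-calibration and an
  EKF-based gravity-direction observer that fuses accelerometer and
  gyroscope samples into segment inclination (radians, signed, sagittal).
- **`gaitfuse.joint`** — knee flexion angle from thigh and shank
  inclination series (flexion positive, 0° at full extension), plus a
  static standing-offset calibration.
- **`gaitfuse.compare`** — verification arithmetic: cross-correlation
  time alignment, resampling onto the wearable clock, and agreement
  statistics (RMSE, mean, population SD, min/max — reported in degrees).
- **`gaitfuse.store`** — a metrics store with one endpoint per
  measurement type, JSON-array ingestion, and per-column query-string
  filters (`col=v`, `col.gt=v`, `col.lt=v`; text columns equality-only;
  strict inequalities; gt+lt combine to a range), backed by SQLite, with
  a thin optional HTTP binding (`gaitfuse.store_http`, stdlib only).

`gaitfuse.experiments` wires the pieces into the two end-to-end
verification experiments (pendulum, treadmill) and `gaitfuse.cli`
exposes everything as a command-line tool.

## CLI

```sh
# synthetic data
gaitfuse simulate pendulum --duration 60 --seed 1 --out-dir out/pend
gaitfuse simulate gait --speed 3 --duration 60 --seed 1 --out-dir out/gait

# sensor pipeline
gaitfuse calibrate out/gait/thigh_imu.csv --window 4
gaitfuse fuse out/gait/thigh_imu.csv --out out/gait/thigh_inclination.csv
gaitfuse fuse out/gait/shank_imu.csv --out out/gait/shank_inclination.csv
gaitfuse knee-angle --thigh out/gait/thigh_inclination.csv \
    --shank out/gait/shank_inclination.csv --out out/gait/knee.csv
gaitfuse compare --est out/gait/knee.csv --ref out/gait/reference_knee_angle.csv \
    --max-lag 2.0 --report out/gait/stats.json

# end-to-end experiments (exit code 3 if --max-rmse is exceeded)
gaitfuse verify-pendulum --seed 1 --max-rmse 3.5
gaitfuse verify-gait --speeds 3,6,9,12 --seed 1 --max-rmse 8.0 --out-dir out/report

# metrics store
gaitfuse define-endpoint --db metrics.db --endpoint inclination \
    --column time:timestamp --column sensor_id:text --column angle:real
gaitfuse ingest records.json --db metrics.db --endpoint inclination
gaitfuse query "angle.gt=0.1&angle.lt=0.5" --db metrics.db --endpoint inclination
gaitfuse serve --db metrics.db --port 8080
```

IMU streams are CSV (`time_s, ax, ay, az, gx, gy, gz`; m/s² and rad/s)
with a JSON metadata sidecar; angle series are CSV
(`time_s, angle_rad`).

## Conventions

- World frame: z up; sagittal rotation about y; a segment at
  inclination θ sees world vectors through `C(θ) = R_y(θ)`, so an
  upright stationary sensor reads specific force `(0, 0, +g)` and
  inclination is `atan2(-g_x, -g_z)` of the estimated gravity
  direction (forward lean positive).
- Angles are radians internally; agreement statistics and CLI tables
  are degrees.
- All randomness flows from explicit integer seeds; a fixed seed gives
  bit-identical streams and reports.
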