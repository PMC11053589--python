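"""Sensor-side computation: gyro self-calibration and the EKF gravity
observer that turns 6-axis IMU samples into sagittal-plane inclination.

The observer state is the gravity *direction* in the sensor frame (a
unit 3-vector) with a 3x3 covariance. Prediction rotates the estimate
by the bias-corrected angular rate (gravity is world-fixed, so it moves
by ``-omega`` in the sensor frame); the measurement update pulls the
estimate toward the normalized negative accelerometer reading, but only
when the accelerometer norm is close enough to g that the sample is
plausibly gravity-dominated (norm gating).

Inclination is the signed sagittal projection
``atan2(-g_x, -g_z)`` under the frame convention of
:mod:`gaitfuse.synthetic` (upright sensor: gravity direction
``(0, 0, -1)``, inclination 0; forward lean positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gaitfuse.errors import NotStationaryError
from gaitfuse.series import AngleSeries, ImuStream
from gaitfuse.synthetic import GRAVITY

__all__ = [
    "GyroBias",
    "ObserverParams",
    "GravityObserverState",
    "calibrate_gyro_bias",
    "observer_init",
    "observer_step",
    "inclination_from_state",
    "run_observer",
    "min_sampling_rate",
]

logger = logging.getLogger(__name__)

_MIN_CAL_SAMPLES = 50


def min_sampling_rate(max_signal_frequency: float) -> float:
    """Minimum sampling rate (Hz) required by the sampling theorem.

    Twice the highest frequency component of the signal; e.g. a gait
    signal reaching 4.5 Hz needs at least 9 Hz.
    """
    if max_signal_frequency <= 0:
        raise ValueError("max_signal_frequency must be > 0")
    return 2.0 * max_signal_frequency


@dataclass(frozen=True)
class GyroBias:
    """Per-axis gyroscope offset estimated during a stationary window."""

    bias: np.ndarray
    n_samples: int
    stationarity_score: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "bias", np.asarray(self.bias, dtype=float))
        if self.bias.shape != (3,):
            raise ValueError("bias must be a 3-vector")
        if not np.all(np.isfinite(self.bias)):
            raise ValueError("bias components must be finite")

    @staticmethod
    def zero() -> "GyroBias":
        """Explicit zero bias (uncalibrated sensor)."""
        return GyroBias(np.zeros(3), n_samples=0)


@dataclass(frozen=True)
class ObserverParams:
    """Gravity-observer tuning. All defaults are artifact choices."""

    process_noise_sd: float = 0.001  # rad/sqrt(s)
    accel_meas_noise_sd: float = 1.0  # m/s^2
    accel_gate_threshold: float = 0.06 * GRAVITY  # |"a"-g| beyond which update skipped
    gravity: float = GRAVITY
    initial_covariance: float = 0.1  # rad^2

    def __post_init__(self):
        for name in (
            "process_noise_sd",
            "accel_meas_noise_sd",
            "accel_gate_threshold",
            "gravity",
            "initial_covariance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GravityObserverState:
    """Unit gravity direction in the sensor frame with covariance."""

    gravity_dir: np.ndarray
    covariance: np.ndarray
    time: float
    last_rate: np.ndarray | None = None  # bias-corrected rate of previous sample

    def __post_init__(self):
        self.gravity_dir = np.asarray(self.gravity_dir, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.gravity_dir.shape != (3,):
            raise ValueError("gravity_dir must be a 3-vector")
        if self.covariance.shape != (3, 3):
            raise ValueError("covariance must be 3x3")


def calibrate_gyro_bias(
    stream: ImuStream,
    window: float,
    gyro_sd_threshold: float = 0.05,
    accel_norm_threshold: float = 0.5,
    gravity: float = GRAVITY,
) -> GyroBias:
    """Estimate the gyro offset from a stationary window at stream start.

    The window is first checked for stationarity: per-axis gyro standard
    deviation must stay below ``gyro_sd_threshold`` (rad/s) and the mean
    accelerometer norm must lie within ``accel_norm_threshold`` (m/s^2)
    of g. The bias is the per-axis mean of the gyro samples.

    Raises
    ------
    NotStationaryError
        Naming the violated check (``"gyro_rate_sd"`` or ``"accel_norm"``).
    ValueError
        If the window covers fewer than 50 samples.
    """
    t_end = stream.times[0] + window if len(stream) else 0.0
    mask = stream.times <= t_end
    n = int(mask.sum())
    if n < _MIN_CAL_SAMPLES:
        raise ValueError(
            f"calibration window covers {n} samples; at least {_MIN_CAL_SAMPLES} required"
        )

    gyro = stream.angular_rate[mask]
    accel = stream.specific_force[mask]

    gyro_sd = float(gyro.std(axis=0, ddof=0).max())
    if gyro_sd > gyro_sd_threshold:
        raise NotStationaryError("gyro_rate_sd", gyro_sd, gyro_sd_threshold)

    accel_dev = float(abs(np.linalg.norm(accel, axis=1).mean() - gravity))
    if accel_dev > accel_norm_threshold:
        raise NotStationaryError("accel_norm", accel_dev, accel_norm_threshold)

    score = max(gyro_sd / gyro_sd_threshold, accel_dev / accel_norm_threshold)
    return GyroBias(gyro.mean(axis=0), n_samples=n, stationarity_score=score)


def observer_init(first_accel, params: ObserverParams) -> GravityObserverState:
    """Initialize from the first accelerometer sample.

    Under the static specific-force convention the gravity direction is
    the normalized negative of the reading.
    """
    a = np.asarray(first_accel, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("cannot initialize from a zero or non-finite accelerometer sample")
    return GravityObserverState(
        gravity_dir=-a / norm,
        covariance=params.initial_covariance * np.eye(3),
        time=-np.inf,
    )


def _rotation_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix for a rotation vector."""
    angle = np.linalg.norm(rotvec)
    if angle < 1e-12:
        return np.eye(3)
    axis = rotvec / angle
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def observer_step(
    state: GravityObserverState,
    time: float,
    accel,
    gyro,
    bias: GyroBias,
    params: ObserverParams,
) -> GravityObserverState:
    """One predict(+update) cycle of the gravity observer.

    Predict: rotate the gravity direction by ``-(gyro - bias) * dt`` and
    inflate the covariance by process noise. Update: if the accelerometer
    norm is within the gate of g, blend toward the normalized negative
    reading; otherwise (or for an exactly antipodal measurement) keep the
    prediction. The direction is renormalized after every step.
    """
    if state.time != -np.inf and time <= state.time:
        raise ValueError(f"non-increasing timestamp: {time} after {state.time}")

    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    if not (np.all(np.isfinite(accel)) and np.all(np.isfinite(gyro))):
        logger.warning("skipping non-finite IMU sample at t=%.6f", time)
        return GravityObserverState(
            state.gravity_dir.copy(), state.covariance.copy(), time, state.last_rate
        )

    dt = 0.0 if state.time == -np.inf else time - state.time
    rate = gyro - bias.bias
    g_dir = state.gravity_dir
    p = state.covariance
    if dt > 0:
        # trapezoidal rate over the interval: avoids the half-sample lag a
        # zero-order hold of the newest sample would introduce
        mean_rate = rate if state.last_rate is None else 0.5 * (rate + state.last_rate)
        rot = _rotation_matrix(-mean_rate * dt)
        g_dir = rot @ g_dir
        p = rot @ p @ rot.T + (params.process_noise_sd**2 * dt) * np.eye(3)

    a_norm = np.linalg.norm(accel)
    if a_norm > 0 and abs(a_norm - params.gravity) <= params.accel_gate_threshold:
        z = -accel / a_norm
        if float(z @ g_dir) > -0.999:  # antipodal: predict-only fallback
            r = (params.accel_meas_noise_sd / params.gravity) ** 2 * np.eye(3)
            gain = p @ np.linalg.inv(p + r)
            g_dir = g_dir + gain @ (z - g_dir)
            p = (np.eye(3) - gain) @ p

    p = 0.5 * (p + p.T)
    g_dir = g_dir / np.linalg.norm(g_dir)
    return GravityObserverState(g_dir, p, time, rate)


def inclination_from_state(state: GravityObserverState) -> float:
    """Signed sagittal inclination in (-pi, pi]."""
    g = state.gravity_dir
    angle = float(np.arctan2(-g[0], -g[2]))
    if angle == -np.pi:
        angle = np.pi
    return angle


def run_observer(
    stream: ImuStream, params: ObserverParams, bias: GyroBias
) -> AngleSeries:
    """Fold the observer over a stream; one inclination per sample."""
    n = len(stream)
    if n == 0:
        return AngleSeries(np.empty(0), np.empty(0), stream.sensor_id)

    state = observer_init(stream.specific_force[0], params)
    out = np.empty(n)
    for i in range(n):
        state = observer_step(
            state,
            stream.times[i],
            stream.specific_force[i],
            stream.angular_rate[i],
            bias,
            params,
        )
        out[i] = inclination_from_state(state)
    return AngleSeries(stream.times.copy(), out, stream.sensor_id)
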