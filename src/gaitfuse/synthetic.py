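"""Synthetic rigid-body motion and IMU measurement generation.

Generates ground-truth sagittal-plane trajectories (damped pendulum,
treadmill gait) on a dense solver grid and converts them into noisy,
saturating IMU streams plus a noiseless high-rate reference angle
series standing in for an optical motion-capture system.

Frame conventions (shared with :mod:`gaitfuse.fusion`):

* World frame: z up, x horizontal, sagittal motion rotates about y.
* A segment at inclination ``theta`` (signed, 0 = vertical) maps a world
  vector ``v_w`` into its sensor frame via ``v_s = C(theta) @ v_w`` with
  ``C(theta) = R_y(theta)``; an upright stationary sensor therefore
  measures specific force ``(0, 0, +g)`` and the gravity *direction*
  in the sensor frame is ``(-sin(theta), 0, -cos(theta))``.
* The sensor angular rate in its own frame is ``omega_y = -theta_dot``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from gaitfuse.errors import IntegrationError
from gaitfuse.series import AngleSeries, ImuStream

__all__ = [
    "GRAVITY",
    "GaitConfig",
    "ImuNoiseModel",
    "MotionTrajectory",
    "PendulumConfig",
    "SegmentMotion",
    "imu_from_trajectory",
    "reference_angle",
    "simulate_gait",
    "simulate_pendulum",
    "with_stationary_preroll",
]

GRAVITY = 9.81
G_STANDARD = 9.81  # used for full-scale defaults expressed in g

DEG = np.pi / 180.0

#: default accelerometer full scale, 16 g
ACCEL_FULL_SCALE = 16.0 * G_STANDARD
#: default gyroscope full scale, 2000 dps
GYRO_FULL_SCALE = 2000.0 * DEG


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PendulumConfig:
    """Damped free-swinging pendulum parameters.

    ``length`` is the pivot-to-sensor-mount distance in metres. The
    pendulum angle is measured from the vertical; its dynamics are
    ``theta'' = -(g/L) sin(theta) - damping * theta'``.
    """

    length: float = 0.25
    initial_angle: float = 30.0 * DEG
    initial_rate: float = 0.0
    damping: float = 0.2
    gravity: float = GRAVITY
    duration: float = 60.0
    solver_dt: float = 1e-3

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not (0 < self.solver_dt <= self.duration):
            raise ValueError("solver_dt must be in (0, duration]")
        if self.damping < 0:
            raise ValueError("damping must be >= 0")
        if self.gravity <= 0:
            raise ValueError("gravity must be > 0")


def _default_cadence(speed_kmh: float) -> float:
    # stride frequency, monotone in speed; step frequency is double this,
    # inside the 1.5-2.5 Hz walking band
    return float(np.interp(speed_kmh, [3.0, 6.0, 9.0, 12.0], [0.9, 1.1, 1.3, 1.5]))


def _default_peak_flexion(speed_kmh: float) -> float:
    # swing-peak knee flexion in degrees: ~65 deg walking, ~85 deg jogging
    return float(np.interp(speed_kmh, [9.0, 12.0], [65.0, 85.0]))


def _default_bounce(speed_kmh: float) -> float:
    # vertical pivot (hip) acceleration amplitude; flight phases appear
    # only at jogging speed
    return float(np.interp(speed_kmh, [9.0, 12.0], [0.0, 3.0]))


@dataclass(frozen=True)
class GaitConfig:
    """Treadmill gait profile parameters.

    Angles in the config are in degrees (converted internally); ``None``
    fields are derived from ``speed``.
    """

    speed: float = 3.0  # km/h
    duration: float = 60.0
    cadence: float | None = None  # stride frequency, Hz
    peak_swing_flexion: float | None = None  # deg
    stance_flexion: float = 15.0  # deg, early-stance bump
    thigh_amplitude: float = 25.0  # deg
    thigh_length: float = 0.45  # m, hip -> knee
    bounce_accel: float | None = None  # m/s^2, vertical hip acceleration
    gravity: float = GRAVITY
    solver_dt: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if self.duration < 1.0 / self.stride_frequency:
            raise ValueError("duration must cover at least one full stride")
        if self.solver_dt <= 0:
            raise ValueError("solver_dt must be > 0")
        if self.thigh_length <= 0:
            raise ValueError("thigh_length must be > 0")

    @property
    def stride_frequency(self) -> float:
        return self.cadence if self.cadence is not None else _default_cadence(self.speed)

    @property
    def swing_peak_deg(self) -> float:
        if self.peak_swing_flexion is not None:
            return self.peak_swing_flexion
        return _default_peak_flexion(self.speed)

    @property
    def bounce_amplitude(self) -> float:
        return self.bounce_accel if self.bounce_accel is not None else _default_bounce(self.speed)


@dataclass(frozen=True)
class ImuNoiseModel:
    """Additive white noise, constant gyro bias, and full-scale clipping."""

    accel_noise_sd: float = 0.05  # m/s^2
    gyro_noise_sd: float = 0.005  # rad/s
    gyro_bias: Tuple[float, float, float] | None = None  # rad/s; None -> drawn from seed
    gyro_bias_range: float = 0.02  # rad/s, uniform per-axis range when drawn
    accel_full_scale: float = ACCEL_FULL_SCALE
    gyro_full_scale: float = GYRO_FULL_SCALE
    seed: int = 0

    def __post_init__(self):
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.accel_full_scale <= 0 or self.gyro_full_scale <= 0:
            raise ValueError("full scales must be > 0")

    def draw_bias(self, rng: np.random.Generator) -> np.ndarray:
        if self.gyro_bias is not None:
            return np.asarray(self.gyro_bias, dtype=float)
        return rng.uniform(-self.gyro_bias_range, self.gyro_bias_range, size=3)

    @staticmethod
    def noiseless() -> "ImuNoiseModel":
        return ImuNoiseModel(accel_noise_sd=0.0, gyro_noise_sd=0.0, gyro_bias=(0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class SegmentMotion:
    """Planar motion of one rigid segment: angle, its derivatives, and the
    world-frame linear acceleration of the segment's pivot point."""

    angle: np.ndarray  # rad
    rate: np.ndarray  # rad/s
    accel: np.ndarray  # rad/s^2
    pivot_accel: np.ndarray  # (n, 3) m/s^2, world frame


@dataclass
class MotionTrajectory:
    """Ground-truth rigid-body state on a dense time grid.

    ``angle_pair`` names the two segments whose inclination difference
    is the experiment's reference angle (moving minus reference segment).
    """

    times: np.ndarray
    segments: Dict[str, SegmentMotion]
    angle_pair: Tuple[str, str]
    gravity: float = GRAVITY

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in self.angle_pair:
            if name not in self.segments:
                raise ValueError(f"angle_pair references unknown segment {name!r}")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def reference_angles(self) -> np.ndarray:
        a, b = self.angle_pair
        return self.segments[a].angle - self.segments[b].angle


def _zero_segment(n: int, angle: float = 0.0) -> SegmentMotion:
    return SegmentMotion(
        angle=np.full(n, angle),
        rate=np.zeros(n),
        accel=np.zeros(n),
        pivot_accel=np.zeros((n, 3)),
    )


def simulate_pendulum(config: PendulumConfig) -> MotionTrajectory:
    """Integrate ``theta'' = -(g/L) sin(theta) - c theta'`` on a dense grid.

    Returns a trajectory with segments ``"pendulum"`` (swinging) and
    ``"fixed"`` (stationary vertical reference).
    """
    g_over_l = config.gravity / config.length
    c = config.damping

    def rhs(_t, y):
        theta, omega = y
        return [omega, -g_over_l * np.sin(theta) - c * omega]

    n = int(round(config.duration / config.solver_dt)) + 1
    times = np.linspace(0.0, config.duration, n)
    sol = solve_ivp(
        rhs,
        (0.0, config.duration),
        [config.initial_angle, config.initial_rate],
        t_eval=times,
        method="RK45",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        bad = np.argmax(~np.isfinite(sol.y).all(axis=0)) if sol.y.size else 0
        t_bad = times[bad] if sol.y.size else 0.0
        raise IntegrationError("pendulum integration produced non-finite state", t_bad)

    theta, omega = sol.y
    accel = -g_over_l * np.sin(theta) - c * omega
    segments = {
        "pendulum": SegmentMotion(theta, omega, accel, np.zeros((n, 3))),
        "fixed": _zero_segment(n),
    }
    return MotionTrajectory(times, segments, ("pendulum", "fixed"), config.gravity)


def _knee_fourier_coeffs(
    swing_peak_deg: float, stance_deg: float, n_harmonics: int = 6
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fit a truncated Fourier series to a normative per-stride knee shape.

    The target shape is a small early-stance flexion bump followed by a
    large swing peak, built from periodic (von Mises) bumps; the fitted
    series is rescaled so that its maximum equals ``swing_peak_deg``.
    Returns ``(a0, a[1..K], b[1..K])`` in degrees.
    """
    phi = np.linspace(0.0, 1.0, 1024, endpoint=False)
    two_pi = 2.0 * np.pi

    def bump(center, kappa):
        return np.exp(kappa * (np.cos(two_pi * (phi - center)) - 1.0))

    shape = stance_deg * bump(0.15, 18.0) + swing_peak_deg * bump(0.72, 9.0)

    k = np.arange(1, n_harmonics + 1)
    cos_basis = np.cos(two_pi * np.outer(phi, k))
    sin_basis = np.sin(two_pi * np.outer(phi, k))
    design = np.hstack([np.ones((len(phi), 1)), cos_basis, sin_basis])
    coeffs, *_ = np.linalg.lstsq(design, shape, rcond=None)
    a0, a, b = coeffs[0], coeffs[1 : n_harmonics + 1], coeffs[n_harmonics + 1 :]

    fitted = design @ coeffs
    scale = swing_peak_deg / fitted.max()
    return a0 * scale, a * scale, b * scale


def _eval_fourier(a0, a, b, freq, t):
    """Evaluate a Fourier series and its first two time derivatives."""
    k = np.arange(1, len(a) + 1)
    w = 2.0 * np.pi * freq * k  # angular frequency per harmonic
    phase = np.outer(t, w)
    cos_p, sin_p = np.cos(phase), np.sin(phase)
    value = a0 + cos_p @ a + sin_p @ b
    rate = (-sin_p * w) @ a + (cos_p * w) @ b
    accel = (-cos_p * w**2) @ a + (-sin_p * w**2) @ b
    return value, rate, accel


def simulate_gait(config: GaitConfig) -> MotionTrajectory:
    """Generate periodic thigh and shank motion for treadmill gait.

    Thigh inclination is a sinusoid at the stride frequency; the knee
    flexion angle per stride is a truncated Fourier series matching a
    normative stance-bump/swing-peak shape; shank = thigh - knee.
    The hip pivot gets a vertical bounce acceleration at step frequency
    (nonzero by default only at jogging speeds) and the shank pivot
    (the knee point) inherits the full thigh-rotation kinematics.
    """
    f = config.stride_frequency
    n = int(round(config.duration / config.solver_dt)) + 1
    t = np.linspace(0.0, config.duration, n)
    w = 2.0 * np.pi * f

    amp = config.thigh_amplitude * DEG
    thigh_angle = amp * np.sin(w * t)
    thigh_rate = amp * w * np.cos(w * t)
    thigh_accel = -amp * w**2 * np.sin(w * t)

    a0, a, b = _knee_fourier_coeffs(config.swing_peak_deg, config.stance_flexion)
    knee_deg, knee_rate_deg, knee_accel_deg = _eval_fourier(a0, a, b, f, t)
    knee = knee_deg * DEG
    knee_rate = knee_rate_deg * DEG
    knee_accel = knee_accel_deg * DEG

    shank_angle = thigh_angle - knee
    shank_rate = thigh_rate - knee_rate
    shank_accel = thigh_accel - knee_accel

    hip_acc = np.zeros((n, 3))
    hip_acc[:, 2] = config.bounce_amplitude * np.sin(2.0 * w * t)

    # knee-point acceleration: hip + thigh-length rotational terms
    sin_t, cos_t = np.sin(thigh_angle), np.cos(thigh_angle)
    u = np.stack([sin_t, np.zeros(n), -cos_t], axis=1)  # along-thigh, distal
    u_prime = np.stack([cos_t, np.zeros(n), sin_t], axis=1)
    knee_acc = (
        hip_acc
        + config.thigh_length * thigh_accel[:, None] * u_prime
        - config.thigh_length * thigh_rate[:, None] ** 2 * u
    )

    segments = {
        "thigh": SegmentMotion(thigh_angle, thigh_rate, thigh_accel, hip_acc),
        "shank": SegmentMotion(shank_angle, shank_rate, shank_accel, knee_acc),
    }
    return MotionTrajectory(t, segments, ("thigh", "shank"), config.gravity)


def with_stationary_preroll(
    traj: MotionTrajectory, duration: float, ramp: float = 1.0
) -> MotionTrajectory:
    """Prepend a stationary hold of each segment's initial pose.

    Used to give the gyro self-calibration a still window before motion
    starts; the motion part is shifted later in time by ``duration``.
    A cosine onset envelope of length ``ramp`` seconds blends from the
    hold into the motion so the angular rate is continuous (a hard rate
    step would alias into a persistent integration offset downstream).
    """
    if duration <= 0:
        return traj
    dt = float(np.median(np.diff(traj.times)))
    n_pre = int(round(duration / dt))
    pre_times = np.arange(n_pre) * dt
    new_times = np.concatenate([pre_times, traj.times + n_pre * dt])

    rel = traj.times - traj.times[0]
    ramp = min(ramp, traj.duration)
    u = np.clip(rel / ramp, 0.0, 1.0) if ramp > 0 else np.ones_like(rel)
    s = 0.5 - 0.5 * np.cos(np.pi * u)  # C^1 onset: s'(0) = s'(1) = 0
    s_dot = np.where(u < 1.0, 0.5 * np.pi / ramp * np.sin(np.pi * u), 0.0)
    s_ddot = np.where(u < 1.0, 0.5 * (np.pi / ramp) ** 2 * np.cos(np.pi * u), 0.0)

    segments = {}
    for name, seg in traj.segments.items():
        a0 = seg.angle[0]
        rel_angle = seg.angle - a0
        angle = a0 + s * rel_angle
        rate = s_dot * rel_angle + s * seg.rate
        accel = s_ddot * rel_angle + 2.0 * s_dot * seg.rate + s * seg.accel
        pivot = s[:, None] * seg.pivot_accel
        segments[name] = SegmentMotion(
            angle=np.concatenate([np.full(n_pre, a0), angle]),
            rate=np.concatenate([np.zeros(n_pre), rate]),
            accel=np.concatenate([np.zeros(n_pre), accel]),
            pivot_accel=np.concatenate([np.zeros((n_pre, 3)), pivot]),
        )
    return MotionTrajectory(new_times, segments, traj.angle_pair, traj.gravity)


# ---------------------------------------------------------------------------
# measurement model
# ---------------------------------------------------------------------------


def _interp_columns(t_new, t_old, arr):
    if arr.ndim == 1:
        return np.interp(t_new, t_old, arr)
    return np.stack([np.interp(t_new, t_old, arr[:, j]) for j in range(arr.shape[1])], axis=1)


def imu_from_trajectory(
    traj: MotionTrajectory,
    segment: str,
    mount_radius: float,
    rate: float,
    noise: ImuNoiseModel,
    sensor_id: str | None = None,
    start_skew: float = 0.0,
) -> ImuStream:
    """Sample a segment's motion into a noisy, saturating IMU stream.

    The gyroscope measures the segment angular velocity expressed in the
    sensor frame (``omega_y = -theta_dot``) plus bias and noise; the
    accelerometer measures the specific force at the mount point
    (gravity reaction + tangential ``r*theta''`` + centripetal
    ``r*theta'^2`` + pivot acceleration) rotated into the sensor frame,
    plus noise. Both channels clip at their full scales.

    ``start_skew`` delays the first sample to exercise time alignment.
    """
    if segment not in traj.segments:
        raise ValueError(f"unknown segment {segment!r}; have {sorted(traj.segments)}")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if mount_radius < 0:
        raise ValueError("mount_radius must be >= 0")

    seg = traj.segments[segment]
    t0, t1 = traj.times[0] + start_skew, traj.times[-1]
    n = int(np.floor((t1 - t0) * rate)) + 1
    t = t0 + np.arange(n) / rate

    theta = _interp_columns(t, traj.times, seg.angle)
    theta_dot = _interp_columns(t, traj.times, seg.rate)
    theta_ddot = _interp_columns(t, traj.times, seg.accel)
    pivot_acc = _interp_columns(t, traj.times, seg.pivot_accel)

    sin_t, cos_t = np.sin(theta), np.cos(theta)
    u = np.stack([sin_t, np.zeros(n), -cos_t], axis=1)
    u_prime = np.stack([cos_t, np.zeros(n), sin_t], axis=1)
    a_world = (
        pivot_acc
        + mount_radius * theta_ddot[:, None] * u_prime
        - mount_radius * theta_dot[:, None] ** 2 * u
    )
    # specific force in world frame: proper acceleration minus gravity
    f_world = a_world - np.array([0.0, 0.0, -traj.gravity])
    # rotate into the sensor frame: v_s = C(theta) v_w, C = R_y(theta)
    fx = cos_t * f_world[:, 0] + sin_t * f_world[:, 2]
    fz = -sin_t * f_world[:, 0] + cos_t * f_world[:, 2]
    f_sensor = np.stack([fx, f_world[:, 1], fz], axis=1)

    gyro = np.zeros((n, 3))
    gyro[:, 1] = -theta_dot

    rng = np.random.default_rng(noise.seed)
    bias = noise.draw_bias(rng)
    gyro = gyro + bias
    if noise.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, noise.gyro_noise_sd, size=(n, 3))
    if noise.accel_noise_sd > 0:
        f_sensor = f_sensor + rng.normal(0.0, noise.accel_noise_sd, size=(n, 3))

    f_sensor = np.clip(f_sensor, -noise.accel_full_scale, noise.accel_full_scale)
    gyro = np.clip(gyro, -noise.gyro_full_scale, noise.gyro_full_scale)

    return ImuStream(
        sensor_id=sensor_id or segment,
        times=t,
        specific_force=f_sensor,
        angular_rate=gyro,
        nominal_rate=rate,
        metadata={
            "segment": segment,
            "mount_radius_m": mount_radius,
            "noise_seed": noise.seed,
            "gyro_bias_true": list(map(float, bias)),
            "accel_full_scale": noise.accel_full_scale,
            "gyro_full_scale": noise.gyro_full_scale,
        },
    )


def reference_angle(traj: MotionTrajectory, rate: float = 220.0) -> AngleSeries:
    """Noiseless ground-truth angle sampled at the reference rate.

    Stands in for the optical reference system: the pendulum angle for
    the pendulum trajectory, the knee flexion angle for gait.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t0, t1 = traj.times[0], traj.times[-1]
    n = int(np.floor((t1 - t0) * rate))
    t = np.concatenate([t0 + np.arange(n) / rate, [t1]])  # preserve endpoint
    t = np.unique(t)
    angles = np.interp(t, traj.times, traj.reference_angles())
    return AngleSeries(t, angles, name="reference")
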