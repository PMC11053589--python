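import numpy as np
import pytest

from gaitfuse.errors import IntegrationError
from gaitfuse.synthetic import (
    DEG,
    GRAVITY,
    GaitConfig,
    ImuNoiseModel,
    MotionTrajectory,
    PendulumConfig,
    SegmentMotion,
    imu_from_trajectory,
    reference_angle,
    simulate_gait,
    simulate_pendulum,
    with_stationary_preroll,
)


def constant_rate_trajectory(rate, duration=2.0, dt=1e-3, angle0=0.0):
    t = np.arange(0.0, duration + dt / 2, dt)
    n = len(t)
    seg = SegmentMotion(
        angle=angle0 + rate * t,
        rate=np.full(n, rate),
        accel=np.zeros(n),
        pivot_accel=np.zeros((n, 3)),
    )
    fixed = SegmentMotion(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros((n, 3)))
    return MotionTrajectory(t, {"seg": seg, "fixed": fixed}, ("seg", "fixed"))


class TestPendulumConfig:
    def test_invalid_length(self):
        with pytest.raises(ValueError):
            PendulumConfig(length=0.0)

    def test_invalid_solver_dt(self):
        with pytest.raises(ValueError):
            PendulumConfig(duration=1.0, solver_dt=2.0)

    def test_negative_damping(self):
        with pytest.raises(ValueError):
            PendulumConfig(damping=-0.1)


class TestSimulatePendulum:
    def test_equilibrium_stays_at_zero(self):
        traj = simulate_pendulum(
            PendulumConfig(initial_angle=0.0, initial_rate=0.0, duration=5.0)
        )
        assert np.allclose(traj.segments["pendulum"].angle, 0.0, atol=1e-12)

    def test_small_angle_period_matches_closed_form(self):
        # oracle: small-angle period T = 2*pi*sqrt(L/g); L chosen so T = 1 s
        length = 0.2485
        expected = 2.0 * np.pi * np.sqrt(length / GRAVITY)
        traj = simulate_pendulum(
            PendulumConfig(length=length, initial_angle=2.0 * DEG, damping=0.0, duration=30.0)
        )
        theta = traj.segments["pendulum"].angle
        # period from upward zero-crossing times, linearly interpolated
        sign_change = (theta[:-1] < 0) & (theta[1:] >= 0)
        idx = np.flatnonzero(sign_change)
        t_cross = traj.times[idx] - theta[idx] * (
            (traj.times[idx + 1] - traj.times[idx]) / (theta[idx + 1] - theta[idx])
        )
        periods = np.diff(t_cross)
        assert abs(periods.mean() - expected) / expected < 0.005

    def test_damped_peaks_strictly_decreasing(self):
        traj = simulate_pendulum(
            PendulumConfig(damping=0.2, initial_angle=30.0 * DEG, duration=20.0)
        )
        theta = traj.segments["pendulum"].angle
        peaks = theta[1:-1][(theta[1:-1] > theta[:-2]) & (theta[1:-1] > theta[2:])]
        positive = peaks[peaks > 1e-4]
        assert len(positive) >= 5
        assert np.all(np.diff(positive) < 0)

    def test_undamped_energy_conserved(self):
        cfg = PendulumConfig(damping=0.0, initial_angle=30.0 * DEG, duration=60.0)
        traj = simulate_pendulum(cfg)
        seg = traj.segments["pendulum"]
        energy = 0.5 * cfg.length**2 * seg.rate**2 + GRAVITY * cfg.length * (
            1.0 - np.cos(seg.angle)
        )
        drift = np.abs(energy - energy[0]).max() / energy[0]
        assert drift < 1e-3

    def test_rate_is_derivative_of_angle(self):
        traj = simulate_pendulum(PendulumConfig(duration=5.0))
        seg = traj.segments["pendulum"]
        fd = np.gradient(seg.angle, traj.times)
        # boundaries use one-sided differences; check the interior
        assert np.allclose(fd[1:-1], seg.rate[1:-1], atol=5e-3)


class TestSimulateGait:
    @pytest.mark.parametrize(
        "speed, lo, hi", [(3.0, 60.0, 70.0), (6.0, 60.0, 70.0), (12.0, 80.0, 90.0)]
    )
    def test_max_knee_angle_in_expected_band(self, speed, lo, hi):
        traj = simulate_gait(GaitConfig(speed=speed, duration=10.0))
        knee_deg = np.degrees(traj.reference_angles())
        assert lo <= knee_deg.max() <= hi

    def test_knee_angle_above_hyperextension_floor(self):
        traj = simulate_gait(GaitConfig(speed=3.0, duration=10.0))
        assert np.degrees(traj.reference_angles()).min() >= -5.0

    def test_knee_series_periodic(self):
        # cadence 1 Hz so the stride period is an exact number of grid steps
        traj = simulate_gait(GaitConfig(speed=3.0, duration=4.0, cadence=1.0))
        knee = traj.reference_angles()
        shift = int(round(1.0 / 1e-3))
        assert np.abs(knee[shift:] - knee[:-shift]).max() < 1e-6

    def test_shank_is_thigh_minus_knee(self):
        traj = simulate_gait(GaitConfig(speed=6.0, duration=5.0))
        thigh = traj.segments["thigh"].angle
        shank = traj.segments["shank"].angle
        assert np.allclose(thigh - shank, traj.reference_angles())

    def test_duration_below_one_stride_rejected(self):
        with pytest.raises(ValueError):
            GaitConfig(speed=3.0, duration=0.5)

    def test_bounce_only_at_jogging_speed(self):
        walk = simulate_gait(GaitConfig(speed=3.0, duration=5.0))
        jog = simulate_gait(GaitConfig(speed=12.0, duration=5.0))
        assert np.allclose(walk.segments["thigh"].pivot_accel, 0.0)
        assert np.abs(jog.segments["thigh"].pivot_accel[:, 2]).max() > 1.0

    def test_rate_is_derivative_of_angle(self):
        traj = simulate_gait(GaitConfig(speed=9.0, duration=5.0))
        for seg in traj.segments.values():
            fd = np.gradient(seg.angle, traj.times)
            assert np.allclose(fd, seg.rate, atol=5e-2)


class TestImuFromTrajectory:
    def test_static_reading_opposes_gravity(self, noiseless):
        traj = constant_rate_trajectory(0.0)
        stream = imu_from_trajectory(traj, "seg", 0.1, 50.0, noiseless)
        assert np.allclose(stream.angular_rate, 0.0, atol=1e-12)
        assert np.allclose(stream.specific_force, [0.0, 0.0, GRAVITY], atol=1e-9)

    def test_constant_rate_gyro_and_accel_norm(self, noiseless):
        omega = 0.7
        traj = constant_rate_trajectory(omega)
        stream = imu_from_trajectory(traj, "seg", 0.0, 50.0, noiseless)
        # sensor y-rate convention: omega_y = -theta_dot
        assert np.allclose(stream.angular_rate[:, 1], -omega, atol=1e-12)
        assert np.allclose(np.abs(stream.angular_rate[:, 1]), omega, atol=1e-12)
        norms = np.linalg.norm(stream.specific_force, axis=1)
        assert np.allclose(norms, GRAVITY, atol=1e-9)

    def test_gyro_full_scale_clipping(self):
        commanded = 2500.0 * DEG
        full_scale = 2000.0 * DEG
        traj = constant_rate_trajectory(-commanded, duration=1.0)
        noise = ImuNoiseModel.noiseless()
        stream = imu_from_trajectory(traj, "seg", 0.0, 50.0, noise)
        assert np.allclose(stream.angular_rate[:, 1], full_scale)

    def test_no_sample_exceeds_full_scales(self):
        traj = simulate_gait(GaitConfig(speed=12.0, duration=5.0))
        noise = ImuNoiseModel(seed=3)
        stream = imu_from_trajectory(traj, "shank", 0.22, 50.0, noise)
        assert np.abs(stream.specific_force).max() <= noise.accel_full_scale
        assert np.abs(stream.angular_rate).max() <= noise.gyro_full_scale

    def test_turning_point_tangential_accel_matches_ode_rhs(self, noiseless):
        # oracle: at a turning point (rate = 0) the ODE gives
        # theta_ddot = -(g/L) sin(theta_max); the sensor-frame x axis is the
        # tangential direction, carrying r*theta_ddot plus the gravity
        # projection g*sin(theta)
        cfg = PendulumConfig(length=0.3, initial_angle=25.0 * DEG, damping=0.0, duration=5.0)
        traj = simulate_pendulum(cfg)
        radius = 0.2
        stream = imu_from_trajectory(traj, "pendulum", radius, 1000.0, noiseless)
        theta = np.interp(stream.times, traj.times, traj.segments["pendulum"].angle)
        rate = np.interp(stream.times, traj.times, traj.segments["pendulum"].rate)
        i = np.argmin(np.abs(rate[100:900])) + 100  # interior turning point
        theta_max = theta[i]
        theta_ddot = -(GRAVITY / cfg.length) * np.sin(theta_max)
        expected_fx = radius * theta_ddot + GRAVITY * np.sin(theta_max)
        assert stream.specific_force[i, 0] == pytest.approx(expected_fx, abs=2e-3)

    def test_fixed_seed_bit_identical(self):
        traj = simulate_gait(GaitConfig(speed=3.0, duration=5.0))
        kwargs = dict(segment="thigh", mount_radius=0.25, rate=50.0)
        a = imu_from_trajectory(traj, noise=ImuNoiseModel(seed=42), **kwargs)
        b = imu_from_trajectory(traj, noise=ImuNoiseModel(seed=42), **kwargs)
        assert np.array_equal(a.specific_force, b.specific_force)
        assert np.array_equal(a.angular_rate, b.angular_rate)
        assert np.array_equal(a.times, b.times)

    def test_different_seed_differs(self):
        traj = simulate_gait(GaitConfig(speed=3.0, duration=5.0))
        a = imu_from_trajectory(traj, "thigh", 0.25, 50.0, ImuNoiseModel(seed=1))
        b = imu_from_trajectory(traj, "thigh", 0.25, 50.0, ImuNoiseModel(seed=2))
        assert not np.array_equal(a.specific_force, b.specific_force)

    def test_unknown_segment(self, noiseless):
        traj = constant_rate_trajectory(0.0)
        with pytest.raises(ValueError, match="unknown segment"):
            imu_from_trajectory(traj, "nope", 0.0, 50.0, noiseless)

    def test_start_skew_delays_first_sample(self, noiseless):
        traj = constant_rate_trajectory(0.0, duration=5.0)
        stream = imu_from_trajectory(traj, "seg", 0.0, 50.0, noiseless, start_skew=0.37)
        assert stream.times[0] == pytest.approx(0.37)


class TestReferenceAngle:
    def test_zero_pendulum_gives_zero_series(self):
        traj = simulate_pendulum(PendulumConfig(initial_angle=0.0, duration=2.0))
        series = reference_angle(traj, 220.0)
        assert np.allclose(series.angles, 0.0)

    def test_deterministic_resampling_across_rates(self):
        traj = simulate_gait(GaitConfig(speed=3.0, duration=4.0))
        s220 = reference_angle(traj, 220.0)
        s440 = reference_angle(traj, 440.0)
        # every 220 Hz timestamp also appears on the 440 Hz grid
        common = np.intersect1d(np.round(s220.times, 9), np.round(s440.times, 9))
        assert len(common) > 800
        v220 = s220.angles[np.isin(np.round(s220.times, 9), common)]
        v440 = s440.angles[np.isin(np.round(s440.times, 9), common)]
        assert np.array_equal(v220, v440)

    def test_endpoints_preserved(self):
        traj = simulate_pendulum(PendulumConfig(duration=2.0))
        series = reference_angle(traj, 10000.0)  # denser than the solver grid
        assert series.times[0] == traj.times[0]
        assert series.times[-1] == traj.times[-1]
        assert series.angles[0] == traj.reference_angles()[0]
        assert series.angles[-1] == traj.reference_angles()[-1]

    def test_invalid_rate(self):
        traj = simulate_pendulum(PendulumConfig(duration=1.0))
        with pytest.raises(ValueError):
            reference_angle(traj, 0.0)


class TestPreroll:
    def test_preroll_is_stationary_then_continuous(self):
        traj = simulate_pendulum(PendulumConfig(initial_angle=20.0 * DEG, duration=2.0))
        pre = with_stationary_preroll(traj, 3.0)
        seg = pre.segments["pendulum"]
        head = pre.times < 3.0 - 1e-9
        assert np.allclose(seg.angle[head], 20.0 * DEG)
        assert np.allclose(seg.rate[head], 0.0)
        assert pre.duration == pytest.approx(traj.duration + 3.0, abs=2e-3)
        assert np.all(np.diff(pre.times) > 0)
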