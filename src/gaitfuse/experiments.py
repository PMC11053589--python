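"""End-to-end verification experiments: pendulum and treadmill gait.

Each experiment simulates ground truth, synthesizes noisy wearable IMU
streams (with a stationary pre-roll for self-calibration), runs the
calibration + gravity-observer pipeline on each sensor, forms the angle
of interest as the difference of the two inclinations, and scores it
against the high-rate reference with the alignment/resampling/statistics
chain. Results are written as JSON reports plus a reproducibility
manifest when an output directory is given.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gaitfuse import __version__
from gaitfuse.compare import AgreementStats, verify
from gaitfuse.fusion import GyroBias, ObserverParams, calibrate_gyro_bias, run_observer
from gaitfuse.joint import knee_angle
from gaitfuse.series import AngleSeries
from gaitfuse.synthetic import (
    GaitConfig,
    ImuNoiseModel,
    PendulumConfig,
    imu_from_trajectory,
    reference_angle,
    simulate_gait,
    simulate_pendulum,
    with_stationary_preroll,
)

__all__ = [
    "PendulumExperimentConfig",
    "GaitExperimentConfig",
    "run_pendulum_experiment",
    "run_gait_experiment",
]

logger = logging.getLogger(__name__)

_SETTLE_MARGIN = 1.0  # s after motion onset excluded from scoring


def _noise_for(noise: ImuNoiseModel, seed: int) -> ImuNoiseModel:
    return dataclasses.replace(noise, seed=seed)


def _config_dict(obj) -> dict:
    def clean(v):
        if dataclasses.is_dataclass(v):
            return _config_dict(v)
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, (tuple, list)):
            return [clean(x) for x in v]
        if isinstance(v, Path):
            return str(v)
        return v

    return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}


def _write_manifest(out_dir: Path, config, extras: dict) -> None:
    manifest = {"version": __version__, "config": _config_dict(config), **extras}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


@dataclass(frozen=True)
class PendulumExperimentConfig:
    pendulum: PendulumConfig = field(default_factory=PendulumConfig)
    noise: ImuNoiseModel = field(default_factory=ImuNoiseModel)
    observer: ObserverParams = field(default_factory=ObserverParams)
    wearable_rate: float = 50.0
    reference_rate: float = 220.0
    preroll: float = 5.0
    calibration_window: float = 4.0
    max_lag: float = 2.0
    mount_radius: float | None = None  # None -> pendulum length
    seed: int = 1
    output_dir: Path | None = None


@dataclass(frozen=True)
class GaitExperimentConfig:
    speeds: tuple = (3.0, 6.0, 9.0, 12.0)
    duration: float = 60.0
    noise: ImuNoiseModel = field(default_factory=ImuNoiseModel)
    observer: ObserverParams = field(default_factory=ObserverParams)
    wearable_rate: float = 50.0
    reference_rate: float = 220.0
    preroll: float = 5.0
    calibration_window: float = 4.0
    max_lag: float = 2.0
    thigh_mount_radius: float = 0.25
    shank_mount_radius: float = 0.22
    seed: int = 1
    output_dir: Path | None = None

    def __post_init__(self):
        if any(s <= 0 for s in self.speeds):
            raise ValueError("speeds must be positive")
        if self.duration < 60.0:
            logger.warning("duration %.1f s is below the 60 s protocol default", self.duration)


def _fuse_pair(
    stream_a,
    stream_b,
    observer: ObserverParams,
    calibration_window: float,
) -> tuple[AngleSeries, AngleSeries]:
    bias_a = calibrate_gyro_bias(stream_a, calibration_window)
    bias_b = calibrate_gyro_bias(stream_b, calibration_window)
    return (
        run_observer(stream_a, observer, bias_a),
        run_observer(stream_b, observer, bias_b),
    )


def run_pendulum_experiment(config: PendulumExperimentConfig) -> AgreementStats:
    """Pendulum verification: swinging vs fixed sensor against ground truth.

    The fixed sensor defines the vertical; the measured angle is the
    difference of the two inclinations. Scoring starts after the
    stationary pre-roll plus a settling margin.
    """
    traj = with_stationary_preroll(simulate_pendulum(config.pendulum), config.preroll)
    mount = config.mount_radius if config.mount_radius is not None else config.pendulum.length

    swing = imu_from_trajectory(
        traj, "pendulum", mount, config.wearable_rate,
        _noise_for(config.noise, config.seed), sensor_id="swing",
    )
    fixed = imu_from_trajectory(
        traj, "fixed", 0.0, config.wearable_rate,
        _noise_for(config.noise, config.seed + 7919), sensor_id="fixed",
    )

    inc_swing, inc_fixed = _fuse_pair(swing, fixed, config.observer, config.calibration_window)
    est = knee_angle(inc_swing, inc_fixed)  # swing minus fixed = pendulum angle
    ref = reference_angle(traj, config.reference_rate)

    t_start = config.preroll + _SETTLE_MARGIN
    stats = verify(est.crop(t_min=t_start), ref.crop(t_min=t_start), config.max_lag)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        swing.to_csv(out / "swing_imu.csv")
        fixed.to_csv(out / "fixed_imu.csv")
        est.to_csv(out / "estimated_angle.csv")
        ref.to_csv(out / "reference_angle.csv")
        stats.to_json(out / "pendulum_stats.json")
        _write_manifest(out, config, {"experiment": "pendulum"})
    return stats


def run_gait_experiment(config: GaitExperimentConfig) -> dict:
    """Treadmill verification: per-speed knee-angle agreement statistics.

    For each speed: simulate gait, generate thigh and shank streams,
    calibrate and fuse each, form the knee angle, and verify against the
    reference-rate ground truth. Returns ``{speed: AgreementStats}``.
    """
    results: dict[float, AgreementStats] = {}
    for k, speed in enumerate(config.speeds):
        gait = GaitConfig(speed=speed, duration=config.duration, seed=config.seed)
        traj = with_stationary_preroll(simulate_gait(gait), config.preroll)

        thigh = imu_from_trajectory(
            traj, "thigh", config.thigh_mount_radius, config.wearable_rate,
            _noise_for(config.noise, config.seed + 1000 * k), sensor_id="thigh",
        )
        shank = imu_from_trajectory(
            traj, "shank", config.shank_mount_radius, config.wearable_rate,
            _noise_for(config.noise, config.seed + 1000 * k + 7919), sensor_id="shank",
        )

        inc_thigh, inc_shank = _fuse_pair(thigh, shank, config.observer, config.calibration_window)
        est = knee_angle(inc_thigh, inc_shank)
        ref = reference_angle(traj, config.reference_rate)

        t_start = config.preroll + _SETTLE_MARGIN
        stats = verify(est.crop(t_min=t_start), ref.crop(t_min=t_start), config.max_lag)
        results[speed] = stats

        if config.output_dir is not None:
            out = Path(config.output_dir) / f"gait_{speed:g}kmh"
            out.mkdir(parents=True, exist_ok=True)
            thigh.to_csv(out / "thigh_imu.csv")
            shank.to_csv(out / "shank_imu.csv")
            est.to_csv(out / "knee_angle.csv")
            ref.to_csv(out / "reference_knee_angle.csv")
            stats.to_json(out / "gait_stats.json")

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report = {f"{speed:g}": stats.to_dict() for speed, stats in results.items()}
        (out / "gait_report.json").write_text(json.dumps(report, indent=2))
        _write_manifest(out, config, {"experiment": "gait"})
    return results
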