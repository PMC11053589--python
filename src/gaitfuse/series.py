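"""Core timestamped data containers and their CSV representations.

Angle series are stored in radians; IMU streams carry specific force in
m/s^2 and angular rate in rad/s. On-disk formats are plain CSV with a
header (``time_s, angle_rad`` and ``time_s, ax, ay, az, gx, gy, gz``)
plus an optional JSON metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AngleSeries", "ImuStream"]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class AngleSeries:
    """A timestamped scalar angle series (inclination or joint angle).

    Attributes
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing.
    angles : ndarray
        Angles in radians.
    name : str
        Identifier (sensor id or derived-quantity name).
    """

    times: np.ndarray
    angles: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.times = _as_1d(self.times, "times")
        self.angles = _as_1d(self.angles, "angles")
        if self.times.shape != self.angles.shape:
            raise ValueError("times and angles must have the same length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def shifted(self, offset: float) -> "AngleSeries":
        """Return a copy with ``offset`` added to every timestamp."""
        return AngleSeries(self.times + offset, self.angles.copy(), self.name)

    def crop(self, t_min: float = -np.inf, t_max: float = np.inf) -> "AngleSeries":
        """Return the sub-series with ``t_min <= t <= t_max``."""
        m = (self.times >= t_min) & (self.times <= t_max)
        return AngleSeries(self.times[m], self.angles[m], self.name)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "angle_rad": self.angles}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "") -> "AngleSeries":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["angle_rad"].to_numpy(), name or Path(path).stem)


@dataclass
class ImuStream:
    """Timestamped 6-axis samples from one sensor.

    ``specific_force`` and ``angular_rate`` are ``(n, 3)`` arrays in the
    sensor frame (m/s^2 and rad/s).
    """

    sensor_id: str
    times: np.ndarray
    specific_force: np.ndarray
    angular_rate: np.ndarray
    nominal_rate: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = _as_1d(self.times, "times")
        self.specific_force = np.asarray(self.specific_force, dtype=float)
        self.angular_rate = np.asarray(self.angular_rate, dtype=float)
        n = len(self.times)
        if self.specific_force.shape != (n, 3):
            raise ValueError(f"specific_force must have shape ({n}, 3)")
        if self.angular_rate.shape != (n, 3):
            raise ValueError(f"angular_rate must have shape ({n}, 3)")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def window(self, t_min: float, t_max: float) -> "ImuStream":
        """Return the sub-stream with ``t_min <= t <= t_max``."""
        m = (self.times >= t_min) & (self.times <= t_max)
        return ImuStream(
            self.sensor_id,
            self.times[m],
            self.specific_force[m],
            self.angular_rate[m],
            self.nominal_rate,
            dict(self.metadata),
        )

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write samples as CSV; metadata goes to ``<path>.meta.json``."""
        df = pd.DataFrame(
            {
                "time_s": self.times,
                "ax": self.specific_force[:, 0],
                "ay": self.specific_force[:, 1],
                "az": self.specific_force[:, 2],
                "gx": self.angular_rate[:, 0],
                "gy": self.angular_rate[:, 1],
                "gz": self.angular_rate[:, 2],
            }
        )
        df.to_csv(path, index=False)
        if sidecar:
            meta = {
                "sensor_id": self.sensor_id,
                "nominal_rate_hz": self.nominal_rate,
                **self.metadata,
            }
            Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, sensor_id: str | None = None) -> "ImuStream":
        df = pd.read_csv(path)
        meta_path = Path(str(path) + ".meta.json")
        meta: dict = {}
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
        return cls(
            sensor_id or meta.get("sensor_id", Path(path).stem),
            df["time_s"].to_numpy(),
            df[["ax", "ay", "az"]].to_numpy(),
            df[["gx", "gy", "gz"]].to_numpy(),
            float(meta.get("nominal_rate_hz", 0.0)),
            {k: v for k, v in meta.items() if k not in ("sensor_id", "nominal_rate_hz")},
        )
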