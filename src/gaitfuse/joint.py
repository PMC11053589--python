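"""Knee joint angle from two segment inclination series.

One sensor on the thigh, one on the shank, both parallel to the sagittal
plane: the knee flexion angle is the difference of the two inclinations
(flexion positive, 0 at full extension).
"""

from __future__ import annotations

import numpy as np

from gaitfuse.errors import NotStationaryError
from gaitfuse.series import AngleSeries

__all__ = ["knee_angle", "extension_offset_calibration"]


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    wrapped = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def knee_angle(
    thigh: AngleSeries, shank: AngleSeries, master: str = "thigh"
) -> AngleSeries:
    """Knee flexion angle on the master sensor's clock.

    The other series is linearly interpolated onto the master timestamps
    restricted to the temporal overlap of the two series, then
    ``knee = thigh - shank``, wrapped to (-pi, pi].

    Raises
    ------
    ValueError
        If either series has fewer than two samples (cannot interpolate)
        or the time ranges do not overlap.
    """
    if len(thigh) < 2 or len(shank) < 2:
        raise ValueError("both series need at least two samples to interpolate")
    if master not in ("thigh", "shank"):
        raise ValueError("master must be 'thigh' or 'shank'")

    t_lo = max(thigh.times[0], shank.times[0])
    t_hi = min(thigh.times[-1], shank.times[-1])
    if t_lo >= t_hi:
        raise ValueError(
            f"no temporal overlap: [{thigh.times[0]:.3f}, {thigh.times[-1]:.3f}] vs "
            f"[{shank.times[0]:.3f}, {shank.times[-1]:.3f}]"
        )

    base, other = (thigh, shank) if master == "thigh" else (shank, thigh)
    mask = (base.times >= t_lo) & (base.times <= t_hi)
    t = base.times[mask]
    other_interp = np.interp(t, other.times, other.angles)
    if master == "thigh":
        diff = base.angles[mask] - other_interp
    else:
        diff = other_interp - base.angles[mask]
    return AngleSeries(t, _wrap_angle(diff), name="knee")


def extension_offset_calibration(
    series: AngleSeries,
    window: float,
    stillness_sd_threshold: float = np.deg2rad(0.5),
) -> float:
    """Static zeroing offset: mean knee angle over a standing-still window.

    Subtracting the returned value makes quiet standing read 0. The
    window (seconds from series start) must be still: angle standard
    deviation below ``stillness_sd_threshold``.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    mask = series.times <= series.times[0] + window
    values = series.angles[mask]
    if len(values) == 0:
        raise ValueError("window contains no samples")
    sd = float(values.std(ddof=0))
    if sd > stillness_sd_threshold:
        raise NotStationaryError("knee_angle_sd", sd, stillness_sd_threshold)
    return float(values.mean())
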