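"""Verification arithmetic: time alignment, resampling, agreement stats.

The estimate (wearable, low rate) is aligned to the reference (high
rate) by cross-correlation, the reference is interpolated onto the
wearable clock, and pointwise differences are summarized as RMSE, mean,
population standard deviation, and extrema — all reported in degrees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from gaitfuse.errors import AlignmentUnreliableError
from gaitfuse.series import AngleSeries

__all__ = [
    "AgreementStats",
    "estimate_time_offset",
    "resample_onto",
    "agreement_stats",
    "verify",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementStats:
    """Pointwise difference statistics (estimate minus reference), degrees.

    Population convention: ``rmse**2 == mean_diff**2 + std_dev**2``.
    """

    rmse: float
    std_dev: float
    mean_diff: float
    min_diff: float
    max_diff: float
    n: int
    mean_abs_diff: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _difference_stats(diff_deg: np.ndarray) -> AgreementStats:
    return AgreementStats(
        rmse=float(np.sqrt(np.mean(diff_deg**2))),
        std_dev=float(diff_deg.std(ddof=0)),
        mean_diff=float(diff_deg.mean()),
        min_diff=float(diff_deg.min()),
        max_diff=float(diff_deg.max()),
        n=int(diff_deg.size),
        mean_abs_diff=float(np.abs(diff_deg).mean()),
    )


def estimate_time_offset(
    est: AngleSeries,
    ref: AngleSeries,
    max_lag: float,
    min_correlation: float = 0.5,
) -> float:
    """Time offset that aligns ``est`` with ``ref``.

    Both series are resampled internally onto a common uniform grid, and
    the lag maximizing the normalized cross-correlation within
    ``+-max_lag`` is located and refined by parabolic interpolation
    around the peak. Adding the returned offset to the estimate's
    timestamps aligns it with the reference.

    Raises
    ------
    AlignmentUnreliableError
        If the peak normalized correlation is below ``min_correlation``.
    ValueError
        If either series does not span more than ``2 * max_lag``.
    """
    if max_lag <= 0:
        raise ValueError("max_lag must be > 0")
    for s, label in ((est, "est"), (ref, "ref")):
        if len(s) < 2 or s.times[-1] - s.times[0] <= 2.0 * max_lag:
            raise ValueError(f"{label} series must span more than 2*max_lag")

    dt = min(float(np.median(np.diff(est.times))), float(np.median(np.diff(ref.times))))
    est_t0, ref_t0 = est.times[0], ref.times[0]
    est_grid = np.arange(est_t0, est.times[-1], dt)
    ref_grid = np.arange(ref_t0, ref.times[-1], dt)
    x = np.interp(est_grid, est.times, est.angles)
    y = np.interp(ref_grid, ref.times, ref.angles)
    x = x - x.mean()
    y = y - y.mean()

    corr = signal.correlate(y, x, mode="full")
    lags = signal.correlation_lags(len(y), len(x), mode="full")

    # normalize each lag by the energies of the overlapping windows
    cum_x2 = np.concatenate([[0.0], np.cumsum(x**2)])
    cum_y2 = np.concatenate([[0.0], np.cumsum(y**2)])

    def _overlap_energy(cum, lo, hi):
        return cum[hi] - cum[lo]

    norm = np.empty_like(corr)
    for i, lag in enumerate(lags):
        x_lo, x_hi = max(0, -lag), min(len(x), len(y) - lag)
        y_lo, y_hi = max(0, lag), min(len(y), len(x) + lag)
        ex = _overlap_energy(cum_x2, x_lo, x_hi)
        ey = _overlap_energy(cum_y2, y_lo, y_hi)
        norm[i] = np.sqrt(ex * ey) if ex > 0 and ey > 0 else np.inf
    ncc = corr / norm

    grid_offset = ref_t0 - est_t0
    valid = np.abs(lags * dt + grid_offset) <= max_lag
    if not np.any(valid):
        raise ValueError("no lags within max_lag; series too far apart in time")
    ncc_valid = np.where(valid, ncc, -np.inf)
    peak = int(np.argmax(ncc_valid))
    best = float(ncc_valid[peak])
    if best < min_correlation:
        raise AlignmentUnreliableError(best, min_correlation)

    # parabolic refinement around the peak
    lag = float(lags[peak])
    if 0 < peak < len(ncc) - 1 and np.isfinite(ncc[peak - 1]) and np.isfinite(ncc[peak + 1]):
        y0, y1, y2 = ncc[peak - 1], ncc[peak], ncc[peak + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                lag += delta

    return lag * dt + grid_offset


def resample_onto(series: AngleSeries, target_times) -> AngleSeries:
    """Linear interpolation of a series onto new timestamps.

    Target points outside the series' span are dropped (count logged);
    values at shared timestamps are reproduced exactly.
    """
    target = np.asarray(target_times, dtype=float)
    mask = (target >= series.times[0]) & (target <= series.times[-1])
    dropped = int((~mask).sum())
    if dropped:
        logger.warning("resample_onto dropped %d out-of-range target points", dropped)
    kept = target[mask]
    if kept.size == 0:
        raise ValueError("no target times fall within the series span")
    return AngleSeries(kept, np.interp(kept, series.times, series.angles), series.name)


def agreement_stats(est: AngleSeries, ref: AngleSeries) -> AgreementStats:
    """Difference statistics for two series on identical timestamps."""
    if len(est) != len(ref):
        raise ValueError(f"length mismatch: {len(est)} vs {len(ref)}")
    if len(est) == 0:
        raise ValueError("empty series")
    if not np.allclose(est.times, ref.times, rtol=0.0, atol=1e-9):
        raise ValueError("series timestamps differ; resample first")
    diff_deg = np.degrees(est.angles - ref.angles)
    return _difference_stats(diff_deg)


def verify(est: AngleSeries, ref: AngleSeries, max_lag: float = 2.0) -> AgreementStats:
    """Full comparison: align, resample onto the wearable clock, score.

    Estimates the time offset, shifts the estimate, interpolates the
    reference onto the (shifted) estimate timestamps within the overlap,
    and returns agreement statistics.
    """
    offset = estimate_time_offset(est, ref, max_lag)
    shifted = est.shifted(offset)
    mask = (shifted.times >= ref.times[0]) & (shifted.times <= ref.times[-1])
    if not np.any(mask):
        raise ValueError("no overlap between aligned series")
    est_overlap = AngleSeries(shifted.times[mask], shifted.angles[mask], est.name)
    ref_on_est = resample_onto(ref, est_overlap.times)
    return agreement_stats(est_overlap, ref_on_est)
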