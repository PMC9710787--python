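"""Candidate-peak characterization: m/z centroid and extent, apex/valley
profiles in mobility and retention time, and RT gap trimming.

A voxel's candidate peak is located by its intensity-weighted m/z centroid;
its m/z extent is three standard deviations either side, with sigma implied by
the instrument resolution (FWHM = m/z / R, default R = 40,000).  The mobility
and RT extents come from flattening the points onto one axis, smoothing with a
Savitzky-Golay filter, and taking the local maximum nearest the voxel midpoint
with the nearest local minima on either side as the valleys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .model import DegenerateDataError

RESOLUTION = 40000.0
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.35482...
MOBILITY_HALF_WINDOW = 40      # scans: twice the mean mobility peak width
RT_HALF_WINDOW = 13.2          # seconds: twice the mean RT base peak width
SAVGOL_WINDOW = 11
SAVGOL_ORDER = 3
APEX_MIN_FRACTION = 0.05       # local maxima below 5% of series max are noise
RT_MAX_GAP = 1.0               # seconds


@dataclass
class PeakProfile:
    """A 1-D flattened intensity series along mobility (scan) or RT (seconds)."""

    axis: str                    # "mobility" | "rt"
    positions: np.ndarray        # distinct axis coordinates, ascending
    raw_series: np.ndarray       # summed intensity per position
    smoothed_series: np.ndarray
    apex: float
    valley_lo: float
    valley_hi: float
    edge_apex: bool = False      # apex sat on the window edge (low confidence)

    def __post_init__(self) -> None:
        if not (self.valley_lo <= self.apex <= self.valley_hi):
            raise ValueError("apex must lie between its valleys")
        if len(self.smoothed_series) != len(self.raw_series):
            raise ValueError("smoothed series length mismatch")


@dataclass
class PeakBounds3D:
    """The candidate peak's bounds in all three dimensions."""

    mz_centroid: float
    mz_lo: float
    mz_hi: float
    scan_lo: int
    scan_hi: int
    scan_apex: int
    rt_lo: float
    rt_hi: float
    rt_apex: float

    def __post_init__(self) -> None:
        if not (self.mz_lo < self.mz_centroid < self.mz_hi):
            raise ValueError("m/z centroid must lie strictly inside its bounds")
        if self.scan_lo > self.scan_hi or self.rt_lo > self.rt_hi:
            raise ValueError("bounds must be ordered")


def mz_centroid(mz: np.ndarray, intensity: np.ndarray) -> float:
    """Intensity-weighted mean m/z of a point set."""
    mz = np.asarray(mz, float)
    intensity = np.asarray(intensity, float)
    if mz.size == 0:
        raise DegenerateDataError("cannot centroid an empty point set")
    total = intensity.sum()
    if total <= 0:
        raise DegenerateDataError("cannot centroid zero total intensity")
    return float((mz * intensity).sum() / total)


def mz_extent(centroid: float, resolution: float = RESOLUTION) -> tuple[float, float]:
    """3-sigma m/z bounds around a centroid at the given resolving power."""
    if centroid <= 0 or resolution <= 0:
        raise ValueError("centroid and resolution must be positive")
    sigma = (centroid / resolution) / FWHM_TO_SIGMA
    return centroid - 3.0 * sigma, centroid + 3.0 * sigma


def profile_extent(
    positions: np.ndarray,
    intensities: np.ndarray,
    axis: str,
    midpoint: float,
    half_window: float,
    savgol_window: int = SAVGOL_WINDOW,
    savgol_order: int = SAVGOL_ORDER,
    apex_min_fraction: float = APEX_MIN_FRACTION,
) -> PeakProfile:
    """Flatten points onto one axis and find the apex and bounding valleys.

    Points outside ``midpoint +/- half_window`` are ignored; the rest are
    grouped by axis coordinate with intensities summed (conserving total
    intensity), smoothed, and scanned for local maxima above
    ``apex_min_fraction`` of the series maximum.  Among multiple apexes the one
    nearest the midpoint wins (ties to the lower coordinate).  The valleys are
    the nearest interior local minima either side of the apex, or the window
    edges when none exist.  Fewer than 3 distinct positions is a degenerate
    peak and raises.
    """
    if axis not in ("mobility", "rt"):
        raise ValueError("axis must be 'mobility' or 'rt'")
    positions = np.asarray(positions, float)
    intensities = np.asarray(intensities, float)
    keep = np.abs(positions - midpoint) <= half_window
    positions, intensities = positions[keep], intensities[keep]
    uniq, inverse = np.unique(positions, return_inverse=True)
    if len(uniq) < 3:
        raise DegenerateDataError(
            f"only {len(uniq)} distinct {axis} positions in window"
        )
    series = np.bincount(inverse, weights=intensities, minlength=len(uniq))

    win = min(savgol_window, len(series) if len(series) % 2 else len(series) - 1)
    if win > savgol_order:
        smoothed = savgol_filter(series, win, savgol_order)
    else:
        smoothed = series.copy()

    floor = apex_min_fraction * smoothed.max()
    maxima, _ = find_peaks(smoothed, height=floor)
    edge_apex = False
    if len(maxima) == 0:
        apex_i = int(np.argmax(smoothed))           # apex on the window edge
        edge_apex = apex_i in (0, len(smoothed) - 1)
    else:
        dist = np.abs(uniq[maxima] - midpoint)
        apex_i = int(maxima[np.argmin(dist)])       # argmin ties -> lower coord

    minima, _ = find_peaks(-smoothed)
    left = minima[minima < apex_i]
    right = minima[minima > apex_i]
    lo_i = int(left[-1]) if len(left) else 0
    hi_i = int(right[0]) if len(right) else len(uniq) - 1

    return PeakProfile(
        axis=axis,
        positions=uniq,
        raw_series=series,
        smoothed_series=smoothed,
        apex=float(uniq[apex_i]),
        valley_lo=float(uniq[lo_i]),
        valley_hi=float(uniq[hi_i]),
        edge_apex=edge_apex,
    )


def trim_rt_gaps(
    rts: np.ndarray, profile: PeakProfile, max_gap: float = RT_MAX_GAP
) -> np.ndarray:
    """Mask of points connected to the RT apex without a gap above `max_gap`.

    Frames are walked outward from the frame nearest the apex; the chain stops
    at the first pair of consecutive retained frames more than `max_gap` apart,
    dropping superfluous leading and trailing edges.
    """
    rts = np.asarray(rts, float)
    frames = np.unique(rts)
    if len(frames) == 0:
        return np.zeros(0, dtype=bool)
    anchor = int(np.argmin(np.abs(frames - profile.apex)))
    lo = anchor
    while lo > 0 and frames[lo] - frames[lo - 1] <= max_gap:
        lo -= 1
    hi = anchor
    while hi < len(frames) - 1 and frames[hi + 1] - frames[hi] <= max_gap:
        hi += 1
    return (rts >= frames[lo]) & (rts <= frames[hi])
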