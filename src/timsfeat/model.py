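"""Core domain types shared across the detection workflow.

The detector consumes a sparse 4-D ion point cloud: one row per detector
reading with a frame id (one full mobility sweep), its retention time in
seconds, a mobility scan index with its 1/K0 value, an m/z in Thomson and an
intensity in counts.  Retention time is always seconds, scan indices are
0-based ascending, and all m/z bin edges downstream are half-open ``[lo, hi)``.

Mobility computations are carried out on the scan index; the 1/K0 value is
carried through so detected features can report an apex mobility and be
matched across runs in instrument units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

#: Column order of the native tabular point-cloud format.
POINT_COLUMNS = ["frame_id", "rt", "scan", "inv_k0", "mz", "intensity"]


class SchemaError(ValueError):
    """A tabular input is missing a required column."""


class ParseError(ValueError):
    """A tabular input contains a malformed (non-numeric or invalid) cell."""


class DegenerateDataError(ValueError):
    """An operation received data too sparse or empty to be meaningful."""


class ConfigError(ValueError):
    """A run configuration value is missing or invalid."""


@dataclass(frozen=True)
class RawPoint:
    """A single detector reading.

    Bulk data lives in :class:`PointCloud` as a DataFrame; this type documents
    the per-row contract and is used at the edges (validation, tests).
    """

    frame_id: int
    rt: float          # seconds
    scan: int          # mobility scan index, 0-based
    inv_k0: float      # reduced ion mobility 1/K0
    mz: float          # Thomson
    intensity: float   # counts, >= 0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.rt < 0:
            raise ValueError("rt must be non-negative")
        if self.scan < 0:
            raise ValueError("scan must be non-negative")


class PointCloud:
    """An immutable, m/z-sorted view of raw MS1 readings.

    Parameters
    ----------
    df
        DataFrame with columns ``frame_id, rt, scan, inv_k0, mz, intensity``.
        Rows may be in any order; they are sorted by m/z internally so that
        m/z range queries are O(log n) slices.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in POINT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"point cloud missing column(s): {', '.join(missing)}")
        df = df.loc[:, POINT_COLUMNS].sort_values(
            ["mz", "rt", "scan"], kind="mergesort"
        )
        df = df.reset_index(drop=True)
        self.df = df
        self.frame_id = df["frame_id"].to_numpy(np.int64)
        self.rt = df["rt"].to_numpy(float)
        self.scan = df["scan"].to_numpy(np.int64)
        self.inv_k0 = df["inv_k0"].to_numpy(float)
        self.mz = df["mz"].to_numpy(float)
        self.intensity = df["intensity"].to_numpy(float)
        self._validate()

    def _validate(self) -> None:
        if len(self.df) == 0:
            return
        if (self.intensity < 0).any():
            raise ValueError("point cloud contains negative intensities")
        if (self.mz <= 0).any():
            raise ValueError("point cloud contains non-positive m/z")
        frame_rt = self.frame_rt()
        rts = np.array([frame_rt[f] for f in sorted(frame_rt)])
        if len(rts) > 1 and not (np.diff(rts) > 0).all():
            raise ValueError("frame_id -> rt mapping must be strictly increasing")

    def __len__(self) -> int:
        return len(self.df)

    def frame_rt(self) -> dict[int, float]:
        """Mapping frame_id -> retention time (seconds)."""
        return dict(
            self.df.groupby("frame_id", sort=True)["rt"].first()
        )

    def slice_mz(self, mz_lo: float, mz_hi: float) -> np.ndarray:
        """Indices of points with ``mz_lo <= mz <= mz_hi`` (inclusive)."""
        i0 = np.searchsorted(self.mz, mz_lo, side="left")
        i1 = np.searchsorted(self.mz, mz_hi, side="right")
        return np.arange(i0, i1)

    def region(
        self,
        mz_lo: float,
        mz_hi: float,
        scan_lo: int,
        scan_hi: int,
        rt_lo: float,
        rt_hi: float,
    ) -> np.ndarray:
        """Indices of points inside the closed 3-D box."""
        idx = self.slice_mz(mz_lo, mz_hi)
        if len(idx) == 0:
            return idx
        m = (
            (self.scan[idx] >= scan_lo)
            & (self.scan[idx] <= scan_hi)
            & (self.rt[idx] >= rt_lo)
            & (self.rt[idx] <= rt_hi)
        )
        return idx[m]

    def inv_k0_at_scan(self, scan: float) -> float:
        """1/K0 at a scan index, interpolated from the cloud's own readings."""
        scans = self.scan.astype(float)
        order = np.argsort(scans, kind="mergesort")
        s, k = scans[order], self.inv_k0[order]
        uniq, first = np.unique(s, return_index=True)
        if len(uniq) == 0:
            raise DegenerateDataError("empty cloud has no mobility calibration")
        if len(uniq) == 1:
            return float(k[first][0])
        return float(np.interp(scan, uniq, k[first]))


@dataclass
class Feature:
    """A detected precursor feature and its quality attributes.

    ``identifiability_score`` stays ``None`` until a classifier has scored the
    feature.  ``point_indices`` references the source cloud rows making up the
    feature's isotopic peaks (used for voxel retirement; not serialized).
    """

    mono_mz: float
    charge: int
    intensity: float
    rt_apex: float
    rt_lo: float
    rt_hi: float
    scan_apex: int
    scan_lo: int
    scan_hi: int
    num_isotopes: int
    deconvolution_score: float
    coelution_coefficient: float
    mobility_coefficient: float
    identifiability_score: float | None = None
    inv_k0_apex: float | None = None
    envelope: "object | None" = None
    point_indices: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (self.rt_lo <= self.rt_apex <= self.rt_hi):
            raise ValueError("rt apex must lie within its bounds")
        if not (self.scan_lo <= self.scan_apex <= self.scan_hi):
            raise ValueError("scan apex must lie within its bounds")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.num_isotopes < 1:
            raise ValueError("num_isotopes must be >= 1")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")

    @property
    def classifier_inputs(self) -> tuple[float, float, float, float]:
        """The four attributes the identifiability classifier consumes."""
        return (
            self.deconvolution_score,
            self.coelution_coefficient,
            self.mobility_coefficient,
            float(self.num_isotopes),
        )


def feature_fields() -> list[str]:
    return [f.name for f in fields(Feature)]
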