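"""Voxel work queue: fixed-size 3-D bins ranked by mean point intensity.

The raw data space is divided into voxels of 0.1 Th in m/z, 10 scans in
mobility and 5 seconds in retention time — sized to capture a single isotopic
peak in m/z while sampling broadly enough in the other two dimensions to find
its apex.  Voxels are served in descending order of mean constituent-point
intensity until none above the configured minimum remain; voxels consumed by
an accepted feature's isotopic peaks are retired so the same ion is not used
to seed another feature.

The grid is anchored at coordinate 0 on every axis, with half-open bins
``[k*w, (k+1)*w)``; ranking ties break on the lexicographic voxel key so runs
are reproducible.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .model import PointCloud

MZ_WIDTH = 0.1          # Th
SCAN_SPAN = 10          # scans
RT_SPAN = 5.0           # seconds
BAND_WIDTH = 10.0       # Th, the unit of worker parallelism
RETIRE_FRACTION = 0.80  # strictly-greater-than retirement threshold


class VoxelState(enum.Enum):
    PENDING = "pending"
    PROCESSED = "processed"
    RETIRED = "retired"


@dataclass
class Voxel:
    key: tuple[int, int, int]  # (mz_bin, scan_bin, rt_bin)
    point_idx: np.ndarray      # indices into the source PointCloud
    total_intensity: float
    mean_intensity: float
    state: VoxelState = VoxelState.PENDING

    @property
    def mz_lo(self) -> float:
        return self.key[0] * MZ_WIDTH

    @property
    def mz_hi(self) -> float:
        return (self.key[0] + 1) * MZ_WIDTH

    @property
    def scan_lo(self) -> int:
        return self.key[1] * SCAN_SPAN

    @property
    def scan_hi(self) -> int:  # inclusive upper scan of the half-open bin
        return (self.key[1] + 1) * SCAN_SPAN - 1

    @property
    def rt_lo(self) -> float:
        return self.key[2] * RT_SPAN

    @property
    def rt_hi(self) -> float:
        return (self.key[2] + 1) * RT_SPAN

    @property
    def scan_mid(self) -> float:
        return self.key[1] * SCAN_SPAN + (SCAN_SPAN - 1) / 2.0

    @property
    def rt_mid(self) -> float:
        return (self.key[2] + 0.5) * RT_SPAN


@dataclass
class VoxelIndex:
    """All non-empty voxels of a cloud plus the descending-mean work queue."""

    voxels: dict[tuple[int, int, int], Voxel]
    ranking: list[tuple[int, int, int]]
    min_voxel_intensity: float
    point_keys: np.ndarray = field(repr=False)  # (n_points, 3) voxel key per point
    point_intensity: np.ndarray = field(repr=False)
    _cursor: int = 0

    def next_voxel(self) -> Voxel | None:
        """Highest-ranked pending voxel above the stopping threshold, marked
        processed; None when the queue is exhausted."""
        while self._cursor < len(self.ranking):
            v = self.voxels[self.ranking[self._cursor]]
            self._cursor += 1
            if v.mean_intensity < self.min_voxel_intensity:
                return None  # ranking is sorted; nothing further qualifies
            if v.state is VoxelState.PENDING:
                v.state = VoxelState.PROCESSED
                return v
        return None

    def retire_voxels(self, feature_point_idx: np.ndarray) -> list[tuple[int, int, int]]:
        """Retire every voxel whose intensity is more than 80% made up of the
        given feature points.  Exactly 80% is kept.  Idempotent and monotone:
        adding more feature points can only retire more voxels."""
        if len(feature_point_idx) == 0:
            return []
        keys = self.point_keys[feature_point_idx]
        inten = self.point_intensity[feature_point_idx]
        uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
        sums = np.bincount(inverse, weights=inten, minlength=len(uniq))
        retired = []
        for (mzb, scb, rtb), s in zip(uniq, sums):
            key = (int(mzb), int(scb), int(rtb))
            v = self.voxels.get(key)
            if v is None or v.state is VoxelState.RETIRED:
                continue
            if v.total_intensity > 0 and s / v.total_intensity > RETIRE_FRACTION:
                v.state = VoxelState.RETIRED
                retired.append(key)
        return retired


def build_voxel_index(cloud: PointCloud, min_voxel_intensity: float) -> VoxelIndex:
    """Assign every point to exactly one voxel and rank the voxels.

    Voxels below the stopping threshold stay in the index (their points remain
    readable by neighbourhood queries) but the queue never yields them.
    """
    n = len(cloud)
    if n == 0:
        empty = np.empty((0, 3), dtype=np.int64)
        return VoxelIndex({}, [], min_voxel_intensity, empty, np.empty(0))
    mzb = np.floor(cloud.mz / MZ_WIDTH).astype(np.int64)
    scb = cloud.scan // SCAN_SPAN
    rtb = np.floor(cloud.rt / RT_SPAN).astype(np.int64)
    keys = np.column_stack([mzb, scb, rtb])
    uniq, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    totals = np.bincount(inverse, weights=cloud.intensity, minlength=len(uniq))
    order = np.argsort(inverse, kind="stable")
    splits = np.cumsum(counts)[:-1]
    groups = np.split(order, splits)
    voxels: dict[tuple[int, int, int], Voxel] = {}
    for (a, b, c), idx, tot, cnt in zip(uniq, groups, totals, counts):
        key = (int(a), int(b), int(c))
        voxels[key] = Voxel(
            key=key,
            point_idx=idx,
            total_intensity=float(tot),
            mean_intensity=float(tot / cnt),
        )
    ranking = sorted(voxels, key=lambda k: (-voxels[k].mean_intensity, k))
    return VoxelIndex(voxels, ranking, min_voxel_intensity, keys, cloud.intensity)


def partition_bands(
    index: VoxelIndex, band_width: float = BAND_WIDTH
) -> dict[int, list[tuple[int, int, int]]]:
    """Group queued voxel keys into disjoint m/z bands of `band_width` Th.

    Band ``b`` covers ``[b*band_width, (b+1)*band_width)``; within each band
    the keys keep the global descending-mean order, so a worker draining one
    band sees the same priority it would globally.
    """
    if band_width <= 0:
        raise ValueError("band_width must be positive")
    bands: dict[int, list[tuple[int, int, int]]] = {}
    for key in index.ranking:
        band = int(math.floor(index.voxels[key].mz_lo / band_width))
        bands.setdefault(band, []).append(key)
    return bands


def band_subindex(
    index: VoxelIndex, keys: list[tuple[int, int, int]]
) -> VoxelIndex:
    """A queue over one band's voxels, sharing point data with the parent.

    Retirement through a band sub-index only touches that band's voxels:
    bands schedule voxels, they do not clip data, and cross-band duplicate
    detections are reconciled by the post-pass de-duplication.
    """
    sub = {k: index.voxels[k] for k in keys}
    return VoxelIndex(
        voxels=sub,
        ranking=list(keys),
        min_voxel_intensity=index.min_voxel_intensity,
        point_keys=index.point_keys,
        point_intensity=index.point_intensity,
    )
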