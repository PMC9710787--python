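"""End-to-end orchestration of the detection workflow.

For every queued voxel (most intense first): centroid its peak in m/z, bound
the peak in mobility and retention time from smoothed 1-D profiles, widen the
m/z range to cover the isotopic series, simplify the region to a 2-D spectrum
by intensity descent, deconvolve charge and monoisotopic m/z, accept the best
candidate whose mono or base peak matches the seeding centroid, measure its
intensity and isotope-alignment coefficients, and retire the voxels its
isotopic peaks consumed.  Workers process disjoint 10-Th m/z bands; a closing
classification/de-duplication pass produces the final feature table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from . import classify as _cls
from . import envelope as _env
from . import profile as _prof
from . import voxels as _vox
from .classify import IdentifiabilityClassifier, classify_and_filter, deduplicate
from .model import ConfigError, DegenerateDataError, Feature, PointCloud
from .voxels import VoxelIndex, band_subindex, build_voxel_index, partition_bands

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IsolationWindow:
    """A DDA isolation region in m/z, mobility and retention time."""

    mz_lo: float
    mz_hi: float
    scan_lo: int
    scan_hi: int
    rt_lo: float
    rt_hi: float

    def __post_init__(self) -> None:
        if self.mz_lo > self.mz_hi or self.scan_lo > self.scan_hi \
                or self.rt_lo > self.rt_hi:
            raise ValueError("window bounds must be ordered")

    def contains(self, f: Feature) -> bool:
        return (
            self.mz_lo <= f.mono_mz <= self.mz_hi
            and self.scan_lo <= f.scan_apex <= self.scan_hi
            and self.rt_lo <= f.rt_apex <= self.rt_hi
        )


@dataclass
class RunConfig:
    """All detection knobs.  ``min_voxel_intensity`` has no universal default:
    it is the depth/time trade-off and must be chosen per dataset."""

    min_voxel_intensity: float
    resolution: float = _prof.RESOLUTION
    mobility_half_window: float = _prof.MOBILITY_HALF_WINDOW
    rt_half_window: float = _prof.RT_HALF_WINDOW
    savgol_window: int = _prof.SAVGOL_WINDOW
    savgol_order: int = _prof.SAVGOL_ORDER
    rt_max_gap: float = _prof.RT_MAX_GAP
    mz_lower_extension: float = _env.MZ_LOWER_EXTENSION
    mz_upper_extension: float = _env.MZ_UPPER_EXTENSION
    charge_min: int = _env.CHARGE_MIN
    charge_max: int = _env.CHARGE_MAX
    min_isotopes: int = _env.MIN_ISOTOPES
    score_threshold: float = _env.SCORE_THRESHOLD
    match_ppm: float = _env.MATCH_PPM
    validate_ppm: float = _env.VALIDATE_PPM
    band_width: float = _vox.BAND_WIDTH
    dedup_ppm: float = _cls.DEDUP_PPM
    dedup_scans: int = _cls.DEDUP_SCANS
    dedup_rt: float = _cls.DEDUP_RT
    identifiability_threshold: float = _cls.IDENTIFIABILITY_THRESHOLD
    classifier_path: str | None = None
    worker_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_voxel_intensity < 0:
            raise ConfigError("min_voxel_intensity must be non-negative")
        if self.charge_min < 1 or self.charge_max < self.charge_min:
            raise ConfigError("invalid charge range")
        if self.worker_count < 1:
            raise ConfigError("worker_count must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a key=value text config; keyword overrides win."""
        values: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key=value")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in types:
                    raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**{k: _coerce(cls, k, v) for k, v in values.items()})


def _coerce(cls, key, val):
    if not isinstance(val, str):
        return val
    int_keys = {"savgol_window", "savgol_order", "charge_min", "charge_max",
                "min_isotopes", "dedup_scans", "worker_count", "seed"}
    if key == "classifier_path":
        return val
    try:
        return int(val) if key in int_keys else float(val)
    except ValueError as exc:
        raise ConfigError(f"config key {key}={val!r}: {exc}") from exc


def process_voxel(cloud: PointCloud, voxel: _vox.Voxel, cfg: RunConfig,
                  ) -> Feature | None:
    """Run the per-voxel detection chain; None when no valid feature forms."""
    try:
        pts = voxel.point_idx
        centroid = _prof.mz_centroid(cloud.mz[pts], cloud.intensity[pts])
        pk_lo, pk_hi = _prof.mz_extent(centroid, cfg.resolution)

        # mobility extent from the voxel's own RT slab
        m_idx = cloud.region(
            pk_lo, pk_hi,
            int(np.floor(voxel.scan_mid - cfg.mobility_half_window)),
            int(np.ceil(voxel.scan_mid + cfg.mobility_half_window)),
            voxel.rt_lo, voxel.rt_hi,
        )
        mob = _prof.profile_extent(
            cloud.scan[m_idx], cloud.intensity[m_idx], "mobility",
            voxel.scan_mid, cfg.mobility_half_window,
            cfg.savgol_window, cfg.savgol_order,
        )
        scan_lo, scan_hi = int(mob.valley_lo), int(mob.valley_hi)
        scan_apex = int(round(mob.apex))

        # RT extent within the mobility extent
        r_idx = cloud.region(
            pk_lo, pk_hi, scan_lo, scan_hi,
            voxel.rt_mid - cfg.rt_half_window,
            voxel.rt_mid + cfg.rt_half_window,
        )
        rtp = _prof.profile_extent(
            cloud.rt[r_idx], cloud.intensity[r_idx], "rt",
            voxel.rt_mid, cfg.rt_half_window,
            cfg.savgol_window, cfg.savgol_order,
        )
        in_valleys = r_idx[(cloud.rt[r_idx] >= rtp.valley_lo)
                           & (cloud.rt[r_idx] <= rtp.valley_hi)]
        keep = _prof.trim_rt_gaps(cloud.rt[in_valleys], rtp, cfg.rt_max_gap)
        retained_rt = cloud.rt[in_valleys][keep]
        if len(retained_rt) == 0:
            return None
        rt_lo, rt_hi = float(retained_rt.min()), float(retained_rt.max())
        rt_apex = float(np.clip(rtp.apex, rt_lo, rt_hi))

        bounds = _prof.PeakBounds3D(
            mz_centroid=centroid, mz_lo=pk_lo, mz_hi=pk_hi,
            scan_lo=scan_lo, scan_hi=scan_hi, scan_apex=scan_apex,
            rt_lo=rt_lo, rt_hi=rt_hi, rt_apex=rt_apex,
        )
        region = _env.expand_region(bounds, cfg.mz_lower_extension,
                                    cfg.mz_upper_extension)
        g_idx = cloud.region(region.mz_lo, region.mz_hi, scan_lo, scan_hi,
                             rt_lo, rt_hi)
        if len(g_idx) == 0:
            return None
        spectrum = _env.intensity_descent(
            cloud.mz[g_idx], cloud.intensity[g_idx], cfg.resolution
        )
        envelopes = _env.deconvolve(
            spectrum, (cfg.charge_min, cfg.charge_max), cfg.min_isotopes,
            cfg.match_ppm, cfg.score_threshold,
        )
        env = next(
            (e for e in envelopes
             if _env.validate_candidate(e, centroid, cfg.validate_ppm)),
            None,
        )
        if env is None:
            return None

        feat_points = _env.assign_isotope_points(
            env, cloud.mz[g_idx], g_idx, cfg.resolution
        )
        inten = _env.feature_intensity(
            env, cloud.mz[g_idx], cloud.intensity[g_idx], cloud.rt[g_idx],
            rt_apex, resolution=cfg.resolution,
        )
        coel, mobc = _env.alignment_coefficients(
            env, cloud.mz[g_idx], cloud.intensity[g_idx], cloud.rt[g_idx],
            cloud.scan[g_idx], region, cfg.resolution,
        )
        return Feature(
            mono_mz=env.mono_mz,
            charge=env.charge,
            intensity=inten,
            rt_apex=rt_apex, rt_lo=rt_lo, rt_hi=rt_hi,
            scan_apex=int(np.clip(scan_apex, scan_lo, scan_hi)),
            scan_lo=scan_lo, scan_hi=scan_hi,
            num_isotopes=len(env.peaks),
            deconvolution_score=env.score,
            coelution_coefficient=coel,
            mobility_coefficient=mobc,
            inv_k0_apex=cloud.inv_k0_at_scan(scan_apex),
            envelope=env,
            point_indices=feat_points,
        )
    except DegenerateDataError as exc:
        logger.debug("voxel %s skipped: %s", voxel.key, exc)
        return None


def _process_band(cloud: PointCloud, sub: VoxelIndex, cfg: RunConfig,
                  ) -> list[Feature]:
    out: list[Feature] = []
    while (voxel := sub.next_voxel()) is not None:
        feat = process_voxel(cloud, voxel, cfg)
        if feat is not None:
            out.append(feat)
            sub.retire_voxels(feat.point_indices)
    return out


def _chunk_worker(cloud: PointCloud, band_ids: list[int], cfg: RunConfig,
                  ) -> dict[int, list[Feature]]:
    index = build_voxel_index(cloud, cfg.min_voxel_intensity)
    bands = partition_bands(index, cfg.band_width)
    return {
        b: _process_band(cloud, band_subindex(index, bands[b]), cfg)
        for b in band_ids if b in bands
    }


def detect_features(cloud: PointCloud, cfg: RunConfig,
                    classifier: IdentifiabilityClassifier | None = None,
                    ) -> list[Feature]:
    """Detect precursor features in a point cloud.

    Bands are processed independently (each band's retirement only touches its
    own queue), so results are identical for any worker count.  When a trained
    classifier is supplied (directly or via ``cfg.classifier_path``) features
    are scored and filtered at the identifiability threshold; otherwise scores
    stay unset and only de-duplication runs.
    """
    if len(cloud) == 0:
        return []
    index = build_voxel_index(cloud, cfg.min_voxel_intensity)
    bands = partition_bands(index, cfg.band_width)
    band_ids = sorted(bands)
    logger.info("%d voxels in %d bands (queue threshold %g)",
                len(index.voxels), len(band_ids), cfg.min_voxel_intensity)

    if cfg.worker_count <= 1:
        per_band = {
            b: _process_band(cloud, band_subindex(index, bands[b]), cfg)
            for b in band_ids
        }
    else:
        chunks = [band_ids[i::cfg.worker_count] for i in range(cfg.worker_count)]
        results = Parallel(n_jobs=cfg.worker_count)(
            delayed(_chunk_worker)(cloud, chunk, cfg) for chunk in chunks
        )
        per_band = {}
        for r in results:
            per_band.update(r)

    features = [f for b in band_ids for f in per_band.get(b, [])]
    logger.info("%d candidate features before classification", len(features))

    if classifier is None and cfg.classifier_path:
        classifier = IdentifiabilityClassifier.load(cfg.classifier_path)
    if classifier is not None:
        features = classify_and_filter(features, classifier,
                                       cfg.identifiability_threshold)
        logger.info("%d features above identifiability threshold %.2f",
                    len(features), cfg.identifiability_threshold)
    features = deduplicate(features, cfg.dedup_ppm, cfg.dedup_scans,
                           cfg.dedup_rt)
    logger.info("%d features after de-duplication", len(features))
    return features


def filter_by_windows(features: list[Feature],
                      windows: list[IsolationWindow]) -> list[Feature]:
    """Features whose monoisotopic apex lies inside at least one isolation
    window (closed bounds on every axis)."""
    return [f for f in features if any(w.contains(f) for w in windows)]
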