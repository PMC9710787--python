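"""Synthetic timsTOF-style MS1 point clouds with known ground truth.

Planted peptide features follow the characteristic precursor signature: a
series of isotopic peaks spaced ``1.003355 / charge`` Th apart whose relative
heights follow the averagine composition model, each peak Gaussian in m/z,
mobility (scan) and retention time.  Typical geometry follows what is seen on
a timsTOF: envelopes about 2 Th wide in m/z, peaks ~44 scans wide through
mobility and ~6.6 s wide in retention time (base width taken as 4 sigma).

Points are emitted on the discrete frame/scan grid the instrument measures
on: for every grid node inside a feature's footprint the expected intensity
is the product-Gaussian profile, and the emitted count is a Poisson draw from
it, so weak features fray into sparse points the way real low-abundance
peptides do.  Ambient noise is uniform in position with exponentially
distributed intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PointCloud

#: 13C - 12C mass difference in Da; isotope spacing is this over the charge.
ISOTOPE_SPACING = 1.003355
#: Mass of a proton in Da (m/z = (M + z*PROTON) / z).
PROTON_MASS = 1.00727646688

# Averagine: average amino-acid residue composition, per 111.1254 Da.
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254

# Nucleon-offset abundance vectors (index = extra neutrons vs lightest isotope).
_ELEMENT_ABUNDANCE = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
}

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.35482


def _conv_power(dist: np.ndarray, n: int, keep: int) -> np.ndarray:
    """n-fold self-convolution of an abundance vector, truncated to `keep` terms."""
    out = np.zeros(keep)
    out[0] = 1.0
    base = dist[:keep].copy()
    while n:
        if n & 1:
            out = np.convolve(out, base)[:keep]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:keep]
    return out


def averagine_envelope(neutral_mass: float, n_isotopes: int) -> np.ndarray:
    """Predicted relative isotope abundances for a peptide of a given mass.

    The elemental composition is the averagine model scaled to ``neutral_mass``
    (atom counts rounded to integers), and the aggregated isotopic distribution
    is the exact convolution of the per-element isotope abundances.  Returns
    the first ``n_isotopes`` abundances renormalized to sum to 1.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if n_isotopes < 2:
        raise ValueError("n_isotopes must be >= 2")
    scale = neutral_mass / _AVERAGINE_MASS
    keep = n_isotopes + 4  # headroom so truncation does not skew the ratios
    dist = np.ones(keep)
    dist[1:] = 0.0
    for el, per_residue in _AVERAGINE.items():
        count = int(round(per_residue * scale))
        if count <= 0:
            continue
        dist = np.convolve(dist, _conv_power(_ELEMENT_ABUNDANCE[el], count, keep))[:keep]
    frac = dist[:n_isotopes]
    total = frac.sum()
    if total <= 0:
        raise ValueError("degenerate isotopic distribution")
    return frac / total


@dataclass(frozen=True)
class GroundTruthFeature:
    """One planted feature: position, geometry and envelope of a precursor ion."""

    mono_mz: float
    charge: int
    total_intensity: float
    rt_apex: float
    rt_sigma: float
    scan_apex: int
    scan_sigma: float
    mz_sigma: float
    n_isotopes: int
    envelope_fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_isotopes < 2:
            raise ValueError("n_isotopes must be >= 2")
        for name in ("mono_mz", "charge", "total_intensity", "rt_apex",
                     "rt_sigma", "scan_apex", "scan_sigma", "mz_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.envelope_fractions:
            frac = averagine_envelope(
                (self.mono_mz - PROTON_MASS) * self.charge, self.n_isotopes
            )
            object.__setattr__(self, "envelope_fractions", tuple(frac))
        if abs(sum(self.envelope_fractions) - 1.0) > 1e-9:
            raise ValueError("envelope_fractions must sum to 1")

    def isotope_mzs(self) -> np.ndarray:
        return self.mono_mz + ISOTOPE_SPACING / self.charge * np.arange(self.n_isotopes)


@dataclass(frozen=True)
class NoiseSpec:
    """Ambient noise: uniform positions at `density` points per (Th x scan x s),
    exponential intensities with the given mean, optional detector saturation."""

    density: float = 3e-4
    intensity_mean: float = 30.0
    saturation_limit: float | None = None

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")


@dataclass(frozen=True)
class Extent:
    """The simulated acquisition space."""

    mz_lo: float = 400.0
    mz_hi: float = 1000.0
    scan_lo: int = 0
    scan_hi: int = 800
    rt_lo: float = 0.0
    rt_hi: float = 600.0

    def contains(self, t: GroundTruthFeature) -> bool:
        hi_mz = t.isotope_mzs()[-1]
        return (
            self.mz_lo <= t.mono_mz and hi_mz <= self.mz_hi
            and self.scan_lo <= t.scan_apex <= self.scan_hi
            and self.rt_lo <= t.rt_apex <= self.rt_hi
        )


def default_mz_sigma(mz: float, resolution: float = 40000.0) -> float:
    """Peak sigma implied by the instrument resolution (FWHM = m/z / R)."""
    return (mz / resolution) / FWHM_TO_SIGMA


def generate_dataset(
    truths: list[GroundTruthFeature],
    noise: NoiseSpec | None = None,
    extent: Extent | None = None,
    frame_period: float = 0.5,
    seed: int = 0,
    inv_k0_intercept: float = 1.6,
    inv_k0_slope: float = -0.001,
) -> tuple[PointCloud, pd.DataFrame]:
    """Simulate a point cloud with planted features plus ambient noise.

    Returns the cloud and a manifest with one row per planted feature.  The
    same seed always produces a bit-identical cloud and manifest.  The
    scan -> 1/K0 map is affine with a negative slope (lower scan index means
    higher 1/K0), mimicking the instrument's mobility calibration.
    """
    noise = noise if noise is not None else NoiseSpec()
    extent = extent if extent is not None else Extent()
    for i, t in enumerate(truths):
        if not extent.contains(t):
            raise ValueError(f"truth {i} (mono {t.mono_mz:.4f}) outside extent")

    rng = np.random.default_rng(seed)
    n_frames = int(math.floor((extent.rt_hi - extent.rt_lo) / frame_period)) + 1
    frame_rts = extent.rt_lo + frame_period * np.arange(n_frames)
    scans = np.arange(extent.scan_lo, extent.scan_hi + 1)

    cols: dict[str, list[np.ndarray]] = {c: [] for c in
                                         ("frame_id", "rt", "scan", "mz", "intensity")}

    def emit(frame_idx, scan_v, mz_v, inten_v):
        cols["frame_id"].append(frame_idx.astype(np.int64) + 1)
        cols["rt"].append(frame_rts[frame_idx])
        cols["scan"].append(scan_v.astype(np.int64))
        cols["mz"].append(mz_v)
        cols["intensity"].append(inten_v)

    for t in truths:
        f_lo = np.searchsorted(frame_rts, t.rt_apex - 4 * t.rt_sigma)
        f_hi = np.searchsorted(frame_rts, t.rt_apex + 4 * t.rt_sigma, side="right")
        f_idx = np.arange(f_lo, f_hi)
        s_lo = max(extent.scan_lo, int(math.floor(t.scan_apex - 4 * t.scan_sigma)))
        s_hi = min(extent.scan_hi, int(math.ceil(t.scan_apex + 4 * t.scan_sigma)))
        s_idx = np.arange(s_lo, s_hi + 1)
        if len(f_idx) == 0 or len(s_idx) == 0:
            continue
        w_rt = np.exp(-0.5 * ((frame_rts[f_idx] - t.rt_apex) / t.rt_sigma) ** 2)
        w_rt /= w_rt.sum()
        w_scan = np.exp(-0.5 * ((s_idx - t.scan_apex) / t.scan_sigma) ** 2)
        w_scan /= w_scan.sum()
        grid = np.outer(w_rt, w_scan)  # frames x scans, sums to 1
        for iso, (center, fracv) in enumerate(
            zip(t.isotope_mzs(), t.envelope_fractions)
        ):
            expected = t.total_intensity * fracv * grid
            counts = rng.poisson(expected)
            ff, ss = np.nonzero(counts)
            if len(ff) == 0:
                continue
            inten = counts[ff, ss].astype(float)
            mzs = rng.normal(center, t.mz_sigma, size=len(ff))
            emit(f_idx[ff], s_idx[ss], mzs, inten)

    volume = (
        (extent.mz_hi - extent.mz_lo)
        * (extent.scan_hi - extent.scan_lo + 1)
        * (extent.rt_hi - extent.rt_lo)
    )
    n_noise = rng.poisson(noise.density * volume)
    if n_noise > 0:
        f_idx = rng.integers(0, n_frames, size=n_noise)
        scan_v = rng.integers(extent.scan_lo, extent.scan_hi + 1, size=n_noise)
        mz_v = rng.uniform(extent.mz_lo, extent.mz_hi, size=n_noise)
        inten = np.maximum(1.0, np.round(rng.exponential(noise.intensity_mean,
                                                         size=n_noise)))
        emit(f_idx, scan_v, mz_v, inten)

    df = pd.DataFrame({c: np.concatenate(v) if v else np.array([]) for c, v in
                       cols.items()})
    if noise.saturation_limit is not None and len(df):
        df["intensity"] = df["intensity"].clip(upper=noise.saturation_limit)
    df["inv_k0"] = inv_k0_intercept + inv_k0_slope * df.get(
        "scan", pd.Series(dtype=float)
    )
    if len(df) == 0:
        df = pd.DataFrame({c: [] for c in
                           ("frame_id", "rt", "scan", "inv_k0", "mz", "intensity")})

    manifest = pd.DataFrame([asdict(t) for t in truths])
    if len(manifest):
        manifest["envelope_fractions"] = [
            ";".join(f"{x:.6g}" for x in t.envelope_fractions) for t in truths
        ]
        manifest["inv_k0_apex"] = inv_k0_intercept + inv_k0_slope * manifest[
            "scan_apex"]
    return PointCloud(df), manifest


def make_benchmark_truths(
    n: int = 50,
    seed: int = 1,
    extent: Extent | None = None,
    charge_range: tuple[int, int] = (2, 4),
    intensity_range: tuple[float, float] = (2e5, 2e7),
) -> list[GroundTruthFeature]:
    """The standard synthetic benchmark: well-separated features, charges 2-4,
    total intensities log-uniform across a 100-fold range, geometry drawn from
    the typical feature dimensions (scan sigma 11 +/- 3.5, rt sigma 1.65 +/-
    0.6 s, m/z peak width from resolution 40,000).

    Features are rejection-sampled to be pairwise separated by more than the
    dedup/matching tolerances, since overlapping-envelope co-deconvolution is
    outside the detector's contract.
    """
    extent = extent if extent is not None else Extent()
    rng = np.random.default_rng(seed)
    placed: list[GroundTruthFeature] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not place features with required separation")
        charge = int(rng.integers(charge_range[0], charge_range[1] + 1))
        mono = float(rng.uniform(extent.mz_lo + 5, extent.mz_hi - 10))
        scan_apex = int(rng.integers(extent.scan_lo + 60, extent.scan_hi - 60))
        rt_apex = float(rng.uniform(extent.rt_lo + 20, extent.rt_hi - 20))
        ok = True
        for p in placed:
            close_mz = abs(p.mono_mz - mono) < 4.5
            close_scan = abs(p.scan_apex - scan_apex) < 80
            close_rt = abs(p.rt_apex - rt_apex) < 25
            if close_mz and close_scan and close_rt:
                ok = False
                break
        if not ok:
            continue
        rt_sigma = float(np.clip(rng.normal(1.65, 0.6), 0.8, 3.5))
        scan_sigma = float(np.clip(rng.normal(11.0, 3.5), 5.0, 22.0))
        log_lo, log_hi = math.log(intensity_range[0]), math.log(intensity_range[1])
        total = float(math.exp(rng.uniform(log_lo, log_hi)))
        placed.append(
            GroundTruthFeature(
                mono_mz=mono,
                charge=charge,
                total_intensity=total,
                rt_apex=rt_apex,
                rt_sigma=rt_sigma,
                scan_apex=scan_apex,
                scan_sigma=scan_sigma,
                mz_sigma=default_mz_sigma(mono),
                n_isotopes=4,
            )
        )
    return placed


def write_manifest(manifest: pd.DataFrame, path: str | Path,
                   params: dict | None = None) -> None:
    """Write the ground-truth manifest plus a key=value sidecar of parameters."""
    path = Path(path)
    manifest.to_csv(path, index=False)
    if params is not None:
        side = path.with_suffix(path.suffix + ".params")
        with open(side, "w") as fh:
            for k, v in params.items():
                fh.write(f"{k}={v}\n")
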