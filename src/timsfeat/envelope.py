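"""Isotopic-envelope construction: region expansion, intensity descent,
charge/monoisotopic deconvolution, candidate validation, feature intensity and
isotope-alignment coefficients.

After the seeding voxel's peak is bounded in 3-D, the m/z range is widened
(0.6 Th down, 3 Th up) to take in the rest of the isotopic series, the region
is simplified to a 2-D spectrum by intensity descent, and candidate envelopes
are assembled at each charge by matching peaks at the expected 1.003355/z
spacing and comparing their heights with the averagine prediction.  A
candidate only survives if its monoisotopic or base peak matches the seeding
voxel's centroid, which ties every reported feature back to the peak that
seeded it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .model import DegenerateDataError
from .profile import PeakBounds3D, mz_extent, RESOLUTION
from .simulate import ISOTOPE_SPACING, PROTON_MASS, averagine_envelope

MZ_LOWER_EXTENSION = 0.6   # Th below the peak: room for one charge-2 isotope
MZ_UPPER_EXTENSION = 3.0   # Th above: room for ~six charge-2 isotopes
CHARGE_MIN = 1
CHARGE_MAX = 4
MIN_ISOTOPES = 3
MATCH_PPM = 10.0           # isotope-position tolerance during assembly
VALIDATE_PPM = 10.0        # mono/base-vs-centroid acceptance tolerance
SCORE_THRESHOLD = 20.0
N_INTENSITY_ISOTOPES = 3   # feature intensity sums the first three isotopes
N_APEX_FRAMES = 3          # frames averaged at the RT apex


@dataclass
class Spectrum2D:
    """Centroided peaks (m/z ascending) after intensity descent."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if len(self.mz) > 1 and not (np.diff(self.mz) > 0).all():
            raise ValueError("spectrum m/z must be strictly increasing")


@dataclass
class IsotopicEnvelope:
    """A deconvolved isotopic peak series."""

    mono_mz: float
    charge: int
    peaks: list[tuple[float, float]]   # (mz, intensity), mono first
    score: float
    base_peak_index: int

    def __post_init__(self) -> None:
        if self.base_peak_index != int(np.argmax([p[1] for p in self.peaks])):
            raise ValueError("base_peak_index must point at the tallest peak")

    @property
    def base_peak_mz(self) -> float:
        return self.peaks[self.base_peak_index][0]

    def isotope_mzs(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])


def expand_region(
    bounds: PeakBounds3D,
    lower: float = MZ_LOWER_EXTENSION,
    upper: float = MZ_UPPER_EXTENSION,
) -> PeakBounds3D:
    """Widen the m/z bounds to cover the whole isotopic series.

    Scan and RT bounds are unchanged.  Single-call contract: the extension is
    absolute, so applying it twice widens twice.
    """
    return replace(bounds, mz_lo=bounds.mz_lo - lower, mz_hi=bounds.mz_hi + upper)


def intensity_descent(
    mz: np.ndarray, intensity: np.ndarray, resolution: float = RESOLUTION
) -> Spectrum2D:
    """Greedy centroiding: repeatedly group every point within the 3-sigma
    resolution window of the most intense remaining point into one peak.

    Each emitted peak carries the group's intensity-weighted centroid and
    summed intensity, so total intensity is conserved exactly.  Intensity ties
    break toward the lower m/z point.
    """
    order = np.argsort(mz, kind="mergesort")
    mz = np.asarray(mz, float)[order]
    intensity = np.asarray(intensity, float)[order]
    alive = np.ones(len(mz), dtype=bool)
    out_mz: list[float] = []
    out_int: list[float] = []
    while alive.any():
        live = np.flatnonzero(alive)
        seed = live[np.argmax(intensity[live])]  # first max -> lowest m/z tie-break
        lo, hi = mz_extent(mz[seed], resolution)
        half = mz[seed] - lo
        grp = live[np.abs(mz[live] - mz[seed]) <= half]
        w = intensity[grp]
        total = w.sum()
        centroid = float((mz[grp] * w).sum() / total) if total > 0 else float(mz[seed])
        out_mz.append(centroid)
        out_int.append(float(total))
        alive[grp] = False
    order = np.argsort(out_mz)
    return Spectrum2D(np.array(out_mz)[order], np.array(out_int)[order])


def _candidate_score(
    obs_int: np.ndarray, ppm_err: np.ndarray, predicted: np.ndarray,
    match_ppm: float
) -> float:
    """Penalized similarity between an assembled series and its averagine
    prediction: each matched peak contributes the square root of its intensity,
    discounted by its position error and by the mismatch between observed and
    predicted relative heights."""
    obs_n = obs_int / obs_int.sum()
    pred_n = predicted / predicted.sum()
    height = np.clip(1.0 - np.abs(obs_n - pred_n) / np.maximum(pred_n, 1e-12),
                     0.0, 1.0)
    spacing = np.clip(1.0 - np.abs(ppm_err) / match_ppm, 0.0, 1.0)
    return float(np.sum(np.sqrt(obs_int) * spacing * height))


def deconvolve(
    spectrum: Spectrum2D,
    charge_range: tuple[int, int] = (CHARGE_MIN, CHARGE_MAX),
    min_isotopes: int = MIN_ISOTOPES,
    match_ppm: float = MATCH_PPM,
    score_threshold: float = SCORE_THRESHOLD,
) -> list[IsotopicEnvelope]:
    """Assemble scored isotopic envelopes from a centroided spectrum.

    Every peak is tried as a putative monoisotopic peak at every charge in the
    range; successive isotopes must appear within `match_ppm` of the expected
    ``mono + k * 1.003355 / z`` position, and assembly stops at the first gap.
    Series with at least `min_isotopes` peaks are scored against the averagine
    prediction at the implied neutral mass; envelopes above `score_threshold`
    are returned, strongest first.  Every envelope peak is a peak of the input
    spectrum.
    """
    mzs, ints = spectrum.mz, spectrum.intensity
    out: list[IsotopicEnvelope] = []
    for j in range(len(mzs)):
        mono = mzs[j]
        for z in range(charge_range[0], charge_range[1] + 1):
            idx = [j]
            ppm_err = [0.0]
            k = 1
            while True:
                expected = mono + k * ISOTOPE_SPACING / z
                tol = expected * match_ppm * 1e-6
                i0 = np.searchsorted(mzs, expected - tol)
                i1 = np.searchsorted(mzs, expected + tol, side="right")
                if i0 >= i1:
                    break
                cand = i0 + int(np.argmin(np.abs(mzs[i0:i1] - expected)))
                idx.append(cand)
                ppm_err.append((mzs[cand] - expected) / expected * 1e6)
                k += 1
            if len(idx) < min_isotopes:
                continue
            obs = ints[np.array(idx)]
            neutral_mass = (mono - PROTON_MASS) * z
            if neutral_mass <= 0:
                continue
            predicted = averagine_envelope(neutral_mass, len(idx))
            score = _candidate_score(obs, np.array(ppm_err), predicted, match_ppm)
            if score <= score_threshold:
                continue
            peaks = [(float(mzs[i]), float(ints[i])) for i in idx]
            out.append(
                IsotopicEnvelope(
                    mono_mz=float(mono),
                    charge=z,
                    peaks=peaks,
                    score=score,
                    base_peak_index=int(np.argmax(obs)),
                )
            )
    out.sort(key=lambda e: (-e.score, e.mono_mz, e.charge))
    return out


def validate_candidate(
    envelope: IsotopicEnvelope, voxel_centroid_mz: float,
    tolerance_ppm: float = VALIDATE_PPM,
) -> bool:
    """True when the envelope's monoisotopic or base peak matches the seeding
    voxel's m/z centroid within the ppm tolerance."""
    tol = voxel_centroid_mz * tolerance_ppm * 1e-6
    return (
        abs(envelope.mono_mz - voxel_centroid_mz) <= tol
        or abs(envelope.base_peak_mz - voxel_centroid_mz) <= tol
    )


def feature_intensity(
    envelope: IsotopicEnvelope,
    mz: np.ndarray,
    intensity: np.ndarray,
    rt: np.ndarray,
    rt_apex: float,
    saturation: Callable[[np.ndarray], np.ndarray] | None = None,
    resolution: float = RESOLUTION,
    n_isotopes: int = N_INTENSITY_ISOTOPES,
    n_frames: int = N_APEX_FRAMES,
) -> float:
    """Feature intensity: sum over the first `n_isotopes` isotopes of the mean,
    across the `n_frames` frames nearest the RT apex, of each frame's most
    intense reading inside that isotope's 3-sigma m/z extent.

    Averaging three frames damps single-point intensity fluctuations.  The
    optional `saturation` hook corrects each reading before the maximum is
    taken (identity when None); a frame with no reading for an isotope
    contributes zero to that isotope's mean.
    """
    mz = np.asarray(mz, float)
    intensity = np.asarray(intensity, float)
    rt = np.asarray(rt, float)
    frames = np.unique(rt)
    if len(frames) == 0:
        raise DegenerateDataError("no points near the RT apex")
    chosen = frames[np.argsort(np.abs(frames - rt_apex), kind="stable")][:n_frames]
    corrected = saturation(intensity) if saturation is not None else intensity
    total = 0.0
    for peak_mz, _ in envelope.peaks[:n_isotopes]:
        lo, hi = mz_extent(peak_mz, resolution)
        in_iso = (mz >= lo) & (mz <= hi)
        vals = []
        for f in chosen:
            sel = in_iso & (rt == f)
            vals.append(float(corrected[sel].max()) if sel.any() else 0.0)
        total += float(np.mean(vals))
    return total


def alignment_coefficients(
    envelope: IsotopicEnvelope,
    mz: np.ndarray,
    intensity: np.ndarray,
    rt: np.ndarray,
    scan: np.ndarray,
    bounds: PeakBounds3D,
    resolution: float = RESOLUTION,
) -> tuple[float, float]:
    """Mean cosine similarity of each isotope's RT profile (coelution) and
    mobility profile with the monoisotopic peak's, on a common grid.

    Isotopes with an all-zero profile are excluded from the mean; if the
    reference itself (or every comparison) is all zero the coefficient is
    undefined and raises.
    """
    mz = np.asarray(mz, float)
    intensity = np.asarray(intensity, float)
    rt = np.asarray(rt, float)
    scan = np.asarray(scan)
    if len(envelope.peaks) < 2:
        raise DegenerateDataError("need at least two isotopes for alignment")

    frames = np.unique(rt[(rt >= bounds.rt_lo) & (rt <= bounds.rt_hi)])
    scans = np.arange(bounds.scan_lo, bounds.scan_hi + 1)
    if len(frames) == 0 or len(scans) == 0:
        raise DegenerateDataError("empty feature bounds")

    def profiles(peak_mz: float) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = mz_extent(peak_mz, resolution)
        sel = (
            (mz >= lo) & (mz <= hi)
            & (rt >= bounds.rt_lo) & (rt <= bounds.rt_hi)
            & (scan >= bounds.scan_lo) & (scan <= bounds.scan_hi)
        )
        rt_prof = np.zeros(len(frames))
        sc_prof = np.zeros(len(scans))
        if sel.any():
            fi = np.searchsorted(frames, rt[sel])
            np.add.at(rt_prof, fi, intensity[sel])
            si = (scan[sel] - bounds.scan_lo).astype(int)
            np.add.at(sc_prof, si, intensity[sel])
        return rt_prof, sc_prof

    def cosine(a: np.ndarray, b: np.ndarray) -> float | None:
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return None
        return float(np.dot(a, b) / (na * nb))

    ref_rt, ref_sc = profiles(envelope.peaks[0][0])
    co, mo = [], []
    for peak_mz, _ in envelope.peaks[1:]:
        p_rt, p_sc = profiles(peak_mz)
        c = cosine(ref_rt, p_rt)
        m = cosine(ref_sc, p_sc)
        if c is not None:
            co.append(c)
        if m is not None:
            mo.append(m)
    if not co or not mo:
        raise DegenerateDataError("all isotope profiles are zero")
    return float(np.mean(co)), float(np.mean(mo))


def assign_isotope_points(
    envelope: IsotopicEnvelope,
    mz: np.ndarray,
    region_indices: np.ndarray,
    resolution: float = RESOLUTION,
) -> np.ndarray:
    """Indices (into the source cloud) of region points lying inside any
    isotope's 3-sigma m/z extent — the points the feature consumes."""
    mz = np.asarray(mz, float)
    mask = np.zeros(len(mz), dtype=bool)
    for peak_mz, _ in envelope.peaks:
        lo, hi = mz_extent(peak_mz, resolution)
        mask |= (mz >= lo) & (mz <= hi)
    return np.asarray(region_indices)[mask]
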