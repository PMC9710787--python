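"""Envelope construction: region expansion, intensity descent, deconvolution,
candidate validation, feature intensity, alignment coefficients."""

import numpy as np
import pytest

import timsfeat as tf
from timsfeat.envelope import assign_isotope_points
from timsfeat.profile import PeakBounds3D


def _bounds(mz_lo=500.00, mz_hi=500.05):
    return PeakBounds3D(
        mz_centroid=(mz_lo + mz_hi) / 2, mz_lo=mz_lo, mz_hi=mz_hi,
        scan_lo=280, scan_hi=320, scan_apex=300,
        rt_lo=95.0, rt_hi=105.0, rt_apex=100.0,
    )


class TestExpandRegion:
    def test_expansion_arithmetic(self):
        out = tf.expand_region(_bounds())
        assert out.mz_lo == pytest.approx(499.40)
        assert out.mz_hi == pytest.approx(503.05)

    def test_scan_rt_bounds_invariant(self):
        b = _bounds()
        out = tf.expand_region(b)
        assert (out.scan_lo, out.scan_hi, out.rt_lo, out.rt_hi) == (
            b.scan_lo, b.scan_hi, b.rt_lo, b.rt_hi
        )

    def test_not_idempotent(self):
        once = tf.expand_region(_bounds())
        twice = tf.expand_region(once)
        assert twice.mz_lo != once.mz_lo


class TestIntensityDescent:
    def test_close_points_grouped_with_weighted_centroid(self):
        spec = tf.intensity_descent([500.000, 500.001], [10.0, 5.0])
        assert len(spec.mz) == 1
        assert spec.intensity[0] == pytest.approx(15.0)
        expect = (500.000 * 10 + 500.001 * 5) / 15
        assert spec.mz[0] == pytest.approx(expect, rel=1e-12)

    def test_separated_points_stay_separate(self):
        spec = tf.intensity_descent([500.0, 505.0], [10.0, 5.0])
        assert len(spec.mz) == 2

    def test_conservation_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(2, 200))
            mz = rng.uniform(500, 504, n)
            inten = rng.uniform(1, 100, n)
            spec = tf.intensity_descent(mz, inten)
            assert spec.intensity.sum() == pytest.approx(inten.sum(), rel=1e-12)
            assert (np.diff(spec.mz) > 0).all()

    def test_deterministic_lower_mz_tie_break(self):
        # two equal-intensity singletons: the lower-m/z one seeds first
        spec = tf.intensity_descent([502.0, 500.0], [10.0, 10.0])
        assert list(spec.mz) == [500.0, 502.0]


def _envelope_spectrum(mono=500.0, charge=2, n=4, intensity=1e4, extra=()):
    """Peaks of a synthetic averagine envelope plus optional extras."""
    frac = tf.averagine_envelope((mono - tf.PROTON_MASS) * charge, n)
    mzs = mono + tf.ISOTOPE_SPACING / charge * np.arange(n)
    peaks = list(zip(mzs, intensity * frac)) + list(extra)
    peaks.sort()
    return tf.Spectrum2D(
        np.array([p[0] for p in peaks]), np.array([p[1] for p in peaks])
    )


class TestDeconvolve:
    def test_clean_charge2_envelope_recovered(self):
        spec = _envelope_spectrum(mono=500.0, charge=2, n=4)
        envs = tf.deconvolve(spec)
        assert envs
        best = envs[0]
        assert best.charge == 2
        assert abs(best.mono_mz - 500.0) / 500.0 * 1e6 < 5
        assert len(best.peaks) == 4

    def test_single_peak_yields_nothing(self):
        spec = tf.Spectrum2D(np.array([500.0]), np.array([1e4]))
        assert tf.deconvolve(spec, min_isotopes=2) == []

    def test_translation_property(self):
        a = tf.deconvolve(_envelope_spectrum(mono=500.0, charge=2))[0]
        b = tf.deconvolve(_envelope_spectrum(mono=600.0, charge=2))[0]
        assert b.charge == a.charge
        assert b.mono_mz == pytest.approx(a.mono_mz + 100.0, abs=1e-9)

    def test_emitted_peaks_exist_in_input_spectrum(self):
        rng = np.random.default_rng(4)
        extra = [(float(rng.uniform(498, 504)), float(rng.uniform(10, 5e3)))
                 for _ in range(6)]
        spec = _envelope_spectrum(mono=500.0, charge=3, extra=extra)
        for env in tf.deconvolve(spec):
            for mz, inten in env.peaks:
                j = int(np.argmin(np.abs(spec.mz - mz)))
                assert spec.mz[j] == pytest.approx(mz, abs=1e-12)
                assert spec.intensity[j] == pytest.approx(inten, abs=1e-12)

    def test_correct_charge_outscores_harmonics(self):
        for charge in (2, 3, 4):
            spec = _envelope_spectrum(mono=700.0, charge=charge, n=5)
            best = tf.deconvolve(spec)[0]
            assert best.charge == charge


class TestValidateCandidate:
    def _env(self, mono, base):
        peaks = [(mono, 50.0), (base, 100.0)]
        return tf.IsotopicEnvelope(
            mono_mz=mono, charge=2, peaks=peaks, score=100.0, base_peak_index=1
        )

    def test_mono_at_centroid(self):
        env = self._env(500.0, 500.5017)
        assert tf.validate_candidate(env, 500.0)

    def test_both_far_away_rejected(self):
        env = self._env(500.0, 500.5017)
        off = 500.0 * (1 + 50e-6)
        assert not tf.validate_candidate(env, off, tolerance_ppm=10.0)

    def test_base_match_suffices(self):
        env = self._env(500.0, 500.5017)
        assert tf.validate_candidate(env, 500.5017)


def _intensity_fixture(per_isotope):
    """Three frames; in each frame every isotope has one point at its target
    intensity, so the three-frame mean equals the target."""
    charge = 2
    mono = 500.0
    mzs = mono + tf.ISOTOPE_SPACING / charge * np.arange(len(per_isotope))
    rows_mz, rows_int, rows_rt = [], [], []
    for rt in (99.5, 100.0, 100.5):
        for mz, inten in zip(mzs, per_isotope):
            rows_mz.append(mz)
            rows_int.append(inten)
            rows_rt.append(rt)
    peaks = [(float(m), float(i)) for m, i in zip(mzs, per_isotope)]
    env = tf.IsotopicEnvelope(
        mono_mz=mono, charge=charge, peaks=peaks, score=100.0,
        base_peak_index=int(np.argmax(per_isotope)),
    )
    return env, np.array(rows_mz), np.array(rows_int), np.array(rows_rt)


class TestFeatureIntensity:
    def test_sum_of_first_three_isotopes(self):
        env, mz, inten, rt = _intensity_fixture([100.0, 60.0, 30.0, 10.0])
        out = tf.feature_intensity(env, mz, inten, rt, rt_apex=100.0)
        assert out == pytest.approx(190.0)

    def test_shorter_envelope_sums_what_exists(self):
        env, mz, inten, rt = _intensity_fixture([100.0, 60.0])
        out = tf.feature_intensity(env, mz, inten, rt, rt_apex=100.0)
        assert out == pytest.approx(160.0)

    def test_linearity_and_identity_hook(self):
        env, mz, inten, rt = _intensity_fixture([100.0, 60.0, 30.0])
        base = tf.feature_intensity(env, mz, inten, rt, rt_apex=100.0)
        with_hook = tf.feature_intensity(
            env, mz, inten, rt, rt_apex=100.0, saturation=lambda x: x
        )
        doubled = tf.feature_intensity(env, mz, 2 * inten, rt, rt_apex=100.0)
        assert with_hook == pytest.approx(base)
        assert doubled == pytest.approx(2 * base)

    def test_saturation_hook_applied_per_point(self):
        env, mz, inten, rt = _intensity_fixture([100.0, 60.0, 30.0])
        capped = tf.feature_intensity(
            env, mz, inten, rt, rt_apex=100.0,
            saturation=lambda x: np.minimum(x, 50.0),
        )
        assert capped == pytest.approx(50.0 + 50.0 + 30.0)

    def test_no_points_near_apex_raises(self):
        env, mz, inten, _ = _intensity_fixture([100.0, 60.0, 30.0])
        with pytest.raises(tf.DegenerateDataError):
            tf.feature_intensity(env, mz, inten, np.array([]), rt_apex=100.0)


def _alignment_fixture(profile_by_isotope):
    """Points on a frame x scan grid; isotope i gets profile_by_isotope[i]
    as its per-frame intensity, constant across 3 scans."""
    charge = 2
    mono = 500.0
    frames = 95.0 + 0.5 * np.arange(len(profile_by_isotope[0]))
    mzs = mono + tf.ISOTOPE_SPACING / charge * np.arange(len(profile_by_isotope))
    rows = {"mz": [], "int": [], "rt": [], "scan": []}
    for iso, prof in enumerate(profile_by_isotope):
        for f_i, inten in enumerate(prof):
            if inten == 0:
                continue
            for scan in (299, 300, 301):
                rows["mz"].append(mzs[iso])
                rows["int"].append(inten / 3.0)
                rows["rt"].append(frames[f_i])
                rows["scan"].append(scan)
    peaks = [(float(m), float(sum(p))) for m, p in zip(mzs, profile_by_isotope)]
    env = tf.IsotopicEnvelope(
        mono_mz=mono, charge=charge, peaks=peaks, score=100.0,
        base_peak_index=int(np.argmax([sum(p) for p in profile_by_isotope])),
    )
    bounds = PeakBounds3D(
        mz_centroid=mono, mz_lo=mono - 1, mz_hi=mzs[-1] + 1,
        scan_lo=295, scan_hi=305, scan_apex=300,
        rt_lo=frames[0], rt_hi=frames[-1], rt_apex=float(frames.mean()),
    )
    return env, rows, bounds


class TestAlignmentCoefficients:
    def _run(self, profiles):
        env, rows, bounds = _alignment_fixture(profiles)
        return tf.alignment_coefficients(
            env, np.array(rows["mz"]), np.array(rows["int"]),
            np.array(rows["rt"]), np.array(rows["scan"]), bounds,
        )

    def test_identical_profiles_give_unity(self):
        co, mo = self._run([[10, 50, 10], [10, 50, 10], [10, 50, 10]])
        assert co == pytest.approx(1.0)
        assert mo == pytest.approx(1.0)

    def test_disjoint_rt_support_gives_zero_coelution(self):
        co, mo = self._run([[10, 10, 0, 0], [0, 0, 10, 10]])
        assert co == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_cosine(self):
        rng = np.random.default_rng(8)
        profiles = [list(rng.integers(1, 50, 4).astype(float))
                    for _ in range(3)]
        co, _ = self._run(profiles)
        ref = np.array(profiles[0])
        brute = np.mean([
            np.dot(ref, p) / (np.linalg.norm(ref) * np.linalg.norm(p))
            for p in (np.array(profiles[1]), np.array(profiles[2]))
        ])
        assert co == pytest.approx(brute, rel=1e-9)

    def test_all_zero_profiles_raise(self):
        env, rows, bounds = _alignment_fixture([[10, 10], [10, 10]])
        with pytest.raises(tf.DegenerateDataError):
            tf.alignment_coefficients(
                env, np.array(rows["mz"]), np.zeros(len(rows["int"])),
                np.array(rows["rt"]), np.array(rows["scan"]), bounds,
            )


class TestAssignIsotopePoints:
    def test_points_inside_any_isotope_extent_claimed(self):
        env = tf.IsotopicEnvelope(
            mono_mz=500.0, charge=2,
            peaks=[(500.0, 100.0), (500.5017, 60.0)],
            score=50.0, base_peak_index=0,
        )
        mz = np.array([500.0, 500.25, 500.5017, 503.0])
        region = np.array([7, 8, 9, 10])
        got = assign_isotope_points(env, mz, region)
        assert list(got) == [7, 9]
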