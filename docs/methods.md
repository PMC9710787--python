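# Methods

## The detection model

`timsfeat` treats MS1 feature detection as template-guided pattern recognition
in a sparse 4-D point cloud.  A peptide precursor's signature has four parts:
(i) a series of isotopic peaks whose spacing is `1.003355/z` Th (the
¹³C−¹²C mass difference over the charge); (ii) peak height ratios that follow
the isotopic distribution of an average amino-acid composition (averagine)
at the implied neutral mass; (iii) per-peak profiles that are approximately
Gaussian in m/z, mobility and retention time; and (iv) isotope profiles that
are aligned (coelute) in mobility and retention time.  Detection seeds on
local intensity (voxels), characterises the seeded peak non-parametrically
(apex/valley, not model fitting), and accepts a feature only when the
deconvolved envelope explains the seed.

### Voxel queue

Voxels are fixed at 0.1 Th × 10 scans × 5 s: one isotopic peak wide in m/z,
and broad enough in the other axes to sample a peak's apex.  The grid is
anchored at 0 on every axis with half-open bins, and ranking ties break on
the voxel key, so a given cloud always yields the same queue.  The stopping
rule compares the *mean* point intensity of a voxel against
`min_voxel_intensity` — the same statistic used for ranking — so the queue is
a simple prefix of the ranking.  This also gives the depth knob a clean
monotonicity property: raising the threshold truncates the per-band
processing sequence, and the features found at a higher threshold are a
subset of those found at a lower one.

`min_voxel_intensity` deliberately has no default: it trades depth for time
and should be chosen per dataset.  The synthetic benchmark uses 100 counts,
which sits above almost all single-point noise voxels (exponential noise with
mean 30 counts) while seeding the weakest planted features.

### Band parallelism and worker invariance

Workers own disjoint 10-Th m/z bands of the voxel queue; features are built
from the global cloud (bands schedule seeds, they do not clip data).
Retirement — removing voxels whose intensity is more than 80% explained by an
accepted feature's isotopic peaks — is band-local: a feature found in one
band never mutates another band's queue.  That makes the result of a run
independent of the worker count by construction, at the cost of occasional
duplicate detections where an envelope spans a band edge; the closing
de-duplication pass collapses them.  The 80% rule is strict
("more than 80%"): a voxel exactly 80% consumed stays in the queue.

### Peak characterisation

The m/z extent is ±3σ around the intensity-weighted centroid with
σ = (m/z / R) / (2√(2 ln 2)), R = 40,000 — i.e. the resolution is read as
FWHM-defining.  Mobility flattening uses ±40 scans around the voxel midpoint
(twice the typical mobility peak width of ~44 scans, base width ≈ 4σ);
RT flattening uses ±13.2 s (twice the typical 6.6 s base width).
Savitzky–Golay smoothing uses window 11, order 3 — a standard choice for
peaks sampled at ~40 points — shrunk to the series length when needed.
Local maxima below 5% of the series maximum are treated as noise; among the
rest, the apex nearest the voxel midpoint wins (ties to the lower
coordinate).  Valleys are the nearest interior local minima, falling back to
the window edges for clean unimodal peaks; an apex sitting on the window edge
is processed but logged as low-confidence.  RT gap trimming walks outward
from the frame nearest the apex and stops at the first inter-frame gap above
1 s; it runs after the valley extent is fixed, as the workflow orders it.

### Envelope assembly and scoring

The original workflow delegates deconvolution to an external package; here
the scoring is specified in-package so behaviour is reproducible.  Every
spectrum peak is tried as a putative monoisotopic peak at every charge in
1–4; successive isotopes must lie within 10 ppm of the expected position and
assembly stops at the first gap.  A series of ≥ 3 peaks is scored as

    score = Σ_k √I_k · (1 − |Δppm_k|/10)₊ · (1 − |o_k − p_k| / p_k)₊

where `I_k` is the observed peak intensity, `o` and `p` are the observed and
averagine-predicted relative heights, and `(·)₊` clamps at zero.  The square
root damps the dominance of saturated base peaks, in the style of
msdeconv-family scores.  The threshold (default 20) was calibrated on the
synthetic suite so that noise-only regions essentially never produce
envelopes, while three genuine peaks of ≥ ~50 counts pass.  Among validated
candidates the pipeline keeps only the best-scoring envelope per voxel:
charge harmonics of a true envelope (e.g. a z=2 reading of a z=4 series)
score lower because they match fewer peaks and fit the predicted heights
worse, and emitting only the winner prevents a harmonic from surviving
de-duplication with a deceptively high identifiability score.

The averagine model scales the canonical composition
(C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇ per 111.1254 Da) to the neutral mass,
rounds atom counts, and convolves the exact per-element isotope abundance
vectors aggregated by nucleon count.  The implied neutral mass uses
M = (mono_mz − m_proton)·z.

### Intensity and alignment

Feature intensity is the sum over the first three isotopes (indexed from the
monoisotopic peak) of the mean, across the three frames nearest the RT apex
(inclusive of the apex frame), of each frame's most intense reading within
the isotope's ±3σ m/z extent.  The saturation correction is a pluggable
per-point hook (default: identity); detectors with known saturation models
can supply `corrected = f(raw)`.  Coelution and mobility coefficients are the
mean cosine similarity between isotope i ≥ 1 and the monoisotopic profile on
a shared frame/scan grid inside the feature bounds; all-zero profiles are
excluded from the mean.

### Identifiability classifier

The classifier maps (deconvolution score, coelution coefficient, mobility
coefficient, number of isotopes) to a probability that the feature would be
identified from MS2 spectra.  Architecture: three hidden blocks of
dense(200) → batch normalisation → ReLU → dropout(0.4), then a single
sigmoid unit.  The hidden-layer count is a configurable default (3): the
width, normalisation and dropout are fixed design points, the depth is not
published.  Training is binary cross-entropy with Adam at 1e-3 (standard
adaptive defaults), inputs z-scored with statistics fit on the 80% training
split, and an 80/10/10 split; defaults are 4000 epochs at batch size 512.
The network is implemented directly in numpy with a hand-written backward
pass (verified against finite differences in the test suite), so training is
bit-reproducible from a single seed across platforms.  Real training labels
(q < 1% search identifications) are external inputs; the package ships only
the training harness and accepts any labelled table in its documented format.

Filtering at 0.2 keeps everything but the least-identifiable tail; the
subsequent de-duplication uses single-linkage grouping within
10 ppm / 20 scans / 5 s and keeps each group's highest score (ties: higher
intensity, then lower m/z).  Filtering runs before de-duplication so the
survivor of a duplicate group is always an above-threshold feature.

## The synthetic generator

The generator is the package's test bed: it plants features with known
ground truth so that every downstream stage has an oracle.  Each feature is
defined by monoisotopic m/z, charge, total intensity, apex positions,
per-axis Gaussian widths and an isotope count; its envelope defaults to the
averagine prediction at the implied mass.  Points are emitted on the
discrete frame/scan grid the instrument measures on: the expected intensity
at each node is the product-Gaussian profile scaled by the isotope fraction,
and the emitted count is a Poisson draw, so weak features fray into sparse
points realistically.  Each point's m/z is drawn Gaussian around the isotope
centre with σ implied by resolution 40,000.

Defaults encode the typical feature geometry seen on the instrument:
RT σ = 1.65 ± 0.6 s and mobility σ = 11 ± 3.5 scans (both read as base
width ≈ 4σ from typical base widths of 6.6 s and 44 scans), a 500 ms MS1
frame period, and an affine scan → 1/K0 calibration with negative slope
(1.6 − 0.001·scan over scans 0–800) standing in for the instrument's
calibration, which real-data users must supply.  Ambient noise is uniform in
position and exponential in intensity (mean 30 counts) at a density of
3×10⁻⁴ points per (Th·scan·s) — about 86,000 noise points over the default
600 Th × 800 scan × 600 s extent.  No public noise statistics exist for the
instrument, so these are the package's own study conditions: dense enough
that ranking, the stopping rule and the score threshold are genuinely
exercised, sparse enough that planted truth remains unambiguous.

The standard benchmark plants 50 features with charges 2–4 and total
intensities log-uniform over 2×10⁵–2×10⁷ counts (a 100-fold span).
Features are rejection-sampled to be pairwise separated beyond the
de-duplication tolerances, because overlapping-envelope co-deconvolution is
explicitly outside the detector's contract.

What the generator does *not* emulate — chromatographic tailing,
charge-to-mobility correlation, detector saturation artefacts (beyond an
optional hard clip), correlated/structured noise, and overlapping envelopes —
bounds what passing tests show: they demonstrate the correctness of the
mechanics (binning, ranking, profiling, deconvolution arithmetic, scoring,
bookkeeping) under realistic geometry and sparsity, not detection
performance on real chromatographic data.

## Numerical choices and degenerate inputs

- All m/z bins are half-open `[lo, hi)`; region queries for peak assembly are
  closed boxes.  RT is seconds everywhere; scans are 0-based integers.
- Intensity descent breaks intensity ties toward the lower m/z point and
  conserves total intensity exactly; emitted peaks are strictly increasing in
  m/z.
- Voxels with fewer than 3 distinct profile positions, zero-total-intensity
  centroids, or no points near the RT apex are skipped and logged, never
  fatal.
- The frame-axis voxel span is 5 s of retention time, not a frame count, so
  behaviour is invariant to the instrument frame rate.
- Greedy closest-in-ppm matching in `match_feature_sets` can differ from the
  optimal assignment on pathological instances; the test suite bounds the
  difference against an exhaustive bipartite oracle on small instances.

## Problem sizes

The bundled benchmark (50 features, ~4×10⁵ points) runs the full pipeline in
a few seconds on one CPU; the classifier sanity checks train 200 epochs on
2,000 labelled rows in a few seconds.  These sizes were chosen so the whole
suite, including property tests, stays desk-scale while every stage still
operates far from trivial regimes (10⁵ points, ~9×10⁴ voxels, 60 bands).

## Known limitations

- Envelope assembly is single-ownership: overlapping envelopes compete for
  peaks rather than being co-deconvolved.
- The deconvolution score threshold is calibrated on the synthetic suite;
  real data with different noise floors may need retuning.
- The classifier's published operating point (threshold 0.2) presumes
  training labels from a search pipeline; on unlabelled data the detector
  runs unclassified and de-duplication falls back to intensity ordering.
- Vendor raw readers are out of scope; the tabular format is the boundary.
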