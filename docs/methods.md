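# Methods

This note documents the models, estimators and numerical choices behind
`azstorm`, and what the synthetic scenes do and do not establish about
real data.

## Scope and data model

The pipeline operates on localization tables — one row per fitted
single-molecule emission: planar position (nm), camera frame index and
fitted intensity (camera A/D counts).  Raw-frame processing (PSF
fitting, drift correction, channel registration) is upstream and out of
scope.  Coordinates use the image convention: origin at the top-left of
the field, y increasing downward; all histogram/pixel bins are half-open
`[lo, hi)`; ROI boundary points count as inside.  These conventions are
arbitrary but fixed, so that every operation is deterministic and
byte-reproducible.

## Localization precision (NeNA)

A fluorophore that remains emissive across two consecutive frames is
localized twice; the displacement between the two fits is the difference
of two independent isotropic Gaussian errors, so its length is Rayleigh
with scale √2·σ.  NeNA pools, over all frames t, the distance from each
localization in frame t to its nearest neighbour in frame t+1, and fits
the unit-area histogram (1 nm bins on [0, 200] nm) with

    f(d) = A · d/(2σ²) exp(−d²/4σ²)
         + B · N(d; d_c, ω)                (mismatched neighbours)
         + C · d                           (uniform background in 2D)

by bounded least squares.  Initialisation: σ₀ = histogram mode / √2,
correction amplitudes 0, d_c ≈ 4σ₀.  Degenerate samples (all-zero
distances, fewer than 100 values) are rejected with a fit error carrying
the initial values and residuals.  σ is estimated per image; images are
compared, never pooled.  On simulated scenes the fit recovers the
generative σ within a few tenths of a nanometre for n ≥ 10⁴ distances;
the mismatch terms matter once scenes are dense enough that the nearest
neighbour in the next frame is sometimes a different molecule.

## AZ segmentation

Active zones are extracted as HDBSCAN clusters of the (x, y) positions
(scikit-learn implementation: mutual-reachability distances,
excess-of-mass cluster selection, Euclidean metric in nm; frames and
intensities are ignored).  Defaults min_cluster_size = 100,
min_samples = 25 sit on a broad plateau of the cluster-count landscape;
`parameter_sweep` evaluates the full standard grids (minimum cluster
size 10–90 step 10 and 100–500 step 100; minimum samples 2, 5–25 step 5,
30–100 step 10 — 14 × 14 combinations) and reports the median AZ count
per image in contour-ready form.  Sweep counts are of raw clusters,
before area filtering.  Noise points carry label −1 and are never
counted as clusters.  Note that excess-of-mass HDBSCAN on finite uniform
noise does emit occasional sparse clusters; they span microns and are
removed by the AZ area window, which is the invariant the pipeline
relies on.

## Alpha-shape morphometry

The area of an AZ is the total area of the Delaunay triangles of its
member localizations whose **squared circumradius** is at most α (α in
nm²; α → ∞ recovers the convex hull; fewer than 3 points, collinear
sets, or no surviving triangle give area 0, never an exception).  The
comparison is `≤`.  α is selected per dye by sweeping α = x² nm² for
x = 5…200 in steps of 5, computing the median area over all AZs pooled
across the dye's images at each α, and taking the first grid value whose
median-area increase relative to the previous step falls below 5 % —
past that point the shape only inflates.  The percent-increase
denominator is the previous step's median; a zero-to-zero step counts as
0 %, zero-to-positive as ∞.  The curve is computed before area
filtering; the filter — keep 0.03 µm² < area < 0.3 µm², both bounds
excluded — is applied at the selected α.  Per-point-set areas across the
grid are obtained from a single triangulation by sorting triangles on
squared circumradius and prefix-summing, so the α sweep is O(n log n)
after the triangulation.

## Ripley's H and subclusters

For one AZ with n member localizations and reference area A,

    K(r) = A · Σ_{i≠j} 1(d_ij ≤ r) / (n (n−1)),
    L(r) = √(K/π),   H(r) = L(r) − r,

computed without edge correction on r = 0…150 nm in 1 nm steps.  A is
the AZ's alpha-shape area at the selected morphometry α, which keeps H
comparable across AZ sizes.  Per-AZ curves are averaged pointwise per
dye; the radius of the mean curve's maximum (ties to the smaller r)
estimates the subcluster radius.  AZs with fewer than 2 points after
filtering are dropped from averaging and counted.

Uncorrected K on a bounded window is negatively biased (edge deficit),
and H inherits a further small negative Jensen bias from the square
root; both are properties of the estimator the analysis deliberately
uses.  For null-model validation the estimator is therefore evaluated
where it is exactly unbiased: fixed-n uniform patterns with
minimum-image (torus) distances (`ripley_k(..., periodic=L)`), on which
E[K] = πr² holds identically.  A minus-sampling variant
(`neighbors=...`) that counts pairs from an interior subsample to all
points is also provided.

Subclusters (SCs) are extracted per AZ by a second-level HDBSCAN.  SC
areas use a fixed α = 300 nm² for all dyes, and the SC radius is defined
as the equivalent-circle radius √(area/π) — so π·r² = area holds by
construction.  `calibrate_sc_params` grid-searches
(min_cluster_size, min_samples) pairs and picks the pair whose pooled
median SC radius is closest to a target (typically the H maximum), ties
going to the smaller min_cluster_size then min_samples.  The exhaustive
rectangle (mcs 3–60, ms 2–mcs, ≈1700 pairs) is supported but the default
grid is coarsened (mcs in steps of 3, ms from the ladder
2,3,5,7,9,11,15,19,25) so that calibrating a full scene takes seconds;
a brute-force sub-grid search in the tests confirms the coarse search
selects the same winner where the grids coincide.

## Group statistics

Per-AZ and per-image quantities are skewed, so groups are described as
median (25th–75th percentile, linear interpolation) and compared with
Kruskal–Wallis (one-way ANOVA on ranks) followed by Dunn's pairwise
z-comparisons on pooled mid-ranks with tie correction
T = Σ(t³−t)/(12(N−1)).  Shapiro–Wilk p-values are reported per group.
The multiple-comparison adjustment is configurable: plain two-sided z
p-values (default) or Bonferroni.  Degenerate inputs (all pooled values
identical) are reported as non-testable rather than raising.
Significance threshold defaults to 0.05.

## Synthetic scenes

The generator emulates one dSTORM image of Brp-stained AZs: a
20 × 20 µm field, 15000 frames, n_az AZ centers placed uniformly with a
minimum separation (default twice the footprint radius; placement is
rejection sampling with a bounded retry budget).  Each AZ consists of
Poisson(sc_per_az) subcluster centers uniform in an annulus of the AZ
footprint (inner radius 0, outer radius = footprint radius) with
molecules uniform in discs of the preset SC radius, plus a diffuse
fraction of molecules uniform over the whole footprint.  Each molecule
blinks Geometric(mean 3) times; each blink is a burst of
Geometric(mean 2) consecutive frames starting uniformly in the movie,
clipped at the movie end; every burst frame yields one localization at
the molecule position plus isotropic Gaussian noise of sd σ_loc per
axis.  Intensities are lognormal with the preset median and shape 0.45
(chosen so a visible fraction falls below the inclusion threshold and
the threshold logic is exercised); background localizations are uniform
in space and frames at 5 per µm² over the movie.  Expected molecule
numbers are derived from the preset so that mean localizations per AZ
match the preset target under the blink model.

Per-dye presets freeze the measured study conditions: σ_loc 8/11/10 nm,
median intensity 8228/4144/3879 A/D, thresholds 3000/1000/1000 A/D,
localization yield 1085/1481/547 per AZ, SC radius 25/34/26 nm and
12/6/10 SCs per AZ for AF647/CF568/CF583R.

Two geometry defaults were calibrated once against the reference
measurements rather than invented: the AZ footprint radius (170 nm) and
the diffuse molecule fraction (0.5).  Together they reproduce the
reference AZ alpha-shape areas (simulated medians ≈ 0.08–0.09 µm²
against reported ≈ 0.11 µm², comfortably inside the 0.03–0.3 µm²
window), selected α values in the reported range, and — critically —
AZs that are single contiguous density clusters, as real Brp AZs are.
A smaller footprint or a purely subcluster-based molecule layout makes
synthetic AZs fragment into SC islands and hug the lower area bound,
neither of which matches the imaging data the generator stands in for.
The diffuse fraction slightly dilutes the H-function peak, so recovered
H maxima sit 2–4 nm below the generative SC radius; the calibration
step (which matches SC extraction to the measured H maximum, not to the
generative radius) is unaffected.

What passing on these scenes does **not** show: robustness to drift,
repeated-antibody label displacement, astigmatic/3D effects, camera
noise, dye-specific photophysics (duty cycle, photobleaching kinetics),
or ring-versus-filled AZ geometry — none of which are modelled.  The
annulus/diffuse layout is a stand-in, not a structural claim about Brp.

## Determinism and provenance

All randomness flows through one `numpy.random.default_rng(seed)` per
scene/pipeline; reruns with the same config are byte-identical (CSV
floats are written with shortest round-trip `repr` and read back with
`float_precision="round_trip"`).  `run_pipeline` writes a
`manifest.json` with the full config echo, input SHA-256 hashes,
package version and seed.

## Problem sizes

Validation workloads are sized for a single CPU: scenes of 12–30 AZs
per image (one to two images per check), 100 Monte-Carlo patterns of
800 points for the Poisson null, 10⁴ distance pairs per NeNA recovery
point, 1000 replicates for the Kruskal–Wallis calibration, and the
coarse calibration grid described above.  All sizes are parameters, so
larger studies simply pass larger values.

## Known limitations

- The NeNA mismatch-correction parameterisation follows the published
  two-term form; σ estimates from very dense scenes are sensitive to
  the correction amplitudes, which the fit diagnostics expose.
- Uncorrected K underestimates clustering at radii comparable to the
  AZ diameter; H maxima are interpretable as relative, per-dye
  quantities, not absolute cluster radii.
- `parameter_sweep` medians are over raw (pre-filter) cluster counts;
  a post-filter sweep can be composed from the library pieces if
  needed.
- ImageJ binary `.roi` files are not parsed; ROIs are CSV polygons.
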