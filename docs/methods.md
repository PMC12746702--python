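# Methods

## Scope and model of the data

`ovomorph` analyzes fluorescence micrographs of cultured primary ovarian
somatic cells (channels: DNA, F-actin, vimentin, optionally a plasma-membrane
counterstain) and transmitted-light scans of agarose micromolds in which
dissociated cells aggregate into organoids. The analysis has two arms:

* **Single-cell morphology**: per-cell nuclear and cellular masks →
  a catalog of morphological parameters → feature selection → 2D embedding →
  k-means morphological clusters → group-level enrichment statistics.
* **Aggregation**: microwell ROIs → thresholded particles per well →
  organoid counts and size → particles-per-well frequency curves.

No raw study imagery is bundled; a seeded synthetic generator reproduces the
relevant structure of the data with known ground truth, and every stage is
validated against that truth or an independent oracle.

## Synthetic data generator

**Cell shapes** are star-convex:
`r(θ) = R · f_ellipse(θ) · (1 + Σ_{h=2..6} a_h cos(hθ + φ_h))`,
with the ellipse factor set by the elongation (major/minor ratio) at fixed
geometric-mean radius `R`, and harmonic amplitudes `a_h ∝ 1/h` scaled so
their sum is 0.9 × `boundary_irregularity` (radius stays positive; roughness
and curvature grow monotonically with the parameter). The nucleus is a
smoother, smaller star-convex shape offset by `nucleus_offset_frac` of the
cell radius and clipped to the eroded cell raster, so nucleus ⊂ cell holds
exactly.

**Populations.** All positive quantities are log-normal, parameterized by
median and geometric sd — strictly positive and right-skewed like real size
data. A population is a weighted mixture of eight subtypes on a
fibroblast-to-epithelial gradient (median cell radius 28 → 9 µm, elongation
2.6 → 1.06, boundary irregularity 0.22 → 0.03, actin content 1.4e5 → 1.1e4
a.u.), with skewed weights (3–30% per subtype). Eight distinct modes of
widely varying abundance is what heterogeneous primary stromal isolates
resolve into under morphological clustering; a smooth unimodal continuum
would instead yield near-uniform k-means fractions, which is not what such
data look like. Total stain content scales with cell area around the
subtype's median concentration, as for a roughly uniform cytoplasmic stain.

Condition presets: *young* (reference weights), *old* (cell radii ×0.8,
nuclear radii ×0.9 — hence a larger N:C ratio — and weight mass moved toward
the small/round subtypes), *lata* (one common small, round, actin-depleted
distribution used for both ages, emulating post-depolymerization
convergence), *jasp* (compact, rough, actin-bright; also age-shared). The
magnitudes are this package's own choices; only the directions of the age
and treatment effects are anchored to the biology.

**Scenes** default to 1024 × 1024 px at 0.568 µm/px. Stain totals are spread
uniformly over the compartment raster, so per-cell intensity sums are
conserved exactly at zero noise; Gaussian and/or Poisson noise is optional.
Placement is rejection sampling with worst-case outline radii (largest
cells first); a requested fraction of cells is instead placed as touching
pairs at 0.65 × the sum of mean radii and truth-flagged confluent, so
curation recall is measurable. A fourth `membrane` channel (constant per-cell
amplitude, independent of actin) models a plasma-membrane counterstain that
keeps cell boundaries segmentable when actin is drug-depleted.

**Micromolds**: a grid of ring-drawn wells (default 9 × 9, 400 µm diameter,
600 µm pitch, 3.3 µm/px); per-well particle counts are Poisson (negative
binomial optional), particle areas log-normal (median 600 µm², gsd 1.6),
placed without overlap inside the well; over-capacity requests raise.

## Segmentation and curation

Nuclei: Gaussian blur (σ = 1 px) → Otsu threshold (manual override
available) → distance transform → watershed seeded at the regional maxima of
the h-reconstruction, with per-component `h = max(1, 0.25 × in-radius)`.
Taking regional maxima of the reconstruction (rather than the raw h-maxima
residue) keeps equal-height ridge peaks connected as one plateau, so mild
boundary roughness never splits a lone nucleus, while saddles deeper than
`h` — two genuinely merged nuclei — still do. Cells: seeded watershed from
the nucleus labels over the thresholded cytoplasm/membrane channel; cell
label ids equal their seed nucleus ids.

Curation removes, in order: border-touching cells; confluent cells (mask
8-adjacent to another cell mask, or more than 4 neighbor centroids within
3 × the median equivalent diameter); size-gate failures (default
30–10⁴ µm²); and cells without exactly one majority-overlap nucleus.
Retained nuclei are clipped to their cell raster. The report reconciles
exactly: removed + retained = detected.

## Morphometry

Per compartment (nucleus, cell): area, perimeter, equivalent/Feret
diameters, axis lengths, aspect ratio, eccentricity, circularity, solidity,
convexity and roughness (convex-perimeter ratios), extent, orientation,
bbox/convex areas, boundary radial-distance statistics, curvature statistics
and bending energy from a smoothed closed contour, Fourier boundary-harmonic
amplitudes h = 2..9 normalized by the mean radius, and the 7 Hu moments;
cross-compartment: N:C ratios, centroid offset, orientation alignment; plus
intensity sums/means/sds and the masked texture statistic when an intensity
table is attached. 94 geometric/cross features; ≥ 100 with intensities.

Numerical choices: areas are pixel counts × pixel_size²; connectivity is
8-way; the boundary contour is the longest 0.5-level contour of the padded
mask, smoothed with a wrapped Gaussian of window 5% of the contour length.
The headline `perimeter` (and hence circularity) is the smoothed-contour arc
length: the Crofton estimator, kept as its own feature, showed ~3%
orientation-dependent bias on rotated-ellipse rasters, while the arc length
is rotation-stable to < 1% and keeps disk circularity at ≈ 1.001.
Curvature is `(x′y″ − y′x″)/(x′² + y′²)^{3/2}` on the smoothed contour
(units 1/µm); bending energy is `Σ κ² ds`. Cells with a degenerate contour
(< 8 boundary points) or any non-finite feature are dropped and counted
(complete-case). The catalog order is frozen and hashed into output
metadata.

The texture statistic is information measure of correlation 1 on a masked
co-occurrence matrix: in-mask intensities quantized to 8 levels over the
in-mask range (offset-invariant by construction), symmetric GLCMs at
distance 1 averaged over the four principal directions, then
`(H_XY − H_XY1)/max(H_X, H_Y)`; constant regions return 0, masks under 2 px
return NaN. Entropies use natural log; the ratio is base-independent.

## Profiling

* **Preprocess**: strictly positive features get `log`, others the signed
  `log1p`; then per-feature min-max to [−1, 1] (default; z-score optional).
  Constant columns are dropped with a warning; the stored transform
  re-applies bit-identically to the training rows.
* **Communality selection**: principal-component factoring of the feature
  correlation matrix (principal-axis iteration optional); loadings are the
  top-2 eigenvectors × √eigenvalues; communality_j = Σ loadings_j²;
  features below 0.5 are dropped. Verified to 1e-9 against an independent
  eigendecomposition oracle.
* **Embedding**: UMAP (seeded, single-threaded, reproducible) or PCA
  (deterministic; each component's largest-magnitude loading made positive).
* **k-means**: scan k = 2..15 recording inertia and mean silhouette
  (silhouette subsampled at 5000 for large n, seeded). A warm-start extra
  init (previous centroids + worst-fit point) guarantees the inertia curve
  never increases with k. Plateau rule: the smallest k whose relative
  inertia drop to k+1 is < 10% while its silhouette is within 0.01 of the
  running maximum. If no k satisfies both, the fallback takes the
  best-silhouette k among those whose forward inertia drop is < 25% — a
  drop that large means k+1 still splits a real cluster, so such k are
  under-merged and excluded. Labels are 1..k. The default clustering space
  is the selected preprocessed features; clustering on the 2D embedding is a
  flag, since both readings of the published workflow are defensible.

The statsmodels-style wrapper `MorphologyProfileModel(...).fit(seed)` runs
the four stages and returns a results object carrying the transform records,
loadings/communalities, embedding, cluster model and diagnostics, with
`summary()`, `cell_table()`, `characterize()` and plotting helpers.

## Group statistics

Morphological enrichment is summarized per group as the fractional abundance
vector over the k clusters (default) or as a Gaussian-KDE map on a shared
embedding grid (100 × 100, pooled extent + 5% margin, Scott bandwidth,
duplicate points collapsed to weights so exact duplication leaves the map
unchanged); enrichment correlation is the Pearson correlation of either
summary. Which representation underlies published correlation values of
this kind is generally ambiguous — both are provided; cluster fractions are
the deterministic default. Centroid shift is the Euclidean distance of each
reference cell to the coordinate-wise mean embedding position of a target
group. Two-group comparisons use Welch's t-test (p = 1 when both groups are
constant and equal); Benjamini–Hochberg adjustment is available but off by
default, matching common practice for these figure-level comparisons.

## Aggregation

Wells are located by normalized cross-correlation with a ring template,
snapped to the stated lattice via circular-mean phase estimation (error if
fewer than half the expected wells respond); a geometry-only mode places a
centered lattice on any image. Manual exclusion lists model out-of-focus
wells; an automatic focus criterion is deliberately not applied by default.
Per well, the ring-free interior is Otsu-thresholded (skipped if local
contrast is under 10% of the image range, so empty wells yield zero
particles; a fixed global threshold can override); 8-connected components
above a 20 µm² debris floor are particles, assigned to the well containing
their centroid. A particle is an organoid iff area > 300 µm² — strict
inequality. Aggregates per microwell = organoid count / visible wells.
Particles-per-well histograms are compared after Gaussian kernel smoothing
(sd 0.5 counts — wide enough to smooth unit-spaced histograms without
merging adjacent modes), each curve renormalized to unit area on a shared
support; curve distance is L1.

## Pipeline and reproducibility

A YAML config (unknown keys rejected before any compute) drives
simulate → segment → features → profile → groupstats (+ aggregate). A single
global seed fans out to per-stage seeds via `SeedSequence(entropy=seed,
spawn_key=(stage,))`, so stages can be re-run independently. The run
manifest records per-stage seeds, cell counts (which must reconcile at every
boundary) and SHA-256 file digests; with the PCA embedding the whole run is
hash-reproducible.

## What the synthetic tests do and do not show

Passing recovery tests show the pipeline is internally correct: it recovers
known masks, counts, communalities, cluster counts and group contrasts from
data whose generative process matches the package's assumptions (star-convex
cells, uniform stain fill, isolated or pairwise-touching placement, ring
wells with disk particles). Real micrographs add optics blur, uneven
illumination, stain heterogeneity, debris, dense confluency and focus
variation that the generator deliberately omits (no PSF, no 3D, no
fusion kinetics); thresholds such as the curation gates and the Otsu
override exist precisely because real data will need them. Quantities
reported from synthetic runs (enrichment correlations, aggregates per
microwell) characterize the method under the stated simulation conditions,
not any biological sample.

## Problem sizes

Default validation sizes: 50-cell scenes at 1536² px for segmentation
recovery; 2000 cells/group for the age contrast; 1500 cells/condition for
pooled enrichment analyses; n = 5000 for split-half stability; 20 seeded
runs per condition for the Monte-Carlo checks; 9 × 9 micromolds. These are
the package's standard verification sizes and complete in a few minutes on
one CPU.

## Known limitations

* Segmentation is classical (threshold + watershed); heavily confluent or
  low-contrast real images would need a learned segmenter upstream.
* The feature catalog is this package's own frozen definition; it is not a
  reconstruction of any external tool's parameter list.
* Auto well detection assumes a regular lattice of circular wells at known
  pitch/diameter.
* UMAP embeddings are reproducible per seed but not stable across library
  versions; PCA is provided where determinism matters.
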