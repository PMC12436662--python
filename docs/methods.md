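# Methods

This note documents the models, conventions and numerical choices behind
`caq`, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Coordinate and unit conventions

All images are 0-based `(row, col)` arrays with row = y increasing downward.
Physical units enter only through `pixel_size_um`; lengths are reported in
both px and µm where relevant. Time is in minutes. Connectivity is
8-connected in 2D throughout. CSV outputs carry unit suffixes
(`_um`, `_px`, `_kcal_mol`).

## Partitioning thermodynamics

Condensates are segmented by Otsu thresholding after Gaussian convolution
(default σ = 2 px; the smoothing stabilizes the threshold against pixel
noise). Components below `min_area_px` (default 20 px) are discarded.

The partition coefficient of region *i* is

    Kp_i = mean(I in region i) / mean(I outside all regions)

with one dilute mean shared by all regions ("outside of condensates" is read
globally, not per-condensate). The transfer free energy is

    ΔG = −R·T·ln(Kp),   R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹,  T default 298.15 K.

The constant 1.9872 is the gas constant in cal mol⁻¹ K⁻¹; the default
converts it so that ΔG really is in kcal/mol. `R_AS_PRINTED` (the bare
1.9872, CLI flag `--r-as-printed`) is kept for reproducing pipelines that
plug the unconverted number in.

**PSF-bleed corrections.** Blur moves intensity across the condensate
boundary in both directions, so two symmetric corrections are applied by
default and can each be disabled:

* the dilute mean excludes a 2-px dilation ring around every region
  (`exclude_dilation_px=2`);
* the dense mean of each region is taken over the region eroded by 2 px
  (`erode_px=2`; the full region is used if erosion empties it).

On synthetic fields (disk radius 10 px, PSF σ = 1 px) these reduce the
systematic Kp error from ~5–8% (low) to under 1%. Kp is invariant under
global multiplicative rescaling of the image; additive offsets change it —
background offsets must be handled upstream.

**ROUT outliers.** GraphPad's ROUT procedure is re-expressed for a single
sample: the robust constant model is the median; the robust residual scale
(RSDR) is the 68.27th percentile of absolute residuals times `n/(n−1)`;
residuals map to two-sided t-tail probabilities with `n−1` degrees of
freedom; the most extreme points are removed by a Benjamini–Hochberg step at
rate Q (a percentage; Q = 0 removes nothing). When the RSDR is exactly zero
(majority of values identical) any nonzero residual is treated as an
outlier.

## Actin network reconstruction

Pipeline order in `trace_network`:

1. iterative median filter (2 iterations, circular radius 2 px) on the raw
   image — running the despeckle *before* thresholding keeps salt-and-pepper
   noise from distorting the Otsu threshold of the band-passed image; with
   this order a 1% salt-noised aster traces identically to the clean one;
2. difference of Gaussians, narrow minus wide (σ 1.0 − σ 2.0), clipped at 0,
   so ~2–4 px fibrils respond positively;
3. Otsu threshold of the enhanced image;
4. OR with the Otsu-thresholded (despeckled) original to restore
   fibril–condensate connections the band-pass severs;
5. topological thinning (Lee 2D/3D medial axis) and graph tracing.

**Tracing.** Skeleton pixels are linked by 8-adjacency; diagonal links whose
two pixels share an orthogonal skeleton neighbor are dropped (avoids false
triangles on staircases). Pixels of degree ≠ 2 become nodes, adjacent node
pixels are merged into one supernode; chains of degree-2 pixels become edges
carrying their pixel path and Euclidean length (1 per orthogonal step, √2
per diagonal). Pure cycles get a single anchor node. Tracing is fully
automatic and deterministic — no interactive step.

**Short-segment filtering (< 3 px).** Terminal spurs and short self-loops
are deleted, iterating to a fixpoint because pruning exposes new spurs;
short junction–junction connectors inside hubs are *contracted* (their
endpoints merged) rather than deleted, since deletion would disconnect the
graph. Pass-through nodes left with degree 2 are merged away.

**Tip extension.** Thinning retracts filament ends by roughly half the
filament width. Terminal edges are therefore extended along their local
direction (mean of the last ≤ 5 steps) while still inside the original
mask, at most 4 px. A 50-px bar of width 4 then traces to 49 px instead of
46.

Lee thinning's direction-ordered sub-iterations make skeletons differ by a
few pixels between image orientations; total length is stable to ~3% under
rotation, and edge counts are preserved.

## Sholl profiling

Shells are circles in the image plane (the analyzed data are 2D
projections), spaced 0.5 µm by default. Shells are half-open `[r_i, r_{i+1})`:
a point at exactly radius r belongs to the outer side. A crossing of shell r
is a consecutive point pair on one edge path with one point strictly inside
r and the next at or beyond it; a tortuous edge contributes every crossing.
The default maximum radius reaches the farthest traced pixel, so profiles
always end in a zero shell; centers are condensate segmentation centroids.

`compare_sholl_lmm` fits `intersections ~ condition × radius` with a random
intercept per profile (statsmodels MixedLM, REML) and reports the condition
main effect. Singular or failed fits — common under the null, where the
between-profile variance is ~0 — fall back to a permutation test (condition
labels shuffled across whole profiles, ≥ 1999 permutations, statistic =
|difference in mean area-under-profile| for two conditions, between-condition
variance of mean AUC otherwise).

## Node morphometrics

Binary network images are labelled and touching nodes split by watershed on
the negated Euclidean distance transform, seeded at h-maxima with h = 2 px —
small unimodal blobs are never split, and no size cutoff for "largest nodes"
is needed. The watershed partitions the foreground exactly (pixel
conservation is asserted in tests). Nodes under 100 px are removed.

Ten properties per node (2D mode): volume = area·px² (µm²; area·depth with a
z-depth), surface area = perimeter·px, diameter = maximum Feret diameter,
main/second axis lengths = 4√λ of the intensity-weighted central-moment
covariance eigenvalues (third axis stored as 0 in 2D), mean/max/min
intensity, and the median centroid-to-centroid Euclidean distance to all
other nodes (centroids, not nearest surfaces).

Before correlation, intensity columns are min-max rescaled to [0, 1] per
dataset so tables from different acquisitions can be concatenated.
Zero-variance columns propagate NaN rather than silent zeros. Clustering and
PCA run on `log10(x + ε)`-transformed columns (ε = 10⁻⁶ of each column's
smallest positive value), column-standardized; k-means uses ≥ 10 restarts
with a fixed, recorded seed, and k is chosen by maximum mean silhouette over
k = 2..8. Identical rows report "no structure" rather than an arbitrary
labelling.

## Enrichment kinetics

Rigid translation per frame is estimated by Fourier cross-correlation with
subpixel refinement and corrected by spline resampling. The reference frame
defaults to 0, but for growth movies whose early frames are nearly
featureless the CLI registers to the highest-contrast frame; featureless
frames register at zero shift with a warning.

ROI series: mean intensity inside the ROI per frame, minus the frame-0 mean
outside the ROI, divided by the series maximum (so a saturating series
plateaus near 1; plateau normalization is available via `normalize='none'`
plus rescaling). The Gompertz law

    Y(X) = YM · (Y0/YM)^exp(−K·X),  Y(0) = Y0,  Y(∞) = YM

is fitted by bounded Levenberg–Marquardt/trust-region least squares with
initialization `YM₀ = max(y)`, `Y0₀ = max(y[0], 10⁻³)`, `K₀ = 1/time to
half-plateau`. Noiseless model data is recovered to ≤ 10⁻⁵ relative error
across a parameter grid spanning an order of magnitude per parameter, with
R² = 1. Plate-reader baseline correction is elementwise subtraction of a
scalar (buffer-only) baseline.

## Bouton quantification and statistics

Marker masks are Otsu after σ = 1 px Gaussian smoothing, with an optional
absolute intensity floor (the expansion-microscopy variant); rescue-mode
masks are the AND of marker and GFP masks. ROIs below circularity
4πA/P² < 0.5 (default) can be re-split by the same distance-transform
watershed. Actin enrichment per ROI is max(actin in ROI)/max(actin in
image) — scale-invariant by construction — summarized per image by the
median. Ring periodicity is the lag of the first local maximum after lag 0
of the mean-subtracted, variance-normalized autocorrelation. Cluster
density counts components with intensity > θ_I (default 4000 counts) and
area > θ_A (default 10 px, both strict) inside the axon mask, per mask area;
the axon mask is user-supplied or the convex hull of suprathreshold signal.

Group comparison: optional outlier removal (iterative two-sided Grubbs at
α = 0.05, or ROUT), Shapiro–Wilk normality on each group, then a two-sided
Mann–Whitney U test if either group rejects normality (exact when both
n ≤ 20 without ties, normal approximation with tie correction otherwise) or
Welch's t-test if both pass. Under a Gaussian null with n = 50 per group the
type-I error rate is calibrated to 0.05 (checked over 1000 simulations).

## Synthetic scenes: what they emulate, and what they do not

Generators are bit-for-bit reproducible for identical (parameters, seed) and
record every planted object. Defaults describe the experimental regime the
analyses target: condensates of radius ~1–2 µm at 0.1 µm/px, dense/dilute
ratios 2–10, additive Gaussian noise a few percent of the dilute level
(optional Poisson mode), enrichment movies of 36 one-minute frames with
(YM, Y0, K) = (0.9611, 0.01032, 0.2958), STED-like ring profiles at 0.02
µm/px with a 0.19 µm period, and cluster thresholds (4000 counts, 10 px).

Morphology is phenomenological: flat disks convolved with a 1-px Gaussian
PSF, straight filaments with Gaussian cross-section (σ 1 px) at jittered
even angles, rigid whole-frame drift. There is no condensate coarsening or
wetting, no filament curvature, crossing disorder or polarity, no depth
structure, and no detector-specific noise. Passing recovery tests therefore
demonstrates correctness of the measurement code under known geometry and
noise, not robustness to every artifact of real micrographs; torus rim
widths and aster filament-count distributions are free knobs, not claims
about real data. Placement is rejection sampling with an explicit capacity
error when requested objects exceed ~30% of the frame.

## Problem sizes used in the test and acceptance suites

Recovery studies use 128–384 px frames, 20 scenes per condition for
partitioning, 20 traced asters for the Sholl oracle, 50 random fields for
watershed conservation and density oracles, 100 series for the Monte-Carlo
Gompertz study and ring-period sweep, and 1000 simulations for the type-I
calibration. The full suite runs in well under a minute on one core.

## Known limitations

* 2D only for segmentation, tracing and Sholl (the target data are planes or
  projections); 3D morphometric formulas exist only for volume via a given
  z-depth.
* The mixed-model comparison assumes Gaussian residuals of counts; for few
  profiles or boundary variance estimates it silently degrades to the
  permutation test (with a warning), which is conservative.
* ROUT here is the constant-model special case, not robust nonlinear
  regression.
* Registration models pure translation; rotation or shear in a movie will
  alias into apparent intensity changes.
* The ring-period estimator reports the first autocorrelation peak; profiles
  mixing two periodicities report only the shorter-lag one.
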