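# caq — condensate-actin quantification

`caq` is a Python package for quantifying how biomolecular condensates
(liquid-liquid phase-separated droplets, e.g. of the synaptic protein
synapsin-1) interact with the actin cytoskeleton in fluorescence microscopy
data. It bundles, as tested and reusable library code, the measurement
pipelines this kind of study needs:

* **Partitioning thermodynamics** (`caq.segment`) — condensates are
  segmented by Otsu thresholding after Gaussian convolution; each
  condensate's partition coefficient is
  `Kp = mean intensity inside / mean intensity outside`, and the apparent
  transfer free energy is `ΔG = −RT ln(Kp)` with
  `R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹`. ROUT-style FDR outlier removal is
  included.
* **Actin network reconstruction** (`caq.network`) — difference-of-Gaussians
  fibril enhancement (σ = 1.0 minus σ = 2.0), mask restoration against the
  thresholded original, iterative median despeckling, topological
  skeletonization and fully automatic tracing into a graph of
  endpoints/junctions and pixel-path edges (segments < 3 px discarded); SWC
  export included.
* **Sholl profiling** (`caq.sholl`) — intersections of traced filaments with
  concentric circles in 0.5 µm increments around condensate centers, plus a
  linear mixed-effects comparison between conditions (random intercept per
  condensate) with a permutation fallback.
* **Node morphometrics** (`caq.morphometrics`) — watershed splitting of
  touching network nodes on the distance transform, ten per-node properties
  (volume, surface area, Feret diameter, inertia-tensor axis lengths,
  intensity statistics, median inter-node distance), Pearson co-dependency
  matrices, k-means with silhouette model selection and PCA on the
  log-transformed property matrix.
* **Enrichment kinetics** (`caq.kinetics`) — rigid x-y drift correction,
  background-subtracted ROI time series, and nonlinear least-squares fitting
  of the Gompertz growth law `Y(X) = YM·(Y0/YM)^exp(−K·X)` (initial value
  `Y0`, plateau `YM`, rate `K` in min⁻¹), plus the scalar baseline
  correction used for plate-reader traces.
* **Super-resolution bouton statistics** (`caq.bouton`) — marker-positive
  ROI extraction (optionally gated on a GFP channel, optionally re-split by
  circularity), per-ROI actin maxima normalized to the image-wide actin
  maximum, autocorrelation-based detection of the ~190 nm axonal actin-ring
  period, suprathreshold cluster density (>4000 counts, >10 px defaults),
  and Grubbs/normality-gated Mann–Whitney-or-Welch group comparisons.
* **Synthetic scenes** (`caq.synth`) — seeded generators for every input the
  pipelines consume (condensate fields with known Kp, filament asters,
  Gompertz enrichment movies with drift, two-channel bouton images, periodic
  ring profiles, density scenes), each carrying a ground-truth record so all
  analyses are validated without external data.

The library is aimed at microscopists and image analysts working on
condensate-cytoskeleton reconstitution or synapse imaging who want scripted,
deterministic versions of quantifications usually spread across FIJI macros,
MATLAB scripts and Prism sessions.

## Worked example

```python
import numpy as np
from caq import synth, segment, network, sholl, kinetics

# --- partitioning: planted Kp = 4, 2% noise -------------------------------
sc = synth.make_condensate_field(n=6, radius_px=10, kp_true=4.0,
                                 noise_sd=0.02, seed=7)
img = sc.image.plane()
seg_res = segment.segment_condensates(img)
for r in segment.partition_coefficient(img, seg_res, T_kelvin=298.15)[:3]:
    print(f"region {r.region_id}: Kp = {r.Kp:.2f}, "
          f"dG = {r.deltaG_kcal_mol:+.3f} kcal/mol")

# --- enrichment kinetics: planted (YM, Y0, K) = (0.9611, 0.01032, 0.2958) -
ms = synth.make_enrichment_movie(noise_sd=0.01, seed=7)
movie = ms.image.frames()
shifts, corrected = kinetics.register_translation(movie, reference=-1)
roi = segment.segment_condensates(corrected[-1]).labels > 0
fit = kinetics.fit_gompertz(kinetics.roi_timeseries(corrected, roi))
print(f"Gompertz fit: YM = {fit.YM:.4f}, Y0 = {fit.Y0:.4f}, "
      f"K = {fit.K:.4f} /min (1/K = {fit.one_over_K:.2f} min), R2 = {fit.R2:.4f}")

# --- Sholl profile of a 6-filament aster ----------------------------------
aster = synth.make_aster_scene(n_condensates=1, filaments_per=6,
                               filament_len_px=40, seed=7, shape=(200, 200))
graph = network.trace_network(aster.image.plane(), pixel_size_um=0.1)
prof = sholl.sholl_profile(graph, aster.truth.condensate_centers[0], step_um=0.5)
print("Sholl counts:", prof.counts[:8].tolist())
```

Output:

```
region 1: Kp = 3.98, dG = -0.819 kcal/mol
region 2: Kp = 3.98, dG = -0.818 kcal/mol
region 3: Kp = 3.98, dG = -0.819 kcal/mol
Gompertz fit: YM = 0.9994, Y0 = 0.0097, K = 0.2977 /min (1/K = 3.36 min), R2 = 1.0000
Sholl counts: [6, 6, 6, 6, 6, 6, 6, 6]
```

The measured Kp sits within 1% of the planted ratio (ΔG < 0: enrichment in
the dense phase), the fitted rate constant recovers the generating value
within 1%, and every 0.5 µm shell between the condensate rim and the
filament tips is crossed exactly six times — one crossing per planted
filament.

A `caq` console command exposes the same pipelines
(`caq synth|partition|network|sholl|nodes|kinetics|bouton|density|autocorr|run`);
see `caq --help`.

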