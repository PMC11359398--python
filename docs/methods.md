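# Methods

This note documents the models, conventions and design choices behind
`histotex`, in the spirit of a statistical software appendix: what is
computed, under which assumptions, with which defaults, and what the
synthetic test bed does and does not establish.

## Pipeline model

The package treats a whole-slide image as a mosaic of stationary
textures on a bright, nearly constant background. The analysis makes
three assumptions:

1. **Bimodal intensity.** Tissue is darker than the empty glass, so a
   single global Otsu threshold separates foreground from background.
   Otsu's objective — maximize the between-class variance
   ω₀ω₁(μ₀−μ₁)² — is evaluated exhaustively over all 255 candidate
   thresholds in exact rational arithmetic, so the argmax and its
   smallest-threshold tie-break are reproducible to the bit. The
   polarity rule (foreground = the class with the lower mean) is a
   modeling choice: H&E tissue absorbs light. Images with dark
   backgrounds are handled correctly by the same rule.
2. **Texture stationarity within a patch.** Each non-overlapping
   patch is summarized by one co-occurrence matrix; patches straddling
   tissue boundaries mix textures. Edge cells that do not fit entirely
   are discarded, never padded, because padding would inject artificial
   co-occurrence pairs. Patch retention requires a foreground
   fraction ≥ 0.5 (majority rule, configurable).
3. **Cluster = texture population.** Patches with similar
   (standardized) co-occurrence features are assumed to belong to the
   same tissue compartment. No spatial smoothness is imposed: every
   patch is clustered independently of its neighbors.

## GLCM conventions

- Quantization is uniform-width binning `q = ⌊v·L/2^B⌋` (default
  L = 256, i.e. identity on 8-bit input). Equal-width bins keep the
  contrast scale interpretable; histogram equalization would make
  features depend on the global intensity distribution.
- Offsets: distance d ≥ 1 (default 1) and angles from {0°, 45°, 90°,
  135°} (default {0°}), with 0° = rightward along a row and the
  diagonal angles pointing up-right/up/up-left. Non-symmetric counting
  by default; `symmetric=True` adds each reversed pair.
- With several angles, counts are also summed into one overall matrix,
  but the four features are computed per angle and averaged, which
  keeps the feature vector 4-dimensional for any angle set.
- Degenerate marginals: a patch whose quantized levels are constant
  along the scan direction has σᵢσⱼ = 0; correlation is then defined
  as 1 (a perfectly predictable sequence). This convention matters for
  near-constant background patches and matches mainstream image
  stacks.
- A useful identity for reasoning about textures: for any stationary
  texture, contrast = 2σ²(1−ρ) where σ² is the marginal variance of
  the quantized levels and ρ the lag-d correlation. Correlation is
  therefore *not* an independent degree of freedom of a texture — a
  fact that shaped the synthetic generator (below).

## Clustering

- **Standardization** (per column, population SD; zero-variance
  columns map to zero) is applied before clustering by default, since
  raw contrast is several orders of magnitude larger than energy or
  homogeneity and would otherwise dominate the Euclidean geometry. A
  `--no-standardize` path preserves raw-feature clustering.
- **k-means**: Lloyd iterations from k-means++ seeds, `n_init = 10`
  restarts (best WCSS wins), stop when the largest centroid shift
  < 1e-4, empty clusters reseeded from the farthest point. After Lloyd
  converges, a Hartigan single-point refinement pass runs until no
  individual reassignment lowers the WCSS. The refinement is not
  cosmetic: there exist 10-point instances whose global optimum is a
  Lloyd fixed point that Lloyd cannot reach from *any* two-point
  initialization; single-point moves escape such traps, and Hartigan
  fixed points still satisfy the nearest-centroid invariant. The
  per-iteration WCSS trace is retained on the model so monotonicity is
  checkable.
- **Gaussian mixture**: full covariances, EM from a k-means
  initialization per restart, ridge 1e-6 on covariance diagonals,
  convergence when the log-likelihood gain < 1e-3, labels by maximum
  posterior responsibility. The full log-likelihood trace is retained;
  EM monotonicity is asserted in tests. With k = 1 the first M-step
  reproduces the closed-form mean and (ridge-shifted) ML covariance.
- **Elbow selection.** The WCSS curve over k ∈ [k_min, k_max] (default
  [1, 10]) is computed with a fresh fit per k. The automated knee is
  the interior k with the **largest relative drop** wcss(k−1)/wcss(k).
  The more common discrete-curvature rule (largest second difference)
  was evaluated and rejected as the selector: on curves that decay
  geometrically — which correlated feature spaces like this one
  produce — the second difference is maximal at k = 2 regardless of
  the true structure, whereas the relative-drop rule locates the last
  large collapse of the objective. Both statistics are computed and
  returned (`curvature_scores`, `drop_ratios`) together with the full
  curve, so the choice can always be overridden visually, which is how
  the elbow heuristic is classically applied. The relative-drop rule
  is scale-free but can be noisy when the curve approaches zero; the
  implementation floors the denominator at 1e-12 of the curve maximum.

## Evaluation indices

Silhouette (singletons contribute 0; 0/0 defined as 0), Davies–Bouldin
(diagnostic error if two clusters share a centroid with positive
scatter), contingency table, ARI and NMI. NMI uses natural-log
entropies with arithmetic-mean normalization (geometric available);
two constant labelings give NMI 1, one constant against a non-trivial
one gives 0. Silhouette, ARI, NMI and the contingency table are
delegated to scikit-learn, whose conventions coincide with the ones
stated here; Davies–Bouldin is computed directly (and cross-checked
against scikit-learn in the tests). All indices are invariant to label
permutation; for *display* only, labels of two methods are matched by
Hungarian assignment on the contingency table.

## Synthetic scenes

`generate_scene` builds a grayscale image from 150-px blocks: the
leftmost block column is background (245 ± 3, near-constant bright),
the remaining blocks carry K texture classes round-robin. Because 150
is divisible by 30, 50, 75 and 150, patches at those sizes never
straddle a region boundary — every retained patch has exactly one true
class, which makes ground-truth scoring exact. Patch size 100 does
straddle block boundaries; sweep rows at size 100 therefore include
mixed patches, as real tissue boundaries would.

Each class texture is smoothed Gaussian noise (granularity = smoothing
radius) plus an optional sinusoidal stripe along rows or columns,
clipped to [0, 255]. The five default classes were designed — and then
frozen — so that (a) every class mean stays ≤ 150, far below the
background, giving Otsu ≥ 99% tissue recall, and (b) the standardized
class centroids in feature space are close to equidistant, so the WCSS
curve collapses exactly at the true K. The contrast identity above
means the generator has only two effective texture axes (local
difference scale and marginal spread); a period-2 vertical stripe is
used to reach negative co-occurrence correlation, which is what keeps
the high-contrast classes apart. Five is about the practical limit for
near-equidistant classes in this feature geometry.

What the synthetic bed does **not** establish: robustness to staining
variation, illumination gradients, scanner artifacts, non-stationary
textures, or tissue boundaries that cut through patches at every size.
Passing the recovery tests shows the pipeline's machinery is correct
and well-calibrated on its own model assumptions, not that four
clusters is the right description of any real plaque.

## Problem sizes and determinism

Default test and acceptance runs use one 600×600 scene (108 patches at
size 50, 300 at size 30, 48 at size 75), k ranges up to 8–10 and 10
restarts; a full pipeline run takes a few seconds on one core. All
randomness (scene noise, k-means++ seeds, EM restarts) flows from a
single integer seed through numpy `SeedSequence`, so two runs with the
same image, config and seed produce byte-identical CSV/JSON outputs.

## Known limitations

- Single global threshold: slides with strong vignetting or multiple
  background modes would need local thresholding (out of scope).
- Features are first-order GLCM descriptors at one offset; textures
  that differ only at longer ranges are not separated unless the
  offset distance is raised in the config.
- The elbow heuristic — under any automation rule — assumes the WCSS
  curve has a knee; overlapping texture populations produce smooth
  curves where the selected k is not meaningful, which is why the
  curve itself is always part of the output.
- Pyramidal WSI containers (SVS/NDPI/OME-TIFF), stain deconvolution
  and color normalization are deliberately unsupported; input is a
  plain single-resolution raster.
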