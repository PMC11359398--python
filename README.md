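# histotex

Unsupervised texture-based tissue characterization for histopathological
whole-slide images (WSIs).

Digitized H&E slides of atherosclerotic carotid plaques contain several
tissue compartments — fibrous cap, necrotic core, calcifications,
hemorrhage — that differ more in *texture* than in raw intensity.
`histotex` segments tissue from the bright glass background, tiles it
into patches, describes each patch by four gray-level co-occurrence
(Haralick) features, and groups the patches by unsupervised clustering,
so a pathologist can see the slide's compositional structure as a
colored overlay without any manual annotation. Because annotated plaque
WSIs are scarce, the package ships a synthetic scene generator with
known per-pixel ground truth, which makes every stage of the pipeline
testable end to end.

## Method

1. **Segmentation.** Otsu's threshold `t* = argmax_t ω₀ω₁(μ₀ − μ₁)²` on
   the 256-bin intensity histogram; the darker class (tissue absorbs
   light) is foreground. The foreground is tiled into non-overlapping
   `s × s` patches (default s = 50) anchored at the image origin; a
   patch is kept when its foreground fraction is ≥ 0.5.
2. **Texture features.** Per patch, the normalized gray-level
   co-occurrence matrix P(i, j) at offset distance 1, angle 0° (both
   configurable), and from it

   - contrast `Σ P(i,j)(i−j)²`
   - correlation `Σ P(i,j)(i−μᵢ)(j−μⱼ)/(σᵢσⱼ)`
   - energy `√(Σ P(i,j)²)`
   - homogeneity `Σ P(i,j)/(1+(i−j)²)`

3. **Clustering.** Features are standardized (zero mean, unit
   variance), then clustered with k-means (Lloyd + k-means++ restarts +
   Hartigan single-point refinement) and/or a full-covariance Gaussian
   mixture fitted by EM. The number of clusters is chosen at the elbow
   of the WCSS-vs-k curve.
4. **Evaluation.** Internal quality via the silhouette score (in
   [−1, 1], higher is better) and the Davies–Bouldin index (≥ 0, lower
   is better); agreement between the two clusterings via the
   contingency table, Adjusted Rand Index (ARI) and Normalized Mutual
   Information (NMI). A patch-size sweep repeats the whole analysis at
   sizes {30, 50, 75, 100, 150} to check that conclusions are stable in
   the tiling resolution.

See `docs/methods.md` for modeling assumptions, parameter defaults and
numerical conventions.

## Worked example

Generate a 4-class synthetic scene and run the full analysis:

```sh
histotex simulate --classes 4 --size 600 --seed 7 --out scene.png
histotex run --input scene.png --seed 7 --outdir results/
```

The run prints a JSON report (abridged):

```json
{
  "threshold": 187,
  "n_patches": 108,
  "k": 4,
  "methods": {
    "kmeans": {"silhouette": 0.9600, "davies_bouldin": 0.0571, "n": 108, "k": 4},
    "gmm":    {"silhouette": 0.9600, "davies_bouldin": 0.0571, "n": 108, "k": 4}
  },
  "agreement": {"ari": 1.0, "nmi": 1.0}
}
```

Reading: Otsu found threshold 187 (tissue below, glass above); 108
foreground patches of 50×50 px were kept; the elbow on the WCSS curve
(431.9 → 228.9 → 112.8 → 0.94 → flat) selects k = 4 — the collapse
after k = 4 marks four texture populations; both clustering methods
separate them cleanly (silhouette 0.96 near its maximum of 1, tiny
Davies–Bouldin) and agree perfectly with each other (ARI = NMI = 1.0).
`results/` additionally holds the foreground mask, per-patch features
and labels as CSV, the elbow curve, and one cluster overlay PNG per
method.

The patch-size sensitivity sweep:

```sh
histotex sweep --input scene.png --seed 7 --sizes 30,50,75 --outdir results/
```

```
 Size  K  Silhouette Score  Davies-Bouldin Index  ARI  NMI  n_patches status
   30  4          0.925818              0.108825  1.0  1.0        300     ok
   50  4          0.960012              0.057149  1.0  1.0        108     ok
   75  4          0.975835              0.035778  1.0  1.0         48     ok
```

The selected cluster count and the method agreement are stable across
patch sizes, which is the property the sweep is designed to probe.

Every step is also available as a library call (`histotex.run_pipeline`,
`histotex.generate_scene`, `histotex.compute_glcm`, …) and as separate
CLI stages (`segment`, `features`, `cluster`, `evaluate`).

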