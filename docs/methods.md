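# Methods

## Scope and model

`pedopress` analyzes static plantar-pressure rasters: color-coded maps
where the rendering convention is that deeper red encodes higher
pressure. The package treats raw red-band intensity as the pressure
proxy and never attempts to invert a vendor colormap into physical
units (kPa); every report carries a `pressure_proxy` field stating
this. Consequently all "pressure" quantities are in arbitrary summed
8-bit intensity units, and only *ratios* of them are interpreted.

## Segmentation

A pixel is pressure iff

    R >= T   and   R - max(G, B) >= m.

* `T` — by default the Otsu threshold of the red-band histogram, i.e.
  the cut maximizing between-class variance over all 256 candidates,
  ties broken toward the lower intensity so the marked set is the
  largest among equivalent optima. Otsu is the canonical
  histogram-based choice; a fixed threshold is available for
  reproducibility, and a degenerate (single-valued) histogram raises an
  error directing the caller to the fixed mode rather than guessing.
* `m` — red-dominance margin, default 30 intensity units. Pure
  graylevels have dominance 0 and orange zones (high R, high G) fall
  below the margin, so only genuinely red pixels survive. The value is
  a free parameter echoed into every report.

Enhancement runs threshold → area opening → closing → hole filling:

* **Area opening** removes components with area < `min_blob_area`
  (default 20 px — large enough to kill isolated speckle, small enough
  to keep a toe pad at the image scales the generator produces).
* **Closing** uses a disk of radius 2 px. The mask is padded before
  closing and the result is OR-ed with the input, so closing is
  guaranteed extensive (never removes a marked pixel) even at the
  image border.
* **Hole filling** marks every background region not connected to the
  image border, with 4-connected background flood — the standard dual
  of the default 8-connected foreground.
* Connectivity for components defaults to 8 (diagonal contact joins
  blobs); 4 is available.

Invariants maintained and tested: opening never adds pixels,
closing/filling never remove any, both are idempotent, and blob areas
always sum to the marked pixel count.

## Forefoot/hindfoot split and classification

The split row is the midpoint of the marked pixels' bounding box,
`floor((row_min + row_max + 1)/2)`; with toes at the top (the default;
a flag flips it, since exports do not state orientation), marked
pixels with row < split_row are forefoot. The "top 50% of detected
pressure" rule is ambiguous between per-pixel and per-component
assignment; the per-pixel split is the default because it makes
forefoot + hindfoot pressure equal the whole-mask pressure *exactly*
(integer conservation), which is the invariant everything downstream
leans on. A per-component mode (whole blobs assigned by centroid row)
is provided for cases where splitting a blob mid-pixel is
undesirable.

Foot type from the ratio ρ = P_f / P_h:

| Type | condition | reading |
|------|-----------|---------|
| 0 | ρ < 0.8 | hindfoot dominant |
| 1 | 0.8 ≤ ρ ≤ 1.2 | balanced |
| 2 | ρ > 1.2 | forefoot dominant |

The interval for Type 1 is closed on both ends (the boundary values
belong to "balanced"; Types 0 and 2 are strict). An empty hindfoot
with nonempty forefoot reports ρ = +∞ and Type 2; both regions empty
is an error.

## Synthetic images

The generator renders pressure blobs as filled disks whose red value
decays linearly from a peak at the center to 60% of the peak at the
rim, with green = blue = 10 inside blobs and a non-red background
(default (0, 0, 120)). The manifest — exact pressure pixel set,
per-region intensity sums, true ratio and foot type — is computed from
the noise-free rendering; seeded Gaussian noise is added afterwards
and clipped. Three rendering choices make the manifest exactly
recoverable under default segmentation parameters:

* blob reds stay in a high band, so the red histogram is strongly
  bimodal against the zero-red background and Otsu cannot land between
  two blobs of different brightness;
* the background red component is 0, so pixels that closing adds
  around ragged disk boundaries contribute nothing to pressure sums;
* forefoot blobs must lie strictly above the bounding-box midline and
  hindfoot blobs strictly below (validated; violating specs are
  rejected), so the pipeline's 50% split reproduces the generator's
  region assignment.

`ratio_targeted_spec` hits a requested ratio with two blobs: the
forefoot radius gives coarse control (sums scale with disk area) and
its peak intensity fine control; realized ground-truth ratios land
within about 1% of the target. Noise up to σ ≈ 5 leaves foot-type
recovery exact and ratio recovery well inside 5% relative error
(tests use 300 images at 96×64 px, a size chosen to keep the full
suite fast while leaving room for non-trivial blob geometry).

What the generator does *not* emulate: anatomical foot outlines beyond
a simple toes/pad/heel preset, partial-contact artifacts, colormap
gradations through yellow/green, or gait sequences. Passing tests
therefore demonstrate correctness of the operators and the
classification logic, not clinical performance on real exports.

## Clustering

* **Distances**: euclidean, manhattan, cosine (1 − cosine similarity;
  one zero vector is at distance 1 from everything, two zero vectors
  are undefined and raise), jaccard (vectors binarized at nonzero,
  then 1 − |∩|/|∪|; two all-zero vectors are at distance 0).
* **Standardization**: per-column z-score with the *population*
  standard deviation; constant columns raise an error naming the
  column.
* **k-means**: Lloyd iterations from seeded k-means++; assignment ties
  break toward the lowest centroid index; an empty cluster is
  re-seeded to the point farthest from its assigned centroid; stop
  when the largest centroid shift < `tol` (default 1e-8) or after
  `max_iter` (300). The inertia after every assignment step is
  recorded; both steps of Lloyd are non-increasing, so the trace is
  monotone by construction.
* **Elbow**: best of 5 restarts per k, plus one restart warm-started
  from the previous k's best centroids augmented with the farthest
  point — that start can only improve on the previous inertia, which
  guarantees (and the code asserts) a non-increasing curve.
* **Agglomerative**: scipy's linkage/fcluster stand behind the module
  surface for single/complete/average/ward; ward demands euclidean.
  Dendrogram cutting relabels clusters to 0..k−1.
* **Validity indices** are implemented from their definitions:
  silhouette s(i) = (b−a)/max(a,b) with singleton clusters scored 0
  (the common convention) and coincident clusters 0; Davies–Bouldin
  with mean member-to-centroid radii (coincident centroids raise);
  Dunn in two variants. The *standard* Dunn is min between-cluster
  point distance over max intra-cluster diameter (all-singleton
  clusterings report +∞). The *summation* variant evaluates
  (1/n_c) Σ_i max_{j≠i} (r_i + r_j)/d(c_i, c_j) — an alternative form
  that circulates in the applied literature and is structurally the
  Davies–Bouldin expression. Both appear in every
  `ClusterQualityReport` so results are comparable under either
  reading; `standard` is the default.

Indices default to euclidean distances on standardized features.

## Evaluation metrics

Classification: per-class precision, recall, F1 and Jaccard
(intersection-over-union) aggregated by macro (default), micro or
weighted averaging; Hamming loss as the fraction of misclassified
samples; multiclass Matthews correlation from the confusion matrix,
clamped to [−1, 1] against floating-point drift. Per-class ratios with
zero denominators are reported as 0 with a logged warning so reports
stay total. Macro is the default because the intended use (three
near-balanced severity classes) makes class-balanced averaging the
natural reading; the mode is recorded in every report.

Regression: MAE, MSE, RMSE, R² = 1 − SSE/SST (constant truth raises),
RMSLE on log(1+x) (values ≤ −1 raise), and SMAPE in the symmetric
0–200% formulation reported in percent, with 0/0 terms defined as 0.

## Numerical and testing notes

Every stochastic component takes an explicit seed and is bit-exact
reproducible; CLI outputs (PNG, CSV, JSON with sorted keys) are
byte-identical across reruns with the same configuration. Oracle
agreement tests pin the morphology stack to naive flood-fill
references on 200 random 64×64 masks, the validity indices to
per-definition loops within 1e-10 on sets of up to 50 points, the
metric reports to from-definition recomputation within 1e-12, and the
linkage heights to a naive Lance–Williams implementation; scikit-learn
serves as an additional independent cross-check where it implements
the same quantity.

## Known limitations

* Red-intensity sums are an uncalibrated pressure proxy; absolute
  values are not comparable across devices or colormaps.
* The 50% row split is purely spatial; no anatomical landmark
  detection (metatarsal heads, arch) is attempted, and midfoot is
  folded into the hindfoot.
* No left/right foot discrimination and no dynamic (roll-over)
  analysis.
* Divisive (top-down) hierarchical clustering is not implemented;
  dendrogram cutting of the agglomerative tree covers the supported
  use cases.
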