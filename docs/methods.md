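# Methods

## Problem and data model

The unit of data is a *focus*: one activation peak (x, y, z, mm) reported
by one fMRI study, tagged with its stereotactic space (Talairach or MNI), a
binary condition label (1 = branded, 0 = unbranded in the motivating
application; any two-condition contrast fits) and optionally the study's
subject count. Tables are plain pandas DataFrames; files are tab-separated
with header `study_id, x, y, z, space, label[, n_subjects]`, or Sleuth
text. Coordinates must be finite and within ±120 mm — a liberal envelope
around anything a stereotactic atlas can produce; violations raise named
errors rather than being clipped.

Talairach foci are mapped to MNI by the Lancaster tal2icbm affines (the
matrix inverses of the published icbm2tal fits; Lancaster et al., 2007).
Both the SPM-flavour fit (default) and the FSL-flavour pooled fit are
shipped, selectable by name; the conversion is idempotent on MNI input.

## ALE with permutation thresholding

Per study, each focus is stamped on the voxel grid (nearest voxel centre;
exact halves round toward negative indices) with an isotropic Gaussian
kernel truncated at ±3 sd and normalised to sum 1, so MA values are
per-voxel probabilities. Within a study foci combine by voxelwise **max** —
a study with many nearby peaks cannot certify convergence by itself.
Across studies the ALE map is the probabilistic union
`1 − Π(1 − MA)`, which is monotone in every MA value and bounded by
`max MA ≤ ALE < 1`.

Kernel width: with a known subject count n, FWHM follows the empirical
localisation-uncertainty model of the ALE literature — a fixed
between-template term combined in quadrature with a between-subject term
shrinking as 1/√n (≈ 12.6 mm at n = 5, ≈ 9.8 mm at n = 50). Without n the
default is a fixed 10 mm, configurable.

The null hypothesis is spatial randomness: each permutation relocates every
study's foci independently and uniformly over the brain-mask voxels
(per-study focus counts preserved) and recomputes the ALE map. Two
summaries are kept:

* the pooled mask-voxel values across permutations, whose (1 − p) quantile
  (p = 0.0001 by default) is the global cluster-forming threshold — voxels
  are exchangeable under uniform relocation, so one pooled cutoff suffices;
* each permutation's maximum suprathreshold component size, whose
  (1 − 0.05) quantile is the cluster-level FWE cutoff.

Components use 26-connectivity by default (6/18 selectable); surviving
clusters are reported with peak, size (always an exact multiple of the
voxel volume) and subpeaks (local maxima ≥ 8 mm apart). Quantiles use the
`higher` method and strict `>` comparisons, which makes the test slightly
conservative at small permutation counts. The null is Monte-Carlo rather
than an analytic histogram convolution: it matches the permutation
formulation directly and is verifiable by exhaustive enumeration on tiny
grids (with one study of one focus, each permutation's value multiset must
equal the kernel stamped at some mask voxel — a test asserts exactly
this).

Memory note: the null stores per-permutation mask values in float32
(n_perm × mask voxels), which keeps re-thresholding at a different
cluster-forming p possible without re-simulation.

## Brain mask

The default mask is an axis-aligned ellipsoid, semi-axes (72, 90, 65) mm
centred at (0, −16, 11) mm. A real MNI brain is posterior- and
superior-shifted relative to the origin; an origin-centred ellipsoid
either misses occipital cortex (reported foci reach y ≈ −105) or balloons
far outside the skull elsewhere. The chosen ellipsoid snugly contains the
coordinate ranges that published two-condition foci tables actually span,
including the occipital cluster centroids near y = −87. Any
`EllipsoidMask` or rasterized mask function can be substituted.

## Synthetic foci generator

The generator exists so the spatial stages can be validated by parameter
recovery: ground truth is known by construction. Each focus of a
label-L study picks an origin — planted cluster c with probability
`p_labelL[c]`, else background. Planted foci are trivariate normals around
the cluster centre, truncated to the mask by rejection (cap 1000 rounds,
so the within-mask law is exactly the stated mixture, not a clipped one);
background is uniform over the mask. Study sizes are uniform integers
nudged by ±1 to hit exact per-label totals, because printed-table
reproduction needs exact totals.

`brand_study_spec()` encodes the motivating study's shape: 26 + 39 studies,
exactly 679 + 733 = 1412 foci, three branded-biased plants at the
parahippocampal/lingual centroids and two unbranded-biased plants at the
inferior-parietal/superior-frontal centroids, with inclusion probabilities
mirroring the published per-cluster count shares (≈ 8% vs 4% of a
condition's foci in a biased cluster). The planted sd is 6 mm: that is the
localisation scatter of a *convergent site* (kernel scale). The wider
9–13 mm per-axis dispersions printed for fitted clusters describe whole
k-means cells, background foci included, and are recovered as outputs (the
fitted Voronoi cells show exactly such dispersions), not fed in as inputs.

What the generator does **not** emulate: publication bias, study-level
covariates, anatomically structured (non-uniform) background, or
kernel-width heterogeneity. Passing recovery tests therefore show the
algorithms work under the stated mixture model, not that real foci follow
it.

## k-means and the elbow rule

Foci are clustered in raw mm (axes share units; no standardisation) with
k-means++ and 10 restarts, best SSE kept, deterministic by seed
(scikit-learn's `KMeans`, including its empty-cluster relocation). The
elbow rule is formalised as: K* = (smallest K with SSE(K) ≤ ratio · SSE(1))
+ offset, defaults ratio = 0.1 and offset = 2 — i.e. "SSE down to one
tenth" marks the elbow and the selection takes the upper end of a
three-wide plausible range. SSE(1) is the total sum of squares (closed
form) when K = 1 is not scanned. The result is clamped to the scanned
range with a log message. Cluster ids `cl_0 … cl_{K−1}` follow internal
fit order and carry no anatomical meaning; display centroids are rounded
to integer mm while full precision stays on the model.

## Contingency contrast

Independence of cluster membership and condition is tested with Pearson's
X² (no continuity correction, df = K − 1); zero-total rows are dropped
from the test with a warning, a zero column total is an error. Per-cluster
evidence uses Haberman adjusted standardized residuals; for a two-column
table the two cells of a row are equal in magnitude and opposite in sign,
so one two-sided normal p-value per cluster (from the label-1 cell)
summarises it. Roles: p < 0.1 → dominant (sign decides direction);
p > 0.45 → overlapped, eliminated before classification ("flag 2");
otherwise undetermined. The 0.1 level matches the source analysis, which
treats p = 0.0727 as significant; no multiple-testing correction is
applied across the K residual tests, again matching the source (a Holm
adjustment would be a one-line wrapper but is deliberately not the
default).

A reproduction note: the bundled 26×2 count table reproduces the published
adjusted residuals to 4 decimals, the published role sets, and the
published 945/462/483 post-elimination counts exactly, but its Pearson
statistic is X² = 60.93 (G² = 62.46), whereas the source prints
X²(25) = 45.277 with p = 0.008 — a pair internally consistent with each
other but not with the printed counts. The statistic likely stems from a
different clustering run than the printed table; this package reports the
statistic its inputs imply.

## Cluster-ID classification

With one-hot cluster indicators as the only features, any calibrated
classifier can at best order foci by their cluster's label-1 proportion.
`proportion_score_auc` computes that ceiling exactly (all positive/negative
pairs, ties 0.5) and every cross-validated AUC is asserted against it
(≤ ceiling + 0.01, the slack covering fold-estimation noise).

Evaluation is stratified 5-fold cross-validation with pooled out-of-fold
probabilities; AUC is the rank-based Mann-Whitney form with tied pairs at
0.5 (mandatory here — one-hot data is massively tied and trapezoidal
variants disagree), AUC-PR is step-integrated average precision, logloss
clips probabilities to [1e−15, 1 − 1e−15]. Rows are canonically sorted
(features, then label) before folding, making all metrics exactly
invariant to input row order. The model menu is fixed — XGBoost
gradient-boosted trees (defaults, gain importances), random forest,
logistic regression — with an optional seeded random hyperparameter search
(≤ 20 draws) selecting on CV AUC. An AutoML leaderboard is deliberately
not reproduced; absolute importance scales are implementation-specific, so
only max-1-scaled importances and ranks are contractual.

## ROI cubes

For a discriminative cluster, `sigma_range` reports centroid ± 1 sample sd
per axis (diagnostic; degenerate spread flagged), and the final ROI is an
axis-aligned cube of fixed edge (default 18 mm) centred on the centroid.
The two artifacts are deliberately decoupled: the source fixes an 18 mm
edge even though its ±1σ ranges span 21–26 mm, so the package emits both
without asserting a reconciliation. Rasterization includes a voxel iff its
centre lies inside any cube (inclusive bounds) — deterministic and
checkable against brute-force point-in-box enumeration.

## Numerical and testing choices

* Every stochastic stage takes an explicit integer seed; identical seeds
  give byte-identical artifacts (the pipeline manifest records seeds,
  parameters, versions and row counts).
* Statistical property tests (FWE calibration, type-I rates, null AUC,
  recovery rates) run at reduced scale — 4 mm voxels, 200 permutations,
  20–50 seeds — chosen so each property is still a high-power check: e.g.
  the FWE calibration bound allows at most 6/50 null survivals (binomial
  99% band around 0.05), and the null-AUC band of ±0.05 is ~12 standard
  errors wide for the 20-seed mean.
* Thresholds stated by the analysis itself (0.0001, 0.05, 0.1, 0.45, 5
  folds, 18 mm, 1000 permutations) are defaults, not constants; the config
  file and every function expose them.

## Known limitations

* The ellipsoid mask is a geometric stand-in; anatomical masks must be
  supplied by the user as rasterized predicates.
* The permutation null stores all mask-voxel values; at 2 mm and 1000
  permutations this is ~1 GB of float32 and dominates memory.
* Only binary condition labels are supported; no conjunction/subtraction
  ALE, no Fisher-exact contrast, no anatomical labelling of coordinates,
  and no cognitive decoding of the resulting ROIs.
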