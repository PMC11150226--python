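# Methods

`habitatpipe` reimplements, as a tested pipeline over synthetic data, an
analysis that predicts 6-month durable clinical benefit of immunotherapy
(PFS6: progression-free survival exceeding 6 months) in non-small-cell lung
cancer from a pre-treatment CT scan.  The real patient cohort behind this
kind of study is not publicly deposited, so the pipeline ships with a
synthetic CT cohort generator with known ground truth; every claim the test
suite makes is therefore a claim about the *machinery*, not about clinical
performance on real patients.

## The synthetic cohort

Each patient is a 48³-voxel volume (1 mm isotropic) holding an ellipsoidal
tumor of at least 500 voxels (semi-axes drawn from 8–12 voxels) in a noisy
low-intensity background with a mild smooth additive bias field (low-order
upsampled noise, amplitude 10), so that the VOI-based normalization stage has
real work to do.

The tumor is partitioned into `true_k` contiguous irregular sub-regions:
Voronoi cells of interior seed points, Lloyd-relaxed for five iterations so
cell sizes are comparable.  Habitat `h` draws voxel intensities from
N(mean_h, sd·scale_h) with means 60/120/180 (Hounsfield-like units),
base SD 10 and texture scales `geomspace(0.4, 2.5, k)`.  The per-habitat
scale matters: it gives each sub-region a distinct *local-entropy* signature
in addition to a distinct mean, which is what tumor-habitat analyses assume.
With a single shared SD the entropy channel carries no habitat structure at
all, and a within-cluster-sum-of-squares argument (confirmed empirically)
shows that z-scored two-channel K-means then prefers splitting the nuisance
entropy axis over separating the intensity modes — no parameter setting of
the clustering rescues that geometry.

One habitat (by default the brightest, habitat 3) carries the outcome
signal: for non-responders its mean is shifted by `effect_size` SD units and
its SD inflated by the factor `1 + effect_size/2`, so the classes separate in
both the intensity and the entropy channel.  With `effect_size = 0` the
generated volumes are draw-for-draw identical across classes — the
exchangeable null.

Outcomes: PFS is log-normal (σ_log = 0.5) with median 12 months for
responders and 3 for non-responders, truncated to the correct side of the
6-month boundary so the PFS6 label is always consistent with an observed
event; OS is PFS plus an independent log-normal gap (median 8 months).  PFS
and OS are censored independently with probability `censor_rate` (default
0.2) at a uniform fraction of the true time.  Default cohort: 60% responders
(matching the prevalence such immunotherapy cohorts report).

A second rater's delineation is emulated by toggling up to
`rater2_perturb_voxels` (default 15) boundary voxels of the true mask,
guaranteeing Dice > 0.5 — the structure the ICC reliability filter needs.

**What the generator does not emulate:** scanner/kernel heterogeneity across
centers, contrast phases, respiratory artifacts, non-ellipsoidal growth and
infiltration, or any real correlation structure between radiomic features
and survival beyond the single planted habitat.  Passing tests demonstrate
that the pipeline recovers *planted* structure and stays at chance on *null*
data; they do not validate clinical performance.

## Preprocessing

Volumes and masks are resampled to 1 mm isotropic (trilinear / nearest
neighbour; output axis length `round(n·s_in/s_out)`), then intensities are
linearly mapped to 0–255 using min/max statistics **inside the VOI only**
(clipped outside), and kept real-valued until radiomics discretization.
VOI-based scaling makes the map invariant to affine intensity transforms and
to background content.  A constant VOI maps to 0 by convention.

## Habitat mapping

Per-voxel features are (normalized intensity, local entropy).  Local entropy
is the Shannon entropy (bits) of the in-mask intensities in the cubic window
of radius 1 (3×3×3), histogrammed into 32 equal-width bins over [0, 255];
background voxels are excluded from every window so the VOI edge inherits no
background texture.  Radius 1 rather than a larger window is deliberate: at
the habitat diameters this cohort produces (~12 voxels), a 5×5×5 window
blurs sub-region boundaries enough to pull habitat recovery below the target
ARI (0.72 vs 0.83 median, measured).  The window radius and bin count are
exposed in the config.

For the per-patient label assignment the entropy map is additionally
box-smoothed (3³, mask-aware) before clustering: the radius-1 plug-in
entropy estimator averages only ~27 samples and its variance otherwise
dominates the z-scored channel.  Voxels are then clustered by Lloyd K-means
(k-means++ init, fixed seed, features z-scored per patient — intensity spans
0–255 and entropy 0–5, so raw Euclidean distance would ignore entropy), and
clusters are renumbered by ascending centroid intensity (ties: entropy, then
size) so that "habitat 1 … habitat k" means the same thing in every patient.

The number of habitats is a single cohort-level choice made on the training
split only, by Monti consensus clustering of a pooled voxel sample (up to
~100 voxels per patient, 1200 items total, 20 resamples at 80% item
fraction) scanning k = 2..10: the consensus matrix is the co-clustering rate
among co-sampled pairs, and the selected k is the smallest one after which
the relative gain in consensus-CDF area falls below 0.10; PAC (the share of
consensus values in (0.1, 0.9)) is reported per k as a diagnostic.  The
k-scan runs on the *raw* voxel features (no entropy smoothing): smoothing
makes the habitat-boundary voxels a semi-stable intermediate cluster whose
delta-area at k = 4 (~0.10) straddles the elbow threshold; on raw features
the k = 3 elbow is clean.  This near-threshold fourth cluster is a real
property of boundary voxels, and the one seed in ten where the scan returns
k = 4 instead of 3 is exactly this effect.

## Radiomic features

93 intensity/texture features per region — 18 first-order statistics plus
GLCM (24), GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5) — computed from
first principles on each habitat and on the whole tumor, plus 14 shape
descriptors on the whole tumor only.  Conventions (IBSI leaves aggregation
open; all are regression-tested against exhaustive brute-force oracles):

* discretization: fixed bin number (32) over the region's own [min, max];
  a constant region collapses to one level;
* GLCM and GLRLM merge the 13 unique 3D directions at distance 1
  (co-occurrences symmetrized); GLRLM run percentage is normalized by
  `n_voxels × n_directions`;
* zones (GLSZM) and dependencies (GLDM, α = 0) use 26-connectivity;
* surface area and mesh volume come from a marching-cubes mesh of the padded
  mask; maximum diameters from convex-hull vertex pairs; axis lengths are
  4·√λ of the PCA eigenvalues of the physical voxel coordinates;
* names follow `original_<family>_<FeatureName>`.

An empty habitat (possible: per-patient K-means need not populate every
canonical habitat) yields an all-missing vector; missing values are imputed
with training-column medians inside the selection cascade.

## Deep features

A volumetric ResNet-18-style network — stem convolution (stride 2), max
pool, four residual stages of two basic blocks at widths 64/128/256/512 with
stride-2 downsampling, global average pooling — produces exactly 512
features (`deep_000`…`deep_511`) from the whole-tumor ROI (bounding box with
10% margin, background zeroed, intensities scaled to [0, 1], trilinearly
resized to the configured input shape; 32³ throughout the analyses here,
64³ by default).  The forward pass is plain numpy (im2col convolutions), so
it is bit-reproducible and needs no deep-learning runtime.  Weights are
drawn once from a He initializer under a fixed seed; residual sums are
scaled by 1/√2 to keep activation variance stable without normalization
layers.  These are untrained random-projection features — a documented
limitation, not a claim of learned representation; externally trained
weights can be loaded from an `.npz` via `weights_mode="file"`.  Tests
verify that the descriptor still separates planted classes (random
projections preserve mean-intensity and texture shifts).

## Feature selection

Per model source, in order, on the training split only:

1. **ICC filter** — ICC(2,1) (two-way random effects, absolute agreement,
   single rater; the radiomics convention) between the two raters' feature
   tables; keep ICC ≥ 0.75.  Deep features have no second-rater analogue and
   pass through.
2. **z-score** — means/SDs fitted on training, applied to both splits;
   zero-SD columns dropped.
3. **Pearson pruning** — pairs with |r| > 0.9 processed in descending |r|;
   the member with the smaller outcome |t| is dropped (ties: lexicographic).
4. **Welch t-test** — two-sided, keep p < 0.05, no multiplicity correction.
5. **LASSO** — L1-penalized logistic regression over a 40-point log-spaced λ
   grid (data-driven λ_max from the KKT condition), λ chosen by stratified
   5-fold cross-validated deviance with the 1-SE rule.

One methodological choice deserves emphasis: the λ-selection CV *repeats the
Welch screen inside each fold* (on fold-training rows only).  Screening on
the full training set first and then cross-validating only the LASSO looks
innocent but is not: the screened null features are in-sample correlated
with the labels, the CV deviance inherits that bias, and on label-permuted
data the cascade then reports a median of ~7 selected features (the
canonical R implementation, `cv.glmnet` at `lambda.1se` after the same
screen, reports ~10).  With the fold-internal screen the permuted-label
selection collapses to 0 while planted-feature recovery is unchanged.
Relatedly, the fallback from the 1-SE λ to the deviance-minimizing λ (used
when the 1-SE solution is empty) engages only when the CV minimum beats the
intercept-only deviance by more than one standard error; otherwise the empty
selection stands and the downstream model degrades to the no-information
classifier (constant score = training prevalence) rather than being handed
noise features.

## Models and evaluation

The model roster mirrors the study design: one RBF-SVM per habitat, for the
whole tumor and for the deep features, plus each habitat fused with the deep
features, all habitats + deep, and whole + deep (14 models at k = 5).
Fusion concatenates the raw column pools and re-runs the full cascade, so
the LASSO arbitrates across sources.  (C, γ) are tuned by mean AUC over
stratified 5-fold CV on a log grid (C ∈ {0.1, 1, 10, 100},
γ ∈ {10⁻³…1}), ties toward the first grid point; the final SVC is refit on
the full training split with Platt-scaled probabilities (sigmoid calibration
on cross-validated decision values).  The positive class is the
**non-responder**, so the model output reads as progression risk.

Test-set metrics are computed at the *training* Youden cutoff
(max sensitivity + specificity − 1, lowest cutoff on ties): accuracy,
precision, recall, F1, MCC, PLR = sens/(1−spec), NLR = (1−sens)/spec, and
trapezoidal AUC with a stratified-bootstrap 95% CI (500 replicates in the
bundled analyses; 2000 by config).  Undefined ratios surface as NaN with a
recorded reason, never as silent zeros.

Survival: the same cutoff splits test patients into high/low-risk groups;
Kaplan–Meier curves (lifelines) and the two-group log-rank test are reported
for PFS and OS.  Decision-curve analysis reports net benefit
TP/N − FP/N·t/(1−t) against treat-all and treat-none references on a
0.01–0.99 threshold grid.

## Explanation

Kernel SHAP, written from first principles: coalitions weighted by the
Shapley kernel (M−1)/(C(M,s)·s·(M−s)), missing features marginalized over a
background table (training rows, medoid-capped at 100), and a weighted least
squares with the efficiency constraint φ₀ + Σφ = f(x) eliminated exactly —
local accuracy holds by construction.  For M ≤ 12 features coalitions are
fully enumerated and the result equals exact Shapley values (tested against
a 2^M enumeration oracle at 1e-4); larger M uses kernel-distributed
sampling.  The explained output is the calibrated non-response probability;
the summary ranks features by mean |φ|.

## Determinism and seeds

Everything is a pure function of the run config and one global seed; stage
seeds derive from it as `seed·10007 + stage_offset (mod 2³¹)`.  Two runs
with the same config produce byte-identical selection reports and identical
metric tables (regression-tested, in memory and through the disk pipeline).

## Problem sizes used in the bundled analyses and tests

The demo analysis uses 60 patients at 48³ voxels with a 32³ deep-feature
ROI; the acceptance suite uses 3 end-to-end seeds at n = 240 (160/80
train/test split, effect 1.5 SD) and n = 120 (effect 0), 10 seeds for the
consensus/ARI and cascade-recovery checks at n = 12 patients and n = 160
rows respectively, and 100 random regions for the texture oracles.  The
habitat-geometry checks generate their cohorts at `effect_size = 0` because
the separated regime they probe fixes every habitat's SD at 10, which the
outcome dial would otherwise override for non-responders.

## Known limitations

* The deep features are untrained random projections; with published weights
  the extractor accepts them, but nothing here speaks to what a *trained*
  3D ResNet would add.
* The consensus elbow at the true k sits near the 0.10 delta-area threshold
  (boundary-voxel effect above); about one seed in ten selects k+1.
* Shape features use voxel/mesh approximations, not the exact IBSI mesh
  aggregates; they are internally consistent and tested on analytic shapes.
* The survival generator draws OS as PFS plus noise; no competing risks, no
  cure fraction.
* Printed-table identities aside, nothing in this package reproduces the
  original cohort's numerical results — those data are not public.
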