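# Methods

## Problem and pipeline

`fcage` estimates a person's age — and their age *group* — from resting-state
functional connectivity. The input to the models is the static functional
connectivity (sFC) matrix: for one subject with parcellated BOLD time series
X ∈ ℝ^{T×p} (T timepoints, p regions), the sFC is the p×p matrix of pairwise
Pearson correlations r_ij between regional time courses. Two representations
feed downstream consumers:

* the full symmetric matrix (unit diagonal), used as a single-channel image
  by the convolutional models;
* its strictly-lower-triangle vectorization of length p(p−1)/2, enumerated
  row-major over rows 1..p−1 (frozen for reproducibility), for classical
  feature-vector consumers.

Subjects are binned into four closed age groups: young [20, 40], adult
[41, 55], middle-old [56, 69], old [70, 88]. Ages outside [20, 88] are
excluded at ingest. Feature standardization (per-edge z-scoring across
subjects) is always fitted on the training set only; zero-variance features
(e.g. the constant diagonal) pass through unscaled and are logged. The
deep models consume the standardized matrices by default; a raw-correlation
path exists for comparison.

## Architectures

Both trunks operate on p×p single-channel matrices, 3×3 kernels, ReLU
activations, batch size 16:

* **vgg5** — conv(16) → maxpool → conv(32) → maxpool → conv(64) → conv(64)
  → global average pool → FC(64) → head.
* **resnet5** — conv(16), then four residual blocks at channels
  (16, 32, 64, 64) with strides (2, 2, 2, 1); each block is two 3×3
  convolutions with an identity shortcut, or a strided-subsample +
  1×1-projection shortcut when shape changes; then global average pool →
  FC(64) → head.

The classification head is a 4-way softmax; the regression head is a single
linear unit (age in years). All weights are He-normal initialized
(N(0, 2/fan_in), biases zero), bit-reproducible under a seed.

The channel schedule is deliberately lean — it is frozen in `ModelSpec` and
sized so that full end-to-end experiments on the default synthetic cohort
(below) run in minutes on a laptop CPU; wider schedules are a config change,
not a code change.

### Attention

Soft attention is attached to layers 3 and 4 of either trunk, before the
final (global) pooling. At an attention layer with feature map positions
x_i ∈ ℝ^c:

1. two learned projections M(x) = W_m x and N(x) = W_n x map channels c to
   d = ratio·c, with ratio 1/2 at the first attention layer and 1/4 at the
   second;
2. the per-position compatibility score is
   s_i = (⟨M(x_i), mean_j N(x_j)⟩ + ⟨M(x_i), W_g g⟩) / √d,
   where g is the global-average-pooled trunk output (computed from the
   trunk alone, so there is no circularity with the head);
3. λ = softmax(s) over spatial positions — nonnegative, summing to 1;
4. the attended descriptor is the λ-weighted sum of the original
   per-position features.

The descriptors from both attention layers are concatenated with g before
the FC head. Two numerical choices depart from the plain "sum over pairs"
formulation: the pairwise term uses the **mean** over j rather than the sum,
and scores are scaled by 1/√d. Both keep softmax inputs O(1) regardless of
feature-map size; an unnormalized sum over 64 spatial positions saturates
the softmax at initialization and stalls the attention gradients.

Two ablations exist: `attention=False` removes the blocks entirely, and
`uniform_attention=True` keeps the descriptor pathway but forces λ uniform,
which isolates the effect of the learned weights (and differs in parameter
count by exactly the W_m, W_n, W_g matrices).

## Training protocol

* Stratified 80:20 train/test split over age groups, with sex as a secondary
  stratum when the manifest provides it (degrading to group-only when a
  group×sex cell has fewer than 2 subjects). Per-group test counts are
  round(0.2·n) via largest-remainder allocation, so they deviate from 20%
  by at most one subject.
* Optional stratified 5-fold cross-validation (scikit-learn fold
  assignment), each fold trained from a fresh initialization.
* Loss: cross-entropy on logits (classification), mean squared error
  (regression). Optimizer: Adam, lr 1e-3, no weight decay. These are
  engineering defaults — standard companions of softmax/linear heads — not
  claims inherited from any protocol. Default 100 epochs for library use;
  the packaged end-to-end experiments use 20 epochs, which is past the
  loss plateau on the default synthetic cohort.
* Metrics: accuracy (percent) with per-class confusion counts; MAE, RMSE,
  and r². r² is the coefficient of determination 1 − SS_res/SS_tot (can be
  negative); the squared Pearson correlation is logged alongside because
  both conventions circulate in the brain-age literature.
* Everything (init, shuffling, splits, folds) is seeded; two runs with the
  same seed produce identical weights.

## Integrated gradients

Attribution of a prediction to connectome edges uses the straight-path
Riemann approximation with m steps,

IG_i(x) ≈ (x_i − x′_i) · (1/m) Σ_{k=1..m} ∂F(x′ + (k/m)(x − x′))/∂x_i,

with the all-zero matrix as default baseline x′. For classification, F is
the softmax probability of the predicted (or requested) class; a flag
switches to the pre-softmax logit, which is common practice but changes
the scale of the attributions. For regression, F is the predicted age.

Numerical choices:

* default m = 50; if the completeness residual |Σ IG − (F(x) − F(x′))|
  exceeds 5% of |ΔF|, m doubles (up to 8×) before returning;
* because the input is symmetric, positions (i, j) and (j, i) describe the
  same undirected edge; the attribution matrix folds the two triangles
  (sum) and mirrors, so entry (i, j) carries the full edge attribution.
  The raw (unfolded) sum is kept on the result object as `total` for
  completeness checks.

Aggregations: per-group mean attribution matrices (computed from each
group's mean connectivity matrix); signed node strengths per ROI
(positive = Σ max(a_ij, 0), negative = Σ min(a_ij, 0) over incident edges,
net = positive + negative, diagonal excluded); an edge-contribution table
that omits edges whose |strength| stays below 0.2 in every age group; and
per-network distribution summaries (mean, sd, quartiles per group).

### Age-trajectory labels

A per-ROI profile of four ordered group values (young → old) is labeled,
with tolerance τ = 0.01 (configurable):

* **inverted_U** if the maximum sits at adult or middle-old, the young end
  is lower by more than τ, and the old end is strictly lower;
* otherwise **decreasing** if the profile is non-increasing within τ and
  the total young→old decline exceeds τ;
* otherwise **flat**.

The inverted-U test is applied first; a profile whose maximum is at young
can therefore still be "decreasing" despite a sub-τ mid-life bump.

For *recovering planted trajectories* the default strength profile is the
**attribution-selected group-mean connectivity**: edges whose mean
|attribution| passes the 80th percentile are retained, and each node's
per-group strength is the sum of its retained raw correlation values. The
alternative — trajectories of the signed IG node strengths themselves — is
implemented behind a flag but is not the default: the sign of ∂F/∂edge can
invert a correlation trajectory (a declining edge with a negative gradient
yields an increasing attribution), which makes raw-IG trajectories an
unreliable readout of how *connectivity* changes with age. On the default
synthetic cohort the masked-connectivity readout recovers 32/32 incident
ROIs, the raw-IG readout 4/32.

## Synthetic cohort generator

The generator emulates the structure such a study measures without any
real data: n subjects with ages uniform over [20, 88] (a preset reproduces
the reference group sizes 172/152/154/160 at p = 100), each with a T×p
multivariate-normal time series whose correlation structure varies with age:

* 8 disjoint **decreasing** edges: r linear from 0.6 at age 20 to 0.2 at 88;
* 8 disjoint **inverted-U** edges: r quadratic, peaking at 0.6 at age 60
  (inside the middle-old bin) and falling to 0.2 at the farther endpoint;
* 8 **null** edges constant at r = 0.3; all remaining edges 0.

Defaults: n = 600, p = 32, T = 200, observation-noise sd 0.2 (white noise
added to unit-variance signals, attenuating observed correlations by
1/(1+σ²) ≈ 0.96). Each planted node carries at most one trajectory edge
plus at most one null edge, keeping every row's off-diagonal mass below 1,
so the target matrix is strictly diagonally dominant and the
nearest-PSD repair (eigenvalue clipping at 1e-6, unit-diagonal rescale) is
a verified no-op under the defaults; it exists for user-supplied edge sets.

These defaults are the package's study conditions: strong enough planted
signal for a small CNN to recover the age structure, at a problem size
(p = 32) where the full 3-seed experiment — chosen as desk-scale — runs in
a few minutes of CPU. What passing recovery shows is that the machinery
(extraction → standardization → training → attribution) finds signal that
is present by construction. It does **not** show real-data performance:
the generator has no hemodynamic autocorrelation, no scanner drift, no
motion artifacts, no network-level covariance beyond the planted edges,
and a far higher signal-to-noise ratio than real aging effects.

## Known limitations

* The numpy NN engine is CPU-only and float64; it is sized for p ≤ 100
  matrices and desk-scale cohorts, not for large imaging studies.
* Attention score aggregation (mean over pairwise projections plus a global
  term) is one member of a family of defensible readings of the mechanism;
  the ablation flags exist precisely so its contribution can be measured.
* The 0.2 edge-table threshold and τ = 0.01 trajectory tolerance are
  conventions, configurable at the call sites.
* Classification attribution on the softmax probability saturates when the
  model is very confident; the logit flag is the remedy.
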