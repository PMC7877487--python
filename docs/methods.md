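# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `morphnet`, and what the test suite does and does
not establish.

## Network construction

For one subject, the gray-matter voxel values inside each retained atlas
region are a sample from that region's GM-value distribution. Each sample is
smoothed with a Gaussian kernel and discretized:

- **Sample source.** Densities are estimated from the *voxel values within
  each region*, evaluated on one grid shared by all regions of the subject.
  This is the only reading under which a Kullback–Leibler divergence between
  two regions of the same subject is well defined (a per-region summary
  value would give each region a point mass), and it is the construction
  used by the individual-morphological-network literature this edge
  definition comes from.
- **Grid.** 128 equally spaced points spanning the pooled min–max of the
  subject's retained-region values, padded by 3 of the largest per-region
  bandwidth so that no kernel mass is clipped. 128 points keep the
  discretization error of the divergence far below the between-region
  differences at desk scale; the brute-force oracle test pins the
  implementation at G = 16 to 1e-10.
- **Kernel and bandwidth.** Gaussian kernel with Silverman's rule per region
  (0.9·min(sd, IQR/1.34)·n^(−1/5)) by default; a fixed bandwidth can be set
  in `NetworkConfig` for reproducibility experiments. A zero-variance sample
  falls back to a small fixed bandwidth (1e-3 of the value scale) with a
  `RuntimeWarning` — a constant region has no scale of its own.
- **Probability floor.** 1e-10 is added to the discretized density before
  renormalization so the divergence logs stay finite at grid points where no
  kernel reaches; the floor is far below any real probability mass at
  G = 128 and is applied identically in the brute-force oracle.
- **Diagonal and symmetry.** KLS(P, P) = 1 is set exactly rather than
  computed; the off-diagonal part is symmetrized against floating-point
  asymmetry of the pairwise evaluation (the divergence itself is symmetric
  analytically).
- **Ordering.** Regions are ordered by ascending atlas label after
  exclusion; this fixed region↔index map is what lets Grad-CAM cells be
  reported as named region pairs.

The vermis exclusion drops labels 109–116 (8 parcels), taking the
116-region parcellation to the 108×108 matrix used everywhere downstream.

## Classifier

Five serial bottleneck residual stages (1×1 reduce → 3×3 stride-2 → 1×1
expand; projection skip with 1×1 stride-2 convolution wherever resolution or
width changes; batch normalization after every convolution, before the
activation; no dropout), then global average pooling and a single sigmoid
unit. Spatial sizes run 108 → 54 → 27 → 14 → 7 → 4 with "same" padding
(output = ceil(n/2)).

- **Channel widths** default to (16, 32, 64, 128, 256) with bottleneck
  reduction 4. The widths are a declared design choice: they keep the model
  trainable on one CPU at 108×108 input while preserving the
  five-bottleneck, stride-2 design.
- **Implementation.** The layer stack (convolution via kernel-offset
  matmuls, batch norm, Adam, explicit backward passes) is written in NumPy.
  Every backward pass is checked against central finite differences in the
  test suite, in both training and inference batch-norm modes.
- **Loss.** Binary cross-entropy −(y ln ŷ + (1−y) ln(1−ŷ)) with ŷ clamped to
  [1e-7, 1−1e-7]; the training loop computes the numerically equivalent
  logits form.
- **Hyperparameter defaults** are Adam with learning rate 1e-5 and
  minibatch 32. Desk-scale runs (examples, pipeline defaults, acceptance
  script) use learning rate 1e-3 with ≤ 12 epochs and early-stopping
  patience 4: at a few hundred gradient steps the 1e-5 rate cannot move the
  weights appreciably, so the scaled-down schedule trades the original
  step size against the shortened horizon while keeping the optimizer,
  batch size, loss and architecture fixed.
- **Batch-norm recalibration.** After early stopping restores the best
  weights, running statistics are recomputed in one pass over the training
  data (momentum 1, averaged across batches). Running statistics otherwise
  trail the weights, which distorts eval-mode inference badly at small
  sample sizes.
- **Cross-validation.** Per repeat, subjects are randomly, equally
  partitioned into `n_folds` groups (sizes differ by ≤ 1); the last group is
  the test set and the remaining groups are repartitioned into `n_folds`
  subgroups of which one (chosen at random) validates early stopping. Each
  repeat re-randomizes the partition. Fold assignments are hashable so CNN
  and baselines can be asserted to share them. Test-group IDs never enter
  training or validation; the suite audits this.

## Grad-CAM

Channel weights are the spatial means of ∂score/∂A^k at the fifth stage's
output (4×4 resolution); the map ReLU(Σ_k α_k A^k) is bilinearly upsampled
to 108×108. The class score is the pre-sigmoid logit for ASD (its negation
for TC). With a global-average-pool + linear head the weights have the
closed form α_k = w_k / 16, which the tests use as an independent oracle
against the generic backward pass.

- **Fusion** is the element-wise mean over the maps of correctly classified
  ASD test subjects (across repeats), the minimal aggregate; the fused map
  is symmetrized as (M + Mᵀ)/2 because edges are unordered pairs while the
  CNN is not constrained to be symmetric.
- **Selection**: mean + k·SD threshold (k = 3) computed over the strict
  upper triangle of the fused map — the diagonal is constant 1 in the input
  and self-similarity is not a connectivity. Edges strictly above the
  threshold are reported; the selection is invariant to positive rescaling
  of the maps.

## Evaluation

ASD is the positive class: sensitivity is the ASD detection rate. Confusion
metrics threshold the sigmoid score at 0.5 (SVM margins at 0); metrics with
an empty denominator are reported as missing, never as 0. AUC comes from the
score ranking (scikit-learn), cross-checked against the O(n²)
positive-vs-negative pair count in the tests.

Baselines consume the 11,664 flattened features under the CNN's fold plan,
fitting on training + validation subjects and scoring the test group:
random forest (300 trees), RBF-SVM on standardized features, XGBoost
(200 × depth-3), and an autoencoder (default 11,664 → 512 → 64 with a linear
bottleneck, reconstruction-pretrained on standardized features, frozen
encoder + logistic head; desk-scale runs shrink the hidden sizes).

**Permutation test.** Per iteration, a uniformly random ⌊0.2·n⌋ subset of
labels is inverted and the classifier refit; the p-value is
(1 + #{null ≥ observed}) / (1 + n_perm). Full label permutation is available
behind a flag. Because thousands of CNN refits are not desk-scale, the
default refit target is a logistic surrogate on the flattened features. Two
properties of the surrogate matter for calibration and were chosen for
statistical reasons, not convenience: (i) its statistic is stratified
3-fold cross-validated accuracy, which has granularity 1/n — a coarse
holdout accuracy produces heavy ties with the null draws, and the ≥-count
then biases p upward; (ii) the logistic head uses balanced class weights,
because label flipping unbalances a balanced cohort and an
imbalance-sensitive classifier would score systematically *higher* under
the null than on the original balanced labels. With both in place the null
p-values are approximately uniform (Kolmogorov–Smirnov check in the suite).

## Synthetic study conditions

The generator emulates the preprocessed inputs of a multisite structural-MRI
study: a 116-region parcellation (compact regions grown by a few Lloyd
steps from seeded centroids inside an ellipsoidal mask; every region ≥ 30
voxels) and per-subject GM maps. Within region r, voxel values are
Gamma(k_r, θ_r) — positive and right-skewed like GM density values — with
k_r ~ U(3, 6), θ_r ~ U(0.08, 0.15) fixed per cohort seed, plus:

- additive per-site offsets on θ (default three sites at 0, ±0.008),
  emulating multisite heterogeneity without confounding the group labels;
- per-subject log-normal jitter on θ (sd 0.05), giving within-group
  between-subject variability so that group tests are non-degenerate;
- additive voxel noise (sd 0.02, clipped at 0);
- the group effect: θ multiplied by (1 + shift) in affected regions for ASD
  subjects. The default affected set is six frontal–cerebellar region pairs
  (labels 1–6 vs 103–108); shift 0.5 is the generator default and shift 1.0
  is used as the "strong effect" condition. The effect model is a stand-in
  for case–control differences, not a claim about ASD biology.

What the generator does **not** emulate: T1w image formation, registration
error, tissue-segmentation artifacts, age/sex effects on GM, or
site-by-group interactions. Passing tests therefore show that the pipeline
recovers distributional group differences planted at the voxel level of a
parcellated volume — they do not certify performance on real ABIDE-style
data, whose headline accuracies depend on that external dataset.

## Problem sizes in tests and the acceptance script

Chosen as the package's own desk-scale study design: signal recovery uses a
200-subject cohort (48³ grid, strong shift, 5-fold plan, 3 repeats, 12
epochs); the null calibration uses 20 independent 30-subject cohorts (32³
grid, 3 folds, 5 epochs) pooled to ~200 held-out predictions, giving a
Monte-Carlo AUC standard error of ~0.03 against the ±0.05 acceptance band;
permutation calibration uses 50 cohorts × 99 permutations. The acceptance
script runs a 60-subject strong-effect study plus the same null design and
reports structural numbers (108, 11,664, 8) from a single subject.

## Known limitations

- Training the CNN at the original schedule (lr 1e-5, hundreds of epochs,
  1000+ subjects) is supported but not exercised by the suite.
- The autoencoder baseline is weak at n ≲ 50 with 11,664 features; its
  latent code needs either more subjects or a dominant signal direction to
  carry class information (this mirrors its middling standing among the
  baselines generally).
- The label-flip null (as opposed to full permutation) keeps 80% of the
  label information in every null draw; with real signal present the null
  accuracies are therefore optimistic relative to a fully permuted null,
  which makes the reported p-values conservative in the direction of the
  original protocol.
- `ConnectivitySelection` reports edges of the fused map only; per-subject
  selection variability is not quantified.
- At desk scale the fused Grad-CAM map is an upsampled 4×4 field and has no
  3-SD tail, so the mean + 3SD selection can be legitimately empty; the
  localization tests therefore work on the full edge ranking
  (`rank_edges`), where enrichment of the planted region pairs in the top
  edges is checked against a hypergeometric null.
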