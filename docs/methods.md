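# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## The classification task

Input is an RGB dermoscopic image of a skin lesion; output is a binary
call, melanoma (`MEL`, the positive class) versus benign (`BEN`).  The
benign subtypes nevus (`NV`) and seborrheic keratosis (`SK`) are folded
into `BEN` when requested (`map_benign`); they are not accepted as raw
labels, which keeps the core task strictly binary.

## Data pipeline

**Splitting.**  Datasets are split 70/10/20 into train/validation/test,
stratified per class.  Within a class of size *n* the validation and
test sets receive round-half-up(0.10·n) and round-half-up(0.20·n)
records; the remainder goes to train.  Membership is a seeded uniform
shuffle, so a seed fully reproduces a split.  Curated archives of this
kind do not publish per-image assignments, so no attempt is made to
reproduce any particular historical split.

**Duplicate elimination.**  Archives accumulate re-submissions of the
same lesion.  Candidate pairs are scored by the normalized
cross-correlation of their grayscale images (luma weights
0.299/0.587/0.114), i.e. the Pearson correlation of the two pixel
grids, each centered by its scalar mean intensity:

    corr(I, I') = Σ_xy (I−h̄)(I'−h̄') / sqrt(Σ_xy (I−h̄)² · Σ_xy (I'−h̄')²)

A pair with correlation strictly above 0.99 is treated as identical and
the later record is discarded (greedy scan in manifest order; the first
occurrence is always kept).  Two readings of the procedure are
possible — correlating images or correlating their 256-bin intensity
histograms — because the mean step is described on histograms while the
correlation sums over spatial indices.  The spatial double sum is only
defined on aligned pixel grids, so image mode is canonical; histogram
mode is kept behind `mode="histogram"` for comparison.  Differently
sized images are bilinearly resized to the pipeline resolution 128×128
before correlation.  A constant image has no variance; its correlation
is defined as 0 (with a warning) so degenerate inputs cannot produce
NaNs.

**Preprocessing.**  Center square crop (S = min(H, W), odd margins drop
the trailing edge) followed by bilinear resize to 128×128×3.  The
bilinear convention is half-pixel-centered (`align_corners=false`):
output pixel *o* samples the source at (o+0.5)·S/target − 0.5.
Frameworks disagree on this convention, so it is pinned explicitly and
hand-checked in tests.  Pure sampling interpolation preserves constants
and never overshoots the input range; resizing at the native size is
the identity, making the operation idempotent.  Lesions are assumed
centered by the dermoscopic framing; no lesion detector is applied, and
no hair/bubble/ruler removal is performed — robustness to those
artifacts is the classifier's job.

**Class balancing and augmentation.**  Training sets are balanced by
random oversampling: every class is brought to the size of the largest
class by drawing ids uniformly with replacement; originals are always
retained and duplicates are flagged.  Duplicates are realized lazily as
id references, not materialized copies.  Online augmentation (training
split only, never validation/test — enforced by the training API) draws
per image: a rotation uniform in ±30°, an X-axis scale uniform in
[0.8, 1] with Y fixed at 1, and integer translations uniform in ±5 px
per axis, composed as a single affine map about the image center and
resampled bilinearly.  The rotation bound is ±30°: a range stated as
±300 can only be a degree-sign misprint, since ±300° would exceed a
full turn and make the range meaningless.  The anisotropic scale pair
(0.8, 1.0) is read as the lower bound of a random X-jitter rather than
a fixed squash: a deterministic 0.8 squash applied to every sample
would not be a random augmentation.  Pixels exposed by the transform
are filled with the image's per-channel median — a skin-tone-like value
that avoids dark-corner artifacts (the choice of fill is otherwise
unconstrained).

## The network

LCNet is an 11-block convolutional network for 128×128×3 inputs.  Every
convolution is followed by batch normalization and LeakyReLU with slope
s = 0.3 (negative inputs are scaled by s, non-negative pass through).
The wiring is block-parallel: sibling blocks see the same input and
their feature maps are concatenated channel-wise.

    stem    conv 8@3×3 stride 2 → BN+LReLU → max-pool 2×2      = 32×32×8   (P)
    junction  concat[ block1(P), block2(P), P ]                 = 32×32×72
    block3  36@1×1 → avg-pool 2×2                               = 16×16×36
    group A ×2:  concat[ block4: 32@1×1→64@3×3 ; block5: 64@3×3 ]   → 128 ch
    block6  32@1×1 → avg-pool                                   = 8×8×32
    group B ×4:  concat[ block7: 64@1×1→128@3×3 ; block8: 128@3×3 ] → 256 ch
    block9  64@1×1 → avg-pool                                   = 4×4×64
    group C ×2:  concat[ block10: 128@1×1→256@3×3 ; block11: 256@3×3 ] → 512 ch
    head    global average pool → FC 512→2 → softmax

Design decisions behind this reconstruction:

* Repeat units treat their two blocks as parallel branches on the same
  input, concatenated — mirroring the stem junction, the one place the
  concatenation is described explicitly.  The unit input is *not*
  re-concatenated inside repeat units; only the stem junction carries
  the passthrough.  This is the only wiring consistent with all three
  reference structural totals (11 blocks, 31 conv layers, 3.1 K
  kernels).
* The stem junction concatenates the max-pool *output* (8 channels).
  Pooling argmax indices are not a feature map and cannot be joined
  channel-wise.
* All 3×3 convolutions inside blocks use same-padding stride 1, so
  parallel branches stay spatially aligned; downsampling is confined to
  the stem (stride-2 conv + max-pool) and the three avg-pools.
* The reduction-block widths are 36/32/64 at face value, although 36
  breaks the doubling pattern.
* The stem conv gets BN+LReLU like every other conv, and blocks use the
  uniform order conv→BN→LReLU throughout.
* Weight initialization is fan-in variance-scaling normal with the
  LeakyReLU gain, drawn from a seeded generator: one integer seed fixes
  every weight.

Structural totals of this wiring: **31 conv layers, 3,100 kernels,
3,435,598 learnable parameters** (conv weights+biases 3,428,372, FC
1,026, batch-norm 2 per channel = 6,200; running statistics are not
counted).  The parameter total sits ≈4 % above the 3.3 M headline
figure this architecture is known by.  No variant consistent with the
written description closes that gap (dropping BN+activation from the
stem, re-concatenating unit inputs, or valid padding all move the
totals further away or break the kernel/layer counts), so the
discrepancy is documented rather than guessed away; the kernel and
layer totals match exactly.

### Numerical implementation

No autodiff framework is used: layers are implemented directly on numpy
arrays with hand-derived backward passes.  Convolution is evaluated as
an im2col patch-matrix times kernel-matrix product (one BLAS `sgemm`
per layer); its input gradient is reassembled with k² strided
slice-adds.  Batch normalization uses biased batch variance, ε = 1e-5,
and running statistics updated with momentum 0.1 for inference.
Max-pool ties resolve to the first window element (deterministic).
Compute dtype is float32; the test suite validates every layer's
gradients against float64 central finite differences, which is the
correctness authority in place of autodiff.

## Training

Optimizer: stochastic gradient descent with classical momentum,

    v' = γ·v − α·(g + λ·θ),   θ' = θ + v',

with α = 0.001, γ = 0.99, λ = 0.0005 (L2 folded into the gradient, the
common SGDM convention), batch size 32, up to 100 epochs.  The
momentum recurrence sometimes written as γ(θᵢ+θᵢ₊₁) is not a well-formed recurrence (it references
the next iterate on both sides), so the accepted classical-momentum
update is implemented with the stated γ.

Loss: class-weighted cross-entropy, Loss = −(1/N) Σᵢ Σⱼ wⱼ Tᵢⱼ log Pᵢⱼ,
with P clamped to [1e-12, 1] before the log.  The weights are inverse
class frequencies wₖ = N/(K·nₖ) (unit weights when balanced).  A
version of this loss without the minus sign would be maximized,
not minimized, by a perfect classifier; the standard negation is used.
Validation loss uses the same weights as training so the early-stopping
criterion is consistent with the optimized objective.

Early stopping: validation loss is evaluated after each epoch
(inference-mode batch norm); training stops after `early_stop_patience`
epochs without improvement (default 10, configurable — the reference
description states none) and the best epoch's weights are restored.

Inputs are scaled to [0, 1]; no further normalization is applied — the
stem's batch norm standardizes activations.

## Evaluation

Melanoma is the positive class.  Predicted label is the softmax argmax
with exact ties resolved to benign (the conservative direction for a
screening task).  The five confusion metrics (accuracy, precision,
recall, specificity, F1) are evaluated exactly from integer counts;
zero-denominator cases return 0 with a `degenerate` flag.  The ROC
curve sweeps all distinct score thresholds; AUC is the trapezoidal
area, equal to the Mann–Whitney pair statistic with ties counted half
(asserted against a brute-force pair count and scikit-learn in tests).
Binary single-positive-class metrics are reported, matching the TP/TN
definitions; no macro-averaging is applied.

## Synthetic data

The generator renders lesion-like images so every stage is testable
without clinical data: a beige skin-tone background with Gaussian
sensor noise, a centered radius-perturbed ellipse (dark, irregular,
speckled for MEL; lighter and smooth for BEN), and optional artifacts —
dark hair arcs and bright gel-bubble rings — at configurable rates.
Exact duplicate copies can be injected for the deduplication stage;
they correlate at exactly 1.0 while distinct renders stay well below
0.99, making the threshold test sharp.

The class profiles are fixed and intentionally well separated: the
class-conditional mean luma gap is ≥ 20 intensity units (asserted on
every generated set), with the profile parameters chosen so the
contract holds with ~3σ margin even on two-image sets.  What passing
benchmarks on this data shows is that the pipeline, network, gradients
and optimizer function correctly end-to-end — not that the classifier
reaches any particular accuracy on real dermoscopy, where inter-class
similarity, acquisition variability and label noise are the dominant
difficulties and are deliberately not emulated.

## Benchmark problem sizes

The package's standing benchmarks are scaled to desk hardware: the
training smoke benchmark uses 200 images/class for training, 40/class
for validation, ≤15 epochs, no augmentation (classes are balanced by
construction, and a deterministic per-epoch training set makes the
descent check meaningful), reaching ≥0.90 validation accuracy with at
least an order-of-magnitude training-loss drop over the first five
epochs.  Because the separable task collapses the loss to its numerical
floor within about two epochs, *strict* per-epoch monotonicity is only
asserted on a 10-sample memorization fixture, where the loss remains
far from the floor throughout the window.  The
oversampling effect is checked directionally on an imbalanced set
(25 MEL / 100 BEN train): balancing plus augmentation must not reduce
melanoma recall relative to training on the skewed set.  Published
real-data accuracies for this architecture (81–90 % on the public
dermoscopy challenges) require the original archives and long training
runs and are out of scope here.

## Known limitations

* The parameter total is 4 % above the 3.3 M headline (see above).
* Geometric center cropping approximates lesion centering; off-center
  lesions in real data would need a localizer.
* Determinism is guaranteed on a single device/BLAS configuration;
  bit-identical histories across different BLAS builds are not.
* The synthetic task is intentionally easy; metrics on it say nothing
  quantitative about clinical performance.
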