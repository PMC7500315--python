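# Methods

This note documents the models, the training and evaluation procedures,
the synthetic-data generator, and the numerical and design choices made
where the design was genuinely open.

## Models

**Bilinear pooling.** For feature maps `f_A ∈ R^{C_A×H×W}` and
`f_B ∈ R^{C_B×H×W}` with a shared spatial grid, the pooled descriptor is
`φ = Σ_l f_A(l) f_B(l)^T`, flattened row-major with the stream-A channel
index varying slowest.  The implementation uses the algebraic identity
`φ = A B^T` with `A, B` reshaped to `(C, H·W)`; the test suite checks it
against a literal per-location triple loop.  Sum pooling is the default;
a `pooling="mean"` flag divides by `H·W` (identical after L2
normalization in the forward pass, but better scale-conditioned in the
backward pass).  Accumulation is float64 throughout.

**Fast variant.** One extractor, paired with itself: `φ = Σ_l f(l) f(l)^T`
is symmetric positive semidefinite, needs one backbone pass, and its
classifier sees the same descriptor a shared-weight two-stream model
would produce — the package tests logit-for-logit equality between the
two constructions.

**Normalization chain.** `v = φ / max(‖sign(φ)·√|φ|‖₂, 1e-12)` applied as
signed square root then L2 normalization.  The `1e-12` floor maps the
zero vector to itself instead of NaN.  The signed square root is exact in
the forward pass; its backward pass uses `d/dz = 0.5 / √(|z| + 1e-8)`,
a smoothed subgradient at zero (the derivative is unbounded there).

**Classifier.** A single affine layer + softmax on the normalized
descriptor, trained with categorical cross-entropy.  Nothing about the
method requires more; a deeper head would blur the attribution of
performance to the pooling.

**SE blocks.** Squeeze = per-channel global average; excite =
`σ(W₂ relu(W₁ s))` with reduction ratio `r` (default 16 for the
standalone ops, 4 for the narrow tiny backbone so that `C/r ≥ 2`); no
bias terms by default, matching the two-matrix gate form, with biases
available by flag.  Insertion after any named stage; output shapes are
unchanged and each block adds `2C²/r` parameters.

**Backbones.** The `tiny` backbone is three stride-2 convolution stages
(7×7 stem kernel, then 3×3), each followed by batch normalization and
ReLU; stage widths are `(D/2, 3D/4, D)·width_scale` with final width `D`
(default 16).  The wide stem and the batch-norm layers mirror the
standard ImageNet architectures this method is normally attached to, and
both proved necessary for a *randomly initialized* model to train at the
protocol's learning rate of 0.1: without normalization the pooled
descriptor is dominated by a constant background direction and the loss
barely moves in ten epochs.  ResNet50 / InceptionV3 / InceptionResNetV2
are registered with their documented feature widths (2048 / 2048 / 1536)
and 197-pixel minimum input for configuration and parameter accounting;
building them requires a framework adapter that is intentionally not
bundled, and the constructors raise an explicit error rather than
substituting a random network.

**Batch-norm recalibration.** After training, the running mean/variance
of every batch-norm layer is replaced by the plain average of batch
statistics under the final weights (one extra pass over the training
set).  With batch size 16 and few epochs, the exponential running
estimates can lag the converged network's true statistics badly enough to
destroy eval-mode accuracy; recalibration makes inference match the
trained behavior and is deterministic.

## Training protocol

Mini-batch SGD, initial learning rate 0.1, batch size 16; when the
training loss has not decreased for 10 consecutive epochs the rate is
multiplied by 0.1; training stops at `max_epochs` (default 100) or when
the rate falls below `min_lr` (1e-5).  The plateau metric is the
*training* loss.  Momentum defaults to 0 in `TrainConfig`; the
desk-scale profile (below) sets it to 0.9, the standard SGD convention,
because a randomly initialized model must make useful progress within ten
epochs.  Loss is categorical cross-entropy.  Oversampling balances class
frequencies by duplication with replacement, applied to training folds
only; augmentation (horizontal/vertical flips p=0.5, shifts up to 10% of
the image side, rotations up to 40°) is drawn per epoch from the run's
seeded generator.  Cross-validation is stratified 5-fold at the image
level; a `group_by_slide` option gives leakage-safe slide-level splits
but is off by default to mirror image-level randomization.  Everything is
seeded and CPU-deterministic: identical configs give identical histories.

Transfer learning from ImageNet weights is how the standard backbones are
meant to be initialized; `load_pretrained` raises an explicit error
explaining that no weights ship with the package.

## Desk-scale profile

`bilinearcnn.experiments.DESK_SCALE` pins the configuration used by the
capability tests, the acceptance script and the README example: tiny
backbone, D = 16 channels, `width_scale` 1.5, 64×64 inputs, 10 epochs,
lr 0.1, batch 16, momentum 0.9.  The benchmark is 4 classes × 40 images
(100 train / 60 test, stratified), three pseudo-magnification scales
mixed in training, results averaged over three seeds.  Problem sizes were
chosen so the whole benchmark runs in under a minute on one CPU core
while leaving enough test images (60) for accuracy differences of a few
points to be meaningful.

The baseline for the capability comparison is the same backbone family
with global average pooling and an affine softmax head.  Because the GAP
head needs only `D·K` classifier weights against the bilinear head's
`D²·K`, the baseline's intermediate stage widths are widened
(`matched_gap_width_scale`) until the two models' total trainable
parameter counts agree within ~2%, so the comparison isolates the
descriptor, not the budget.

## Synthetic data: what it emulates, and what it does not

The generator produces dark-field microscopy-style images: bright,
soft-edged motifs (blobs, rings, oriented bars) in fluorophore-like
colors on a near-black noisy background.  Class identity is carried
entirely by local texture statistics; motif centers are uniform over the
image (chi-square-tested), so no class can be recognized from *where*
anything is — the regime in which an orderless descriptor is the right
inductive bias.  Pseudo-magnification scales multiply motif sizes, with
scales cycling within each class so every class is balanced across
scales.

The default four classes contain a deliberate fine-grained pair:

* **mixstain** — 12 blobs per image, half green, half red;
* **purestain** — 12 blobs, all green *or* all red, drawn per image;
* **rings** (yellow) and **hvbars** (cyan) — ordinary classes separable
  by first-order features.

The pair is constructed so that every spatially averaged feature of a
mixed image equals the midpoint of the pure class's two modes; a global
average pooling + linear head therefore cannot separate the pair for
*any* backbone, capping such baselines near 75% on the four-class task.
The bilinear route escapes the degeneracy only through the signed-sqrt +
L2 nonlinearity applied *after* pooling — and only when the descriptor is
not dominated by a constant background component, which is why the
generator uses a dark background: a bright common-mode (as in
bright-field H&E imagery) linearizes the normalization around the
background direction and restores the midpoint degeneracy.  This is a
real limitation of the desk-scale construction to keep in mind when
extrapolating: on bright-field data the advantage of second-order
pooling must come from richer, pretrained feature spaces rather than
from this clean mixture mechanism.

Other things the generator does not emulate: stain variability and
artifacts, patient-level correlation between images (every image is
independent), tissue macro-structure, and class-conditional difficulty
differences.  Passing the desk-scale tests therefore demonstrates that
the implementation learns second-order texture statistics end-to-end
under the stated protocol — not that it reproduces clinical-grade
accuracy on real histopathology.

## Evaluation

Accuracy is the fraction of correctly classified samples;
confusion-matrix consistency (accuracy = trace/total, row sums = class
counts) is asserted on every report.  ROC is one-vs-rest per class with
trapezoidal AUC and macro averaging; a class absent from the test labels
yields a missing (None) AUC rather than NaN.  The sweep-based AUC is
tested exactly against a brute-force pairwise-concordance oracle,
`AUC = P(s⁺ > s⁻) + ½P(tie)`.  t-SNE embeds the pre-softmax activations
(the affine head's outputs) in 2-D; perplexity defaults to 30 capped at
`(n−1)/3`; it is a seeded visualization utility, not part of the method.
Frames-per-second uses batch size 1, ten warm-up frames and the median
over five timed runs; it is hardware-dependent and reported as
informational only — only the *direction* (fast ≥ two-stream) is ever
asserted, with slack.

## Grad-CAM

For a target class `k` and a convolutional layer, channel weights are the
spatial mean of `∂logit_k/∂feature-map`; the map is
`ReLU(Σ_c w_c · map_c)`, max-normalized when nonzero, and bilinearly
upsampled to input resolution.  The default layer is the last feature map
feeding the pooling; for an unshared two-stream model the two streams'
maps are averaged.  The implementation is tested against the closed-form
result for a GAP + linear construction (`w_c = W_kc / HW`), and,
statistically over ≥20 images, trained-model heatmap mass concentrates
inside motif bounding boxes.

## Numerical choices and degenerate inputs

* float64 everywhere; bilinear accumulation never below 32-bit.
* `l2_normalize` eps 1e-12; signed-sqrt backward smoothing 1e-8.
* Zero vector normalizes to zero; all-zero Grad-CAM maps are returned as
  zeros, not NaN.
* He-uniform initialization for conv/linear weights, zeros for biases,
  ones/zeros for batch-norm scale/shift; all draws from a single seeded
  generator per model.
* Resize interpolation is bilinear (PIL); pixel scaling for the tiny
  backbone is [0, 1], recorded in the checkpoint sidecar.
* Image arrays are indexed (row, column), 0-based; channels-first inside
  the network, channels-last at the user surface.
* Ties in oversampling are resolved by seeded sampling with replacement;
  stratified folds come from seeded `StratifiedKFold`.

## Known limitations

* The standard ImageNet backbones are interface stubs; paper-scale
  profiles ship as YAML configs but cannot run without an external
  framework adapter and weights.
* The mixture-vs-pure mechanism that gives the bilinear model its
  desk-scale edge depends on a dark background (see above).
* Image-level (not patient-level) cross-validation is the default split,
  which can overestimate accuracy on real slide data; use
  `group_by_slide=True` for leakage-safe estimates.
* Compact/low-rank bilinear approximations, matrix-normalization
  variants, and higher-order pooling are out of scope.
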