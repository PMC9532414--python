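# Methods

## Model

The segmenter is an iterative encoder–decoder: one full-depth residual
U-Net (the *input network*, 4 encoder levels) followed by `iterations`
smaller refinement U-Nets (3 levels each).  All hidden blocks are
residual units — conv3×3 → batch-norm → ReLU → conv3×3 → batch-norm →
add the block input → ReLU — with a 1×1 projection on the skip whenever
the channel width changes.  Downsampling is 2×2 max pooling after the
residual unit; upsampling is a 2×2 stride-2 transpose convolution.
Feature widths double per level from `base_features` (default 32;
smaller widths are used throughout the test suite to keep CPU runs
fast).  Each sub-network ends in a 3×3 convolution plus sigmoid, so a
forward pass yields `iterations + 1` probability maps; the last is the
final segmentation.

Refinement network *k* is fed the channel-wise concatenation, before its
first downsampling, of (a) the last-hidden-layer features of network
*k−1* and (b) the first-layer (stem) features of the previous two
networks, where network 0's first layer is the input network's stem.
A `skip_mode="all"` variant concatenates the stems of *every* previous
network instead.  The decoder concatenates the corresponding encoder
features *before* the transpose convolution (so the skip is taken at the
pre-upsampled resolution, i.e. from the pooled encoder output); because
the deepest decoder stage would otherwise concatenate a tensor with
itself, a bottleneck residual unit sits between encoder and decoder and
provides the distinct partner.  `pre_concat=False` selects the
conventional order (upsample, then concatenate the pre-pool encoder
features).  Both wirings preserve spatial dimensions end to end; inputs
must be divisible by 2⁴ = 16.

The output head is initialized at a tenth of the usual He scale so an
untrained network emits probabilities near 0.5 rather than saturated
values; all other convolutions use He fan-in initialization from a
seeded generator, making model construction fully deterministic.

## Loss

Training minimizes `α·H + β·(1 − D)` where `H` is binary cross-entropy
(predictions clamped to `[ε, 1−ε]`, ε = 1e−7) and `D` the soft Dice
similarity `(2Σyŷ + ε)/(Σy + Σŷ + ε)`.  Two choices deserve note:

* **Dice direction.** The Dice term is a similarity (1 = perfect), so it
  enters the minimized objective as `1 − D`; adding the similarity
  itself would reward worse overlap.  A `dice_as_similarity` flag
  exposes the raw `+β·D` form for fidelity experiments.
* **Cross-entropy reduction.** The default is the per-pixel mean.  A
  literal sum over a 256×256 patch would make the cross-entropy term
  ~65 000× larger than the Dice term, which is inconsistent with a tuned
  α in the 0.2–1.0 range; `bce_reduction="sum"` restores the literal
  form.

Defaults α = 0.42715, β = 1.0.  Per-batch loss is the mean over samples.
With `supervision_mode="last"` only the final head's loss is optimized
(gradients still reach every earlier sub-network through the feature
chain); `"sum"` attaches the loss to every head (deep supervision).

## Training

Adam with initial learning rate 0.00332 and per-epoch multiplicative
decay 0.89661 (the optimizer family is a package choice; the rate range
matches that regime).  On-the-fly augmentation draws one rotation angle
uniform in [0°, 90°] plus independent horizontal/vertical flips per
sample and applies the identical transform to image (bilinear) and mask
(nearest-neighbour) with reflection fill, so masks stay binary.

Early stopping monitors the held-out mean Dice of the final head
binarized at the configured threshold (default 0.5).  No stop is
considered before `stopping_patience` (17) epochs; afterwards training
stops when the Dice improvement over the last `stopping_epochs` (7)
epochs — current value minus the value that many epochs earlier — is at
most `stopping_tolerance` (0.010).  Two plateau semantics are sensible
here and they disagree at the margins: the window-difference rule above
(which, at a large tolerance, halts even a steadily improving model) and
a best-so-far rule that compares against the best Dice seen before the
window.  The window rule is the default; `plateau_rule="best"` selects
the other.  The weights with the best monitored Dice are restored and
checkpointed.

## Inference

Full images are padded by `patch_size − stride` on every side (reflect
by default, zero-fill optional) plus the minimal bottom/right extra to
align the padded extent to the stride.  Under the defaults
(256-pixel patches, stride 128) this makes every original pixel a member
of exactly (256/128)² = 4 patches — verified by brute-force membership
counting in the tests — so the voting rule is uniform across the image,
borders included.  Each patch's final probability map is binarized and
pixels are labelled foreground only on a strict majority of their
covering patches; a 2-of-4 tie is background.  The alternative of
leaving borders unpadded — edge pixels then receive fewer votes and the
tie rule rarely applies there — is deliberately not the default, since
uniform coverage makes the voting semantics identical everywhere;
zero-fill padding remains available.  Probability averaging across
overlaps is available as an experimental `vote_mode="average"`.

## Metrics

DSC, IoU, sensitivity, specificity and accuracy from per-pixel confusion
counts.  Vacuous denominators (e.g. sensitivity when the ground truth
has no foreground) score 1.0 and the affected image is flagged in
reports, keeping dataset means auditable.  Accuracy is reported but is a
weak indicator under heavy class imbalance — an all-background
prediction on a 90%-background image already scores 0.90.  The identity
IoU = DSC/(2 − DSC) is asserted as a property test.

## Synthetic scenes

The generator emulates the statistical structure of root-on-filter-paper
imagery: thin bright curves of multiplicatively decreasing thickness
branching from a few primary roots that hang downward from the top of
the frame, on a dark background with low-frequency texture, plus
distractors — semi-transparent bright elliptical droplets, 1–3 px dust
specks and a thick vertical stem bar — that are composited into the
image only, never the mask.  Skeletons grow as depth-limited branching
random walks: per step the heading relaxes toward vertical
(factor 0.95) and is perturbed by Gaussian noise (sd 0.15 rad); branches
spawn with probability 0.035 per step up to depth 3.  Defaults
(512×512 canvas, 3 primaries, 120 steps of 4 px, initial thickness 4 px
decaying ×0.72 per generation) give a foreground fraction of roughly
5–11%, matching the heavy class imbalance the loss design targets.
Every sample is a pure function of its spec (seed included).

What the generator does **not** model: photometric gradients and vignetting,
root occlusion physics, gel or soil media, species-specific branching
statistics (no quantitative thickness/branching distributions were
available to calibrate against), and JPEG/sensor artifacts beyond
additive Gaussian noise.  Passing tests therefore demonstrate that the
architecture, loss, voting and training machinery work and can learn
thin branching structures amid bright distractors — not that any
particular Dice level transfers to real root photographs.

## Numerical layer

No deep-learning framework is part of the dependency set; the layers run
on a compact reverse-mode automatic-differentiation engine over float32
numpy arrays written for this package (`iterroot.nn`): fused conv2d
(im2col + BLAS matmul), stride-2 transpose convolution, 2×2 max pooling,
batch normalization with running statistics, and Adam.  Every operation's
gradient is checked against central finite differences in
`tests/test_engine.py`.  Batch normalization uses batch statistics in
training mode and running statistics (momentum 0.1) in evaluation mode,
so inference is deterministic.

## Problem sizes used in the automated checks

The test suite and acceptance script run on one CPU, so the stochastic
learning check uses a scaled-down task: 64×64 patches sampled from
default synthetic scenes (≈120 training, 40 held-out), a
`base_features=8`, 1-iteration model, 8 epochs, 3 seeds — reaching
held-out mean Dice ≥ 0.85 for at least 2 of 3 seeds.  The architecture
checks instantiate the full default configuration (base 32, 3
iterations) and run genuine 256×256 forward passes.  The CLI smoke test
drives generate → train → predict → evaluate on a 20-image 128×128
dataset with a tiny model.  These sizes are package choices for desk-scale
reproducibility; the defaults (`IterRootConfig()`, `TrainConfig()`)
remain the full-scale settings.

## Known limitations

* Training at the full 256×256/base-32 scale is impractical on a single
  CPU with the numpy engine; GPU-scale experiments require porting the
  model definition to a framework backend.
* The empty-mask path of `sample_training_patches` deliberately raises:
  background-only patch sets (the expanded-training-set protocol) must
  be assembled by the caller.
* Masks are strictly binary; no multi-class or root-tip variants.
* The loss-sign, early-stop plateau and border-voting choices documented
  above are deliberate package decisions; the alternatives stay
  reachable behind configuration flags for comparison experiments.
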