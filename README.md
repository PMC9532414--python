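# iterroot

Segmentation of thin, branching plant root systems in 2D images with an
iterative residual U-Net.

## The problem

High-throughput root phenotyping images a root system grown flat on dark
filter paper and needs a per-pixel binary mask (root vs background) before
any trait can be measured.  The images are hard to segment: roots are one
to a few pixels wide, cover well under 20% of the image, and share the
frame with bright non-root objects — water droplets, dust specks and the
plant stem — that must be labelled background.  `iterroot` implements a
complete pipeline for this task, testable end to end without any
downloads through a built-in synthetic root-scene generator.

## The method

**Architecture.** A residual-block U-Net (4 encoder levels) is followed
by a chain of smaller refinement U-Nets (3 levels each; 3 of them by
default).  Every hidden block is a residual unit
(conv3×3 → BN → ReLU → conv3×3 → BN → add input → ReLU).  Refinement
network *k* receives, concatenated before its first downsampling, the
last-hidden-layer features of network *k−1* plus the first-layer features
of the previous two networks.  Every sub-network owns a sigmoid head, so
a forward pass returns *iterations + 1* probability maps; the last one is
the final segmentation.

**Loss.** Training minimizes a weighted combination that counteracts the
foreground/background imbalance:

    loss = α·H(y, ŷ) + β·(1 − D(y, ŷ))

with H the binary cross-entropy, D the soft Dice similarity
2·Σyŷ / (Σy + Σŷ), and defaults α = 0.42715, β = 1.0.  The final
sub-network's loss is the optimized objective (deep supervision over all
heads is available).

**Training.** On-the-fly augmentation (rotation up to 90°, flips),
multiplicative learning-rate decay (0.00332 × 0.89661ᵉ), and early
stopping monitored on held-out Dice (patience 17, tolerance 0.010 over a
7-epoch window), up to 200 epochs at batch size 32.

**Inference.** Full images are reflect-padded and tiled into overlapping
256×256 patches at stride 128 so that every pixel is examined in exactly
4 patches.  Patch predictions are binarized and combined by strict
per-pixel majority vote; a 2–2 tie resolves to background.

**Metrics.** DSC = 2TP/(2TP+FP+FN), IoU, sensitivity, specificity and
accuracy, computed from per-pixel confusion counts.

The network layers run on a small numpy-based automatic-differentiation
engine bundled with the package (`iterroot.nn`), gradient-checked against
finite differences in the test suite.

## Worked example

```python
import numpy as np
import iterroot as ir

# 1. generate a synthetic root scene with ground truth
sample = ir.generate_sample(ir.RootSceneSpec(seed=4))
print(f"scene: {sample.image.shape[0]}x{sample.image.shape[1]}, "
      f"foreground fraction {sample.mask.mean():.3f}")

# 2. sample training and held-out patches
rng = np.random.default_rng(0)
train_x, train_y = ir.sample_training_patches(sample.image, sample.mask,
                                              48, rng, patch_size=64)
held = ir.generate_sample(ir.RootSceneSpec(seed=99))
test_x, test_y = ir.sample_training_patches(held.image, held.mask,
                                            16, rng, patch_size=64)

# 3. train a scaled-down iterative model for a few epochs
model = ir.build_model(ir.IterRootConfig(base_features=8, iterations=1), seed=0)
report = ir.train(model, train_x, train_y, test_x, test_y,
                  ir.TrainConfig(max_epochs=5, batch_size=8, seed=0),
                  log=print)

# 4. segment the held-out scene and score it
pred = ir.segment_image(model, held.image, patch_size=64, stride=32)
scores = ir.score_pair(pred, held.mask)
print(f"full-image DSC {scores.dsc:.3f}  IoU {scores.iou:.3f}  "
      f"sensitivity {scores.sensitivity:.3f}  specificity {scores.specificity:.3f}")
```

Output:

```
scene: 512x512, foreground fraction 0.058
epoch   0  lr 0.003320  train 1.1221  monitor 0.9661  dice 0.4815
epoch   1  lr 0.002977  train 0.6852  monitor 0.5010  dice 0.6968
epoch   2  lr 0.002669  train 0.3930  monitor 0.3188  dice 0.7827
epoch   3  lr 0.002393  train 0.2768  monitor 0.2312  dice 0.8500
epoch   4  lr 0.002146  train 0.2284  monitor 0.1834  dice 0.8662
full-image DSC 0.853  IoU 0.743  sensitivity 0.937  specificity 0.977
```

The monitored Dice climbs from 0.48 to 0.87 within five epochs on a
single synthetic scene; the trained model then segments an unseen scene
patch-wise with majority voting to a full-image Dice of 0.85, while
specificity 0.977 shows the distractors are mostly rejected as
background.

## Command line

```sh
iterroot generate --out data --n 20 --seed 1          # synthetic dataset + manifest
iterroot train    --manifest data/manifest.csv --out run
iterroot predict  --checkpoint run/checkpoint.npz --out masks image.png
iterroot evaluate --checkpoint run/checkpoint.npz --manifest data/manifest.csv \
                  --split validation --out scores.csv
```

Every command accepts a flat YAML `--config` file (flags override it) and
writes its resolved configuration next to its outputs.

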