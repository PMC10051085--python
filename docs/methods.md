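# Methods

## Problem and model

`lesionseg` performs binary semantic segmentation of gastrointestinal
lesions — bleeding spots in capsule-endoscopy frames, polyps in colonoscopy
frames — producing a per-pixel probability that a pixel belongs to a lesion.
Three architectures share one encoder–decoder skeleton:

* **U-Net** — plain convolutional encoder, skip connections by concatenation.
* **AttU-Net** — U-Net with an additive attention gate on each skip.
* **AttResU-Net** — attention gates plus residual encoder blocks (the
  package's headline architecture).

Each encoder stage applies its block (two 3×3 conv → batch-norm → ReLU
stages; for residual blocks the block output is `F(x) + shortcut(x)`, with a
1×1 projection shortcut when channel counts differ) and then 2×2 max
pooling; the channel width doubles per stage from `base_filters` while the
spatial size halves. The decoder mirrors this with 2× nearest-neighbor
upsampling followed by a 3×3 convolution, a skip merge, and a plain conv
block — the residual structure is used only in the encoder. The head is a
1×1 convolution with a sigmoid, so outputs are probabilities in (0, 1);
masks are obtained by thresholding at 0.5 (configurable, `>=` convention at
the boundary).

The attention gate takes the encoder skip `x_l` and the gating signal `g`
from one level deeper (half the resolution, twice the channels). `x_l`
passes a 1×1 convolution with stride equal to the spatial ratio (2 here),
`g` a 1×1 convolution, each followed by batch norm; the two are summed,
passed through ReLU, reduced to one channel by a 1×1 convolution with batch
norm, and squashed by a sigmoid into coefficients α ∈ [0, 1] at the coarse
resolution. α is upsampled bilinearly (the 2-D analogue of the trilinear
interpolation sometimes quoted for this gate) back to `x_l`'s resolution and
multiplies `x_l` channelwise. With all gate weights zero, α = sigmoid(0) =
0.5 exactly — a property the tests exploit.

The intermediate channel width inside the gate defaults to half the gating
signal's channels (at least 1); this keeps the gate cheap and is the common
convention. Batch norm follows every gate convolution, before the
nonlinearity, matching the convention used in the conv blocks.

## Numerical core

No deep-learning framework is part of the dependency set; the package ships
a compact reverse-mode autodiff over NumPy arrays (`lesionseg.nn`) with
exactly the operations the networks need: im2col-based 2-D convolution,
batch normalization (batch statistics + running-buffer updates in training
mode, running statistics in eval mode, momentum 0.1, eps 1e-5), 2×2 max
pooling, nearest and bilinear upsampling (half-pixel-center convention),
channel concatenation, ReLU/sigmoid, and the losses. All tensors are NCHW
float32. Every backward pass is verified against central finite differences
in the test suite. Weights use He-normal initialization seeded through
`build_model(config, seed=...)`, so builds are reproducible.

Inference (`predict`, `predict_mask`, `evaluate_dataset`) always runs in
eval mode and is deterministic.

## Training protocol

* Loss: mean binary cross-entropy over pixels, with probabilities clamped to
  [1e-7, 1−1e-7]; this is the default for sigmoid-output binary
  segmentation. A soft-Dice loss is available via `TrainConfig(loss="dice")`.
* Optimizer: Adam, learning rate 1e-3 (configurable), β₁ = 0.9, β₂ = 0.99.
  The second-moment decay is deliberately 0.99 rather than the more common
  0.999; it is configurable.
* Batch size 40, up to 50 epochs by default.
* Early stopping monitors validation loss with patience 10 and always
  restores the parameters of the best-validation-loss epoch, so the returned
  model is never worse than the best seen.
* Shuffling and augmentation draws derive from `TrainConfig.seed`; identical
  seed + config reproduce identical histories on a fixed platform.
* Augmentation (horizontal/vertical flips, rotation up to ±20°, zoom within
  ±10%, each firing with probability 1/2 per draw) applies on the fly to
  training batches only; validation and test always see the raw samples.
  Rotations by exact multiples of 90° on square frames are index
  permutations and preserve mask foreground counts bit-exactly; arbitrary
  angles and zooms fill revealed pixels with 0 (image) and background
  (mask), and interpolate the mask nearest-neighbor so it stays binary.

Dataset handling: images are normalized to [0, 1] by dividing by 255 and
resized to the model input (128×128 by default; bilinear for the image,
nearest for the mask). Splitting defaults to 60/20/20 with validation/test
sizes `round(n·fraction)` and the rounding remainder assigned to train; an
80/0/20 split is also supported.

## Evaluation

Pixelwise confusion counts give accuracy (TP+TN)/total; Dice
2|A∩B|/(|A|+|B|) and Jaccard |A∩B|/|A∪B| measure overlap, with the
convention that both equal 1 when prediction and reference are both empty.
`evaluate_dataset` reports the per-image mean of each metric as the
headline and the pooled-count variants alongside, since the two
aggregations differ whenever image difficulty varies.

## Synthetic scenes

The generator emulates the statistics of endoscopic lesion datasets — a
smoothly textured pink-brown mucosal background (Gaussian-filtered color
noise, amplitude 0.06), one or more red-dominant blobs, additive Gaussian
pixel noise clipped to [0, 1] — with exact ground truth. Lesion boundaries
are radially perturbed rotated ellipses, `r(θ) = r_base·(1 + irregularity·
s(θ))`, where `s` is a 4-harmonic random trigonometric series normalized to
|s| ≤ 1; hence no lesion pixel lies farther than `(1+irregularity)·r_max`
from its center, an invariant the tests check. Default colors are lesion
RGB (0.72, 0.18, 0.16) on background (0.78, 0.55, 0.48); with zero noise the
lesion's mean color is closer to its target than to the background's.

What the generator does *not* emulate: specular highlights, vignetting,
instrument artifacts, texture inside lesions, ambiguous boundaries, or class
imbalance across frames. Passing the synthetic end-to-end test therefore
shows the architecture, optimizer, augmentation and evaluation plumbing all
cooperate and that the network can learn a color/shape segmentation task —
it does not certify clinical-grade performance on real endoscopy data.

## Problem sizes and defaults used in verification

The shipped end-to-end experiment trains the tiny configuration —
AttResU-Net and U-Net with `base_filters=8`, `depth=3` on 200 synthetic
64×64 scenes (split 120/40/40) for up to 15 epochs at batch size 40 — which
the package treats as its reference study: large enough that an untrained
network scores near zero Dice while a trained one exceeds 0.85 on
validation, small enough to run on one CPU core in a few minutes. The
full-width default (`base_filters=64`, depth 4, 128×128 inputs) is the
configuration intended for real datasets and a GPU-class budget.

## Known limitations

* CPU-only NumPy execution: full-width training on real datasets is slow;
  the package is sized for method development and small experiments.
* Batch norm with batch size 1 degenerates (zero variance); use batch
  size ≥ 2.
* `float32` accumulation means bit-exact reproducibility holds per platform
  and BLAS build, not across platforms.
* Anisotropic skip/gating ratios in the attention gate are rejected rather
  than supported; all shipped architectures use a ratio of 2.
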