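# Methods

## Problem and model

The package segments protruding colorectal lesions (polyps) in RGB
endoscopy frames as a per-pixel binary classification.  The architecture is
an encoder–decoder in which a four-level feature pyramid (strides 4/8/16/32)
is consumed by three cooperating decoder modules:

* a **top-down cascade** over the three deepest levels, in which upsampled
  deep features multiplicatively gate shallower ones before each
  aggregation — the gating means a region suppressed by the deepest
  semantics contributes nothing downstream (an exact annihilator property
  that the tests exercise);
* a **multiscale context module** on the shallowest level, combining
  parallel multi-kernel convolutions (1/3/7/11), parallel 3×3 dilated
  convolutions (rates 1/3/7/11, padding = rate so resolution is preserved),
  a projected residual of the input, and CBAM-style channel + spatial
  attention;
* a **residual fusion block** joining the two streams (deep stream
  bilinearly upsampled ×2 to stride 4), followed by a 1×1 head and ×4
  bilinear upsample to full resolution.

Assumptions: single foreground class; masks are (near-)binary 8-bit images;
input sizes divisible by 32; channel-first float32 tensors throughout.

## Design choices where the design was open

* **Second-path source in the cascade.**  The two natural wirings are to
  feed the second aggregation stage either the first stage's aggregate
  (`f3''`) or its refined-only tensor (`f3'`).  The default consumes
  `f3''` — otherwise the first aggregation would compute a dead tensor and
  the cascade would not actually cascade.  `cam.second_path_source =
  f3_prime` selects the alternative; the tests verify that under it `f3''`
  receives no gradient.
* **Dilated branch topology.**  The four dilated convolutions are parallel
  (each consumes the multi-kernel concatenation), not chained; parallel
  branches keep the four receptive-field scales independent.
* **Attention realisation.**  CBAM: channel gate from average- and
  max-pooled descriptors through a shared bottleneck MLP (reduction 16;
  4 in the tiny configuration), spatial gate from channel mean/max maps
  through a 7×7 convolution; both sigmoid, applied multiplicatively in
  sequence.
* **Head.**  Nothing deeper than a 1×1 convolution plus ×4 bilinear
  upsample; no deep supervision.
* **Ablation fallbacks.**  With the cascade off, the deep stream is a
  1×1-projected `f2`; with the context module off, the shallow stream is a
  1×1-projected `f1`; with the fusion block off, fusion is concatenation
  plus one conv block.  Each toggle changes exactly one degree of freedom.
* **`Conv(·)` convention.**  3×3 convolution + batch norm + ReLU with a
  shared internal width (`mid_channels`, default 64; 16 in the tiny
  configuration); 1×1 projections channel-align inputs before each
  elementwise product.  Upsampling is bilinear with the half-pixel
  convention, no corner alignment.

## Loss

`L = L_BCE + L_Dice`, unweighted.

* BCE is the mean over all pixels of the batch, computed in logit space as
  `max(z,0) − z·y + log(1+e^−|z|)` so extreme logits stay finite; its
  gradient is `(σ(z) − y)/N`.
* Dice uses soft probabilities (differentiable), is computed per image and
  averaged over the batch, with smoothing `ε = 1e−6` so empty masks give a
  well-defined value.

## Metrics

Per image: IoU, DSC, recall, precision, F2 (β = 2) and the exact symmetric
Hausdorff distance between foreground pixel sets (via
`scipy.spatial.distance.directed_hausdorff`, checked against an all-pairs
oracle).  Dataset values are arithmetic means over images, never global
pixel pooling.  Conventions: both masks empty → all ratios 1 and HD 0;
exactly one empty → ratios 0 and HD equal to the image diagonal
`sqrt((H−1)² + (W−1)²)`; other zero denominators → 0.  Binarisation is
strict (`p > threshold`, default 0.5).  HD is reported in pixels at the
evaluation resolution, with no normalisation; it is therefore
resolution-dependent and not comparable across image sizes.

## Numerical core

No deep-learning framework is used: `canet.nn` is a reverse-mode autodiff
engine over numpy arrays.  Convolution is im2col + BLAS matmul with an
exact slice-scatter adjoint (covers stride and dilation); resizing is a
pair of dense separable interpolation matrices whose adjoint is their
transpose; `max` splits gradient evenly across ties so the finite-difference
checks are exact; batch norm uses ε = 1e−5 and momentum 0.1 with running
statistics for eval mode.  Adam uses the standard bias-corrected update
(β = 0.9/0.999, ε = 1e−8).  Every primitive's gradient is tested against
central finite differences, and the conv forward pass against a
quadruple-loop dense oracle.

For the equation-fidelity tests, modules are built with `batch_norm=False`
and their convolutions set to the identity (centre tap 1) or to a channel
sum where the width reduces, which collapses each module to direct array
arithmetic on toy feature maps.

## Training protocol

Defaults: Adam, lr 1e−4, batch 16, up to 500 epochs, images 256×256,
early stopping after 50 epochs without validation improvement
(improvement = increase of the validation mean Dice by more than 1e−5).
The validation set is a seeded 10% carve-out of the training pairs, so the
test split never influences stopping.  No learning-rate schedule, no
gradient clipping.  Checkpoints store weights, config, seed and threshold,
so evaluation and prediction are self-describing.  A non-finite loss aborts
with the epoch and step.

The desk-scale configuration (`tiny_train_config`) uses the tiny backbone
(channels 16/32/64/96), decoder width 16, 96×96 images, batch 8 and lr
1e−3; a 12–24 epoch budget trains in one to two minutes on one CPU and
reliably exceeds held-out mean Dice 0.8 on the default synthetic data.
These sizes were chosen so the whole pipeline — data synthesis, training,
evaluation — is routinely re-runnable on a laptop core.

## Synthetic data

The generator emulates the axes that make real colonoscopy data difficult:
lesion area spanning 0.2%–25% of the frame (including sub-1% "small
polyp" cases), smoothly deformed elliptical outlines (squashed ellipse
modulated by low-frequency radial harmonics), adjustable
foreground/background contrast (default range 0.3–0.9; values near 0 give
the nearly invisible lesions that defeat segmentation models), a textured
background (smoothed Gaussian field), Gaussian-blurred intensity edges and
multiplicative speckle.  Masks are exact by construction; when pixel
quantisation nudges a lesion outside the requested area range, a
morphological correction (dilation/erosion) restores it.  Everything is a
pure function of the seed — datasets are bitwise reproducible.

What it does **not** emulate: specular highlights, vignetting, instrument
shadows, fluid and debris, motion blur, interlacing artefacts,
camera-specific colour response, and the anatomy-driven correlation between
lesion appearance and position.  Passing the desk-scale tests therefore
demonstrates that the architecture, losses, metrics and training loop are
correct and can learn the size/contrast axes — not that the model reaches
clinical-grade accuracy on real endoscopy data, which additionally requires
the real benchmark datasets and much larger training budgets.

## Known limitations

* The PVT-style and ResNet-50 encoders are randomly initialised; no
  pretrained weights ship with the package, and `pretrained=True` degrades
  to random initialisation with a warning.  The PVT variant is a
  v1-tiny-like configuration (depths 2/2/2/2, heads 1/2/5/8, spatial
  reduction 8/4/2/1, MLP ratio 4, ReLU in the MLP) — a documented
  assumption, configurable via channel widths.
* Training at the full 256×256/batch-16 protocol is possible but slow on
  one CPU; the package is tuned for desk-scale verification, not benchmark
  training runs.
* The Hausdorff metric is exact (not the 95th-percentile variant) and in
  raw pixels; comparisons against normalised boundary metrics require an
  explicit conversion by the user.
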