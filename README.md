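# canet-seg

Binary segmentation of colorectal polyps in endoscopy images with a
cascaded-aggregation encoder–decoder, built for researchers who need a fully
inspectable, CPU-testable implementation: every layer — convolution, batch
norm, attention, bilinear resizing and their gradients — runs on a small
bundled numpy autodiff core that is verified against finite differences and
brute-force oracles in the test suite.

## The model

A pyramid encoder produces four feature levels `f1..f4` at strides
4/8/16/32 (PVT-style transformer by default; ResNet-50 and a tiny CNN are
drop-in alternatives).  Three decoder modules turn the pyramid into a mask:

* **CAM — cascaded aggregation.**  Top-down refinement of the deep levels:
  `f3' = Conv(Up(f4) ⊙ f3)`, `f3'' = Concat(Conv(Up(f4)), f3')`, then
  `f2' = Conv(Up₂(f4) ⊙ Conv(Up(f3) ⊙ f2))`,
  `f2'' = Concat(Conv(Conv(Up(f3''))), f2')` and
  `f_cam = Conv(Conv(f2''))` at stride 8.  The elementwise products let
  high-level semantics gate shallower features.
* **MCAM — multiscale context.**  On `f1`: parallel convolutions with
  kernels {1, 3, 7, 11}, then parallel 3×3 dilated convolutions with rates
  {1, 3, 7, 11}, a 1×1-projected residual of `f1` added back, and
  CBAM-style channel-then-spatial attention.  Output `f_mcam` keeps stride 4.
* **RFM — residual fusion.**  `f_cam` (upsampled ×2) and `f_mcam` are
  concatenated and passed through a residual block
  `f_rfm = Conv(ReLU(BN(Conv(ReLU(BN(Conv(f_con))))) + BN(Conv₁ₓ₁(f_con))))`;
  a 1×1 head and ×4 bilinear upsample produce full-resolution logits.

Training minimises the hybrid objective `L = L_BCE + L_Dice` (pixel-mean
binary cross-entropy in logit space plus per-image soft Dice).  Evaluation
reports per-image mIoU, mDSC, recall, precision, F2 (β = 2) and the exact
symmetric Hausdorff distance in pixels, averaged over images.

Each decoder module can be toggled off (`model.use_cam`, `model.use_mcam`,
`model.use_rfm`), which yields the module-ablation lattice from bare
backbone to full model.

## Worked example

Generate a seeded synthetic dataset (textured backgrounds, low-contrast
deformed-ellipse lesions spanning 0.2%–25% of the frame), train the
desk-scale model and evaluate on a held-out split:

```python
import canet

pairs = canet.generate_synthetic(canet.SyntheticSpec(seed=1), "data/synth")
train_pairs, test_pairs = canet.split_train_test(pairs, 160, seed=1)

cfg = canet.tiny_train_config(seed=1, epochs=12, patience=12, val_fraction=0.125)
_, state = canet.train(cfg, pairs=train_pairs)

report = canet.evaluate_model(state.model, test_pairs, cfg.image_size)
print({k: round(v, 4) for k, v in report.means.items()})
```

On one CPU this takes about a minute and prints

```
{'iou': 0.847, 'dsc': 0.9096, 'recall': 0.9304, 'precision': 0.9061,
 'f2': 0.9183, 'hd': 10.0406}
```

i.e. the 40 held-out synthetic images are segmented with mean Dice ≈ 0.91
and mean IoU ≈ 0.85; the Hausdorff column is the mean worst-case boundary
error in pixels at 96×96.  The same pipeline is available from the shell:

```sh
canet synth --n 200 --size 96 --seed 1 --out data/synth
canet train --tiny --data data/synth --out runs/tiny
canet eval  --checkpoint runs/tiny/best.npz --data data/synth
canet predict --checkpoint runs/tiny/best.npz --images data/synth/images --out maps/
canet ablate --tiny --data data/synth --out runs/ablation
```

`canet ablate` trains the six-row module grid (baseline backbone, backbone
swap, each decoder module alone, full model) with a shared seed and writes
one comparison table with columns mIoU / mDSC / Recall / Prec. / F2 / HD.

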