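# Methods

This note records the modelling choices, numerical conventions and known
limitations of the package, in the order a reader meets them.

## Architecture

**Dual encoders, shared skip space.** The transformer encoder (patch embed
→ alternating W-MSA/SW-MSA blocks → patch merging) and the MBConv encoder
produce pyramids at strides 4·2ⁱ. Both are projected into a *canonical*
skip space with the transformer's channel schedule C·2ⁱ: the transformer
side with a per-stage per-token linear map (tokens → dense C×H×W), the CNN
side with per-stage 1×1 convolutions. Fusion of the two pyramids is
element-wise addition by default (`fusion.encoder_mode="concat"` switches
to channel concat + 1×1 reduce). The projections live *inside* their
branches so that enabling/disabling a branch changes the total parameter
count by exactly that branch's parameters — the additive default keeps the
fusion itself parameter-free and the ablation grid comparable.

**Where fusion happens.** Encoders run independently and only their output
pyramids are fused; the fused skips feed whichever decoders are enabled.
With one encoder and one decoder enabled the network reduces exactly to
that branch's U-shape. An alternative reading — injecting CNN features into
the transformer stream *during* encoding — would entangle the branches and
break additive parameter accounting; it is not implemented.

**Decoders.** The transformer decoder mirrors the encoder: patch expand
(linear C→2C, rearrange to a 2×2 block of C/2 tokens, LayerNorm), concat
with the skip tokens and linear 2C→C reduction, then that resolution's
block stack (decoder depths mirror encoder depths; they are a free choice
here). A final 4× expansion with a per-pixel linear head emits logits. The
CNN decoder is the U-Net unit: bilinear 2× upsampling (a learnable
transposed-conv 2×2 is available per block via `upsample="transpose"`),
skip concatenation, two 3×3 conv+BN+ReLU, then two skip-free blocks from
stride 4 to stride 1 (channels halving, floor 8) and a 1×1 logit head.
The two decoders' logits are averaged (`fusion.output_mode="sum"`
selectable); the mean keeps single- and dual-decoder runs on one scale.

**Classification.** The classifier keeps only the encoders: the stride-32
(bottleneck) maps of the enabled encoders are channel-concatenated, global
average pooled, and passed through one fully connected layer. Concatenation
(rather than addition) was chosen so the head sees both branches'
bottlenecks unmixed; with one encoder it degenerates to plain pooling.
`transfer_encoder_weights` copies every encoder parameter and buffer
bit-exactly from a segmentation model and leaves the head at its fresh
initialisation.

## Transformer conventions

* Relative-position bias table has (2M−1)² rows per head, indexed by
  (Δy+M−1)(2M−1)+(Δx+M−1); per-axis displacements span [−M+1, M−1].
* Attention scale 1/√d with d the per-head dimension; qkv and output
  projections carry biases; bias table initialised trunc-normal(0.02).
* LayerNorm ε = 1e-5; GELU is the exact erf form; MLP hidden ratio 4.
* Attention/path dropout are 0 — reproducibility of tests comes first.
* Grids not divisible by the window are zero-padded right/bottom before
  partitioning and cropped after; padded positions are masked out of
  attention (they form their own mask region), which preserves the
  partition/reverse round-trip bit-exactly. When a grid is no larger than
  the window, the window clamps to the grid and the shift is disabled
  (shifting a single window is a no-op modulo the window).
* The additive mask value is −1e9, which underflows to exactly zero
  weight after softmax in float64.

## CNN conventions

* MBConv: 1×1 expand (skipped at ratio 1) → depthwise k×k → squeeze-excite
  (squeeze = max(1, ⌊in/4⌋), biased 1×1 convs) → 1×1 project; BN after each
  conv, Swish activations, residual when stride 1 and in == out.
* Width rounds to multiples of 8 with the usual never-below-90 % rule;
  depth rounds up. Variants b0–b3 use multipliers (1.0,1.0), (1.0,1.1),
  (1.1,1.2), (1.2,1.4); `tiny` (0.25, 0.25) is the desk-scale variant used
  by tests and can be truncated at a smaller bottleneck stride.
* Stem is a 3×3 stride-2 conv+BN+Swish; pyramid taps take the last block
  at each stride (the richest features per resolution).
* The backbone parameter ledgers (`onet.backbones`) count the standard
  1000-class configurations so totals are comparable with commonly quoted
  numbers; the Inception v3 ledger omits the auxiliary training head.

## Training

* Segmentation loss: 0.4·cross-entropy + 0.6·(1 − soft Dice averaged over
  foreground classes), the convention of the U-shaped transformer
  segmentation lineage; weights configurable, ε = 1e-6 in the soft-Dice
  ratio. Classification uses plain cross-entropy.
* Optimizers: SGD momentum 0.9, weight decay 1e-4, default lr 5e-2 (the
  value a learning-rate sweep over 1e-1 … 1e-3 favours for multi-organ
  CT-style segmentation) or AdamW at lr 1e-4 for the dermoscopy-style
  setting. The desk-scale toys use lr 5e-2 SGD (segmentation) and 1e-3
  AdamW (classification head fine-tune), stopping early once the train
  metric clears 0.97 / 1.0.
* Augmentation: random horizontal/vertical flips and k·90° rotations
  applied identically to image and mask; optional small-angle rotation
  with nearest-neighbour mask resampling is off by default.
* Validation split is deterministic by image index (last 20 %); training
  is fully seeded (data order, augmentation, init) and reruns reproduce
  loss traces bit for bit on the same machine.
* Non-finite loss aborts with a diagnostic rather than training on.
* Checkpoints are `.npz` parameter/buffer archives plus a JSON sidecar of
  the architecture configuration; prediction auto-pads inputs to the
  model's total stride and crops the argmax masks back.

## Metrics

* Confusion counts are one-vs-rest per class. Dice of two empty masks is
  1.0; ratios with empty denominators return 0 with a warning — both keep
  batch aggregation finite. Accuracy equals pixel accuracy for binary
  per-class counts (the formula's "TP+TF" numerator is read as TP+TN).
* Contours are foreground pixels with a background 4-neighbour; image
  borders count as contour. Distances are Euclidean in pixel units (2-D
  slices carry no spacing metadata).
* Hausdorff is the exact max form by default; `percentile=95` gives HD95.
  Classes absent from both masks score Dice 1 and are excluded from the
  HD mean; classes present in exactly one mask have undefined HD (NaN,
  excluded). Whether a benchmark's "HD" column is max-HD, HD95 or an
  average surface distance is often unstated — both forms are provided
  and neither is claimed to reproduce any particular table.
* ROC AUC is the midrank Mann–Whitney statistic (ties handled exactly).

## Synthetic data

The generator emulates what matters for exercising the pipeline: a few
compact structures (ellipse / rectangle / annulus, one kind per class) of
distinct mean intensity on a noisy background, non-overlapping, with
pixel-exact masks and a separable classification target (class of the
largest shape; E[presence] = 2/3 per foreground class). Defaults: 224×224
grayscale, 4 classes, semi-axes between size/14 and size/4 pixels,
intensity means 0.15 (background) and 0.35–0.85 (classes), noise σ 0.05.
One master seed spawns a separate stream per image index, so extending a
dataset never changes existing images. It deliberately does **not**
reproduce CT Hounsfield statistics, dermoscopic colour texture, organ
shape priors or annotation noise — passing tests show the machinery
learns and evaluates correctly, not that it matches clinical accuracy.

## Problem sizes

Tests and the acceptance script run the `tiny` configuration (C=24,
depths (1,1), heads (2,2), window 4, `tiny` CNN variant, 64×64 grayscale
inputs): 101 420 parameters, which the package's own numpy engine trains
in a few dozen SGD steps. The full-size defaults (C=96, depths (2,2,6,2),
EfficientNet-b3, 224×224) construct and run forward/backward but are not
trained in the test suite. Desk-scale learning checks use 8 images —
enough to make memorisation a meaningful end-to-end assertion while
keeping runs under a minute.

## Known limitations

* Float64 numpy throughout: correct and reproducible, but orders of
  magnitude slower than GPU frameworks; full-resolution training is out
  of reach by design.
* No pretrained weights; the optional checkpoint import in the CNN branch
  reads this package's own `.npz` format only.
* 2-D only; no volumetric windows or 3-D surface distances.
* BatchNorm running statistics make eval-mode outputs depend on training
  history; toy evaluations therefore report train-set metrics after
  convergence.
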