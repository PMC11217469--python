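# Methods

This note records the model as implemented, the defaults and why they are
what they are, what the synthetic data does and does not exercise, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Model

The backbone is a four-stage hybrid of multi-branch grouped convolutions
(EC blocks) and sandwich-layout transformer blocks (ET blocks) whose token
mixer is grouped cascade attention (GCA). The design assumptions:

- **Small-lesion, small-data regime.** Every stage mixes convolutional and
  attention computation rather than reserving attention for late stages, so
  local detail and long-range context are both available at every scale.
- **Attention redundancy.** Full multi-head attention computes h highly
  similar maps over the full channel width. GCA gives each head a distinct
  1/h channel slice (diversity by construction, cost ÷h) and cascades head
  outputs (depth without parameters).
- **Windowing.** Attention is restricted to m×m spatial tiles; cost is
  linear in image area. m = 7 divides each stage resolution (56, 28, 14, 7)
  evenly at 224 input, so no window is ever ragged.

### Choices the architecture description leaves open

These were genuinely open; each is fixed here as a package convention:

- **Per-head value width = dim/h.** The cascade adds head j−1's *output* to
  head j's channel slice, which forces the value width to equal the slice
  width. (A free value width would make the cascade shape-inconsistent.)
- **Attention scale** is `key_dim^(-1/2)`, the standard scaled dot-product.
- **Q-side local interaction** is a residual depthwise 3×3 convolution on
  the projected queries, applied before windowing.
- **Projection-then-window order.** q/k/v are projected (and batch-
  normalized) on the full map, then window-partitioned. Windows are
  enumerated row-major; heads follow channel order; the cascade follows
  head order.
- **Normalization** is batch normalization after every convolutional
  projection, consistent with the conv-realized layers elsewhere in the
  network; there is no layer norm anywhere.
- **Residual wrapping.** Patch embedding, FFN and the attention layer are
  all residual. With all weights zero an ET block is the identity, which
  keeps deep stacks trainable from scratch.
- **EC stride convention.** The shape-preserving EC variant uses stride 1;
  downsampling within a stage happens in its first EC block, so the ET
  block always runs at the stage's final resolution. The 1×1 branch shares
  the 3×3 branch's group count, which is what makes exact single-conv
  fusion possible.
- **Stem groups = 1**: 3 input channels admit no useful grouping into 64
  outputs.
- **Non-divisible spatial sizes** are a hard error by default; an opt-in
  flag (`pad_windows`) zero-pads bottom/right before windowing and crops
  after merging.

### Calibrated defaults

Channel widths, repeats and the window size are fixed by the architecture;
the remaining knobs (heads, key_dim, ec_groups, n_ffn, ffn_ratio,
pe_groups) are not printed anywhere and were calibrated once, by a small
integer grid search, so that the default model's analytic totals land on
the published complexity budget of ~25.2 M parameters and ~6.4 G MACs at
224×224 with a 3-class head. The frozen result:

| knob | default | meaning |
|---|---|---|
| heads | 4 | GCA heads per stage |
| key_dim | 16 | per-head q/k width |
| ec_groups | (8, 8, 4, 2) | EC conv groups per stage |
| n_ffn | 2 | (patch-embed + FFN) pairs per side of attention |
| ffn_ratio | 3 | FFN expansion |
| pe_groups | (4, 4, 8, 4) | patch-embed conv groups per stage |

The per-stage group counts are the lever that lets both totals land at
once: parameters scale with 1/g while a layer's MAC/parameter ratio is set
by its stage's resolution, so shifting grouping across stages trades the
two totals against each other. The resulting model reports 25.17 M / 6.39 G
(`examples/complexity_summary.py` prints the per-segment table).

**"FLOPs" means MACs here.** The accounting counts one multiply–accumulate
as one operation — the dominant convention in the vision literature's
complexity tables (a ResNet-50 is 4.1 G under it). Normalization,
activations and residual additions are excluded. Parameters count every
learnable array, including batch-norm affine terms.

## Training

Defaults follow the published recipe: 224×224 inputs, batch 32, Adam at
lr 1e-4, weight decay 0.1, cosine annealing to zero over 300 epochs;
augmentation is random resized crop, horizontal flip (p = 1/2) and
per-channel standardization only.

- **Weight decay is decoupled** (AdamW-style) and applied only to conv and
  linear weights, not biases or norm parameters. A coefficient of 0.1 fed
  through Adam's gradient path as classic L2 would dominate the loss
  gradient at lr 1e-4; the decoupled reading is the one under which the
  recipe is sane.
- **Loss** is categorical cross-entropy with one-hot targets, *averaged*
  over the batch (a batch-sum would couple the effective lr to batch size).
- **Crop scale** defaults to (0.7, 1.0) of the image area — conservative so
  small lesions survive cropping.
- **Normalization constants** default to dataset-computed channel mean/std
  (from up to 200 images), with fixed natural-image constants available.
- An 8:2 stratified split helper mirrors the usual train/test division; no
  validation-based model selection is built in.

All randomness (init, shuffling, augmentation) flows from explicit seeds;
two runs with the same seed reproduce the first-epoch loss exactly.

## Metrics

Accuracy, precision, recall and F1 come from the confusion matrix,
one-vs-rest per class. Multi-class values are **macro** averages — the
unweighted mean over classes — stated as this package's convention. AUC is
the rank statistic (sum of positive ranks − M(M+1)/2)/(M·N) with average
ranks for ties, identical to pairwise win-counting with ties at ½;
multi-class AUC is one-vs-rest on each class's predicted probability,
macro-averaged, with single-class columns reported as undefined rather
than as a number. ROC curves are threshold staircases whose trapezoid area
equals the rank AUC in the absence of ties.

## Synthetic data

The generator emulates the *structure* of small medical-image sets: smooth
low-frequency backgrounds with pixel noise, class-conditional soft-edged
elliptical inclusions (size range, signed contrast, optional sinusoidal
texture), a lesion-free "normal" class, 2–4 classes, optional class
imbalance (a colon-slide-like 18:14:23:11 preset). It does **not** model
speckle physics, acquisition artefacts, anatomy, inter-observer label
noise, or any real covariate structure — so green tests demonstrate that
the pipeline (generation → training → evaluation → fusion) is correct and
has learning capacity, not that the architecture reaches any particular
accuracy on clinical data.

Default image size is 224 (matching the model input, no resize needed); a
64-pixel preset pairs with the width-reduced model configuration
(channels ÷8, repeats (1, 1, 2, 1), window 2) for fast tests.

## Numerical choices

- Everything runs in float64; convolutions are im2col + BLAS, backward is
  col2im. Activations are cached for backprop only in training mode, so
  inference on the full model stays memory-light.
- Softmax subtracts the row max before exponentiation; cross-entropy clips
  probabilities at 1e-300 before the log.
- Batch-norm running statistics use momentum 0.1 with the unbiased variance
  correction; eps is 1e-5. Branch fusion requires eval mode (frozen
  statistics) and raises otherwise.
- Conv weights use He initialization (fan-in); the classifier layer uses a
  uniform ±1/√fan_in; norm layers start at identity. Initialization is
  seeded through `ModelConfig.seed`.
- Test sizes: the unit suites run on 4–16 channel layers at 4–14 pixel
  resolutions; the training smoke test uses 32 images at 64 px for 200
  steps; the acceptance script's three-class run uses 90 images for 60
  epochs. These sizes are chosen so the whole suite runs comfortably on a
  single CPU while still exercising every code path at full depth.

## Known limitations

- No GPU path and no float32 fast path; wall-clock throughput is not a goal.
- The label-noise robustness questions raised by histology datasets are out
  of scope (no noise-handling machinery).
- Whether reported metrics should come from the last or the best epoch is
  left to the caller; `train` returns the full history and takes no
  model-selection decision.
- The exact head counts and key widths of the published configuration are
  unprinted; the calibrated defaults reproduce its complexity budget, not
  necessarily its exact layer shapes.
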