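# Methods

This note documents the models, the training procedures, the synthetic data
the package is exercised on, and the numerical and design choices a
maintainer would want to know. It states no empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The target domain is object detection in images where the objects are
small (a few to a few dozen pixels), low-contrast, and embedded in noise —
the regime of lesion detection in low-resolution medical imagery. The
pipeline couples three ideas: masked-patch self-supervised pretraining to
learn structure from unlabeled images, window-restricted self-attention to
concentrate modeling capacity locally while keeping cost linear in image
area, and a single-stage anchor head for dense prediction.

## Synthetic data generator

`maskdet.synthetic` renders grayscale images in [0, 1]:

* **Background**: a mixture of three low-frequency 2-D cosines with random
  frequency, phase and amplitude, rescaled to [0.3, 0.7]. This gives smooth
  intensity gradients resembling tissue background without anatomical
  structure.
* **Lesions**: 0–5 rotated ellipses per image, rendered by 4× supersampling
  of the ellipse indicator (anti-aliased coverage in {0, ¼, ½, ¾, 1}),
  added with a signed contrast drawn from ±[0.25, 0.55]. Each annotation is
  the tight bounding box of the rendered coverage mask (pixel-scan, so the
  boxes are exact by construction).
* **Noise**: additive Gaussian with configurable σ (default 0.05 on the
  [0, 1] scale), applied after lesion compositing, then clipped.
* **Placement**: rejection sampling (≤100 attempts) keeps every ellipse
  fully inside the image and pairwise box IoU ≤ 0.3; overlap up to 0.3 is
  allowed deliberately so NMS and greedy matching are exercised honestly.
* **Size modes**: semi-axes are drawn from [2, 13] px in `small` mode
  (rendered boxes ≤ 27 px per side, area < 32²) and [17, 40] px in `medium`
  mode (areas in [32², 96²)), aligning the generator with the size-banded
  AP definitions.
* **Determinism**: a master seed spawns per-image seeds through
  `numpy.random.SeedSequence(master, index)`; equal (seed, config) gives
  bit-identical pixels and annotations.
* **Splits**: 70/15/15 train/val/test by `round`, remainder to test.

What the generator does **not** emulate: anatomy, CT windowing, DICOM
physics, 3-D context, inter-slice correlation, or class-dependent lesion
appearance (classes differ only by label, not morphology — classification
here tests the plumbing, not radiology). Passing tests on these images
therefore demonstrate that the algorithms are implemented correctly and can
learn this controlled task; they say nothing about clinical performance.

## Autodiff engine

All models run on `maskdet.autodiff`, a reverse-mode engine over float64
numpy arrays with the exact operator set the models need. Backward closures
receive the upstream gradient as an argument and never reference their own
output tensor, so the graph is acyclic in the reference-counting sense and
is freed as soon as the loss goes out of scope (this matters: the naive
self-referencing formulation leaks until the cycle collector runs).
Gradients of every operator and of the full transformer block are verified
against central differences in the test suite.

## Masked autoencoder

* Patch size default 16 with smaller values used in the toy configurations;
  tokens are flattened patches in row-major grid order.
* Masking: uniform random without replacement; mask count =
  `round(ratio × n)`; default ratio 0.75 (upper end of the 65–75% band that
  the mask-ratio ablation favors); resampled every step.
* Encoder: pre-norm ViT blocks over **visible patches only**, with fixed
  2-D sine-cosine positional embeddings added before the stack. The
  alternative reading (encoder sees mask tokens too) is rejected: it wastes
  encoder capacity and breaks the exclusion contract tested in
  `test_encoder_ignores_masked_patch_content`.
* Decoder: a lighter stack (defaults: half width, half depth) over the full
  sequence, masked slots filled with one shared learnable token plus the
  slot's positional embedding; linear head back to pixels.
* Loss: mean squared error over **all** pixels by default (the literal
  objective), with a masked-positions-only option (`loss_on="masked"`,
  the common MAE practice).
* Optimizer: Adam; the package default learning rate is 1e-4 with batch 32,
  dropout 0.5 and L2 weight 5e-4; toy configurations use 3e-3 / smaller
  batches / no dropout because at width ≤ 64 and ≤ 30 epochs the default
  rate barely moves the loss.
* `transform` reconstructs with a random mask at the training ratio and
  keeps original pixels at visible positions — the encoder never saw
  unmasked sequences during training, so feeding one would be out of
  distribution.

## Window-attention backbone

* Attention logits use the conventional 1/√d scaling by default; a
  `scale_mode="linear"` switch (1/d) is provided for the alternative form.
  Multi-head (default 4) reduces to the single-head equations at
  `n_heads=1`, which is the configuration the oracle tests pin down.
* W-MSA: the grid is padded to a multiple of the window size M (default 4),
  tiled into non-overlapping M×M windows, and attention runs per window;
  pad positions are masked out of the softmax.
* SW-MSA: cyclic roll by ⌊M/2⌋ in both axes, windowed attention with an
  additive −1e9 mask on token pairs originating from different regions
  (wrapped across the boundary) — equivalent, as tested, to running plain
  attention on each contiguous sub-window of the rolled layout.
* Block pair: LN→W-MSA→residual; LN→MLP→residual; LN→SW-MSA→residual;
  LN→MLP→residual (standard consecutive pre-norm form).
* Patch merging between stages: concatenate 2×2 neighbours, LayerNorm,
  linear 4C→2C. Stage s output (pre-merge) is emitted for the neck, giving
  channel widths C, 2C, 4C, …
* Positional embeddings: the fixed sine-cosine table is **optional** in the
  backbone (`use_pos`). The detector disables it by default: absolute
  position channels let a small model memorise training-image layouts, and
  removing them (making the backbone translation-equivariant up to window
  alignment) measurably improves held-out detection in the toy regime.
  The autoencoder always uses positions (reconstruction needs them).
* Relative position bias is deliberately omitted.

## Detector

* **Anchors**: 3 priors per pyramid level, estimated by k-means on training
  box shapes under the 1−IoU distance (median update), split across levels
  by area; fixed priors can be supplied instead.
* **Assignment**: each ground truth takes its best-shape anchor (shape IoU
  of centered rectangles) plus any anchor above `multi_assign_thr` (default
  0.5); the containing cell and its two nearest neighbour cells are
  responsible (the expanded decode below lets neighbours reach the center).
* **Decode**: center = (cell + 2σ(t) − 0.5)·stride, size = prior·exp(t),
  with t clipped to ±4 before exp for numerical safety; boxes are clipped
  to the image at inference only (clipping is left out of the training
  graph to keep gradients alive).
* **Losses**: box −ln(max(IoU, 1e-7)) on assigned pairs (weight 2 in the
  toy configuration); per-class cross-entropy on softmax class
  probabilities clamped to [1e-7, 1−1e-7]; objectness BCE-with-logits whose
  positive targets are the IoU that each cell-centered prior has with its
  best ground truth (`obj_target_mode="anchor_iou"`). These targets are
  purely geometric, hence stationary over training and comparable across
  images, which stabilises the confidence ranking; the dynamic variant
  (targets = IoU of the current decoded box, `"pred_iou"`) is kept as an
  option. Positive and negative objectness terms are normalised separately
  (negatives weighted `noobj_weight`), otherwise the dense background
  drowns the rare positives.
* **Augmentation**: the training loop samples one of the 8 symmetries of
  the square (4 flips × transpose) per image per step, realised as index
  permutations on patch tokens. No photometric or test-time augmentation.
* **Optimizer**: Adam with a linear warmup (first tenth of the epochs) into
  a cosine decay; classic L2 on all parameters.
* **Inference**: sigmoid objectness × max softmax class probability scores
  each anchor; candidates above `conf_thr` are clustered by score-weighted
  box fusion (IoU > 0.3 within class; the fused box is the score-weighted
  average, which cancels per-anchor regression noise — important for small
  boxes where one pixel moves the IoU a lot) and then passed through
  class-wise greedy NMS (IoU 0.45, score-then-index tie-break).
* **Pretraining hand-off**: default wire-up copies the autoencoder's patch
  projection into the backbone embedding and each encoder block into the
  W-MSA half of a stage-0 block pair (shape-matching pairs only). The
  alternative (`backbone_init="denoised"`) trains the detector on
  mask-reconstructed images instead.

## Evaluation

* Greedy confidence-descending matching; each detection claims the
  unmatched ground truth with the highest IoU ≥ threshold; ties between
  ground truths resolve to the lowest index. Classification accuracy is
  per ground truth under class-agnostic matching at IoU 0.5 (an unmatched
  ground truth counts as an error).
* AP: 101-point interpolation — the right-running maximum of precision
  evaluated at recall 0.00, 0.01, …, 1.00; unreached recall contributes 0.
  A scene with no ground truths and no detections has AP 0 by convention.
* Size bands are half-open: [0, 32²), [32², 96²), [96², ∞). Band AP
  restricts ground truths to the band and discards detections matched to
  out-of-band ground truths; unmatched detections count as false positives
  in every band. Bands without ground truth are undefined and are dropped
  from the composite mean (with a warning) rather than scored 0 — a
  synthetic scene with no large objects should not be penalised on AP_L.
* The composite mAP is the arithmetic mean of AP50, AP75, AP_S, AP_M, AP_L
  (the latter three at IoU 0.5); the conventional COCO mAP@[.5:.95] is
  reported alongside under its own name.

## Toy-scale reference configurations

The self-contained study conditions used by the tests and the acceptance
script (chosen once as a realistic desk-scale instance of the generator's
regime): 64×64 grayscale images, 1–3 small lesions per image, noise σ 0.05,
200 images (140/30/30). The reference autoencoder uses patch 4, width 32,
1+1 blocks, mask ratio 0.75, 20 epochs; the reference detector uses patch 4,
base width 32, one block pair per stage at strides 4 and 8, 3 anchors per
level, 40 epochs at batch 4. The mask-ratio comparison runs a further
reduced instance (48×48, 80 images, 10+12 epochs) so that one full
pretrain+train+evaluate cycle takes seconds.

## Known limitations

* Single-channel images only in the trainable pipeline (the patching layer
  itself handles RGB).
* All images in one fit must share one size; there is no mosaic/resize
  pipeline.
* The detector's accuracy on multi-class scenes is limited by the
  generator's class-independent morphology: classes are only separable by
  chance, so multi-class configurations exercise mechanics, not learning.
* Float64 numpy on one CPU: fine at toy scale, not a route to full-size
  training.
* At these model and data sizes, run-to-run variation of detection AP
  across seeds is substantial; single-seed comparisons of design choices
  are unreliable (the package's own tuning used multi-seed means).
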