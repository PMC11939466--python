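# Methods

## Problem and model

The package classifies 350 × 350 histopathology patches ("signatures")
into three classes — background/`others`, irregular epithelial
stratification, and bulbous rete ridge — and slides the classifier over
whole images to localize the two dysplastic features. The classifier is
a compact CNN:

* **Convolution block** *(repeated 5×, channels 16/32/64/128/256)*:
  an *l₁*-dilated *w₁* × *w₁* convolution (default 3 × 3, dilation 1),
  batch normalization, ReLU; then an *l₂*-dilated *w₂* × *w₂* convolution
  (default 1 × 1 pointwise), batch normalization, ReLU; then 2 × 2 max
  pooling with stride 2. All convolutions are *valid* (no padding) and
  use the cross-correlation convention (kernels are not flipped); both
  carry bias terms and BN carries affine scale/shift. With these
  conventions the reference configuration counts exactly 1,014,867
  trainable parameters, and a 350-pixel side shrinks 348 → 174 → 172 →
  86 → 84 → 42 → 40 → 20 → 18 → 9 through the five blocks.
* **Global pooling**: each of the *M* final feature maps is reduced to a
  scalar by mean (GAP), maximum (GMP) or log-sum-exp (GLSEP); GLSEP is
  computed max-shifted, `m + log Σ exp(h − m)`, so it is exact for any
  magnitude and satisfies `GMP ≤ GLSEP ≤ GMP + log(F₁F₂)`.
* **Head**: dense layer of width *h₁* (default 2048) with ReLU and
  inverted dropout (survivors scaled by 1/(1−p) during training, identity
  at inference), then a 3-way output with softmax probabilities.

Inputs are converted from unit-scale RGB to YCbCr with the fixed affine
map `[16 128 128]ᵀ + (1/256)·A·[R G B]ᵀ`. Applied at unit scale this
confines Cb/Cr to 128 ± 0.44 and Y to [16, 16.86]; a `rgb_scale="8bit"`
switch applies the matrix at the conventional 0–255 scale instead. The
channel ranges are immaterial to the classifier because the trainer
standardizes each channel (mean/sd computed on the training split, stored
on the model and re-applied at inference). Standardization also protects
the texture signal when the forward pass runs at half precision, where
the resolution near 128 is only 0.0625.

## Training

* **Loss**: weighted cross-entropy `l_n = −w_c·(x_c − logsumexp(x))`
  with `w_c ∝ 1/n_c`, normalized so Σw_c = C. Any positive rescaling of
  the weights only rescales the gradient, which Adam largely absorbs; the
  Σw = C convention keeps the loss comparable to the unweighted one.
* **Optimizer**: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) on float32 master
  weights. Learning rate 10⁻³ halved every 50 epochs
  (`lr(e) = 10⁻³·0.5^⌊e/50⌋`). Defaults: 200 epochs, batch 32.
* **Precision**: `full_32` runs everything in float32; `mixed_16_32`
  casts the convolution/dense arithmetic of the forward and backward
  passes to float16 and converts the gradients back to float32 for the
  optimizer step. Batch-norm statistics always accumulate in float32.
  The two modes are contractually accuracy-neutral (final losses within
  5% on the synthetic library).
* **Cross-validation**: stratified K = 4 folds; per label, signatures are
  shuffled deterministically from the master seed and dealt round-robin,
  so every fold contains all classes and proportions match within one
  signature. Each fold trains an independently initialized model (seed
  offset per fold) and is scored on its held-out chunk; the summary is
  the mean ± sd of fold accuracies.
* **Metrics**: accuracy = trace/total; per-class precision/recall/F1 are
  combined by support weighting, which makes weighted recall identically
  equal to accuracy (Σ (n_c/N)(TP_c/n_c) = trace/N) — a useful internal
  consistency check on any reported table.
* **Seeding**: one master seed drives fold assignment, weight
  initialization, shuffling and dropout masks; run manifests record it.

The whole network stack (im2col dilated convolutions, BN, pooling, dense
layers, backpropagation, Adam) is implemented directly on numpy. The
layers are verified against an independent loop-based evaluation of the
dilated-convolution sum and against finite-difference gradients in
float64. One caveat found during verification: with zero-initialized
biases, pixels whose inputs are all ReLU-clipped sit *exactly* on the
next ReLU's kink, where central differences disagree with the (correct)
subgradient; the gradient test therefore randomizes biases first.

## Signature library

The patch-labeling rule is area coverage: a grid patch takes a feature
label when that class's mask covers ≥ `positive_fraction` (default 0.5)
of its area, ties broken toward the rarer bulbous class; otherwise
`others`. The extraction grid stride defaults to 50 px for library
building (the blind-scan stride is 10 px; library stride is a free
choice bounding patch counts). Augmentation (three flips/rotations)
applies to the training portion of the bulbous class only, multiplying
its count by four — 607 → 2428 in the reference tally, for an augmented
training total of 11,786.

## Synthetic data

The generator emulates the *statistical* contrast between the classes,
not histology:

* background: eosin-pink field with hematoxylin-purple nucleus dots on a
  regular row lattice (`row_spacing`, default 14 px; `dot_spacing` 11 px;
  `dot_radius` 3 px) with ±1 px lattice jitter;
* irregular stratification: dot positions jittered by
  `stratification_disorder` (default 0.75) × row spacing in both axes
  and dot radii spread by ±2·disorder — uneven arrangement of the same
  elements. At disorder 0 nothing is perturbed and no region is marked;
* bulbous rete ridges: solid teardrop blobs — half-width shrinking as
  (1−t)^0.6 from a broad base to a narrow top — in the nucleus hue;
* Gaussian pixel noise (sd 0.02), clipped to [0, 1].

Regions are placed in distinct patch-aligned grid cells with a 2 px
inset. This guarantees by construction that class masks are disjoint,
each ridge is one 8-connected component, and some extraction window
(when the stride divides the patch size) covers each region by more than
half its area, so no class silently vanishes from a generated library.
Defaults: 1050 px slides, 20 slides, 1–3 ridges and 1–2 stratification
regions per slide, 80/20 train/test split *by slide*.

What passing tests show — and do not show: the generated classes are
separable by local texture statistics (large solid blobs; dot-spacing
variance), so a reduced network reaching ≥ 95% held-out accuracy
demonstrates that extraction, weighting, training, and evaluation are
wired correctly. It says nothing about accuracy on real H&E slides,
which vary in stain color, magnification and morphology far beyond this
generator.

## Detection

Window scores (stride 10, softmax triplets) are thresholded per class;
firing windows paint their full 350 × 350 extent onto a coverage mask
(difference-array accumulation, so the sweep is O(windows) per
threshold) and 8-connected components of the mask become countable
regions. A ground-truth region counts as detected if any predicted
region of its class overlaps it by ≥ 1 pixel; one predicted region
overlapping two ground-truth regions detects both; multiple predicted
regions hitting one ground-truth region count it once. False positives
are predicted regions overlapping no ground-truth region of their class,
normalized per image. Because coverage masks shrink monotonically as the
threshold rises, the probability of detection is non-increasing in the
threshold. Alternates are available by argument: center-pixel painting
(`painting="center"`) and IoU matching (`matching="iou"`, threshold
0.25). The default threshold sweep is 101 evenly spaced values in [0, 1].

## Desk-scale problem sizes

The full 350 × 350 / five-block geometry is exercised by construction,
shape-inference and parameter-count tests. Learning-dependent checks run
at a reduced scale chosen once: 288 px slides, 96 × 96 patches, three
blocks (8/16/32 channels, hidden width 64), 16 slides, 24 epochs —
about two minutes of single-core compute — and the miniature unit-test
scale is 96 px slides with 32 × 32 patches and one block. The `ablate`
command accepts the same overrides to shrink the 16-architecture sweep.

## Known limitations

* No stain normalization or H&E deconvolution; stain-color shift moves
  YCbCr values and would degrade a model trained elsewhere.
* Images smaller than the window are rejected rather than padded;
  partial windows at image borders are simply never scored.
* The numpy implementation is single-threaded BLAS-bound; it is sized
  for the desk-scale experiments, not for whole-slide throughput.
* Exponentially chained dilation schedules are deliberately out of
  scope; dilations are per-layer constants from the ablation vocabulary.
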