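# Methods

## Problem

In droplet-based microfluidic (DBMF) secretion assays, cells are
encapsulated in ~40 pL water-in-oil droplets together with paramagnetic
nanobeads that, under a magnetic field, align into a vertical column — the
*beadline* — serving as the capture surface of an in-droplet immunoassay.
Because encapsulation follows Poisson loading, droplets must be classified
by the number of cells they contain (Empty/0, Single/1, Multiple/2) before
any per-cell quantity can be measured.  The only label-free channel is
brightfield, where the beadline both *occludes* cells that touch it and
*mimics* cells through occasional blob-like irregularities.  `dropclass`
implements a preprocessing pipeline that erases the beadline before a
residual-network classifier sees the image, plus three conventional
cell-counting baselines and an evaluation harness.

## Preprocessing model

The full pipeline is, in order:

1. **Horizontal-edge Prewitt convolution** with the kernel
   `[[+1,+1,+1],[0,0,0],[-1,-1,-1]]` (`scipy.signal.convolve2d`, same-size
   output, zero-padded border).  Any structure constant along the vertical
   axis — in particular an ideal beadline — has exactly zero response,
   while horizontal cell contours map to ±3·h for a step of height h.  The
   sign asymmetry (white above / black below an edge) is a property of the
   kernel and carries no information the classifier needs.
2. **Bisigmoidal contrast filter**: with per-image minimum m, maximum M and
   mean μ,

       out = S · ( σ(−α₁) + σ(α₂) − 1/2 ),   σ(x) = 1/(1+e^{−x})
       α₁ = min((p − m + μ)/D, C),  α₂ = min((p − M + μ)/D, C)

   with scale S = 24000, divisor D = 600, cap C = 700.  Both arguments are
   additionally clamped below at −C; C = 700 sits just below the
   double-precision overflow threshold of e^x, which is its evident
   purpose.  The output is confined to the open interval (−S/2, 3S/2), so
   half its peak-to-peak range equals S.  The printed form of α₁/α₂ is
   typographically ambiguous; the parse above uses each of min/max/mean
   exactly once per branch and is isolated in one function so it can be
   swapped.
3. **Resize** to 55×55, bilinear (`skimage.transform.resize`, order 1),
   explicitly *without* anti-aliasing.
4. **Min-max normalization** to [0, 65535] (per-image minimum → 0, maximum
   → 65535; constant images map to zeros with a warning), followed by a
   **circular mask** zeroing everything at distance ≥ 55/2 − 5 from the
   image center, which removes the droplet rim and intruding neighbor
   droplets.

The *minimal* control variant is resize + normalization only.  Stage order
is convolve → bisigmoid → resize → normalize → mask; the module contains
no randomness.

### Dynamic-range regime

The bisigmoid highlights only pixels whose Prewitt response lies within a
few multiples of D = 600 counts of the per-image extremes.  With zero
padding those extremes are ±3×background (the border rows), so a structure
of absolute intensity v is visible after the filter in proportion to
σ(−v/200): structures must be within a few hundred counts of black for the
published constants to produce the graded contour enhancement the pipeline
relies on.  This is the regime of dim, short-exposure brightfield frames,
and the synthetic generator's default intensity levels are chosen inside
it (background 20000; rim 150, beadline 100, cell ring 500 counts).  At
mid-gray structure intensities the filter saturates and flattens all
contours — no usable acquisition would operate there.

## Synthetic droplet generator

`simulate` renders what the pipeline assumes about the data: a square
16-bit crop whose side equals the droplet diameter plus a 2-px margin
(default side 110, radius 53), containing

* a dark circular rim (ring of thickness 2 px),
* an optional beadline: a vertical stripe of width 3–6 px through the
  center, column-constant over the full crop height, composed with the
  scene by pixelwise minimum (darkest structure wins — occlusion is
  physical).  With probability `beadline_irregularity` (default 0.1) one
  ellipse-shaped blob 1.5–2× the line width is added on the line,
  emulating the morphological irregularities that mimic cells;
* 0–4 cells drawn as dark rings (thickness 1.8 px, radius 5–8 px) with
  slightly brighter interiors (+600 counts), the defocused brightfield
  lymphocyte look; centers uniform in the droplet with a small pairwise
  clearance, and cells may sit on the beadline (the hard case).  Failure
  to place cells after bounded retries raises rather than under-placing;
* arc fragments of neighboring droplets intruding at the border
  (default 2), and additive Gaussian sensor noise (default sd 250),
  clipped and rounded to uint16.

Labels are a pure function of the cell count; the Multiple class draws its
count uniformly from {2, 3, 4}.  Each droplet uses four independent child
streams of `numpy.random.SeedSequence(seed)` (cells, beadline, neighbors,
noise), so toggling one structure leaves the others bit-identical — this
is what makes "same scene with and without beadline" a well-defined
counterfactual.  Chamber mosaics place droplets on a staggered grid with
centers ≥ 2 radii apart and Poisson(0.5) loading, with a planted-truth
table for detection tests.

What the generator does **not** emulate: diffraction/PSF optics, intensity
gradients across the chamber, cell debris and aggregates, focus drift, and
the full morphological variability of real cells.  Passing tests therefore
demonstrate that the pipeline's mechanics behave as designed under the
stated visual model, not that the printed real-data accuracies transfer;
the real-data tables are reproducible only from the deposited microscopy
dataset, which this package reads through the same TIFF/manifest interface.

## Classifier and training recipe

Two residual architectures share one I/O contract (input (n, 55, 55) in
[0, 65535], scaled internally by 1/65535; output 3-way softmax):

* `small` — 3×3 stem (16 ch), max-pool, two strided basic residual blocks
  (32, 64 ch), global average pooling, dense head: an 18-layer-style
  network sized for desk-scale data.
* `50` — the standard bottleneck residual network (stages 3-4-6-3, ×4
  expansion, ~23.5 M parameters), grayscale replicated to 3 channels.

The network stack (im2col convolutions, batch normalization, residual
blocks, manual backprop, SGD) is implemented directly in numpy (`nn.py`)
and verified by numerical gradient checking in development.

Training: categorical cross-entropy minimized by mini-batch SGD at
learning rate 0.001 for 6 epochs, batch 160, on a seeded stratified 95/5
train/validation split.  Two conventions matter and are deliberate:

* **Summed batch loss.** The cross-entropy is summed (not averaged) over
  the mini-batch, i.e. classical empirical-risk mini-batch SGD; the
  effective mean-reduction step is lr×batch = 0.16 at the defaults.  At
  desk scale (≤ a few thousand images, ≲160 updates in 6 epochs) a
  mean-reduced step of 0.001 cannot move the logits of any architecture
  appreciably; the summed convention both trains in this budget and
  reproduces the observed instability of large batch sizes (the effective
  step grows with the batch), which a mean-reduced loss would invert.
  Momentum defaults to 0 and is config-exposed.
* **Batch-norm warm start.** Running statistics are initialized from the
  first training batch and then updated by EMA (momentum 0.1).  With
  ≲160 updates, an EMA started from (0, 1) would still be far from the
  true activation scale at the end of training, leaving inference mode
  inconsistent with training mode.

No augmentation and no pretrained weights are used by default (both are
deliberate omissions, not hooks).  Determinism: a fixed seed gives
identical initial weights and shuffling; run-to-run reproducibility holds
on one machine, bit-identical training across platforms is not promised
(floating-point reduction order).

Predictions carry a confidence = 100 × max softmax probability;
`filter_by_confidence` keeps predictions at or above a threshold and
reports the retained fraction, which is non-increasing in the threshold by
construction.

## Conventional baselines

All three counters map a cell count to a class via 0→Empty, 1→Single,
≥2→Multiple and are restricted to the droplet interior:

* **Hough**: circles of radius 4–10 px on a Canny edge map
  (`skimage.transform.hough_circle`), accepted at normalized accumulator
  ≥ 0.45 with centers strictly inside the droplet (distance < R − r);
  concentric duplicates and double-edge side lobes are suppressed within
  0.8·(r_i + r_j) of a stronger peak.
* **MSER**: dark extremal regions tracked across an ascending intensity
  ladder (step 1500 counts); a region is stable when its relative area
  growth across one step is ≤ 0.35.  Shape filters (area 25–500 px²,
  circularity 4πA/P² ≥ 0.55, centroid inside the interior) act on the
  hole-filled region because a defocused cell's extremal region is an
  annulus.  Written directly on the threshold ladder; no MSER routine
  exists in the scientific stack used here.
* **Morphological segmentation**: Sobel gradient magnitude thresholded at
  Otsu's level, circular interior mask, dilation by two linear structuring
  elements (horizontal + vertical, length `dilatation` = 15), hole
  filling, erosion by the same elements, connected components, centroid
  count.  Structures closer than the element length merge into one
  component by construction.

Defaults were calibrated once on the synthetic fixture set and are all
exposed in `BaselineConfig`.  Their failure under the beadline is the
point, not a defect: the line breaks circularity, occludes touching cells
and (Hough/MSER) contributes blob irregularities that pass cell-shaped
filters.

## Evaluation

Confusion matrices are 3×3 counts (rows = true), per-class accuracy =
100·diag/row-sum, overall = 100·trace/total; accuracies are reported in
percent with one decimal.  Retention curves report, per ascending
confidence threshold, the retained fraction and the accuracy on the
retained subset; an empty subset has *undefined* accuracy, surfaced as
missing and never imputed.  Replicate model scores are compared with
Welch's two-sided t-test (`scipy.stats.ttest_ind(equal_var=False)`,
Welch–Satterthwaite df); two identical constant samples are defined as
(t=0, p=1).  A paired t-test (index-paired) is included for
threshold-condition comparisons across experiments; no multiple-testing
correction is applied.

## Numerical choices and degenerate inputs

* Images are float64 in the pipeline, float32 inside the network; files on
  disk are always uint16 (values rounded and clipped on write).
* 8-bit TIFF inputs are rescaled ×257 (255·257 = 65535) with a log record;
  RGB/multi-channel files are rejected; non-square inputs are
  center-cropped with a warning.
* Constant images: the bisigmoid returns zeros (no contours exist), the
  normalizer returns zeros with a warning (the transform is undefined).
* Circle membership uses strict Euclidean distance; coordinates are
  0-based (row, col); the mask/interior center is ((side−1)/2, (side−1)/2).
* `crop_droplet` pads out-of-mosaic regions with the chamber median.

## Problem sizes used in the shipped experiments

The package's experiment scripts generate 1,500 training and 300 held-out
images per class for the end-to-end accuracy measurement, 400 per class ×
3 replicates per arm for the full-vs-minimal comparison, and 200 per
condition for the baseline-degradation comparison.  These sizes give
stable estimates for the directional and threshold claims being tested
while remaining desk-scale; the full-scale training regime of the original
assay (10⁴–10⁵ images per class) is supported by the same code paths.

## Known limitations

* The beadline-suppression guarantee is exact only for column-constant
  stripes; real beadlines with curvature or intensity texture are
  suppressed approximately, and blob irregularities are *not* suppressed —
  they are left for the classifier to learn.
* The Eq.-parse of the bisigmoid arguments and the symmetric application
  of the cap at −700 are documented interpretations of an ambiguous
  printed formula, isolated in `preprocess._sigmoid_pair`/`bisigmoid`.
* The Prewitt sign orientation (which side of an edge goes white) is
  conventional; both orientations satisfy every stated property.
* Baseline parameter defaults other than the dilatation length are not
  canonical — the original comparison scripts' settings are unpublished —
  so absolute baseline accuracies on synthetic data are not comparable to
  the printed real-data values; only directions are asserted.
* nd2 acquisition files, OME/pyramidal TIFF, fluorescence channels and
  sorting-hardware control are out of scope.
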