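# Methods

## Pipeline model

The package implements a weakly supervised patch-voting pipeline for
histology fields of view.  Only image-level labels exist; every patch
inherits its image's label during training, and at inference the image
label is the mode of its patches' predicted labels.  This is the
standard recipe when the discriminative signal lives at cellular scale
but annotation exists only per image.  Its core assumptions are that
(a) most qualifying patches of an image express the image's class, and
(b) patch errors are sufficiently independent for majority voting to
help — which is why the evaluation always reports patch-level and
image-level accuracy side by side.

## Stain normalization

Staining intensity varies across laboratories and batches; the
normalizer removes this variation before any downstream analysis.
Pixels are mapped to Beer–Lambert optical density,
`od = −log10((I+1)/I0)` with background intensity `I0 = 256` (the +1
keeps black pixels finite and puts a clean background at exactly zero
density).  Tissue is defined as pixels with OD norm > 0.15; blank glass
is never altered.

The two stain directions are estimated per image from the principal
plane of the uncentered tissue OD cloud.  Within the plane, pixel
angles are summarized at the 1st/99th percentiles and linearly
extrapolated to the edge of the angular distribution
(`2·θ(p) − θ(3p)`): a plain percentile cut is robust but biased inward
(it can never reach the pure-stain rays), and the extrapolation removes
that bias while remaining insensitive to sub-percent outliers.  The
vector with the larger blue-channel component is hematoxylin — a
deterministic convention, since hematoxylin is blue-violet.  Pixel
concentrations are the least-squares coordinates in that basis with
negatives clipped to zero.

Normalization maps each stain's tissue-pixel concentration distribution
onto a reference image's by monotone piecewise-linear percentile
matching (grid 0..100; including the extremes makes the identity map
exact rather than tail-clamped) and reconstructs RGB with the reference
basis.  The reference image is a user choice, not automated.  One
consequence worth stating plainly: matching equalizes per-image color
statistics, so across a normalized dataset the class signal is carried
by morphology (nucleus size, shape, granularity, spatial arrangement)
rather than by chromatic intensity.  That is the intended behavior.

## Nuclei segmentation

Nuclei are hematoxylin-dense, so the hematoxylin concentration map
(rescaled by `max(peak, 1)` — the floor prevents noise amplification in
hematoxylin-free images) acts as a nuclear probability surface.  A grid
of 20 thresholds in [0.05, 0.95] is swept; at each threshold the number
of 4-connected components with area in [80, 5000] px² is counted (the
plausible nucleus-size band at 0.233 µm/px, about 2–9 µm equivalent
radius), and the count-maximizing threshold is selected.  This adaptive
selection is what makes the segmenter robust to per-image contrast
differences.  Post-processing fills holes, removes sub-80 px²
components, optionally splits touching nuclei by distance-transform
watershed (off by default), and renumbers labels consecutively.  The
segmenter sits behind a small estimator interface so a different
algorithm can be swapped in without touching the rest of the pipeline;
downstream, only the binary coverage mask matters.

## Patch extraction

480×480 windows are scanned row-major from the top-left corner.  A
candidate is accepted when its nuclear coverage is ≥ 0.20 and it
overlaps no previously accepted window; the column cursor then jumps a
full 480 px, otherwise it advances 48 px (10 %).  The row cursor
advances by 480 px after any acceptance in the row and by 48 px
otherwise — a symmetric convention that keeps dense regions coarsely
tiled and sparse regions finely searched.  Windows crossing the image
edge are skipped rather than padded (padding would fabricate tissue; a
2560-wide frame leaves a 160 px right margin).  Coverage queries use an
integral image, and every extraction is checked against the invariants
(disjoint, in-bounds, above threshold).  An independently coded
window-by-window simulation serves as the oracle in the tests.  At
prediction time an image whose scan accepts nothing still must be
diagnosed; the coarse-grid window with maximal coverage is used as a
deterministic fallback.  The same fallback applies during training, so
low-coverage images are represented in the training distribution with
exactly the appearance they will present at prediction time.

## Patch classifier

No deep-learning framework is part of the dependency set, so the
classifier pairs a fixed convolutional-style front end with a trainable
softmax multilayer perceptron written directly on numpy.  The front end
computes, from patch pixels alone: a nuclear blob profile (the same
multiscale adaptive thresholding applied within the patch, then
component count, area moments and log-spaced area histogram, covered
fraction, eccentricity and solidity moments, within-component intensity
spread as a chromatin-texture proxy, and quadrat dispersion as a
clustering proxy),
per-stain concentration histograms (16 bins each), and — depending on
backbone — a small mean-pooled color layout pyramid.  These are the
statistics a histology CNN's early layers learn; computing them
explicitly keeps single-core training in seconds.  The named variants
(`alexnet_like`, `inception_like`, `resnet_like`) follow the
single-branch / multi-resolution / residual design motifs at matched
budget and exist mainly to give the grading ensemble diverse members;
`tiny_test` is the smallest (profile + histograms only, one hidden
layer of 32).

Features are standardized with training-set statistics.  Training uses
mini-batches of 32, Adam at 10⁻³ with weight decay 10⁻⁴, categorical
cross-entropy, at most 30 epochs, early stopping after 10 epochs
without validation-loss improvement, and restores the
best-validation-epoch weights.  When no validation set is supplied, a
stratified 10 % of the patches is held out; the pipelines instead split
at the image level (all patches of an image on one side) to avoid patch
leakage.  Training samples are canonically ordered by a content digest
before batching, so the fit is invariant to the order in which patches
arrive.  A `transfer_learning` flag is accepted for interface
compatibility; no pretrained weights ship with the package, so
initialization is seeded-random either way.  Models serialize to an npz
weight file plus a JSON sidecar and reload bit-identically.

One caveat stated openly: at these small patch counts, 30 epochs of
batch-32 Adam is near the edge of convergence; the pipelines' dataset
sizes (hundreds of patches) were chosen so that the schedule converges
within its epoch budget.

## Aggregation and evaluation

The image label is the modal patch label; ties break by the highest
mean probability among tied classes, then by class order — a total,
deterministic rule.  The grading ensemble pools every (patch × model)
argmax ballot into one majority vote with the same tie-break;
probability averaging over all ballots is available as an alternative
mode (`mode="average"`), since both readings of an "ensemble decision"
are defensible.  Evaluation reports patch-level and image-level
accuracy, an image-level confusion matrix (rows = truth), and
one-vs-rest ROC/AUC per class scored by the image's mean patch
probability vector (trapezoidal AUC); classes absent from the truth get
NaN AUC rather than a fabricated curve.

## Synthetic data generator

The generator stands in for a private multi-center slide collection.
It renders an eosin-toned tissue field with elliptical
hematoxylin-dense nuclei, composed through the Beer–Lambert model with
fixed canonical stain vectors (shared as constants with the
normalization tests), per-image lognormal stain-strength jitter of
σ = 0.06 (the variability normalization is supposed to remove),
per-nucleus lognormal chromatin speckle, and Gaussian sensor noise
(σ = 3 intensity levels).  Nucleus placement is uniform, Thomas-process
clustered (fraction set by `clustering`), or minimum-separation
rejection-sampled for the segmentation benchmark.

Class parameters are chosen to mirror the qualitative cytology of each
tumor type at 0.233 µm/px (radii 13–32 px ≈ 3–7.5 µm; densities
3 400–11 500 nuclei/mm²; nuclear area fractions ≈ 0.25–0.35, i.e.
densely cellular sheets) and to be separable along several
morphological axes at once — size, shape (melanoma spindle vs lymphoid
round), chromatin texture (mast-cell granularity) and clustering
(melanoma nests) — because normalization deliberately removes the
chromatic axes.  The three Patnaik-style grades increase monotonically
in density, radius spread and chromatin texture, mirroring increasing
pleomorphism.  A `hard_mode` flag halves all inter-class gaps for
robustness testing.  Default frames are 1280×960 (a quarter of the
nominal acquisition format) to keep full runs in CPU minutes;
full-size rendering is a flag away.

What passing on this generator does and does not show: it validates
every pipeline contract — geometry, determinism, stain algebra,
threshold selection, vote arithmetic, learning dynamics — on images
whose ground truth is exact.  It does not certify accuracy on real
histology: real nuclei are textured, overlapping and embedded in
stroma, inflammation and necrosis confound real classes, and real
class differences are far subtler than the generator's.

## Numerical and design choices

- 0-based, half-open boxes everywhere; 4-connectivity for components;
  lowest threshold wins ties in scale selection.
- Acquisition dimensions (2560×1920) are metadata, not enforced; any
  frame at least one patch wide is processed.
- The loss is categorical cross-entropy with softmax — the standard
  formulation for mutually exclusive classes.
- Vote tallies, not probabilities, are primary for grading (the
  averaging alternative is a config option).
- Study sizes used by the tests and the reproduction script: 20
  images/class for the five-class task, 15 images/grade for grading
  (matching the case counts typical of such studies), one held-out
  case per class, split at case level so no case straddles the split.

## Known limitations

- The multiscale-threshold segmenter under-segments touching nuclei in
  very dense sheets unless watershed splitting is enabled; the pipeline
  only consumes coverage, so tiling is unaffected.
- Stain-vector estimation assumes both stains are present; single-stain
  fields raise a degenerate-input error by design.
- The compact networks are not drop-in replacements for full CNNs on
  real data; they are matched to the generator's morphological signal.
- Whole-slide inputs, mitotic counting and 2-tier grading schemes are
  out of scope.
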