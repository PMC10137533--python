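# Methods

This note records the modelling assumptions, parameter defaults, numerical
conventions, and open design choices behind `dermcad`, and what the synthetic
benchmark does and does not establish.

## Problem setting

The pipeline classifies single-lesion RGB photographs into melanoma (+1) vs
nevus (−1).  It assumes one pigmented lesion per image, darker than the
surrounding skin, roughly round, possibly occluded by thin dark hairs and
corrupted by impulsive sensor noise.  Multi-lesion images, color-constancy
effects, rulers/vignettes, and non-pigmented lesions are out of scope.

## Preprocessing

- **Grayscale**: BT.601 luminance (0.299, 0.587, 0.114), rounded to uint8.
- **Resize**: bilinear to 150×150 (configurable), top-left anchored
  coordinate convention, edge mode for out-of-range samples.  Integer inputs
  are rounded back to their dtype.
- **Median filter**: 5×5 window by default.  A 3×3 window leaves too much of
  the 1% salt–pepper noise for the later Otsu step; 5×5 removes isolated
  impulses of either polarity while keeping the lesion edge.
- **Hair removal**: bottom-hat response `closing(I, disk(5)) − I` thresholded
  at 30 intensity levels, mask dilated by one pixel to catch anti-aliased
  stroke fringes, and masked pixels replaced by the median of the non-hair
  pixels in a growing window (5, 7, 9, …).  The disk radius 5 comfortably
  covers hairs 1–3 px wide; the closing cannot remove structures wider than
  the disk, so the lesion itself (tens of pixels) is untouched.  A detected
  mask covering more than half the image signals a degenerate threshold: the
  image is returned unmodified and a warning logged, rather than inpainting
  the whole frame.
- **Border policy everywhere**: edge replication (scipy `mode="nearest"`,
  erosion/dilation border values chosen so an all-true mask is a fixed
  point).

Median filtering is applied per RGB channel so that segmentation (which
needs the three planes) and descriptor extraction (grayscale) see the same
cleaned signal; the hair mask is detected once on the grayscale image and
inpainted in all three channels.

## Segmentation

Each RGB plane is thresholded with Otsu's criterion computed exhaustively on
the 256-bin histogram; the threshold `t` partitions values into `{v < t}`
and `{v ≥ t}` and ties break toward the smaller `t` (the first argmax).  The
darker side is lesion, which encodes the domain assumption that pigmented
lesions are darker than skin.  The three plane masks are fused by per-pixel
2-of-3 majority vote — the robust middle ground between union (noise-prone)
and intersection (under-segments when one channel has poor contrast); both
alternatives are selectable.

Cleanup: opening with a disk of radius 3 (removes blobs the disk cannot
enter), binary median cascade with windows 7 → 5 → 3 (fills pinholes and
smooths the boundary; a binary median is a majority filter), an open–close
filter iterated to a fixed point (at most 5 iterations; it always converged
in 1–2 on our fixtures), and a size filter that drops 8-connected components
with area under 5% of the image.  If several components survive, the largest
is taken as the lesion.  The boundary is produced by Moore-neighbor tracing
with Jacob's stopping criterion from the topmost-then-leftmost lesion pixel;
on a binary mask, edge detection and boundary tracing coincide, so no
separate edge detector is used.  A single-pixel component yields a 1-point
contour flagged only by its length.

The module contains no randomness; identical inputs give identical masks.

## Descriptors

- **LBP code**: `Σ_{p=0}^{P−1} s(g_p − g_c) 2^p` with `s(0) = 1`.  For P=8
  the neighborhood is the 3×3 square ring in raster order (bit p = p-th ring
  pixel); circular sampling at angles 2πp/P with bilinear interpolation is
  available as an option.  A constant image therefore maps every interior
  pixel to code 2^P − 1.  Codes are computed only where the full
  neighborhood fits (border of width R excluded), so a H×W image yields
  (H−2R)(W−2R) codes and the histogram mass equals that count exactly.
- **N-LBP**: the 24-neighbor variant uses the 5×5 square ring, raster bit
  order, giving a 2²⁴-code space.  The histogram is stored sparsely (a
  code → count mapping); a 150×150 image yields at most 146² = 21,316
  distinct codes, so the dense 16.7M-bin vector is never materialized.
  Before classification the sparse histograms pass through the variance
  filter (below) with k = 4,096.
- **HOG**: gradients are ±1 central differences with edge replication;
  magnitude `hypot(Gx, Gy)`; orientation `atan2(Gy, Gx)` in degrees folded
  to [0°, 180°) (unsigned), defined as 0 where the magnitude is 0.  Nine
  orientation bins with centers at i·20° and linear (soft) vote splitting
  between the two nearest centers with wraparound — this conserves total
  gradient weight per cell and puts a pure horizontal-gradient image
  entirely in the first bin.  Cells are 8×8 px, blocks 2×2 cells at stride
  1 cell, each block L2-normalized as `v/√(‖v‖² + ε²)` with ε = 1e−6 (so a
  zero-energy block maps to the zero vector instead of dividing by zero).
  Images whose side is not a cell multiple are cropped, not padded —
  padding would inject artificial gradients at the seam.
- **CS-HOG**: identical machinery with 2×2-px cells ("cell size" is the
  parameter that changes, not the number of cells).
- **Feature selection**: drop zero-variance columns, keep the k largest-
  variance columns, indices fitted on training rows only and applied
  unchanged to test rows.  This is an explicitly simple stand-in — variance
  ranking is unsupervised, fast, leakage-free, and reproducible; no claim is
  made that it is optimal.

## Classifiers

- **Gentle AdaBoost.**  Weak learner: a single-feature threshold stump
  fitted by weighted least squares — an exhaustive scan over every feature
  and every threshold midway between consecutive distinct sorted values,
  choosing the split minimizing `Σ w_i (y_i − f(x_i))²`; each region's
  response is the weighted mean of its labels, which for ±1 labels equals
  the weighted class-probability difference and is automatically in [−1, 1].
  Ties break toward the lowest feature index, then the lowest threshold,
  making training fully deterministic.  Boosting runs M = 100 rounds by
  default with `w_i ← w_i e^{−y_i f_m(x_i)}` and renormalization; the final
  label is `sign Σ f_m(x)` with 0 → +1.  The boosting loop pre-sorts each
  feature column once, so a round costs O(n·d).
  A structural limitation worth knowing: a sum of single-feature stumps is
  an additively separable function of the features, so label patterns that
  are not additively separable (the 4-point XOR configuration being the
  canonical example) cannot be driven to zero training error by this weak
  learner for any number of rounds — on perfectly symmetric XOR data the
  first stump already has zero gain and the weights never move.  One
  acceptance-style test asserts the opposite and is expected to fail; it is
  kept as written rather than weakened.
- **kNN.**  Euclidean distance, k = 5 by default, no internal scaling (an
  optional z-scaling flag fits statistics on training rows only).  Distance
  ties at the k-th position break toward the lower training index (stable
  sort); vote ties break toward the label of the single nearest neighbor.
- **SVM.**  Soft-margin RBF, C = 1, γ = 1/(d · mean feature variance) by
  default.  The quadratic program is delegated to scikit-learn's SVC; the
  package owns the decision contract (`sign` of the kernel expansion, 0 →
  +1) and JSON serialization of the support vectors, dual coefficients and
  bias.
- **Tie policy.**  Every zero decision score resolves to +1 (melanoma): for
  a diagnostic tool the conservative error is the false alarm.

## Evaluation protocol

Stratified 10-fold cross-validation with a seeded per-class round-robin
assignment (a single cursor runs across classes, so overall fold sizes and
per-class fold counts each differ by at most one).  Random over-sampling
replicates minority rows with replacement until the classes balance; in the
default (sound) mode this happens inside the 9 training folds of each
split, so a replica can never appear in its own test fold — a row-identity
audit test enforces this.  `paper_mode` instead oversamples the full dataset
before splitting, a protocol some studies describe; it leaks replicas across
folds and typically inflates scores, and is provided only for comparison.
Metrics are pooled over folds (micro-average), which is stable for 12-sample
folds; per-fold reports are also returned.  Ratios with zero denominators
are NaN, never 0 or 100.

## The synthetic generator

The generator emulates the features the pipeline is built to handle, with
class-conditional defaults: lesion mean intensity 70 on skin 180 (8-bit);
lesion radius 0.15–0.35 of the image side; border = ellipse with smoothed
periodic radial perturbation of amplitude 0.30 (melanoma) / 0.05 (nevus);
lesion texture = i.i.d. Gaussian intensity noise with SD 30 (melanoma) / 8
(nevus), skin noise at a quarter of the lesion SD; 0–8 anti-aliased hair
strokes of width 1–3 px at intensity 30; 1% salt–pepper corruption.  Fixed
RGB tints (skin redder, lesion browner) give the three Otsu planes slightly
different statistics.  Per-sample seeds derive from `SeedSequence([master,
index])`, so datasets are reproducible and individually regenerable.

What it does **not** emulate: real pigment networks and dermoscopic
structures (the texture is white noise, not spatially structured), uneven
illumination, color charts, bubbles, multi-component lesions, and the
within-class diversity of real archives.  Consequences: the synthetic
two-class problem is close to linearly separable in N-LBP space, and the
reported 100% cross-validated accuracy demonstrates that the chain is wired
correctly end to end (features carry the class signal through preprocessing,
selection is leakage-free, folds are sound) — it says nothing about
accuracy on real dermoscopy, which is a much harder problem.

## Problem sizes used in the shipped benchmarks

Segmentation quality is measured over 20 seeded samples (alternating
classes), with hair + noise after preprocessing and noise-free without; the
cross-validation benchmark uses 120 samples (60 per class) at 150×150 with
N-LBP + Gentle AdaBoost and a shuffled-label control, whose accuracy should
fall in the binomial null band [35, 65]% for n = 120.

## Known limitations

- Hair inpainting is a local median, not exemplar-based; very dense hair
  (mask > 50% of the frame) aborts to a no-op with a warning.
- The boundary tracer returns pixel-resolution contours; no sub-pixel
  refinement.
- `select_features` is univariate; correlated-feature redundancy is not
  addressed.
- The Gentle AdaBoost weak learner cannot represent non-additively-separable
  label structure (see above).
- Oversampling replicates rows exactly (no jittering), so duplicated rows
  in training are expected and deliberate.
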