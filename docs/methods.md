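# Methods

`mammoprep` implements the preprocessing stages of a mammography CAD
pipeline: breast-silhouette segmentation, two histogram-based contrast
enhancement methods, labelled patch extraction with class balancing, and
confusion-matrix scoring — validated end to end against a synthetic
phantom with exact ground truth.  This note records the models, the
parameters that matter, the numerical choices, and what the phantom-based
validation does and does not show.

## Intensity model

All algorithmic stages operate on unit images: intensities in [0, 1],
obtained from integer rasters by dividing by `2^depth − 1` (255 for 8-bit,
65535 for 16-bit).  Histograms use `B` equal half-open bins `[i/B,
(i+1)/B)` over [0, 1], with intensity 1 assigned to the closed last bin.
Denormalization rounds half up, so `normalize → denormalize` is the
identity on integer images.  The default `B = 256` matches the bin count
that works best for the adaptive equalization and is used for
thresholding as well (the appropriate bin count for threshold
computation is not otherwise constrained; it is configurable).

## Multilevel Otsu thresholding

Tissue thresholds are the `k` bin-edge cuts maximizing the between-class
variance `Σ_c ω_c (μ_c − μ)²` of the `k+1` classes, equivalently
`Σ_c s_c²/w_c` with `w_c` the class count and `s_c` its first moment.
The search is a dynamic program over cut positions.  Because bin centers
are the rationals `(2i+1)/(2B)`, every class score is an exact `Fraction`
after dropping a common constant factor; the DP therefore runs in exact
arithmetic, ties are mathematical rather than floating-point artifacts,
and they are broken toward the lexicographically smallest cut tuple.
This makes the routine provably identical to exhaustive enumeration of
all `C(B−1, k)` placements, which the test suite checks directly for
B = 16, k ≤ 3.  A histogram with fewer than `k+1` non-empty bins is
rejected as degenerate.  Cost is `O(k·B²)` exact-arithmetic operations —
about a second at B = 256, k = 4, which is the deepest setting used.

## Histogram-based intensity windowing (HIW)

HIW picks an intensity window `[lo, hi]` and maps it linearly onto the
full contrast range: `p ≤ lo → 0`, `p ≥ hi → 1`, linear in between.  The
lower bound is one of the multilevel-Otsu thresholds (1-based
`lower_index`), the upper bound defaults to intensity 1.  Window bounds
are threshold *intensity values*, not rank percentiles: the published
description of the method's presets fixes the lower bound as "the second
threshold" — an intensity — and the upper bound at intensity 1.

Presets: `test1` = 5 regions / threshold 2 (stretches dense tissue,
masses and microcalcifications), `test2` = 4 regions / threshold 2,
`test3` = 4 regions / threshold 1 (keeps fatty tissue in the window).
The "number of thresholds: 4" wording of the finest preset is read as 4
thresholds = 5 regions, which matches its five named tissue classes.

## CLAHE

The image is split into an `M × N` tile grid (tile size
`ceil(rows/M) × ceil(cols/N)`, the image symmetrically reflected up to a
grid multiple and cropped back afterwards).  Per tile:

1. **Clip limit.** `limit = max(ceil(T/B), floor(clip_norm · T))` for a
   tile of `T` pixels and `B` bins, and at least 1.  `clip_norm = 0`
   keeps only the uniform-histogram floor; `clip_norm = 1` disables
   clipping.
2. **Clipping.** Bins are capped at the limit and the excess `E` is
   redistributed in a single pass: `⌊E/B⌋` to every bin plus one to each
   of the first `E mod B` bins.  Counts are conserved *exactly* (a
   property test asserts this); bins may end marginally above the limit,
   which only weakens the limiting.  An iterative redistribution loop
   would converge to a slightly different histogram with the same total;
   the single pass was chosen for determinism and simplicity.
3. **Transfer function.** The clipped CDF `c(b)` is pushed through the
   inverse CDF of a target distribution onto `[out_lo, out_hi]`:
   - uniform: `out_lo + c · (out_hi − out_lo)`;
   - rayleigh (scale `α`): `g = sqrt(−2α² · ln(1 − v))` with
     `v = (1 − e^{−1/(2α²)}) · c`;
   - exponential (rate `α`): `g = −ln(1 − v)/α` with
     `v = (1 − e^{−α}) · c`.

   Scaling `c` by the target's CDF mass below intensity 1 makes a
   full-contrast tile map exactly onto `[out_lo, out_hi]`; `v` is
   additionally clamped below `1 − 1/(2T)` so the logarithms stay
   finite.  The uniform map uses the raw CDF (no clamp), so all mass in
   the last bin maps populated levels exactly to `out_hi`.  With the
   default `α = 0.4` the three maps agree within about 0.12 of the
   output span on a flat histogram — numerically close, with the
   rayleigh map bowing mildly above the uniform one.  `α = 0.4` is a
   compromise keeping both non-uniform targets near the uniform map; the
   parameter has no prescribed value.
4. **Output range.** `full` spans the representable range of the input
   depth ([0, 255], [0, 65535], or [0, 1] for unit images); `original`
   spans the input's own [min, max].  A 16-bit image uses its full
   16-bit range.
5. **Interpolation.** Each output pixel is the bilinear blend of the
   transfer maps of its (up to) four nearest tile centers; index
   clamping at the border leaves corner pixels with one map and edge
   pixels with two.  Integer outputs are rounded half up.

Two oracles pin the implementation down: a single tile with
`clip_norm = 1`, uniform, full range reproduces global histogram
equalization to within one grey level, and every interior pixel matches
an independent per-pixel recomputation of the four-map blend exactly.

Presets: `test4` = (8, 8) grid, clip 0.01; `test5` = (3, 3), clip 0.01;
`test6` = (8, 8), clip 0.05.

## Silhouette extraction

Binarize, clean up morphologically (opening then closing with disk
structuring elements), keep the largest 4-connected component, fill
holes.  Two deliberate choices:

- **Threshold scale.** The single Otsu threshold is computed on the
  *original* intensity histogram, where background and breast are
  bimodal.  Computing it after global equalization is unstable: the
  equalized histogram is flat by construction, so the variance-optimal
  split drifts into the breast interior (on the phantom it discards
  about 30 % of tissue).  Fixed-threshold mode, by contrast, applies its
  cut on the equalized (rank) scale, where a fixed value acts as a
  quantile and transfers across exposures.
- **Morphology defaults.** Opening radius 5 and closing radius 10 at a
  1024-px reference scale, scaled proportionally to the image (1 and 3
  px at 256).  The exact morphological recipe behind published breast
  contours is not recoverable; these radii are exposed in
  `SilhouetteParams` and validated only on phantoms.

The largest-component rule is what discards bright film labels
disconnected from the breast.  Cropping copies breast pixels bit-exactly
and zeroes the rest.

## Tiling and balancing

Non-overlapping `32 × 32` windows on a grid aligned to the image origin
(stride = tile size).  A window is kept iff at least `breast_frac`
(default 0.75) of it lies on the silhouette — partial edge windows below
that are discarded, not padded — and a kept tile is labelled with the
lesion class iff at least `lesion_frac` (default 0.5) of it lies inside
the lesion mask, else healthy.  The five classes are benign/malignant
calcification, benign/malignant mass, and healthy tissue.  Balancing
undersamples every class without replacement to the smallest class
count, using a seeded generator over a fixed class iteration order, so a
seed fully determines the selection.

## Evaluation

The headline score is `(TP + TN)/(TP + TN + FP + FN)` — the fraction of
correct classifications.  Parts of the mammography CAD literature print
this quantity under the name "precision"; this package calls it accuracy
and reports the standard precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
f1 and support alongside, per class (one-vs-rest collapse of the K × K
confusion matrix) and overall (trace/total, whose complement is the
error row).  0/0 scores are reported as 0 with a warning.  Because it is
undeterminable whether published per-set "precision" columns are
one-vs-rest accuracy or per-class recall, both are emitted.

## Phantom

The phantom is a half-elliptical "breast" attached to the left image
edge (area ≈ 50 % of the frame) on a dark background, with four tissue
populations at strictly ordered intensity levels — background 0.05,
fatty 0.35 (with ±0.03 smooth low-frequency texture), dense 0.55
(super-Gaussian plateau blobs), mass 0.68 (soft-edged plateaus), and
microcalcifications 0.92 (clusters of 1–3-px specks) — plus additive
Gaussian noise (default σ = 0.01, a mild film-grain level) clipped to
[0, 1].  The pathology levels sit between 0.6 and 1, where mammogram
pathology pixels live, and the within-breast histogram shows the
fatty/dense/pathology modes the enhancement methods key on.  All
structures are placed by a generator seeded per draw, so a spec is
bit-reproducible.  Ground truth (silhouette, lesion mask, per-pixel
labels with priority calc > mass > dense > fatty) is returned alongside.

What the phantom does **not** emulate: projection physics, scatter and
compression gradients, the soft skin-line falloff, pectoral muscle,
film-scanner artifacts, and realistic parenchymal texture.  Passing
phantom tests therefore demonstrates algorithmic correctness (the stages
compute what they claim on images with the right histogram structure),
not clinical segmentation or classification performance on real
mammograms — reproducing published classification accuracies would
require the original image collections and trained networks, which are
out of scope.

## Problem sizes and determinism

Tests and the acceptance script run on 256 × 256 phantoms (28–33 k breast
pixels), 10 seeds per property, 16-bin histograms for exhaustive-search
equivalence (where enumeration is exact and cheap) and 96 × 96 images for
the interpolation oracle.  Every stochastic step — phantom draws,
balancing, random test inputs — goes through `numpy.random.default_rng`
with an explicit seed; no stage uses global random state, and repeated
runs are bit-identical.
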