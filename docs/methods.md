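# Methods

This note documents the models and procedures implemented in `forestseg`,
the package's own design decisions where the design was genuinely open,
and what the synthetic test conditions do and do not establish.

## Imagery model

Imagery is an H×W×4 unsigned-8-bit raster in fixed (R, G, B, NIR) band
order, assembled from an RGB product and a color-infrared (CIR) product
that share the red and green bands; only the CIR's NIR band (its first
band by convention, configurable via `nir_band`) is retained. Coordinates
are 0-based, row-major, origin top-left, with half-open windows. Region
cutting (`cut_regions`) discards trailing rows/columns that do not fill a
whole square region: a 20,000² extent at region size 4,000 yields exactly
25 regions. Persistence is lossless for both NPY and 8-bit TIFF; any
8-bit TIFF dialect is accepted on read. Binary masks export as 3-band
TIFF with the fixed colors (34, 139, 34) forest and (0, 0, 0) non-forest.
Georeferencing, projections, mosaicking, and radiometric calibration are
out of scope.

## Gaussian-mixture labeling

**Fitting.** EM with full covariances (default; diagonal available),
k-means++ initialization from the given seed, and a fixed 1e-6 ridge on
covariance diagonals. EM is stepped one iteration at a time so the total
log-likelihood trajectory is recorded; it must be non-decreasing, and the
tests assert this on every fixture. Convergence is declared when the
per-sample log-likelihood improves by less than `tol` (default 1e-3).
sklearn's `GaussianMixture` is the EM engine behind this surface; all
criterion, selection, merging, and ranking logic is implemented in the
package. Fitting may use a seeded random subsample of pixels (default cap
2 million) to keep desk-scale runtimes; prediction always covers all
pixels.

**Model selection.** AIC = 2k − 2 ln L and BIC = k ln N − 2 ln L with the
standard mixture log-likelihood (sum over pixels of the log of the
weighted component densities). A regression-form Gaussian log-likelihood
with explicit targets, predictions, and known σ² is provided as a
standalone utility (`regression_log_likelihood`) but is not used in the
criterion path: clustering supplies no per-pixel targets for it. Free
parameters: (K−1) weights + K·d means + K·d(d+1)/2 (full) or K·d
(diagonal) covariance terms. The elbow rule returns the interior K
maximizing the second difference C(K−1) − 2C(K) + C(K+1) of the criterion
curve — the sharpest slowdown of its decrease — with ties broken toward
smaller K and a manual override available. The rule needs a scan of at
least three component counts.

**Merging.** The published workflow merged the two forest clusters by
visual inspection. The automatic rule here is a package-defined
formalization, flagged as such in rule metadata: seed = component with
the highest NIR mean; another component i is merged iff its 4-neighbor
adjacency score A(i) = (pixel pairs adjacent to the seed) / (pixels of i)
is ≥ 0.10 and its visible luminance (mean of the R, G, B means) is below
the seed's. The darkness condition targets the cast-shadow cluster;
the adjacency condition requires it to be spatially interleaved with lit
canopy, as shadow is.

**Filtering.** Median filter (edge replication) then morphological
closing (dilation followed by erosion, square structuring element). The
"9-pixel kernel" of the source workflow is ambiguous between a 9×9 window
and a 3×3 (= 9 pixels) window; the default is 9×9 with 3×3 available in
configuration. On full-size 4,000-px rasters the 9×9 reading is
proportionate; the desk-scale pipeline configuration defaults to 3×3
because on ~160-px synthetic scenes a 9×9 kernel is ~25× larger relative
to the image and erodes class boundaries rather than cleaning noise
(measured: ~0.996 raw mask agreement dropping to ~0.93 after 9×9
filtering, entirely boundary displacement).

**Ranking.** Davies–Bouldin index with σᵢ = mean Euclidean distance of
class-i pixels to the class center; for the two-class masks this is
(σ₀+σ₁)/d(c₀,c₁). The index is used in its standard positive form
(lower is better). Images with an empty class are excluded from ranking
with a logged reason; ranking is ascending with ties broken by image id.

## Dataset construction

Tiles are square powers of two (default 128). When the tile size does not
divide the raster extent, the remainder **and the last full tile** are
discarded, leaving a margin at the partially covered edge: 4,000 px at
tile 128 gives a 3,840-px usable extent and 30 tiles per axis, hence 900
tiles per 4,000² image and 14,400 from 16 images. Patches are views into
the source rasters, so tiling full-size imagery allocates no pixel
copies. The split convention is: seeded shuffle, last `n_test` samples to
test, then `val_fraction` (default 10%, a package default — the source
convention fixes only the 10,000 train+validation / 4,400 test division)
of the remainder to validation; 14,400 samples yield 9,000 / 1,000 /
4,400. Splits pool tiles across images; augmentation is deliberately out
of scope. Tiling then stitching the usable extent is bit-exact.

## U-Net family

Widths derive from the base width b as (b, 2b, 4b, 8b | 16b | 8b, 4b,
2b, b); scenarios 1–6 set b = 64, 32, 16, 8, 4, 2. Blocks: two 3×3
same-padded convolutions with ReLU; 2×2 max-pooling between encoder
blocks; dropout (rate 0.5, parameter-free; a package default, applied to
the pooled output of the last encoder block) before the bridge; in each
decoder block a 2×2 stride-2 transposed convolution halving the channel
count, concatenation with the matching encoder output, then the two
convolutions; a 1×1 single-channel sigmoid output.

The per-layer ledger counts k²·c_in·c_out + c_out parameters per
convolution and 4·c·(c/2) + c/2 per transposed convolution. Kernel counts
follow the feature-map convention: two convolutions per block plus one
up-convolution per decoder block, excluding the 1×1 output. The
`plain_upsample` mode replaces the transposed convolution with
parameter-free nearest-neighbor upsampling (the first decoder convolution
then sees c + skip channels); its honest, smaller ledger is reported for
that mode. Only the transposed-convolution mode reproduces the published
per-scenario totals, which is why it is the default. Building a model
asserts the framework-counted parameters equal the ledger — the
accounting cannot drift from the implementation.

The engine is a deterministic NumPy implementation: im2col convolutions,
explicit backprop, He-normal initialization from a seeded generator.
Adam is implemented from its defining recurrences (β₁ = 0.9, β₂ = 0.999,
bias-corrected moments); `adam_reference_step` exposes the scalar
recurrence and the batched optimizer is tested against it. Binary
cross-entropy clamps probabilities at 1e-7. Training records per-epoch
train/validation loss and accuracy; a non-finite loss aborts with a
diagnostic. Default training configuration is learning rate 1e-4 and
batch size 16 (the source's tuned values for ~6,000-step runs). Pixel
accuracy thresholds the sigmoid at 0.5; F1 uses forest as the positive
class.

## Synthetic scenes

The generator reproduces the statistical structure the labeling pipeline
assumes, not the appearance of real imagery. Layout: a seeded Gaussian-
smoothed noise field thresholded at class-proportion quantiles yields
contiguous blobby land-cover patches with exact proportions; which class
occupies which band of the field is permuted per seed. Pixels are drawn
from per-class 4-band Gaussians (Cholesky sampling) and clipped to
[0, 255] after optional additive noise. Forest is a two-part mixture —
lit canopy and shadow (default shadow fraction 0.35, interleaved per
pixel) — and small disk-shaped holes (radius 1–3 px, default 0.2 per
1,000 forest pixels) are reassigned to bare ground inside forest,
emulating withered trees; holes count as non-forest in the ground truth.

The default five-class scene (forest, crops, orchard, bare land,
settlement; proportions 0.40/0.17/0.17/0.14/0.12) is **stylized**: class
means are placed so the pixel distribution has four roughly equidistant
effective modes (~120 digital levels apart, s.d. 9 per band) — lit canopy
(NIR-maximal), shadow, a vegetation mode shared by crops and orchard, and
a built/bare mode shared by bare land and settlement. This is the cluster
structure the workflow is designed around: a 4-component mixture resolves
two forest plus two non-forest clusters, and the criterion elbow lands at
K = 4. The mode placement was solved as a near-regular simplex under
semantic anchor constraints; the numbers are package-defined defaults,
not measurements of any sensor. `four_class_spec` (an exact regular
simplex on the R/G/B/NIR axes, equal proportions, no shadow) probes
cluster-count recovery; `two_class_spec` (forest vs bare land) is the
separability oracle for downstream tests.

Consequently, passing tests show that the pipeline's machinery is correct
and behaves as designed **when its distributional assumptions hold**.
They do not show robustness to what real aerial imagery adds: spatial
texture and autocorrelation within classes, mixed boundary pixels,
illumination gradients, seasonal variation, or class distributions that
are not Gaussian or not well separated.

## Problem sizes and numerical choices

Test and pipeline defaults are desk-scale by design: scenes of 96–640 px,
mixture fits on seeded subsamples of 3,000–12,000 pixels, scans over
K = 2…8, and the smallest (b = 2) network trained for a few epochs on a
few hundred 32–64 px tiles. The short-training protocol used for the
trainability check (200 tiles of 64², 5 epochs) uses learning rate 3e-3
and batch size 4: 250 Adam steps cannot converge at the 1e-4/batch-16
defaults, which presume thousands of steps; the elevated rate is a
scale-appropriate choice for short runs, not a recommendation for full
training. Further numerics: covariance ridge 1e-6; EM tolerance 1e-3 per
sample; probability clamp 1e-7; posterior ties in cluster prediction go
to the lowest component index; max-pooling ties take the first maximum;
master seed + fixed per-stage offsets derive every stage seed (all below
2³¹) so stages can be rerun independently.

## Known limitations

- The merge rule formalizes a judgment the original workflow made
  visually; on imagery where shadow is not the darkest NIR-adjacent
  cluster (e.g. water bodies inside forest) it can over- or under-merge.
- The elbow rule is a local curvature criterion; on criterion curves with
  several comparable slowdowns it can select a neighboring K. The
  pipeline is robust to mild over-selection (extra clusters simply remain
  unmerged) but not to under-selection below the number of forest modes.
- The NumPy engine is single-threaded-scale; the full-width scenario 1
  builds and counts correctly but training it at realistic dataset sizes
  is outside the intended envelope.
- Eq-style regression likelihood, georeferencing, augmentation,
  multi-class labeling, and competing architecture variants are
  explicitly out of scope.
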