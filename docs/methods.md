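# Methods

`histospec` implements a quantitative bridge between two views of the same
tongue tissue: the microscopic architecture visible in H&E histology and
the macroscopic diffuse-reflectance spectrum captured by wide-field
hyperspectral imaging (HSI). The package (i) segments H&E crops into
epithelium, nuclei and cytoplasm, (ii) condenses each crop into a
712-dimensional bank of color, texture, morphometric and topological
features, (iii) selects discriminative features by
minimal-redundancy-maximal-relevance (mRMR) and classifies normal versus
neoplastic tissue under nested leave-one-subject-out cross-validation, and
(iv) calibrates hyperspectral cubes to relative reflectance, extracts
per-pathology spectral signatures, and quantifies the feature-spectrum
association with Spearman rank correlation. A synthetic-data module
generates paired crops and cubes with known ground truth so the entire
pipeline is exercisable and testable without any external cohort.

## Synthetic study conditions

The generator emulates the appearance the analysis depends on rather than
the physics of staining or light transport.

**H&E crops.** An epithelial band occupies the top fraction of the image;
it is filled with pink cytoplasm (`(230, 150, 180)`), sparse white lacunae
(empty spaces), and blue-purple nuclei (`(64, 48, 128)` with per-nucleus
jitter, s.d. 8 gray levels); the region below the band is near-white
stroma/background (`(250, 250, 250)`). This palette satisfies the color
rules of the segmentation: nuclei have the highest blue ratio, empty space
the highest luminance, and only artifacts exceed red/blue 1.2. Nucleus
outlines are ellipses with a sinusoidal radial perturbation of amplitude
`boundary_irregularity` x radius — one knob that moves outline perimeter
and edge fractal dimension the way atypical nuclear shape does in graded
lesions. Placement is rejection sampling (hard cap 100 x n attempts) with
minimum centroid spacing `1.1 * axes_mean / crowding`, so the `crowding`
knob monotonically reduces nearest-neighbour distance; generation fails
loudly if fewer than half the requested nuclei fit. Per-pixel Gaussian
noise (s.d. 2) keeps color clustering non-degenerate.

Default crops are 320 x 200 pixels with nuclei at realistic pixel scale
(axis lengths 13-18 px), so every absolute pixel threshold of the
segmentation (25/50/150/500 px) retains its meaning while a full cohort
stays computable in minutes on one core. Per-grade defaults:

| grade     | nuclei | axis mean (px) | irregularity | crowding | band |
|-----------|-------:|---------------:|-------------:|---------:|-----:|
| normal    | 35     | 13             | 0.04         | 0.90     | 0.40 |
| dysplasia | 50     | 15             | 0.10         | 1.10     | 0.48 |
| CIS       | 60     | 16             | 0.16         | 1.25     | 0.55 |
| carcinoma | 70     | 18             | 0.22         | 1.40     | 0.62 |

The band fraction rises with grade, reflecting epithelial thickening. No
quantitative morphology distributions per grade are available for this
system, so these defaults are fixed once to reproduce the qualitative
ordering (more, larger, more irregular, more crowded nuclei with grade)
and are scaled linearly toward the normal row by the `effect_size`
parameter; `effect_size = 0` makes all grades statistically identical.

**Spectra.** Reflectance spectra on the 450-900 nm grid (5 nm steps, 91
bands) are logistic-rising baselines scaled by a per-class amplitude
(normal 0.30, dysplasia 0.38, CIS 0.43, carcinoma 0.48, background 0.85)
minus a Gaussian dip centred at 540 nm (s.d. 25 nm, depth 0.35) standing in
for hemoglobin absorption. Neoplastic amplitudes exceed normal, matching
the empirical observation that neoplastic tissue reflects more strongly.
Cubes are synthesized as `raw = dark + (R + noise) * (white - dark)` with a
smooth lamp profile for the white reference, so calibration inverts
generation exactly at zero noise. Per-subject random effects (a few percent
on nucleus counts, sizes and spectral amplitude) make leave-one-subject-out
folds non-exchangeable, as in a real cohort.

**What the generator does not emulate:** chromatin texture inside nuclei,
stain variability and scanner artifacts, specular glare, tissue-optics
coupling between architecture and spectrum (the association arises because
grade drives both, which is the hypothesis under test, not a derived
light-transport model). Passing tests therefore demonstrate that the
pipeline recovers known structure under controlled conditions — not that it
would perform identically on scanned slides.

## Segmentation

1. **Epithelium.** The red channel gives the best epithelium/background
   contrast. It is smoothed edge-preservingly — a grayscale closing with a
   nucleus-scale disk (r = 13) that erases dark nuclear spots at any local
   density, followed by a small median (disk r = 5) — then thresholded with
   Otsu's method, with polarity chosen so tissue (darker than unstained
   background) is foreground; holes are filled and small spurious regions
   removed by opening (disk r = 5). Rank filters preserve the band's step
   edge, which is what makes the global threshold meaningful. A uniform
   image has no defined threshold and yields an empty mask with a warning.
2. **Compartments.** k-means (k = 3, Euclidean, 10 restarts, fixed seed) on
   the RGB values of epithelial pixels. Because k-means cluster indices are
   arbitrary, roles are assigned by color statistics: nuclei = highest mean
   blue ratio `(B/(1+R+G))/(1+R+G+B)`, background = highest luminance among
   the rest, cytoplasm = remainder. Degenerate inputs with fewer than three
   distinct colors keep the same rules on fewer clusters.
3. **Cleanup.** Fill holes, dilate (disk r = 2), open (disk r = 4), drop
   components under 50 px.
4. **Large clusters.** Components with area > 500 px and solidity < 0.9 are
   split by k = 2 k-means on their RGB pixels; the contact boundary between
   the two color groups is carved out so both halves persist as separate
   nuclei, and the loop repeats (cap 20 passes) until no flagged component
   remains. Components with mean per-pixel red/blue ratio > 1.2
   (denominator floored at 1) are removed as false detections; holes are
   filled and components under 25 px dropped.
5. **Small clusters.** Twice: components with area > 150 px and solidity
   < 0.9 are split by marker-controlled watershed flooding the smoothed
   blue-ratio image. Markers are peaks of the distance transform inside the
   component (minimum separation 5 px): on a same-color cluster the
   blue-ratio relief is a flat plateau whose regional maxima are noise, so
   distance peaks — one per nucleus core — are the reliable marker choice,
   while the flooding relief remains the blue-ratio image. Basin boundaries
   are carved; holes filled; components under 50 px dropped.
6. **Finalize.** Components with mean red/blue > 1 are removed; the rest
   are labeled and summarized by a moment-based ellipse fit (centroid,
   axes, orientation, area, solidity).

Invariants maintained end to end: every final nucleus has >= 25 px, mean
red/blue <= 1, and lies inside the epithelium mask; the large-cluster split
is idempotent on its own output.

## Feature bank (712 per crop)

Each compartment (epithelium, cytoplasm, nuclei) contributes 71 color and
149 texture features; nuclei add 44 morphometric and 8 topology features:
220 + 220 + 272 = 712, in a stable `compartment.family.feature` naming
scheme. Degenerate inputs (empty region, constant intensity, < 3 nuclei)
produce zeros with a cleared validity flag, never NaN, so downstream
selection and CV always see finite matrices.

- **Color (71).** Pixels with YCbCr luminance above 180 (white) are
  dropped. Each RGB channel is standardized over the region
  (`(X - mu)/sigma`, scale- and shift-invariant in intensity), clipped to
  [-3, 3], and binned into 16 proportions (48). The red-blue difference
  adds a 16-bin proportion histogram over the fixed range [-255, 255] plus
  mean, median, s.d., min, max, skewness and kurtosis (23).
- **GLCM (19).** The masked region is min-max scaled to 64 gray levels; 16
  symmetric co-occurrence matrices (4 directions x distances 1-4, pairs
  straddling the mask dropped) are each normalized to probabilities and
  averaged. The 13 Haralick statistics plus autocorrelation, cluster
  prominence, cluster shade, dissimilarity, inverse difference and maximum
  probability are computed on the averaged matrix. (The fifth extra
  statistic is taken as the standard *cluster shade*.)
- **Gabor (56).** 28 complex filters: orientations {0, pi/4, pi/2, 3pi/4} x
  radial frequencies 2 sqrt(2) ... 128 sqrt(2) cycles per image width
  (doubling), Gaussian envelope set for a one-octave bandwidth. The region
  mean is subtracted before filtering so border padding cannot leak energy
  (a constant region scores exactly zero everywhere); each magnitude
  response contributes its Shannon entropy (256-bin histogram) and energy
  (mean squared magnitude) over the mask. At small image widths the top
  frequencies exceed Nyquist and act as near-impulse filters; they are kept
  for count fidelity and behave as high-frequency noise probes.
- **LBP (10).** Uniform rotation-invariant local binary patterns, P = 8,
  R = 1, as a 10-bin proportion histogram over interior mask pixels.
- **mSFTA (64).** Four multi-level Otsu thresholds (threshold search on a
  128-bin histogram) decompose the region into 4 upper sets {I > t_i} and 4
  contiguous band sets {t_i < I <= t_{i+1}} (upper bound of the last band =
  maximum gray value). From each of the 8 binary images, the boundary
  (region minus its 4-connected erosion) and the skeleton (thinning) are
  derived; each of the 16 derived images contributes its box-counting
  fractal dimension and pixel count, and the corresponding grayscale-masked
  image its mean intensity and entropy.
- **Box-counting fractal dimension.** The pattern is cropped to its
  bounding box and N(s) counted on a log-spaced ladder of box sizes
  {1, 2, 4} x 3^k (capped at a third of the larger side); the estimate is
  the least-squares slope of log N(s) versus log(1/s). Mixing powers of 2
  and 3 keeps the ladder dense in log scale and samples triadic
  self-similar patterns at their natural scales; a purely dyadic ladder
  underestimates the Sierpinski carpet by ~0.15. Verified closed forms:
  line ~ 1, filled square ~ 2, depth-4 Sierpinski carpet ~ log 8 / log 3,
  all within 0.1.
- **Morphometry (44).** Seven statistics (mean, median, s.d., min, max,
  skewness, kurtosis) of six per-nucleus descriptors — area, major and
  minor axis, solidity, eccentricity, compactness (perimeter^2 / 4 pi area)
  — plus the mean neighborhood radius (half the nearest-centroid distance)
  and the nucleus-to-cytoplasm total-area ratio. The full-statistics
  treatment of all seven descriptors would give 50 features, which
  contradicts the bank's totals; the adopted resolution (42 + 1 + 1 = 44)
  is the only reading consistent with 712.
- **Topology (8).** Delaunay triangulation of nucleus centroids; mean, max,
  min and disorder (`1 - 1/(1 + sigma/mu)`) of triangle areas and
  perimeters.

Texture families operate on the ITU BT.601 luminance. Entropy is always
base-2 Shannon entropy of a binned intensity histogram.

## Feature selection (mRMR)

Mutual information is the histogram plug-in estimate in bits; continuous
variables are discretized by equal-frequency binning into
min(10, ceil(sqrt(n))) bins (already-discrete variables are factorized
as-is). Ranking is greedy under the difference (MID) criterion: the first
feature maximizes I(feature, class); each next feature maximizes
I(feature, class) minus its mean MI with the already-selected set; ties
break toward the lowest column index. The greedy path is verified per step
against an independent brute-force oracle (sklearn's contingency-based MI
estimator) on fixtures up to 20 features. The log base only rescales both
terms and cannot change any ranking.

## Predictive modeling

Binary classification (normal vs. pooled dysplasia/CIS/carcinoma =
neoplastic) with an RBF-kernel SVM inside nested leave-one-subject-out CV:
the outer loop holds one subject out for performance estimation, the inner
loop leaves one remaining subject out to score every (m, c, gamma) triple
by mean inner accuracy. Per inner fold, zero-variance features are dropped,
z-scoring and mRMR ranking are fitted on the inner-training images only,
and the best triple (ties toward smaller m, then c, then gamma) is refit on
the full outer-training set. Pooled predictions give accuracy, sensitivity
and specificity with neoplastic as the positive class; a leakage assertion
checks that no held-out image id intersects its fold's training ids. The
default grid is m in {1, 5, 10, 30, 50, 70, 90, 100, 200, 300, 342} and
c, gamma in 2^{-5, -3, -1, 1, 3, 5}; reported runs on the synthetic cohort
truncate the feature-dimension grid at 50 and the exponents to
{-3, -1, 1, 3}, which keeps a 10-subject, 80-image run within a couple of
minutes without changing the chosen configuration (the inner loop selects
m = 5 with the smallest c and gamma). With tiny inner validation sets,
many triples tie at perfect inner accuracy and the parsimony rule decides;
one image per class per subject proved too small for that rule to be
stable, so the default cohort uses two.

## Association analysis

The sample unit is a (subject, pathology-class) pair carrying that class's
mean feature values and its mean reflectance signature. For every
(feature, wavelength) pair, Spearman's rho is computed as the Pearson
correlation of average ranks (tie-safe) with a two-sided p-value from the
t approximation on n - 2 degrees of freedom; constant columns are flagged
invalid rather than reported as zero. Significance is per-cell at
alpha = 0.05 with no multiple-testing correction by default (a
Benjamini-Hochberg option exists but is off, matching the per-cell
convention of the analysis this reproduces). Heatmap cells are
positive-significant (green), negative-significant (red) or nonsignificant
(white); row summaries report mean ± s.d. of rho across wavelengths and
flag |mean rho| >= 0.5 as strong.

The package's property-level check uses two representative features
computed by the real pipeline on each crop: the edge fractal dimension of
the second upper-threshold mSFTA image of the epithelium (its threshold
sits in the gap between the nuclear and cytoplasmic intensity modes, so
its boundary traces nucleus outlines; it rises with grade and is expected
to associate positively with reflectance amplitude) and the mean
Delaunay-triangle perimeter over segmented nuclei (falls as nuclei crowd,
expected negative association). Across 10 independently seeded cohorts the
sign pattern is recovered in at least 9.

## Problem sizes and numerical choices

Cohort runs use 10 subjects x 4 classes x 2 crops (80 images, 320 x 200
px) for cross-validation and 10 cohorts of 4 subjects x 4 classes x 1 crop
for the association seeds — sizes chosen so a full reproduction completes
in minutes on a single core while every stage operates at realistic pixel
scale. Multi-level Otsu searches a 128-bin histogram (thresholds within ~1
gray level of the 256-bin answer at 16x the cost). Gabor responses are
computed by FFT with kernel spectra cached per image shape. k-means uses a
fixed random state with 10 restarts, making every run bit-reproducible
from one seed. Red/blue ratios floor the denominator at 1 to avoid
division by zero while preserving the 1.2 and 1.0 cutpoints. Reflectance
values above 1 (specular) are kept, not clipped; calibration voxels with a
non-positive white-dark denominator are masked and excluded from
signature means.

## Known limitations

- Synthetic nuclei are uniform in color; chromatin texture, nucleoli and
  staining gradients are absent, so intra-nuclear texture features carry
  little signal here.
- Heavily overlapping nuclei (crowded carcinoma defaults) are undercounted
  by ~20-30%; the count-recovery guarantee (within 10%) holds for
  non-overlapping configurations, which is also the regime where ground
  truth is unambiguous.
- The straight-line pathology map covers the mouse-style dorsal-surface
  geometry only; registration of arbitrarily oriented specimens is out of
  scope.
- Association magnitudes depend on cohort composition and effect size;
  only the sign pattern is treated as a reproducible property.
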