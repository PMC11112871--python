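# Methods

This note documents the models, conventions and numerical choices behind
`fruitmorph`, the synthetic data it validates itself on, and the known
limitations of both.

## Segmentation

Each view is segmented as the set union of two binary masks, computed on
images normalised to [0, 1]:

- **m1 (HSV threshold).** A pixel is fruit iff `S/V > 0.2` and `S > 0.19`
  (strict inequalities; pixels with `V = 0` have an undefined ratio and are
  background). The chamber background is a bright, nearly unsaturated panel
  which fails both conditions with a wide margin.
- **m2 (background difference).** The per-camera empty-chamber reference is
  subtracted from the image; the difference magnitude is thresholded with
  Otsu's method (256 bins over the observed range, ties to the lowest
  threshold). The magnitude is the per-pixel *maximum* absolute difference
  over RGB channels — robust when the fruit matches the background in one
  channel; `luminance` and Euclidean-`norm` alternatives are selectable.
  Identical image and reference give an empty m2 with a warning, not an
  error.

Post-processing keeps the largest 8-connected component of `m1 ∪ m2` and
fills its holes. It never invents pixels away from the union and can be
disabled. A per-camera exclusion region (e.g. for a pedestal visible in
real chambers) can be supplied; none is needed for the renderer, which
draws no pedestal.

## Shape geometry

**Polar profiles.** The mask boundary is extracted at sub-pixel resolution
(0.5-level contour) and converted to a radius per integer degree around the
centroid, with 0° along +x, counter-clockwise, and the image row axis
flipped to mathematical orientation. Between adjacent boundary vertices the
radius is interpolated linearly in angle; where a direction crosses the
boundary more than once the maximum crossing is used, so profiles always
trace the outer boundary. Polygon area reconstructed from a profile agrees
with the pixel count to within 2% for star-shaped masks of realistic size.

**Asymmetry.** The index is `|M △ mirror(M)| / (2|M|)`, where the mirror is
taken across the vertical axis through the column centroid, with
nearest-integer column mapping. The frame is padded internally so the
reflection is never clipped; the index is therefore invariant to integer
translations and to mirroring. It is exactly 0 for pixel-symmetric masks.

**Symmetrization.** Fruit are rarely placed perfectly upright, so side
masks are rotated about their centroid to minimise the asymmetry index
before measuring. The search is a plain grid over ±20° in 0.25° steps
(both configurable) — wide enough for realistic fruit tilt, fine enough
that the residual is dominated by shape, not the grid. Rotation uses
nearest-neighbour resampling to keep masks binary; ties resolve to the
smallest magnitude, negative before positive. Because resampling
discretises the mask, "perfectly symmetric" rotated shapes test at ≤ 0.005
rather than exactly 0; exact 0 is only expected for unrotated
pixel-symmetric inputs.

**Dimensions.** Width and height are the pixel extents (max − min + 1,
counting occupied pixels inclusively) of the symmetrised mask times the
camera's cm-per-px calibration.

**Top-view circles.** Circumcircle, incircle and mean radius are the max,
min and mean of the top profile about the *centroid* — not the true
minimum enclosing circle, which for near-circular fruit tops differs by
well under a pixel; the centroid convention keeps all circle metrics
consistent with the polar profile. The normalised radial SD is the sample
SD (n−1) of radii after scaling the mean radius to 1; it is unitless.

## Shape classification

Profiles are normalised to mean radius 1 and compared to each library
outline by Pearson correlation of the 360-vectors at zero angular lag
(profiles are already rotation-registered by the symmetry correction; a
max-over-lags mode exists for unregistered input). The winner is the class
with the highest correlation, ties to the lowest class id. Per-fruit
classification uses the average of the four side profiles, which
suppresses single-view noise; per-view correlations are retained.

The shipped 13-outline side library is a *parametric stand-in* built from a
superellipse/ovoid family (per-half superellipse exponents, linear taper,
mid-height waist), named by standard pomological descriptors (spherical,
flattened spherical, ellipsoid, ovoid, obovoid, conical, truncate conical,
rectangular, rectangular conical, cylindrical, cylindrical waisted, oblong,
turbinate). Digitised manual outlines can replace it via a plain-text
library file (class id, name, 360 radii per row). Two design constraints
shaped the parameters:

- Pearson correlation of mean-1 profiles is affine-invariant, so classes
  must differ in *harmonic content*, not just amplitude: a mild and a
  strong ellipse correlate near 1.0 and would be indistinguishable.
  The "spherical" outline is slightly superelliptic for the same reason —
  a perfect circle has a constant profile with zero variance and no
  defined correlation.
- The library is checked (in the test suite) to be self-consistent
  (self-correlation 1.0), mutually distinguishable (max off-diagonal
  correlation < 0.995) and robustly recoverable under 3% multiplicative
  radial noise.

The 3-entry top library (circular, weakly/strongly ribbed) is a
placeholder with the same replaceable format.

Average shapes are per-degree means with sample SDs (n−1; 0 when n = 1).
k-means clustering of mean-1 profiles (k between 3 and 8, default 6;
Euclidean distance, 10 restarts, seeded) provides a data-driven complement
to the reference library.

## Color

Peel pixels from the four segmented side views are pooled and converted to
HSV. Hue (normalised so [0, 1] spans 0–360°) and saturation are histogrammed
separately as densities over 64 uniform bins — enough resolution to separate
red/orange/yellow/green peaks while remaining stable at the ~10⁵ pixels a
full-frame fruit contributes; the count is configurable. Pixels with zero
saturation have undefined hue and are excluded from the hue histogram only.
Reporting and the factsheet restrict hue to [0, 0.5]: cyan-to-magenta hues
do not occur on apple peel. Per-bin probability density (not a kernel
estimate) was chosen so densities integrate exactly to 1 and average
linearly across fruit.

## Records and cultivar statistics

The per-fruit record gathers shape class and correlation, weight (from
image metadata, with a manifest fallback; missing weights are flagged, not
fatal), top circle metrics, per-view and mean widths/heights, per-view
symmetry angles, the mean of the four per-view minimal asymmetries, and the
color histograms. The shape index is mean height / mean width — a unitless
elongation measure. Per-fruit asymmetry uses the mean (not median or max)
of the four views: each view is an equally valid projection of the same
fruit.

Cultivar comparisons use one-way fixed-effects ANOVA per trait and Tukey
HSD at α = 0.05, summarised as a compact letter display computed with the
insert-and-absorb algorithm; the display is exactly consistent with the
pairwise matrix (two groups share a letter iff their adjusted p ≥ 0.05),
which the tests check exhaustively. p-values below double-precision
resolution are reported as "< 2e-16", the convention of standard
statistical software.

## Sample-size determination

For sample size n, 200 random subsets of n fruit are drawn *without
replacement* (a subset of distinct fruit, matching how one would actually
subsample a harvest; a with-replacement bootstrap mode exists for
comparison). The relative margin of error is half the 2.5%–97.5% quantile
range of the subset means, divided by the full-sample mean. Quantiles use
linear interpolation between order statistics (type 7); at 200 replicates
the quantile definition shifts the margin noticeably, which is why it is
pinned down here. Without replacement, the margin falls to exactly 0 at
n = N. Cross-cultivar curves aggregate by the arithmetic mean of
per-cultivar margins; per-cultivar curves are always retained. A single
seeded generator drives all resampling, and the seed is recorded in every
result row, so curves are bit-reproducible.

Against the finite-population closed form
`1.96·(σ/μ)/√n·√((N−n)/(N−1))` the estimator agrees to within resampling
noise (checked at n = 20, N = 100, 10,000 replicates). Because weight
tracks volume — which scales cubically with linear size — its coefficient
of variation is roughly three times that of width or height, and its
margin-of-error curve sits above them at every n.

## Synthetic data

Two generators, both first-class tested code:

**Image renderer.** Produces the five 1296 × 1080 16-bit RGB views of one
fruit from 360-degree side/top radius profiles (cm), an HSV peel color
mixture, a weight and an asymmetry shear; backgrounds are uniform neutral
gray (S = 0.05, V = 0.9, failing both m1 conditions by construction), and
images are written as packbits TIFFs with the weight in the description
tag, in the `images/<ID>/cam<N>/` layout. Side view k is sheared by
`skew·k/4`, giving a known, monotone asymmetry control. Rendering is
floating point, quantised to 16 bit; edges are hard (pixel-centre-in-
outline), so the ±1 px boundary band is excluded when scoring segmentation
(sub-pixel edge behaviour is not part of the contract). The renderer does
*not* emulate lighting gradients, shadows, specular highlights, lens
distortion, a pedestal, or natural peel texture — so passing tests
demonstrate the correctness of the geometry/color/statistics machinery,
not robustness to real-chamber imaging artifacts.

**Trait simulator.** For cultivar-scale statistics (15 cultivars × 100
fruit), rendering thousands of full frames adds nothing: trait records are
drawn directly from per-cultivar normal distributions. Defaults are
realistic for dessert apples — weight CV 16%, width CV 5.6%, height CV
6.6%, cultivar means spanning 120–260 g and 6.5–8.5 cm — and give
well-separated cultivars. "Recovering programmed means" means recovering
the means of the values actually generated (as the pipeline must recover
the weights written into image metadata), not beating sampling noise.

## Problem sizes used in validation

The test suite renders single full-frame fruit where full resolution
matters (segmentation accuracy: 20 fruit across red/yellow/green peels) and
small-radius fruit for multi-fruit pipeline runs; the statistical study
uses the trait simulator at 15 × 100. These sizes make every contract
measurable at comfortable margins while keeping the suite quick.

## Known limitations

- The default reference outlines are parametric stand-ins, not digitised
  manual shapes; absolute class assignments on real fruit depend on
  replacing the library.
- Segmentation assumes a single fruit against a uniform bright background;
  multi-fruit scenes, shadows and specular repair are out of scope.
- The asymmetry search covers ±20°; fruit placed on their side are not
  recovered.
- Circle metrics are centroid-based, not true enclosing circles (documented
  deviation; negligible for near-circular tops).
- Mixed models, spatial field-trend correction and multi-year designs are
  out of scope for the cultivar statistics.
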