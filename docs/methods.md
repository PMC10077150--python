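# Methods

This note documents the measurement model, the synthetic-data calibration,
and the numerical choices behind `retmorph`, in the order the pipeline runs
them.

## Coordinate and unit conventions

All rasters are row-major boolean grids, 0-based (row, col), with pixel
centers at integer coordinates and unit pixel extent. Radii and arclengths
are Euclidean pixel distances. Physical lengths use a single scalar scale
(default 12.2 µm/px, the nominal resolution of wide-field pediatric fundus
frames of 1,600 × 1,200 px); only the disc diameter (mm) and caliber (µm)
carry physical units — fractal dimension and density are dimensionless and
curvature is reported in px⁻¹ (its natural log, lnC ≈ −4.7 at these
scales, is the regression variable). No ocular-magnification or
axial-length correction is applied; the masks' pixel scale is taken at
face value.

## Disc geometry

The optic-disc diameter is the long side of the minimum-area enclosing
rectangle of the disc mask, found by rotating calipers over convex-hull
edge orientations of the boundary-pixel-center cloud (the minimum-area
rectangle always has a side collinear with a hull edge, so the edge scan
is exact). Each rectangle side is padded by half a pixel per end to
account for pixel extent: an axis-aligned w-px-wide mask then measures
exactly w, and oblique or curved blobs measure within ~1 px of the
underlying continuous shape (using the full corner cloud instead would
overshoot oblique shapes by up to (√2−1)·w of padding that rasterization
never actually fills). Collinear masks degrade to their principal-axis
extent; a 1-pixel mask reports 1 px with a warning. The disc center is the
foreground centroid.

The analysis region is the annulus between 0.5 and 3.0 disc diameters
(DD) from the disc center, both bounds inclusive, clipped to the frame.
Vessels inside the disc are erased before skeletonization so disc-surface
vasculature cannot contaminate the vascular metrics.

## Skeletonization

Centerlines come from Lee's topology-preserving thinning
(`skimage.morphology.skeletonize(method="lee")`). Zhang–Suen thinning was
rejected after it eroded thin diagonal bands (a 3-px-wide 45° tube) to a
single pixel. The skeleton is decomposed at pixels whose 8-neighbor count
differs from two into simple-path segments; isolated cycles become closed
segments. Thinning consumes roughly (w−1)/2 px at each free end of a
w-px-wide tube, so skeleton length underestimates centerline length by up
to one vessel width per segment; all downstream estimators sample per
skeleton pixel and are insensitive to this.

## Fractal dimension

Box counting on the skeleton pixel set: occupied boxes N(s) are counted on
square grids of dyadic side s = 2, 4, …, ⌊min(H, W)/4⌋ px, with a single
grid anchored at the region's bounding-box origin (the frame origin by
default); FD is the least-squares slope of log N(s) against log(1/s). A
single anchor keeps results bit-reproducible; the cost is that FD is only
exactly translation/reflection invariant for shifts the dyadic grid
divides (about 1 % drift otherwise, which the invariance tests account for
by using dyadic-compatible frames). The region defaults to the whole
frame, with an option to restrict to the 3 DD disc-centered circle — the
field uses both conventions and the difference is documented rather than
hidden. At least 100 pixels are required; fewer is an error. Oracles:
a straight line measures 1.00 (−0.05 from the finite-size +1 box at coarse
scales), a filled square exactly 2, a depth-7 Sierpinski raster exactly
log 3 / log 2 (the dyadic grid aligns with the construction).

## Caliber

At each skeleton pixel the local tangent is taken from the (lightly
smoothed) segment chain, and the mask is sampled along both normal
directions at 0.2-px steps using bilinear interpolation; the lumen
boundary is the 0.5-crossing, localized by linear interpolation between
samples. Caliber is the sum of the two half-widths, averaged (unweighted,
per pixel) over all eligible skeleton pixels in the annulus, then scaled
to µm. Skeleton pixels within 3 px of a branch point are excluded to
avoid junction inflation. This perpendicular-profile estimator was chosen
over reading the Euclidean distance transform at the skeleton, which
under-reads diagonally oriented vessels by up to ~0.8 px (thinning parks
the centerline off the true medial axis, and the transform measures to
background pixel centers rather than to the lumen boundary); the profile
estimator recovers tube widths 3–15 px within 0.5 px at 0°, 30°, 45°, 60°
and 90°.

## Density

Exact integer ratio of vessel pixels to all pixels inside the annulus.
No estimation is involved; a brute-force per-pixel recount agrees
identically.

## Curvature

Along each skeleton segment, every point P with neighbors A and B at
± window (default 9 px) arclength defines a triangle; curvature is the
reciprocal circumradius, 2·|cross(P−A, B−A)| / (|AB|·|AP|·|PB|), zero when
collinear. The mean is unweighted over all evaluated points inside the
annulus. Chains are smoothed with a ±5-px moving average first: raster
jitter of ±0.5 px otherwise rectifies (curvature is non-negative) into a
noise floor of ~0.002 px⁻¹ that swamps gently curved vessels. Smoothing a
circle of radius R with this window biases 1/R by under 0.1 %, collinear
chains stay collinear (straight tubes read exactly zero), and arcs of
radius 50–400 px are recovered within 10 % (worst case ~5 % at R = 400,
where the sagitta over the 18-px chord is only 0.1 px). The 9-px
half-window resolves radii down to ~20 px; both the window and the
smoothing width are parameters.

## Segmentation evaluation

Pixelwise confusion counts with foreground as the positive class;
accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), IoU = TP/(TP+FP+FN). Pooled over pixels (not
per-image-averaged). 0/0 denominators return NaN with a warning rather
than a silent 0 or 1.

## Synthetic scenes

The tree generator grows a recursive bifurcating tree from evenly spaced,
jittered roots on the disc rim: segment lengths are exponential (mean
100/branch_rate px), centerlines are straight baselines plus a sinusoidal
perpendicular perturbation (zero offset at the proximal end so segments
connect), children inherit caliber × caliber_decay and deviate ±17–37°
from the parent, and growth stops at max_depth, below min_caliber_px, or
at the frame border. Rasterization uses the pixel-center rule — a pixel is
vessel iff its center lies within caliber/2 of the centerline polyline,
evaluated with exact point-to-segment distances — so axis-aligned tubes of
odd width w paint exactly w pixels per cross-section. Straight-tube and
circular-arc fixtures share the rasterizer and carry analytic truth
(caliber = width, curvature = 0 or 1/R). Oblique fixtures offset the
centerline 0.21 px off the lattice: a centerline through lattice points is
a degenerate alignment (at 45° it quantizes rasterized width to multiples
of √2/2 around the wrong value) that real vasculature never exhibits.
Ground-truth density is the exact vessel fraction of the annulus defined
by the *generating* disc parameters; the measurement pipeline, which
re-estimates the disc from its mask, agrees within 0.01.

What these scenes do not emulate: gray-scale contrast, the choroidal
background, vessel crossings of distinct arteriole/venule trees (the
measured metrics deliberately do not distinguish the two), caliber
tapering along a segment, or segmentation noise. Passing the oracle suite
therefore validates the measurement operators, not robustness to imperfect
segmentations.

## Synthetic cohorts

A cohort is 146 eyes in six one-year age groups of sizes 43, 25, 24, 14,
16 and 24, ages uniform within each group (the source material gives only
group counts), 64 female and 86 left eyes assigned by random permutation,
gestational age ~ truncated N(38.60, 2.02²) weeks on [26.00, 41.28] and
birth weight ~ truncated N(3250, 586²) g on [930, 4600] as demographic
payload uncorrelated with the metrics. Each metric is generated from its
published age model plus Gaussian noise:

| metric | model (x = age in days) | R² |
|---|---|---|
| disc diameter (mm) | −0.00002·x + 1.362 | 0.025 |
| fractal dimension | −0.000026·x + 1.549 | 0.075 |
| caliber (µm), x < 1095 | −0.008·x + 84.861 | 0.205 |
| caliber (µm), x ≥ 1095 | slope 0.0001, continuous at 1095 | 0.011 |
| density (fraction) | −0.000007·x + 0.134 | 0.023 |
| ln curvature (px⁻¹) | −0.00001·x − 4.657 | 0.001 |

The noise SD comes from inverting the R² identity, σ = |slope|·sd(x)·
√(1/R² − 1), with sd(x) the *design* SD of the age mixture (closed form
from the group bounds and counts, so calibration does not depend on the
realized draw). The caliber pieces are calibrated against the
piece-conditional age SDs, and the second piece continues from the first
piece's value at the 1,095-day breakpoint — the printed second-piece
intercept (6.148 µm) is discontinuous with the first piece by ~70 µm and
physiologically implausible, so it is treated as a typographical artifact
and not reproduced. Curvature is generated on the ln scale and
exponentiated, which also guarantees positivity. Density and fractal
dimension receive jointly drawn bivariate-normal residuals whose
correlation is solved in closed form so the cohort-level Pearson
correlation hits the configured 0.979 on top of what the shared age trend
already induces; infeasible targets (|ρ| ≥ 1 required) are rejected.
Cross-correlations among the remaining metrics are left at zero — no
joint model is published for them.

Refitting over replicate cohorts recovers every configured slope within
10 %, intercepts within 1 %, R² within 0.05 and the density–FD correlation
within 0.01 (replicate averaging is required: single-cohort slope SEs at
these R² values are 20–50 % of the slope).

## Cohort statistics

OLS via `scipy.stats.linregress` (slope p from t with n−2 df); segmented
regression is two independent OLS fits split strictly at the fixed
breakpoint (no continuity constraint and no breakpoint estimation — the
3-year split is fixed a priori; the printed pieces are themselves
discontinuous, so independent fitting matches the procedure), each side
requiring ≥ 3 points. One-way ANOVA with Tukey HSD pairwise comparisons
(the standard companion; the post-hoc method was not otherwise specified,
and is switchable). Sex comparisons use the classic equal-variance
two-sample t-test by default with Welch available. Normality is the
D'Agostino–Pearson K² omnibus test (n ≥ 20 required), whose verdict
selects mean ± SD vs median [IQR] reporting. LOESS (tri-cube local
linear, span 0.75) is attached to the caliber entry for plotting only and
feeds no statistic. α = 0.05 throughout with no multiple-testing
correction across metrics, mirroring the original analysis plan. Within
the assembled report, individual tests that fail their preconditions
(e.g. a single-sex age group) are recorded as error entries instead of
aborting.

## Problem sizes

The validation suite uses 200-px tube fixtures, arcs of radius 50–400 px,
full-frame (1,200 × 1,600) tree scenes for the generator-consistency and
smoke checks, 5,000 null replicates for type-I-error calibration of each
test, and 200 replicate cohorts of n = 146 for model recovery; the
acceptance script uses the same 200 × 146 design. These sizes put the
Monte-Carlo SE of every checked mean well inside its tolerance (e.g.
replicate-averaged slope SEs are ≤ 4 % where the tolerance is 10 %).

## Known limitations

* Metrics are computed on masks as given; segmentation quality is outside
  the loop (the evaluation module quantifies it, nothing corrects for it).
* The caliber estimator reads the rasterized lumen; on vessels narrower
  than ~2 px the 0.5-crossing saturates and widths are unreliable.
* FD depends on the frame/region convention (documented above); values
  from different conventions should not be mixed.
* The cohort generator matches the published *marginal* models, one joint
  correlation, and the demographics table; it does not model eye-level
  clustering, sex effects on metrics, or GA/BW associations, so analyses
  of those structures on synthetic cohorts test only the null machinery.
* Curvature units are px⁻¹ by convention (consistent with lnC ≈ −4.66 at
  12.2 µm/px); convert externally if physical units are needed.
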