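# Methods

## Pipeline model and assumptions

The package treats trabeculation quantification as a per-slice 2-D
problem: each end-diastolic short-axis slice is analyzed independently and
aggregated afterwards. This assumes bSSFP-like contrast (bright blood
pool against darker myocardium) and that the endocardial border —
including trabeculae and papillary muscles — is the object whose
complexity matters. Epicardial borders, compacted-layer thickness and 3-D
connectivity of trabeculae are outside the model.

### End-diastole selection

Cine inputs are reduced to one frame per slice. Default `first-frame`
assumes ECG-triggered acquisition starting at end-diastole, the common
cine CMR convention; `max-pool-area` (largest thresholded bright-pool
area) is provided for acquisitions where that assumption fails. Neither
strategy is claimed to match any particular clinical workflow; the choice
is recorded in the output.

### Magnification

Bicubic interpolation, integer factor, default ×4. Implemented as cubic
B-spline interpolation with prefiltering, which reproduces polynomial
intensity profiles up to degree 3 exactly in the image interior; boundary
effects decay geometrically over ~10 input pixels. Pixel spacing is
divided by the factor. FD is dimensionless, so magnification affects the
resolvable detail, not the units.

### Region of interest

When no ROI is supplied, the image is Otsu-thresholded, the largest
bright connected component is taken as the pool estimate, and the ROI is
the circle at its centroid with radius 1.3× the component's
equivalent-area radius (clipped to the image). An earlier variant based
on the brightest intensity decile was rejected: whenever the pool covers
more than 10% of the frame the decile region is a proper subset of the
pool and the derived circle truncates it. The effective ROI is logged and
fully overridable per slice (JSON sidecar or mask image).

### Segmentation

Two-phase region-based level-set evolution (morphological
Chan–Vese/ACWE), initialized from the Otsu threshold inside the ROI, one
curvature-smoothing pass per step, iteration cap 200, declared converged
when the fraction of changed pixels over a 10-iteration interval drops
below 1e-3. Non-convergence is flagged on the result, not raised. The
brighter phase is taken as pool; the final mask is the largest
8-connected bright component, which keeps inter-trabecular recesses
contiguous with the cavity and discards isolated bright specks. The
segmenter is deterministic; a plain Otsu `threshold` mode exists for
testing and degraded inputs. A constant-intensity ROI raises a
"no contrast" error.

### Edge extraction

Edges are pixels with strictly positive Sobel gradient magnitude of the
binary mask. On binary input the response is quantized, so the zero
threshold involves no tuning. The response band straddles the boundary
and is about two pixels wide — this width is accounted for in the
box-size defaults rather than by thinning: morphological thinning was
evaluated and rejected because 8-connected thin contours under-count
diagonal runs, biasing smooth-border FD below 1.

### Box counting and FD fit

Counts use a single grid anchored at the top-left of the ROI bounding box
(no offset averaging, so results are bit-reproducible), with ceiling
semantics at the right/bottom margins. Default sizes are powers of two up
to the largest ≤ 0.45× the smaller ROI dimension. The minimum size
follows the rule *smallest box ≥ 2× stroke width*: 2 px for bare
rasterized curves, 4 px for Sobel-band edge maps. Boxes smaller than the
stroke measure stroke area rather than boundary length and inflate the
slope by ~0.03–0.05 on smooth borders. FD is the negative slope of the
unweighted OLS fit of ln N(s) on ln s, with R² reported; at least four
scales are required.

Estimator accuracy, measured on fractals with analytic dimension at
1024 px (line 1.0, Koch log4/log3, quadratic Koch 1.5, Sierpinski
triangle log3/log2): mean signed error −0.018, largest individual error
−0.03 (quadratic Koch). Residual known biases: finite rasterization
depth flattens counts at the smallest scales, and few-box quantization at
the largest scales makes smooth-circle FD range over ~1.02–1.10 depending
on radius rather than sitting exactly at 1.

### Aggregation

The most apical slice is excluded from analysis entirely, including the
global mean (partial-volume effects). Global FD is the arithmetic mean of
analyzed slice FDs. The apical/basal split drops the middle slice of
odd-length stacks from both halves but keeps it in the global mean —
the halving rule applies to the regional split only. Base→apex
orientation comes from slice-location metadata; without it the caller
must state the orientation explicitly (no silent guess).

## Reference ranges

Per sex, ordinary least squares of metric on age; 95% prediction
interval at age x as the outer limits. Preconditions: ≥ 10 records per
sex, age span ≥ 20 years; classification is refused more than 10 years
outside the fitted span. Indeterminate regions (the 95% CI of each limit,
accounting for sample size) default to a case-resampling percentile
bootstrap: n_boot = 2000 refits with a fixed seed, 2.5th/97.5th
percentiles of each limit; degenerate resamples are discarded. A
first-order delta-method alternative (Var(limit) ≈ Var(ŷ) + t²g·s²/(2(n−2)))
is available and agrees with the bootstrap to within ~20% on band width
at n = 500. The packaged decade tables are applied as printed, without
interpolation, matching how such tables are used clinically; the
continuous-age path requires a fitted model.

Classification respects each row's lower→upper orientation, so
negative-valued strain metrics (where "upper" means larger magnitude,
i.e. more negative) classify on signed values exactly as tabulated.
Boundary values falling on an indeterminate band are labeled
indeterminate.

## Observer agreement

ICC(2,1): two-way random effects, absolute agreement, single measure,
from the two-way ANOVA mean squares; 95% CI by the F-based approximation
for this variant. Perfect-agreement matrices (zero error and rater
variance) collapse the CI to a point rather than producing NaN.
Averaged-measures ICC(2,k) is available behind a flag. Missing cells are
handled upstream by listwise deletion with a logged count.

## Synthetic data: what it emulates and what it does not

The LV phantom emulates the geometry that drives fractal analysis: a
bright circular pool (intensity 400), myocardial annulus (120) and
background (30) — a contrast of 280 at 3T-bSSFP-like levels — with dark
trabecular fingers indenting the endocardial border, two papillary
bodies, Gaussian noise (default σ = 8), a 10% low-order multiplicative
bias field, base→apex radius taper, and a raised-cosine axial complexity
profile peaking at 60% of the long axis (the papillary level).
Complexity c ∈ [0,1] maps linearly to finger count K ∈ [0,24] and depth
A ∈ [0, 0.35 r]; finger angles occupy evenly spaced slots with jitter
(fully uniform placement makes adjacent-slice FD too erratic for profile
comparisons). Papillary bodies sit at 0.45 r so the deepest indentation
cannot pinch a recess off the cavity. Default stack: 9 slices on a
160-px canvas — small enough that a full stack segments in seconds at ×4
magnification, large enough that ~24 fingers remain resolvable.

The phantom does **not** model motion, through-plane effects, flow
artifacts, surface coil shading beyond the polynomial bias, or real
trabecular branching: its boundary complexity is angular waviness, not a
true fractal. Passing phantom tests therefore demonstrates that the
pipeline measures boundary complexity monotonically and segments
high-contrast pools accurately — not that clinical FD values will match
any particular cohort.

The cohort generator draws ages uniformly over 20–69 and values from
intercept_sex + slope·age + N(0, s) with defaults slope 4e-4 FD/yr,
female intercept 1.180, male−female gap 0.021, s = 0.029, n = 90/sex —
the structure (male offset, slow age rise, decade-balanced recruitment)
of a healthy adult reference cohort. The rater generator is a standard
two-way random-effects model.

## Numerical choices and degenerate inputs

- Zero-variance ROI → "no contrast" error; empty or ROI-filling pool
  masks → validation errors.
- Zero-noise cohorts: residual SD is floored at machine epsilon so the
  prediction band collapses onto the line instead of dividing by zero.
- Spline overshoot below zero after magnification is clipped (intensities
  are physically non-negative).
- All generators are pure functions of (spec, seed); `numpy`'s
  `default_rng` throughout.
- Missing pixel spacing defaults to 1.0 mm with a warning — FD itself is
  unaffected.

## Problem sizes used in the test suite

Phantom-based checks run on the default 160-px canvas: the
complexity-monotonicity grid uses five stacks (40 slice segmentations),
the Dice grid 15 single slices across complexity × noise, and the
FD-bounds grid 60 slices across complexity × noise × slice position.
Reference-range recovery uses 500 records per sex with coverage assessed
on 5000 fresh draws; ICC recovery uses 200 subjects × 2 raters. The
fractal validation suite always runs at the full 1024-px canvas.

## Known limitations

- FD captures border complexity only; it cannot see compacted-layer
  thinning, and deep recesses narrower than the magnified pixel grid are
  invisible.
- Box-count FD of smooth borders carries a +0.02–0.10 discretization
  offset depending on pool radius; comparisons are therefore meaningful
  within a fixed protocol (magnification, box range), which the output
  provenance records.
- The packaged decade tables are specific to the population, scanner
  field strength and analysis tool that produced them; refit
  `fit_reference` on your own cohort when any of those differ.
- The level-set contract is a generic two-phase region-based formulation;
  it is not a reimplementation of any particular published variant.
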