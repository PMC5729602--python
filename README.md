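# lvfractal

Semi-automated fractal analysis of left-ventricular (LV) trabeculation from
short-axis cine cardiovascular magnetic resonance (CMR), with normative
reference ranges and reproducibility statistics.

## Who this is for

Excessive LV trabeculation — up to and including left-ventricular
non-compaction (LVNC) — is conventionally assessed with the
non-compacted/compacted (NC/C) thickness ratio, which is manual and poorly
reproducible. The fractal dimension (FD) of the endocardial border is a
dimensionless, observer-robust alternative: a smooth border has FD near 1,
a heavily trabeculated one approaches 2. This package implements the full
measurement chain for researchers working with short-axis cine stacks
(DICOM series, NIfTI volumes, or plain image directories) and for anyone
who needs to classify FD or global-strain values against sex- and
age-specific reference ranges.

## The method

Per end-diastolic slice:

1. **Magnify** ×4 by bicubic interpolation.
2. **Segment** the bright blood pool inside a circular region of interest
   with a two-phase region-based level set (Otsu-initialized, curvature
   regularized, iteration cap 200); dark trabecular fingers and papillary
   muscles are excluded from the pool, recesses contiguous with the cavity
   are kept.
3. **Extract edges** of the binary pool mask with the Sobel operator —
   the endocardial border including every trabecular indentation.
4. **Box-count**: count grid boxes of side *s* containing border pixels
   for a geometric progression of sizes, and estimate
   FD = −slope of the OLS fit of log *N*(*s*) against log *s*.

Per subject, the most apical slice is excluded (partial-volume effects);
**global FD** is the mean of the remaining slice FDs; the analyzed stack is
split into basal and apical halves (dropping the middle slice of odd
stacks) to give the **mean** and **maximal apical FD**.

Reference ranges are 95% prediction intervals from per-sex linear
regressions of each metric on age,

  (a + b·x) ± t₀.₉₇₅,ₙ₋₂ · s · √(1 + 1/n + (x − x̄)²/Sxx),

each limit carrying a bootstrap 95% CI as an *indeterminate region*;
values classify as abnormal-low / indeterminate-low / normal /
indeterminate-high / abnormal-high. Published decade tables for a healthy
adult cohort (ages 20–69, FD and global strain, both sexes) ship with the
package. Observer agreement uses the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1) with an
F-based 95% CI.

A synthetic-data module provides fractals with analytically known
dimension, parametric bSSFP-like LV phantoms with ground-truth masks and a
tunable trabeculation complexity, cohort tables, and rating matrices — so
every stage is testable without clinical data.

## Worked example

Generate a phantom stack (complexity 0.5, seed 5) and analyze it:

```sh
$ lvfractal phantom stack --seed 5 --out demo.nii.gz
$ lvfractal analyze demo.nii.gz
{
  "subject_id": "demo.nii",
  "global_fd": 1.1313,
  "mean_apical_fd": 1.1485,
  "max_apical_fd": 1.1974,
  "per_slice": [
    {"slice_index": 0, "fd": 1.0816},
    ...
    {"slice_index": 7, "fd": 1.1974}
  ]
}
```

The most apical slice (index 8) was excluded; per-slice FD rises from the
smooth basal slices toward the mid-ventricular trabeculation peak. Global
FD 1.13 sits in the healthy range — classify a measured value against the
packaged tables:

```sh
$ lvfractal classify --sex male --age 25 --value 1.25
global_fd male age 25 value 1.25: indeterminate-high
```

(the 20–29 male decade row has mean 1.199 with upper indeterminate band
1.243–1.257, so 1.25 is borderline-high rather than clearly abnormal).

Observer agreement from a long-format ratings CSV:

```sh
$ lvfractal icc raters.csv
ICC(2,1) absolute agreement: 0.850 (95% CI 0.661-0.938, n=20, k=2)
```

The same functionality is available as a library
(`lvfractal.analyze_stack`, `fit_reference`, `classify`,
`icc_2way_random_agreement`, `make_lv_stack`, ...).

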