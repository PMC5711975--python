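# Methods

## Problem and scope

`ciquant` quantifies *collective invasion* in breast-tumor tissue sections:
the infiltration of the peritumoral fibrous and adipose tissue by cohesive
multicellular tumor units (nests, strands, single-file "Indian file"
chains) rather than by individual cells. The package implements the full
quantitative chain — image cytometry on multiplexed marker channels, the
collective-invasion (CI) score, grouped-versus-individual cell
classification, per-region marker densitometry — and the survival arm that
links the CI score to distant metastasis-free survival (DMFS) in a patient
cohort. Because clinical slide archives cannot be redistributed, every
stage is validated against a synthetic-data module that renders slides and
simulates cohorts with exactly known ground truth.

## The CI score

For one tissue section let

* `pct_adipose` = 100 · (adipose area) / (whole-section tissue area),
* `pct_tumor_in_adipose` = 100 · (tumor area inside adipose) / (total
  tumor area).

The CI score is the ratio

```
CI = pct_tumor_in_adipose / pct_adipose .
```

CI = 1 means the tumor occupies fat in exact proportion to its
availability; CI > 1 means preferential invasion of the adipose
compartment. The normalization by adipose availability makes the score
robust to how much fat happened to be contained in the block. Sections
without adipose tissue have no defined score; they raise an
`ExcludedSlideError` and are flagged `excluded` in batch output rather
than given a number.

A consequence of the definition worth spelling out: the two percentages
have different denominators. 10% of the *tumor* area inside adipose tissue
implies 90% of the tumor outside it (fibrous tissue or non-invading core),
regardless of how large the adipose compartment is.

## Image-cytometry stage

1. **Background correction** (`segmentation.correct_background`). Either a
   morphological rolling-ball background or subtraction of the histogram
   mode (the empty-slide level). Output is clipped at 0, so a constant
   image maps to zero and a constant offset added to the input moves
   foreground means by well under 1%. Mode subtraction is the batch
   default: it is exact for the dominant-background images this pipeline
   sees and costs a histogram rather than a morphological filter.
2. **Thresholding** (`threshold_channel`). Otsu by default (the junctional
   marker channel is strongly bimodal after correction); `fixed:<v>` cuts
   at intensity > v. A constant channel is a degenerate input, not a mask.
3. **Duct exclusion** (`apply_exclusions`). Normal ducts are
   keratin/E-cadherin positive but are not tumor; a supplied exclusion
   mask is subtracted from the thresholded mask before any area is
   measured.
4. **Nucleus detection** (`detect_nuclei`). Gaussian smoothing (1 µm)
   followed by local-maximum seeding with a Euclidean minimum separation
   (default 3 µm, a bit under one nucleus diameter) and a relative
   intensity floor of 0.25 · max. The disk-shaped suppression footprint
   matters: a square (Chebyshev) footprint suppresses diagonal neighbors
   at up to √2 times the nominal distance and silently merges diagonal
   cell pairs in rotated chains.
5. **Group labeling** (`label_groups`). Connected components of the tumor
   mask with 8-connectivity (diagonal contacts must not split a
   single-file chain), each nucleus assigned to its containing component.
   Components with ≥ 2 nuclei are multicellular groups. A single-nucleus
   component is *individual* only if its nearest other epithelial pixel is
   farther than the neighbor radius (default 5 µm, below one cell
   diameter); otherwise it is attributed to that nearest group — an
   operational reading of "no obvious cell neighbor".
6. **Compartment assignment** (`assign_compartments`). By centroid
   membership: adipose wins over core (invading cells inside the adipose
   band are adipose), anything else is fibrous. Centroid membership is
   simpler and more testable than area-overlap voting; groups get the
   majority compartment of their cells.

Individualization is reported as 100 · (individual keratin-positive
cells) / (all keratin-positive cells) within the peritumor invasion zone
(fibrous + adipose compartments, core excluded). Collective-invasion
positivity uses inclusive thresholds on the grouped percentage: ≥ 95% in
both compartments for ductal (IDC) samples; ≥ 75% (fibrous) and ≥ 90%
(adipose) for lobular (ILC) samples, whose files are less cohesive.

## Densitometry

`intensity.mean_gray` is the arithmetic mean of a background-corrected
channel over a supplied region mask; `region_marker_table` tabulates all
channels over named regions (normal luminal epithelium, tumor groups in
adipose tissue, stromal cells). Stromal-cell masks are supplied, not
inferred: automating spindle-shape detection is out of scope. A
max-projection utility handles multi-plane inputs; the module itself works
on single 2D grids.

## Survival arm

Scores are dichotomized at the cohort median (ties go to the low group —
the convention has to be fixed somewhere and `value > median → high` is
the natural reading of "high score"). Curves are Kaplan–Meier
product-limit estimates; at tied times events precede censorings, so
censored subjects remain at risk for events at their own time. The
two-group comparison is the Mantel–Cox log-rank test,
χ² = (O₁ − E₁)²/V with hypergeometric variance accumulated over distinct
event times. The hazard ratio is the O/E (Mantel–Haenszel-style)
estimator

```
HR = (O1/E1) / (O2/E2),   CI95 = exp(log HR ± 1.96 · sqrt(1/E1 + 1/E2)),
```

which is the estimator classical clinical-statistics packages attach to
the log-rank test. Cox regression is deliberately absent: the analysis is
a univariate stratification, and no multivariate model is fitted anywhere.

Secondary comparisons: Mann–Whitney U for CI score between patients with
and without distant metastasis (exact enumeration when the smaller sample
has ≤ 8 observations and no ties; otherwise the tie-corrected normal
approximation without continuity correction), and tie-corrected
Kruskal–Wallis with Dunn's post test (Bonferroni adjustment over all
pairs) for multi-region marker comparisons. Spearman rank correlation
serves both for automated-vs-visual score concordance (the visual score is
ordinal) and for the negative-control correlations of the CI score with
lymph-node status, grade, size and menopausal status. All tests are
two-sided at α = 0.05.

## Synthetic slides

The generator renders a stylized section at the tumor–adipose interface,
at 0.5 µm/pixel by default (a common multiplexed-scan resolution; 0.24 µm
is a one-line override):

* **Geometry.** Tissue fills the frame. The adipose compartment is a
  marginal band whose width realizes the requested area fraction exactly
  (to pixel quantization); adipocytes are packed non-overlapping discs
  (15–35 µm radius) rendered as faint rims inside it. The tumor core is
  an ellipse at the opposite edge. Invading groups are laid out as
  compact hexagonal nests, 3–6-cell-wide strands, or 1–3-cell-wide
  gently curved files, with cell bodies of 4 µm radius at 1.7-radius
  spacing so bodies stay connected. Individualized cells are isolated
  single bodies.
* **Packing.** Objects are placed by rejection sampling with
  circle-against-circle collision tests (per cell body, not per bounding
  box — elongated files would otherwise jam the packer), keeping distinct
  epithelial objects at least `min_separation` (default 10 µm) apart
  boundary-to-boundary. Infeasible requests raise `PackingError` instead
  of silently dropping objects. Elongated layouts are redrawn up to four
  times before a slide is declared infeasible.
* **Rendering.** Nuclear signal on every nucleus (2.2 µm radius);
  pan-cytokeratin on every epithelial body; E-cadherin on IDC epithelium
  and CD44 on ILC epithelium (the junctional-marker switch between the
  subtypes); vimentin only on spindle-shaped stromal cells. A 1-pixel
  Gaussian blur emulates optics. Noise (scaled by `noise_level`, default
  1) adds a smooth random background field plus a planar gradient
  (≈ 20 intensity units against 200-unit signal) and signal-dependent
  Gaussian noise — enough to exercise background correction and
  thresholding without changing any topology.
* **Ground truth.** Masks, the per-cell table (centroid, group id,
  compartment) and the true CI quantities are computed from the geometry
  before rendering, so the CI identity holds exactly on the truth.

Two helpers encode the study conditions: `validation_slide_params` builds
a large slide (~2200 peritumor epithelial cells) at the subtype
individualization levels of 0.75% (IDC) and 4.65% (ILC);
`slide_params_for_ci` solves the geometry (adipose fraction fixed at 0.3,
group placement split and core size derived) for a requested CI score,
which is how the recovery experiments span scores from ~0.1 to ~3.

What the synthetic slides do **not** emulate: staining variability and
bleed-through between channels, tissue folds and autofluorescence
artifacts, nuclear pleomorphism, densely touching groups (objects are
kept separated by construction), and 3D section-to-section continuity —
a cell isolated in one plane may well be connected in the next, so true
individualization is an upper bound in any single section. Passing tests
therefore demonstrate correctness of the measurement chain, not
performance on clinical material.

## Synthetic cohorts

Per patient: a CI score from a lognormal (median ≈ 0.7, σ = 0.9 on the
log scale — right-skewed like observed score distributions), an event
time that is exponential with hazard
`baseline · exp(log HR · 1[score > cohort median])`, independent
exponential censoring, and an administrative cap at 60 months matching a
5-year metastasis window. Defaults: baseline hazard 0.008/month and
censoring 0.005/month, giving roughly 40% vs 65% 5-year event
probability in the low/high groups — event counts at which a 200-patient
cohort has useful power. The generator returns the true parameters it
used, and the hazard is tied to the *cohort* median so the estimand
matches the analysis exactly.

## Numerical and design notes

* All randomness flows from a single `numpy` `default_rng(seed)` per
  generator call; nothing touches global state, and equal seeds give
  bit-identical slides, cohorts and batch outputs.
* Area measurements are pure pixel counts; translation of the scene
  changes them only through frame clipping (tested by rolling).
* The zero-events log-rank case returns χ² = 0, p = 1; a group with zero
  observed or expected events makes the O/E hazard ratio undefined
  (`UndefinedHazardRatioError`) rather than infinite.
* Median dichotomization with all values identical is a degenerate split
  and raises, as does Otsu on a constant channel.
* Batch runs write a manifest (config, SHA-256 config hash, seed) next to
  results; changing any analysis parameter changes the hash.

## Problem sizes used in validation

The shipped experiments use 768²-pixel slides (384 µm side) for unit
checks, 20 slides for CI-score recovery, 2560²-pixel validation slides
(~2200 peritumor cells) for the individualization recovery, 1000
100-patient null cohorts for type-I-error calibration, and 200
200-patient cohorts at true HR 2.3 for estimator calibration. These sizes
give Monte-Carlo standard errors comfortably below the tolerances they
are checked against.
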