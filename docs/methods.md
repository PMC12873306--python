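# Methods

## Coordinate frame and pose normalization

All geometry is in millimetres. The canonical frame places the nasal tip
(pronasale) at the origin; +x points toward the subject's anatomical left
along the inter-endocanthion direction; +y is the trichion-to-gnathion
direction orthogonalized against x (pointing toward the scalp); +z = x × y
points toward the observer. Normalization is a proper rigid motion
(rotation determinant +1, translation), so inter-landmark distances are
exactly preserved; the inverse transform is returned with the normalized
set. Degenerate inputs (coincident endocanthions, eye axis parallel to the
vertical axis) raise a normalization error rather than producing an
arbitrary frame.

Scanner output records left/right from the photographer's viewpoint.
Laterality conversion mirrors the point set about the midsagittal plane and
swaps every `_L`/`_R` label pair; the operation is an involution, and
features are only defined on anatomically labeled sets.

The axis construction itself (eye line → x, Gram–Schmidt vertical → y) is a
package design choice; any rigid-normalization convention that fixes the
nasal tip gives identical distance/perpendicular/area features, and the
extent and axis-angle features are defined relative to this documented
frame.

## Feature roster

47 features are extracted per subject. Exact constructions for every
feature live in `morphrisk.morphometry.default_feature_definitions`; the
classes are:

* **Distances** (e.g. face width = zygion L–R, philtrum length =
  subnasale–labiale superius, nose height = pronasale–subnasale).
* **Extents**: max − min of one coordinate over a fixed landmark subset
  (e.g. "Part nose x" over glabella, nasion, pronasale, subnasale and both
  alae). This reproduces the observed near-equality of part-mouth-x with
  mouth width.
* **Perpendicular depths**: point-to-chord distances — philtrum depth is
  the distance of the philtrum midpoint from the subnasale–labiale-superius
  chord; chin depth is pogonion against the labiale-inferius–gnathion chord.
* **Projected distance**: philtrum length after dropping z ("flat"
  length); never exceeds the 3D length.
* **Axis offset**: nose depth, the |z| offset of pronasale above the alare
  midpoint.
* **Axis angles** ("slopes"): arccos(|v·ê|/‖v‖) of a segment direction
  against each axis, folded to [0, π/2] and **stored in radians**
  (normative tables for such features print values near 1.5, which is only
  consistent with radians despite degree-labeled headers). The three
  angles of any segment satisfy cos²θx + cos²θy + cos²θz = 1.
* **Polygon areas**: shoelace area of the six-point eyelid contour
  projected on the frontal plane; self-intersecting contours warn and
  return the absolute value.
* **Midpoint projection**: forehead height, |y| distance from the
  frontotemporale midpoint to gnathion.

"center eye" is a documented alias for the left eye. Extraction requires
anatomical laterality and internally normalizes pose, so all 47 features
are invariant (to 1e-6 relative) under any rigid motion of the input, and
mirroring a face swaps left/right feature pairs while fixing midline
features.

## Template and calibration

The template is a bilaterally symmetric 72-landmark face whose coordinates
were chosen once so that ten designated calibration features (face width,
jaw width, nose width, philtrum length and depth, mouth width, inner and
outer intercanthal distances, left-eye width, subnasale–stomion distance)
fall within 5% of published normative means for a depression cohort (all
are within 2% as built). Features outside the calibration set are
anatomically plausible but not individually matched; nose length and the
chin measurements in particular depend on constructions that published
tables do not pin down (chin length/depth normative SDs of ~15 mm are hard
to reconcile with any rigid landmark construction, and are left as-is).

## Synthetic cohort generator

The generator defines the study conditions the tests probe:

* **Composition.** Default n = 203, with exact cell counts male/female ×
  no-risk/risk = 50/42/43/68 (55% female overall, 62% female in the risk
  group). In stochastic mode, sex is Bernoulli(111/203) and the risk label
  is drawn from logit P(SR) = −0.174 + 0.633·female, which reproduces the
  same composition in expectation. Intake simulation adds 19 subjects
  (10 withdrawals, 9 scan-quality failures) flagged for the exclusion
  stage, giving the 222 → 203 accounting.
* **Shape variation.** Five smooth global displacement fields — lateral
  width scaling, vertical elongation, depth scaling, philtrum-groove
  deepening along the chord normal, and vertical mouth-block translation —
  with standard-normal scores and scales (3.5, 3.0, 4.0, 1.5, 2.0) mm.
  Scales were set once so key feature SDs approximate published
  within-group SDs (philtrum depth ≈ 1.4 vs 1.6–1.8 mm; philtrum length
  ≈ 2.1 vs 2.1–2.5 mm; face width ≈ 7 vs 8–9 mm). Eyelid-contour area
  varies less than published SDs because no dedicated eye-size mode is
  included — a known limitation.
* **Noise and nuisance.** Isotropic N(0, 0.2 mm) per landmark coordinate
  (scanner accuracy), then a random rigid motion (rotation up to ±20°,
  translation up to ±30 mm) that normalization must undo; faces are emitted
  in photographer laterality by default.
* **Effects.** Displacement fields conditional on group and sex.
  `philtrum_depth_effect(δ)` displaces the philtrum midpoint along the
  chord normal so the depth feature of affected subjects increases by
  exactly δ, enabling exact parameter-recovery targets.
* **Covariates.** Truncated normal at instrument bounds, rounded to
  integer totals; YMRS is generated within 0–6 so no synthetic subject
  violates the mania exclusion. Covariates are drawn independently of the
  group label, matching a cohort whose clinical measures do not separate
  the groups.
* **Determinism.** All draws come from one `numpy` PCG64 generator seeded
  by the config; a fixed seed reproduces cohorts, reports and files
  byte-identically.

What passing tests show — and do not show. Because faces are built from
five global modes plus independent noise, feature covariance is low-rank
and far simpler than real facial variation; there is no sexual dimorphism
of the face itself, no age or BMI dependence, and no expression. Recovery
results therefore validate the *pipeline* (geometry, gating, adjustment,
regression), not any claim about real faces.

## Statistical conventions

* Shapiro–Wilk gate at α = 0.05, applied to each group separately; the
  t-route requires both groups to pass. The gate rule and α are package
  choices; the convention is recorded in every result row.
* Pooled-variance (Student) t rather than Welch: back-computation from
  published group summaries supports the pooled form (2.146 vs the printed
  2.137 from 2-decimal inputs); Welch is nearly identical at these group
  sizes.
* Mann–Whitney U reports the first group's U (U₁ + U₂ = n₁n₂); p-values
  use the tie-corrected normal approximation with continuity correction,
  which tracks the exact permutation null to within ~0.05 even at n = 5.
* Chi-square for 2×2 tables applies the Yates correction by default — the
  corrected statistic (4.329 on the default composition) matches published
  values where the uncorrected one (4.937) does not.
* Benjamini–Hochberg is implemented directly (sort, multiply by m/i,
  cumulative minimum from the top, cap at 1). Adjustment families: the six
  regression terms; the 47 overall-screen tests; the 47 tests within each
  sex stratum. Headline screen flags use raw p < 0.05 with adjusted values
  reported alongside, mirroring how such screens are conventionally
  tabulated.
* Logistic regression: Newton MLE (tolerance 1e-10, max 100 iterations)
  via statsmodels; rank-deficient designs and (quasi-)separation raise
  named errors instead of returning unstable estimates. Continuous
  predictors are z-scored — per-mm odds ratios for features with
  sub-millimetre SDs would be uninformative — and the per-unit estimate is
  reported alongside. Sex coding: male = 0, female = 1.

## Null calibration and correlated features

With no injected effects the screen's per-feature type-I error is the
nominal 5%, but the *count* of raw-p rejections across the 47 features is
over-dispersed relative to Binomial(47, 0.05): features sharing a shape
factor reject together whenever that factor's group contrast is extreme by
chance. Across generator seeds the count typically lies in the binomial
99% band (0–7) but exceeds it in a substantial minority of runs (observed
counts 0–12 over small seed sets). This is a property of any screen over
correlated features, not an error in the tests; rate-based checks (mean
rejection rate, permutation nulls) are the robust formulation and are also
included in the suite.

## Numerical choices

Orthonormality and determinant of rotations are enforced to 1e-9; rigid
invariance of features is asserted to 1e-6 relative; round-trip file I/O is
lossless to 1e-9 mm (12 significant digits written). Ties in extents and
angles need no tie-breaking (max/min and arccos are well defined);
degenerate geometric inputs (coincident chord endpoints, zero vectors,
< 3 contour points, empty subsets) raise `ValueError`s naming the
operation. Report CSVs are written with fixed float formatting so repeated
runs are byte-identical.

## Problem sizes

Default analyses use the study-sized cohort (n = 203). Parameter-recovery
checks use n = 400–1000 with 3-standard-error tolerances; the logistic
recovery test uses n = 2000. These sizes give recovery checks comfortable
power while keeping the full suite fast.

## Known limitations

* The 72-landmark dictionary and the extent/part feature subsets are this
  package's own fixed conventions; other groups' landmark protocols will
  differ in the filler points and possibly in construction details.
* No mesh ingestion: input is landmark tables, not raw scans; automatic
  landmarking, dense registration and surface smoothing are out of scope.
* The generator's factor structure is invented (no public within-group
  feature covariances exist to calibrate against); effect recovery under
  realistic covariance structures beyond low-rank global modes is untested.
* Chin-feature constructions are underdetermined by published summaries and
  should not be interpreted against external normative values.
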