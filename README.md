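# morphrisk

Case-control 3D facial morphometrics for psychiatric cohorts.

Facial shape carries stable traces of neurodevelopment, and several
psychiatric phenotypes have been linked to subtle craniofacial variation.
`morphrisk` implements the full analysis path for studies that ask whether
facial morphology differs between a clinical risk group and a comparison
group — here motivated by suicide-risk screening in depression cohorts,
where landmark-based features such as philtrum length and depth are the
candidates of interest. Clinical 3D scans cannot usually be shared, so the
package also ships a synthetic cohort generator that reproduces the
statistical structure such a study assumes, enabling fully reproducible
method validation by parameter recovery.

The pipeline:

1. **Landmark I/O** — 72 labeled 3D points per subject (mm), long or wide
   CSV; validated cohort tables with clinical covariates (PHQ-9, HDRS-17,
   HAMA, GAD-7, YMRS, IMS), including the YMRS > 6 mania exclusion.
2. **Pose normalization** — photographer-view laterality is converted to
   anatomical orientation; each face is rigidly moved so the nasal tip
   (pronasale) sits at the origin, the inter-endocanthion axis defines +x
   (anatomical left), and the trichion–gnathion axis (orthogonalized) defines
   +y. Rigid, so all inter-landmark distances are preserved.
3. **Feature extraction** — 47 features: 32 distance-class measurements
   (inter-landmark distances, axis-aligned bounding extents, perpendicular
   depths to a chord such as philtrum depth, a frontal-plane projected
   length, a z-offset nose depth), 12 axis angles
   θ(v, ê) = arccos(|v·ê|/‖v‖) in radians, 2 eyelid-contour shoelace areas,
   and a forehead-height midpoint projection.
4. **Screening** — each feature is compared between groups through a
   Shapiro–Wilk gate: pooled-variance t-test when both groups pass
   normality at α = 0.05, otherwise a two-sided Mann–Whitney U (midranks,
   tie-corrected normal approximation with continuity correction).
   Benjamini–Hochberg adjusted p-values are reported alongside raw p.
   The screen runs overall and stratified by sex.
5. **Interaction regression** — maximum-likelihood logistic regression

   logit P(SR) = β₀ + β₁·female + β₂·PhL + β₃·PhD + β₄·DLN
               + β₅·(female×PhD) + β₆·(female×DLN)

   with z-scored continuous features (PhL = philtrum length, PhD = philtrum
   depth, DLN = left-endocanthion-to-nasion distance), Wald 95% CIs
   exp(β̂ ± 1.96·SE), and BH adjustment across the six non-intercept terms.

## Worked example

The toolkit reproduces standard worked examples directly from summary
inputs:

```python
>>> from morphrisk import chi_square_2x2, t_from_summary, bh_adjust
>>> chi_square_2x2(50, 43, 42, 68)        # sex-by-group counts, Yates-corrected
(4.3285, 0.0375)
>>> t_from_summary(16.14, 2.45, 93, 15.45, 2.13, 110)   # philtrum length
(2.1464, 201.0, 0.0330)
>>> [round(p, 3) for p in bh_adjust([0.024, 0.103, 0.034, 0.217, 0.030, 0.470])]
[0.068, 0.154, 0.068, 0.26, 0.068, 0.47]
```

The chi-square shows females over-represented in the risk group; the pooled
t shows a shorter philtrum in the risk group; the BH column reproduces the
adjusted significance of a six-term regression family.

End-to-end with a known injected effect (a 1 mm philtrum-groove deepening
in female risk-group subjects only, n = 400):

```python
>>> from morphrisk import sample_cohort
>>> from morphrisk.synthetic_cohort import GeneratorConfig, philtrum_depth_effect
>>> from morphrisk.study_pipeline import build_feature_table, run_interaction_regression
>>> eff = philtrum_depth_effect(1.0, group="SR", sex="female")
>>> faces, cohort, _ = sample_cohort(GeneratorConfig(n_subjects=400, seed=8, effect_map=(eff,)))
>>> _, table = run_interaction_regression(build_feature_table(faces), cohort)
>>> print(table[["term", "OR", "ci95_low", "ci95_high", "p"]].round(3).to_string(index=False))
                 term    OR  ci95_low  ci95_high     p
                const 0.989     0.727      1.345 0.941
               Female 1.708     1.109      2.632 0.015
      Philtrum length 1.066     0.862      1.318 0.555
       Philtrum depth 1.023     0.750      1.395 0.885
       Dist Leye nose 0.928     0.677      1.273 0.643
Female*Philtrum depth 2.979     1.844      4.812 0.000
Female*Dist Leye nose 0.968     0.631      1.487 0.883
```

Only the sex term and the injected female × philtrum-depth interaction are
significant — the pipeline localizes the effect to the right term (ORs are
per SD of the feature).

A command-line interface wraps the same steps:

```sh
morphrisk --seed 1 simulate --out run/          # landmarks.csv + cohort.csv
morphrisk extract --landmarks run/landmarks.csv --out run/
morphrisk screen --features run/features.csv --cohort run/cohort.csv --by-sex
morphrisk --seed 1 run --out run/report/        # full study, four CSV tables
```

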