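# schoolcommute

Street-network exposure measures and logistic modelling of **active commuting
to school (ACS)** — walking to/from school by children (7–11) and adolescents
(12–18) in urban areas.

Whether a child walks to school depends on the built environment around the
school and on the home–school route.  This package computes the standard
GIS-based predictors of that behaviour on a street network, associates them
with dichotomised ACS through a binary-logistic protocol, locates
route-measure cutoffs with ROC/Youden analysis, and cross-tabulates ACS by
route-directness ranges.  Because questionnaire microdata of this kind are
rarely shareable, it also ships a synthetic-city generator with a known
behaviour model, so every estimator can be validated end-to-end.

## Measures and models

For each school, a **network buffer** (service area) is the set of street
segments within a threshold network distance of the school — 1250 m for
children, 1350 m for adolescents — polygonised by dilating reached segments
by a 25 m pedestrian margin.  On that footprint three walkability measures
are computed:

- **residents density** = residents / area (ha),
- **intersection density** = street nodes of degree ≥ 3 / area (ha),
- **mixed-use diversity** = normalised entropy of floor-area shares over six
  land-use classes, H = −Σ pᵢ ln pᵢ / ln 6 ∈ [0, 1], z-scored across schools.

For each participant, two route measures:

- **distance** — shortest street-network distance home → school (km),
- **PRD** (pedestrian route directness) = network distance / straight-line
  distance; 1 is perfectly direct, ≤ 1.5 conventionally "direct".

The outcome is weekly active trips (0–10), dichotomised active = trips ∈
[4, 10].  The analysis protocol: pooled logit with all five predictors plus
an age-group adjustment (with a crude/adjusted odds-ratio confounding check
at the 10% rule), collinearity diagnostics (pairwise r, VIF, condition
indices), and an age-stratified refit after dropping predictors that are
both non-significant and collinearity-flagged.  School-level measures enter
median-dummied; route measures stay continuous.  Youden's J = sensitivity +
specificity − 1 selects ROC-optimal cutoffs for PRD (active above) and
distance (active below).

## Worked example

Generate a synthetic city (16×16 blocks of 120 m, 15 schools, 300 children +
600 adolescents) and run the whole pipeline:

```sh
schoolcommute simulate demo --seed 11 --blocks 16 \
    --n-children 300 --n-adolescents 600 --config city.yml
schoolcommute run demo/network.geojson demo/participants.csv \
    demo/schools.csv demo/parcels.geojson --outdir demo_out
schoolcommute thresholds demo_out/exposures.csv
```

prints

```
prd_all: AUC=0.571 cutoff=1.475 J=0.117 [valid-exploratory]
prd_children: AUC=0.672 cutoff=1.404 J=0.271 [valid-exploratory]
prd_adolescents: AUC=0.519 cutoff=1.781 J=0.086 [invalid]
distance_all: AUC=0.498 cutoff=1.023 J=0.053 [invalid]
```

i.e. on this draw route directness separates active from non-active
children (AUC 0.67, active above PRD ≈ 1.40) better than adolescents — the
generator's child preset carries a much larger PRD slope (2.43 vs 1.26 on
the log-odds scale), and the stratified fit recovers it:
`demo_out/models.json` reports for children PRD B = 2.96 (OR ≈ 19.3,
p < 0.001) against a planted 2.43, and for adolescents mixed-use OR = 2.09
and intersections OR = 1.91, both positive as planted, versus negative
child coefficients.  `schoolcommute crosstab demo_out/exposures.csv` prints
the ACS × PRD-range table with row percentages and Pearson χ² (here
χ² = 12.3, df = 4, p = 0.015).

Every stage is also callable as a library function
(`schoolcommute.exposure.build_exposure_table`,
`association.run_model_sequence`, `roc.threshold_report`,
`crosstab.build_crosstab`) on pandas DataFrames.

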