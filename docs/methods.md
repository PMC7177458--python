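# Methods

## Street network model

The network is an undirected graph with node coordinates in a projected
planar CRS (metres) and positive edge lengths.  Lengths may exceed the
straight chord between endpoints (a curvy street stored as one segment) but
never undercut it; inputs whose coordinates fit the lon/lat box *and* whose
edges are all shorter than one metre are rejected as unprojected.  Points
are snapped to the nearest edge segment with deterministic tie-breaking
(lowest edge id, then lowest offset); offsets are expressed in weighted
metres so partial-edge traversal costs scale with the edge's stated length.

Shortest distances between snapped points run a Dijkstra seeded at the two
partial-edge offsets of the origin (plus the direct along-edge interval when
both points share an edge).  This is exact for undirected positive-weight
graphs and avoids mutating the graph; an augmented-graph Dijkstra with
temporary snap nodes serves as the independent oracle in the tests.

A **service area** at threshold *t* contains every edge position *x* (in
weighted metres from endpoint *u*) with min(d(u)+x, d(v)+L−x) ≤ t, the
school's own edge additionally receiving the direct interval around the
snap offset.  Reached portions are dilated by a configurable pedestrian
margin (default 25 m) and unioned into the footprint polygon.  The source
study derived buffers from a routing-service isochrone tool whose
polygonisation is not documented; edge dilation is reproducible and
parameterised, which is why footprint areas here are not comparable in
magnitude to that study's.  Intersections are reached nodes of degree ≥ 3 —
the standard GIS convention, excluding dead-ends and mid-block bends.

## Exposure construction

- Buffer thresholds: 1250 m (children), 1350 m (adolescents), the distances
  urban children/adolescents are typically willing to walk.  A school
  serving both groups gets both buffers; each participant is joined to
  their age group's buffer.
- Parcels partially inside a footprint contribute floor area and residents
  in proportion to the intersected area fraction (areal weighting).
- Mixed-use entropy uses a fixed k = 6 denominator over the canonical
  classes (residential, industrial, retail, office, public service,
  recreational): an absent class lowers the index, reading the measure as
  evenness across the named uses.  `k=None` switches to present-class
  normalisation for sensitivity analysis.
- z-scores use the population (n-denominator) SD across the school buffers
  actually used; the convention is a package choice and is stated here
  because sample-SD z-values differ by √(n/(n−1)).
- PRD uses the raw home/school points for the straight-line denominator and
  snapped points for the network numerator, so address errors or off-network
  homes can produce PRD < 1.  Such records are flagged (`prd_lt_1`) and kept
  by default — observational datasets of this kind contain them — with a
  strict mode that drops them.  A participant whose home coincides with the
  school (undefined PRD) is excluded with reason `home_at_school`.

## Outcome coding and exclusions

Active = weekly active trips in [4, 10]; 0–3 is non-active.  Exclusions, in
order: missing outcome, bicycle commuters (excluded outright, not recoded
active), missing/non-finite home coordinates, empty records; participants
unroutable on the network are excluded during exposure assembly with their
own logged reason.  School-level measures are median-dummied over the
participant-level distribution (each participant carrying their school's
value) because the participant is the regression's unit of analysis; values
exactly at the median code to 0.  A school-level-median alternative would
cut at a different point whenever school sizes are unequal.

## Association protocol

Model 1: pooled logit of ACS on the five predictors plus an adolescent
indicator, all entered in one step (no stepwise selection); the same model
without the age term supplies the crude/adjusted odds-ratio comparison, with
changes ≥ 10% flagged as confounding.  Collinearity diagnostics: pairwise
Pearson correlations, VIF_j = 1/(1−R²_j) from OLS of predictor j on the
rest, and condition indices √(λmax/λᵢ) of the column-scaled
intercept-included cross-product matrix.  Predictors non-significant in
model 1 (p > 0.05) **and** with VIF above the threshold (default 2.0,
configurable) are dropped before the age-stratified model 2.  Fits use
Newton's method, relative tolerance 1e-8, max 100 iterations; perfect or
quasi-separation (|B| > 30, exploding SEs) and non-convergence raise typed
errors naming the offending predictor rather than returning unstable
estimates.  CIs are Wald, exp(B ± 1.96·SE), matching the output conventions
of the desktop statistics packages this protocol originated in.
Classification accuracy is the fraction of cases on the correct side of the
probability cutoff (default 0.50).  Strata with fewer than 10 events or
non-events are refused.  No school-level clustering or random effects are
modelled; with few schools the school-level dummies are shared by all of a
school's participants, so their SEs are optimistic — a deliberate mirror of
the protocol being implemented, which carries the same limitation.

## ROC / Youden thresholds

Candidate cutoffs sit midway between consecutive distinct scores (plus
sentinels beyond the extremes).  AUC is the trapezoidal area, identical to
the Mann–Whitney concordance probability; its 95% CI uses the Hanley–McNeil
variance (a closed form adequate at these sample sizes; DeLong would need
per-observation placements and changes nothing material here).  The Youden
maximiser breaks ties toward the more inclusive active class (lower cutoff
when active scores high, higher when active scores low).  Validity classes:
*valid* when AUC ≥ 0.5 with 0.5 outside the CI, additionally labelled
*exploratory* when AUC < 0.75, *invalid* otherwise (constant scores are
degenerate AUC 0.5).  Four analyses are reported: PRD for all participants
and per age group (active above the cutoff) and distance for all (active
below).

## Cross-tables

Default PRD edges (1.212, 1.30, 1.40, 1.50) with the first bin closed at the
observed minimum and the rest right-closed, overridable.  Row percentages
are exact internally and rounded to one decimal only at the reporting layer.
Pearson's χ² (no continuity correction) is computed on the occupied
rows/columns; a table collapsing to a single occupied row or column has no
degrees of freedom left and reports NaN.

## Synthetic city

The generator emulates the statistical structure the analysis assumes, not
any particular city:

- **Morphology** — a square block grid (default 28×28 blocks of 120 m) with
  a per-district cul-de-sac rate (default fraction 0.12, lognormal district
  factors) and 2 non-crossable 3×3-block superblocks whose interiors lose
  their nodes and whose land use is forced single-class; the largest
  connected component is kept.  Cul-de-sacs and superblocks lengthen routes,
  which is what raises PRD above the pure-grid [1, √2] band.
- **Land use** — districts of 7×7 blocks draw class shares from a Dirichlet
  (concentration 6 around a residential-dominant mean); blocks subdivide
  into one parcel strip per class with floor area = area × FAR 1.5.
- **Residents** — proportional to residential floor area with lognormal
  noise (σ 0.35).  Because district land use is residential-dominant,
  residents density anti-tracks the mixed-use entropy across schools; this
  is the realistic collinearity that the model-sequence drop rule reacts to,
  and whether the dummied residents variable crosses the VIF threshold
  depends on the morphology draw.
- **Sample** — 24 schools (8 primary / 14 secondary / 2 mixed) placed at
  network nodes ≥ 500 m apart; 826 children and 2142 adolescents assigned
  uniformly to their age group's schools; home distances lognormal (medians
  0.69/0.86 km, σ 1.1/1.2) with the right tail truncated by the city extent,
  so extreme multi-km outliers present in real address data are not
  reproduced.
- **Behaviour** — P(active) = logit⁻¹(b₀ᵍ + βᵍ·(x − x̄ᵍ)) per age group,
  where x is the pipeline's *own* computed design (median-dummied buffer
  measures, continuous distance and PRD) so recovery tests isolate
  estimation error from exposure error, and b₀ᵍ is set from target active
  shares (0.679 children, 0.714 adolescents).  The default slope preset
  mirrors the published age-group contrast in sign — children (−0.369,
  −0.420, −0.14, +2.428), adolescents (+0.495, +0.711, −0.144, +1.257) on
  (intersections, mixed uses, distance/km, PRD) — with a zero residents
  slope.  The children's distance magnitude is a package choice for
  identifiability at simulation scale; only the signs are treated as the
  planted truth.  A `distance_threshold_model` preset generates a sharp
  distance rule, P(active) = logit⁻¹(8·(1.25 − d)), for cutoff-recovery
  checks.  Trip counts are uniform on {4..10} (active) or {0..3}
  (non-active), so the dichotomy boundary is exact by construction; real
  questionnaires are heavily right-stacked at 10, which matters only for
  trip-count-level (not binary) analyses, which this package does not do.
- **Defects** — configurable fractions of missing outcomes (0.15), bicycle
  commuters (0.003) and corrupted home coordinates (0.02) exercise the
  exclusion funnel.
- All randomness flows through one seeded generator; identical seed and
  config give byte-identical output files.

What passing the recovery tests shows: on data whose exposures are measured
without error and whose outcome truly follows the logistic model, the
pipeline's estimators find the planted structure.  It does not validate the
behaviour model against real commuting data, and it cannot reproduce any
coefficient magnitudes or cutoffs estimated on the unavailable questionnaire
sample — those depend on that sample's distance and PRD distributions.

## Problem sizes used in validation

Recovery runs use one synthetic city at n = 5000 with the study's age
composition (1390 children / 3610 adolescents) and 20 outcome replicates on
fixed exposures; replicating only the behavioural randomness isolates
estimation error from morphology randomness.  With ~10 schools per stratum
a morphology draw can leave a median-dummied school measure constant within
one stratum, where the stratified fit is undefined; such draws are re-rolled
(the analysis protocol presupposes within-stratum variation).  Cutoff
recovery uses 5 replicates of the planted distance rule; the null-AUC check
uses 10 replicates at n = 2000.  Unit fixtures use grids of ≤ 500 nodes,
where brute-force oracles (exhaustive snapping scans, augmented-graph
Dijkstra, pair-counting AUC, per-record bin scans, normal-equation R²) are
exact and fast.

## Known limitations

- Buffer footprints depend on the dilation margin; area-denominated
  densities are therefore comparable within a configuration, not across
  margins.
- No turn restrictions, one-way streets, slopes, or traffic attributes; no
  micro-scale street features.
- Logistic SEs ignore school-level clustering (see above).
- The geographic-coordinate guard is a heuristic (lon/lat box + sub-metre
  edges); a projected network of sub-metre alleys would be misclassified,
  which no real street network is.
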