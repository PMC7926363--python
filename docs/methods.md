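# Methods

This note records the statistical model behind `acceptmap`, the defaults
and numerical choices, what the synthetic generators do and do not emulate,
and the known limitations.

## Data model

An *evaluation* is one observed medicine intake coded on Q = 9 categorical
variables with J = 21 categories in total: result of intake (3), patient
reaction (3), preparation/administration time (3), and six binary coping
methods (2 each). Every stage of the pipeline works on the disjunctive
(indicator) coding Z (n × 21): observed cells are one-hot within their
variable's block; after imputation a block may hold fuzzy memberships, but
it always sums to one per row, so every row of Z sums to Q.

Each variable carries an explicit acceptability order from best to worst
(fully > partly > not taken; positive > neutral > negative; short > medium
> long; method not used > used). This order drives every worst-case
decision: recoding direction, argmax tie-breaks in imputation, and the
tie-break of point classification.

## Worst-case recoding

Raw observer reports carry objective fields alongside the ticked
categories: whether a sublingual tablet was still under the tongue at 30 s
and at 1 min, the administration time in seconds, and free-text notes for
each method. Six rules reconcile them, in a fixed order so that later rules
see earlier rules' output:

| rule | trigger | action |
|------|---------|--------|
| R1 | not under tongue at 1 min, result "fully taken" | result := partly taken |
| R2 | not under tongue at 30 s | alteration := used (tablet plausibly swallowed) |
| R3 | administration < 60 s, result "fully taken" | result := partly taken |
| R4 | administration < 30 s, result "partly taken" | alteration := used |
| R5 | free text matches the keyword map | mapped method := used |
| R6 | seconds disagree with the reported time band | time := band of the seconds |

Time bands are closed on the better side: ≤ 60 s is short, 60–150 s medium,
> 150 s long. Every change is appended to an audit log whose length over
9 × n cells gives the recoded fraction. Design choices worth recording:

- R6 treats the seconds as the authoritative record and overrides the
  reported band in either direction; it is a correction, not a worst-case
  move. The monotonicity guarantee (never moving to a better state)
  covers the result and method variables, where all recodes are worst-case.
- R6 never fills a *missing* time band from the seconds: filling is the
  imputation stage's job, and a band the observer did not report stays
  missing so the imputation model sees it.
- Keyword matching is case-insensitive substring matching over a
  configurable map (default: water, hot chocolate, fruit juice, juice,
  candy → food/drink). No further text analysis is attempted.
- Contradictory raw fields (under the tongue at 1 min but < 30 s reported)
  raise a warning and the worst case is applied.

The cascade is idempotent: re-running it on its own output changes nothing.

## Imputation by regularized iterative MCA

Missing cells are initialized at the observed column proportions of their
variable, then refined by iterating:

1. correspondence analysis of the current Z: P = Z/(nQ), residuals
   S = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2), SVD;
2. rank-ncp reconstruction, with each retained singular value σ_s shrunk to
   (σ_s² − σ̄²)/σ_s where σ̄² is the mean residual eigenvalue
   (regularization, on by default, damps overfitting of the filled cells);
3. overwriting of the missing cells only with the reconstruction, clipped
   at zero and renormalized to sum one per variable block.

Iteration stops when the summed squared change on missing cells falls below
tol = 1e-6 (default max_iter = 1000; non-convergence returns a flagged
result with a warning). Observed cells are bit-identical before and after.
Defaults: ncp = 3, matching the dimensionality of the map the completed
matrix feeds; deterministic initialization, no random restarts, so the
result needs no seed. Each imputed cell is also resolved to a hard
category by per-variable argmax, ties going to the worse category.

Two structural facts matter for users: (a) when ncp reaches the rank of
the current matrix the reconstruction is exact and the initialization is a
fixed point, so ncp should stay below the complete-data rank (at most
J − Q − 1 = 11 here); (b) with ncp at the rank of the complete-data
structure and no regularization, rows that duplicate complete rows recover
their categories exactly.

## The reference framework

The map is the correspondence analysis of the indicator matrix itself (not
the Burt matrix, and with no Benzécri/Greenacre inertia correction):
eigenvalues λ_s = σ_s², row principal coordinates F = D_r^(−1/2)UΣ,
category principal coordinates G = D_c^(−1/2)VΣ. The total inertia of a
complete 9-variable indicator is J/Q − 1 = 4/3, which the tests use as a
closed-form oracle. The indicator dialect was chosen because supplementary
projection and barycentric scoring are defined on row coordinates, which it
yields directly; fuzzy (post-imputation) rows enter P exactly like crisp
ones. ndim is fixed at 3 by configuration, not chosen by an eigenvalue
threshold.

Supplementary evaluations are projected with no influence on the fit by the
transition formula f_s = (1/√λ_s) Σ_j h_j g_js, where h is the row profile
(indicator entries normalized to sum one). Projecting a reference row
reproduces its fitted coordinates; a row at the uniform profile (categories
at their masses) lands at the origin.

Axis orientation is made deterministic by requiring the "fully taken"
category to lie on the non-positive side of every dimension, so the
negative side of each axis is always the favourable side. Categories with
zero total mass are dropped with a warning; supplementary mass on dropped
categories is ignored, also with a warning.

## Profiles and v-tests

Reference rows are partitioned by Ward-linkage agglomerative clustering
(Lance–Williams on squared Euclidean distances, as scipy implements it) on
the 3-D coordinates, cut at k = 2, then consolidated by k-means initialized
at the two cut centroids with no random restarts — deterministic, and the
consolidation can only reduce the within-cluster sum of squares.

A cluster is described by its over-represented categories. For category j
(overall count n_j in N rows) and cluster k (size n_k, in-cluster count
n_kj), the two-tailed p-value comes from the exact hypergeometric law —
summing the probabilities of all outcomes no more likely than the observed
one, not a normal approximation — and is mapped to the v-test
v = sign(n_kj/n_k − n_j/N) · Φ⁻¹(1 − p/2). Categories with v > 1.96
(the two-sided 5% point) characterize the cluster. With k = 2 the v-tests
of the two clusters are equal and opposite.

The cluster holding more of the nine positive categories above the
threshold is labelled green ("positively accepted"), the other red; a tie
is an error, since such a corpus cannot anchor an acceptability reading.
The green/red *areas* of the map are the nearest-centroid halfspaces of the
consolidated centroids — the same rule k-means membership uses — with exact
ties classified red (worst case). This Voronoi delimitation is this
package's own design choice; no other delimitation rule is standard.

## Scoring

A medicine's score is the barycenter of its evaluations' supplementary
coordinates plus, for each of the three dimension pairs, a confidence
ellipse: center at the barycenter, shape S/m (sample covariance of the two
columns over the m evaluations — the covariance of the mean), scaled by
√χ²₂(level) with level = 0.90. This is the normal-theory confidence region
for a mean; whether the original construction was parametric or
bootstrap-based is not documented anywhere we know of, and the parametric
form is the declared choice here. The boundary is traced by n_points =
1000 points at equally spaced angles θ_i = 2πi/n, through the Cholesky
factor of S/m (eigendecomposition fallback near singularity; a singular
covariance or m < 3 is an error). Each 2-D boundary point is completed to
3-D with the barycenter's remaining coordinate before classification,
since classification lives on the full map.

Classification: *positively accepted* iff the barycenter and 100% of the
3 × 1000 ellipse points classify green. The share of ellipse points per
profile is reported as a membership proportion. A reliability floor of 30
evaluations is enforced for headline scores (override flag available);
subgroup scores below the floor are computed with a warning, since
subgroup analyses are descriptive.

Two scores are significantly different when their ellipses are disjoint in
at least one plane (separation in a projection implies separation on the
map); overlap is decided by polygon intersection of the traced boundaries,
which covers containment. Subgroup scoring partitions by visit day, sex,
age, or prior exposure, skips empty levels, compares all pairs, and runs
the three patient-characteristic cross-tabulations (sex × age,
exposure × age, sex × exposure) through the test-selection rule as a
confounding report.

## Contingency tests

Expected counts E = (row margin × column margin)/N select the test:
Pearson χ² (no continuity correction) when at least 80% of cells have
E ≥ 5 and min E > 0, otherwise Fisher's exact test. The r×c Fisher test
enumerates every table with the observed margins and sums the
multivariate-hypergeometric probabilities of tables no more probable than
the observed one, with a (1 + 1e-7) tolerance factor on the comparison —
the convention of mainstream exact-test software, with which this
implementation agrees to seven digits on study-sized tables. Enumeration
is bounded by a work estimate; beyond it, a Monte-Carlo mode samples
fixed-margin tables instead. Missing cells are excluded from all test
denominators and reported separately.

The selection rule is applied mechanically. On study-sized data it can
disagree with a published test choice for borderline tables (e.g. 2×3
tables whose smaller row has expected counts just under 5); callers can
run either test directly, as both are exposed.

## Synthetic data

The generators exist because reference corpora of real evaluations are
proprietary. The reference generator draws, per evaluation, a latent
profile (positive with probability 0.7) and then the nine variables
conditionally independently from per-profile emission tables; every
positive category is strictly more likely under the positive profile
(e.g. fully taken 0.90 vs 0.20, reaction positive 0.80 vs 0.10, methods
not used 0.95 vs 0.40). Defaults: n = 1562 evaluations, matching the scale
of the corpus such frameworks are built from.

The study generator emulates a 37-patient, three-visit design: 12 girls /
24 boys, ages 12/18/6 across 3/4/5 years (the proportional completion of
the study population's printed distribution over the 36 patients with
known demographics), 12 previously exposed / 24 first exposure, one
patient with all demographics missing; one patient lost after the first
visit and one after the second (37/36/35 evaluations); missingness rates
2/108, 4/108, 7/108 on result, reaction and time (13 expected missing
cells of 972); and raw-field quirks injected at rate 0.12 per family
(under-tongue failures, fast administrations, method texts) so the recode
cascade fires at a realistic frequency. Study evaluations draw from the
positive profile with probability 0.85.

What the generator does *not* emulate: country/culture covariates, the
real corpus's eigenstructure, correlations between variables beyond the
shared latent profile, and per-patient behavioural consistency across
days (each evaluation draws its profile independently). Passing tests
therefore demonstrate that the machinery recovers a planted two-profile
structure and calibrated ellipses — not that any particular real medicine
would score the same way.

A one-profile corpus (mixing 0 or 1) is rejected at parameter validation:
two-cluster polarity is undefined without both profiles, so the failure is
surfaced at the earliest stage rather than downstream.

## Problem sizes and determinism

Default analyses run in seconds on one core: the map is an SVD of a
1562 × 21 matrix, Ward clustering is quadratic in n = 1562, ellipses are
1000-point traces, and the r×c Fisher enumerations at study scale visit
tens of thousands of tables. The only stochastic components are the data
generators and the Monte-Carlo utilities, all driven by explicit integer
seeds; fitting, imputation, clustering and scoring are fully deterministic
by construction (no random initializations anywhere).

## Known limitations

- The green/red areas are halfspaces; a curved or density-based
  delimitation of the profiles would classify borderline points
  differently.
- Single imputation only: imputation uncertainty is not propagated into
  the ellipses.
- The ellipse-overlap significance rule is a geometric criterion, not a
  formal test; its operating characteristics depend on the sample sizes of
  both scores.
- The keyword recoder is a substring matcher; multilingual or free-form
  notes need a richer mapping supplied by the caller.
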