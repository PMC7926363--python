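# acceptmap

Medicine-acceptability scoring from observer-reported intake behaviour,
for pharmaceutics and pediatric-formulation researchers.

In pediatrics, *acceptability* — the overall ability and willingness of a
patient to use, and of a caregiver to administer, a medicine as intended —
drives compliance and hence treatment safety and efficacy. A standardized
way to measure it observes each medicine intake and codes it on nine
categorical variables: the result of intake (fully / partly / not taken),
the patient's reaction on a three-point facial hedonic scale, the
preparation-and-administration time band (short ≤ 1 min, medium 1–2.5 min,
long > 2.5 min), and six binary variables for the coping methods used
(divided dose, food/drink, alteration of the intended form of use, a device
not provided, reward, restraint).

`acceptmap` implements the full analysis pipeline around that coding:

1. **Worst-case recoding** — objective raw fields (was a sublingual tablet
   still under the tongue at 30 s / 1 min, the administration time in
   seconds, free-text method notes) are reconciled with the ticked
   categories, always resolving ambiguity in the direction least favourable
   to the medicine, with a full audit log.
2. **Iterative-MCA imputation** — missing categories are imputed from the
   similarities between evaluations and the associations between variables,
   by alternating a regularized truncated multiple correspondence analysis
   with reconstruction of the missing cells of the indicator matrix.
3. **The acceptability reference framework** — an MCA of a large reference
   corpus of intake evaluations defines a 3-D map (eigenvalues λ₁ ≥ λ₂ ≥ λ₃;
   row and category principal coordinates; supplementary projection by the
   transition formula F_sup = H G Λ^(−1/2) for row profiles H).
4. **Two-profile partition** — Ward clustering of the reference rows with
   k-means consolidation yields the "positively accepted" (green) and
   "negatively accepted" (red) profiles; each cluster is described by the
   categories with hypergeometric v-test > 1.96.
5. **Scoring** — a medicine is positioned at the barycenter of its
   evaluations; for each dimension pair a 90% confidence ellipse
   (S/m scaled by √χ²₂(0.90), traced by 1000 points) surrounds it; the
   medicine is *positively accepted* only if the barycenter and every
   ellipse point fall in the green area. Two scores differ significantly
   when their ellipses are disjoint in at least one plane.
6. **Descriptive statistics** — per-day outcome tables and contingency
   tests with the standard selection rule (Pearson χ² when ≥ 80% of
   expected counts are ≥ 5 and none is zero, otherwise an exact r×c Fisher
   test by full enumeration).

Because real reference corpora of this kind are proprietary, the package
ships a synthetic-data module that generates reference corpora with a
latent two-profile structure and study datasets (37 patients × 3 visit
days, dropout, realistic missingness, recodable raw fields), so the whole
pipeline is testable end to end.

## Worked example

```python
import acceptmap as am

# 1. reference corpus and framework
reference = am.generate_reference(am.GeneratorParams(seed=11))
indicator = am.build_indicator(reference.evaluations)
amap = am.fit_mca(indicator, ndim=3)
print("eigenvalues:", amap.eigenvalues.round(4))

# 2. two-profile partition of the map
model = am.cluster_reference(amap)
am.vtest_categories(model, indicator)
am.assign_polarity(model)
print("polarity:", model.polarity)

# 3. study data: recode, impute, score
study = am.generate_study(am.GeneratorParams(seed=5))
evaluations, log = am.apply_worst_case_recoding(study.raw_observations)
print(f"recoded cells: {len(log.entries)} ({100 * log.recoded_fraction:.1f}%)")
result = am.impute_iterative_mca(am.build_indicator(evaluations))
print(f"imputed cells: {result.n_imputed} (converged in {result.iterations_used} iterations)")

score = am.score_medicine(amap, model, result.completed, label="synthetic study medicine")
print(f"n = {score.n_evals}, classification = {score.classification}")
print(f"green membership of ellipse points: {score.membership['green']:.3f}")
```

prints

```
eigenvalues: [0.4639 0.1141 0.1127]
polarity: {1: 'green', 2: 'red'}
recoded cells: 54 (5.6%)
imputed cells: 13 (converged in 8 iterations)
n = 108, classification = positively_accepted
green membership of ellipse points: 1.000
```

The first map dimension absorbs most of the inertia and separates the two
latent profiles; cluster 1 is the green (positively accepted) profile. Of
the 972 observed cells (9 variables × 108 evaluations), 5.6% were recoded
toward the worst case and 13 missing cells were imputed. All 108
evaluations of the simulated medicine project into the green half of the
map, the barycenter and all 3 × 1000 confidence-ellipse points included, so
the medicine is classified as positively accepted. Subgroup scoring
(`am.score_subgroups(..., by="day")`) scores each visit day separately
(n = 37, 36, 35) and reports pairwise ellipse-overlap comparisons plus
confounding checks on the patient characteristics.

The same pipeline is available from the shell:

```sh
acceptmap simulate reference --seed 11 --out data/ref
acceptmap simulate study     --seed 5  --out data/study
acceptmap recode        --in data/study/study_raw.csv --out data/evaluations.csv --log data/recodes.csv
acceptmap impute        --in data/evaluations.csv --ncp 3 --out data/completed.csv
acceptmap fit-framework --in data/ref/reference.csv --ndim 3 --out data/map.json
acceptmap cluster       --map data/map.json --in data/ref/reference.csv --out data/clusters.json
acceptmap score         --map data/map.json --clusters data/clusters.json \
                        --in data/completed.csv --out data/score.json --report data/report.md
```

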