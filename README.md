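# painclust

Symptom-based severity classification of chronic-pain cohorts from
patient-reported outcomes.

Chronic pain conditions are conventionally classified by the anatomical
location of pain, yet the burden they impose — fatigue, disturbed sleep,
depression, anxiety, anger, social isolation — cuts across diagnoses.
`painclust` implements the reverse approach: cluster patients on nine
**pain-agnostic** PROMIS symptom T-scores (population-normed, mean 50,
SD 10), characterize the resulting severity groups against independent
pain-specific measures, classify new patients against the fitted centroids,
and track cluster membership over time against a measurement-error null.
It is written for biostatisticians and pain researchers working with
registry-style patient-reported outcome tables.

## What it computes

- **Discovery** — agglomerative hierarchical clustering (Euclidean distance,
  Ward linkage, ward.D2 convention) of the nine-symptom vectors; the
  agglomerative coefficient AC = mean_i (1 − m_i / h_final) as a linkage
  quality measure; the Tibshirani **gap statistic**
  Gap(k) = (1/B) Σ_b log W*_kb − log W_k with the 1-SE parsimony rule to
  choose k (k = 1..10, B = 50 uniform-range reference sets by default).
- **Separability contributions** — for each symptom j,
  100 · Σ_{(a,b)} (C_aj − C_bj)² / Σ_j' Σ_{(a,b)} (C_aj' − C_bj')²,
  pooling squared centroid differences over all unordered cluster pairs:
  the percent each symptom contributes to between-centroid separability.
- **Profiling** — impairment-oriented norm deviations
  mean_j s_j (C_j − 50)/10 (s_j = −1 for function-scored measures); one-way
  ANOVA (raw values or summary statistics), Bonferroni-adjusted pairwise
  t-tests, Cohen's D with the average-variance denominator
  d = (m₂ − m₁)/√((s₁² + s₂²)/2); days-between-assessments ANCOVA;
  chi-square association with sparse-category dropping.
- **Classification** — nearest-centroid assignment by Euclidean distance,
  ties to the less severe cluster.
- **Dynamics** — baseline→follow-up transition accounting; a bootstrap null
  that jitters each baseline T-score within the PROMIS CAT measurement-error
  bound (±3.0 T-points, uniform) and re-classifies, 1000 replicates; a
  one-sample t locating observed movement against that null; per-patient
  change magnitudes.
- **Synthetic cohorts** — a 3-component Gaussian-mixture generator whose
  per-cluster means/SDs, mixture weights (25.71 / 50.68 / 23.61 %), and
  follow-up transition matrix are the published training-cohort profiles,
  so every stage is testable end to end without access to registry data.

## Worked example

```python
from painclust.simulate import GeneratorConfig, simulate_baseline
from painclust.hierarchy import gap_statistic, select_k, fit_model
from painclust.separability import percent_contribution, norm_deviation
from painclust.schema import SYMPTOMS

sim = simulate_baseline(GeneratorConfig(n=3000, correlation=0.0, seed=1))
X = sim.cohort.data[list(SYMPTOMS)]

curve = gap_statistic(X.to_numpy(), kmax=10, B=50, seed=1)
k = select_k(curve)                      # -> 3
model = fit_model(X, k, seed=1)

print(percent_contribution(model.centroids).to_frame().round(2))
print(norm_deviation(model.centroids).deviation.round(2))
```

Output:

```
                           percent_contribution  rank
depression                                15.07     1
fatigue                                   14.34     2
sleep_impairment                          13.21     3
anxiety                                   12.86     4
anger                                     12.71     5
social_isolation                           9.82     6
satisfaction_social_roles                  9.63     7
sleep_disturbance                          8.84     8
emotional_support                          3.51     9

1   -0.60
2    0.35
3    1.17
```

The gap statistic selects three clusters on a cohort drawn at the published
profiles. Depression contributes most to cluster separability and emotional
support least; the negative-affect block (depression, anxiety, anger)
carries ~40% of it. The norm deviations read in population-SD units:
cluster 1 sits 0.60 SD *better* than the U.S. general-population norm on the
nine symptoms, cluster 2 about 0.35 SD worse, cluster 3 about 1.2 SD worse —
the graded severity scale the labels encode.

The same stages are scriptable from a shell:

```sh
painclust simulate --n 3000 --seed 1 --out cohort.csv --labels truth.csv
painclust discover --cohort cohort.csv --seed 1 --out-dir run/
painclust classify --model run/model.json --cohort cohort.csv --out labels.csv
painclust dynamics --model run/model.json --cohort cohort.csv --out-dir run/
painclust report --run-dir run/
```

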