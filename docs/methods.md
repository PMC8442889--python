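# Methods

This note records the statistical model behind `painclust`, the numerical
conventions it adopts, what the synthetic-cohort generator does and does not
emulate, and the design choices made where more than one defensible option
existed.

## The classification model

Patients are represented by nine pain-agnostic PROMIS symptom T-scores
(fatigue, sleep disturbance, sleep-related impairment, depression, anxiety,
anger, social isolation, emotional support, satisfaction with social roles).
T-scores are normed to the U.S. general population (mean 50, SD 10); for
symptom-scored measures higher is worse, for function-scored measures
(emotional support, satisfaction with social roles, the physical-function
family, Global Health Mental) higher is better. Because all nine measures
already share one scale, no further standardization is applied before
clustering — the cluster geometry would otherwise silently reweight the
symptoms.

Discovery is agglomerative hierarchical clustering on Euclidean distances
with Ward linkage. "Ward" means the Lance–Williams recurrence on unsquared
distances with merge heights on the distance scale (ward.D2; identical to
SciPy's `ward` and R `hclust`'s `ward.D2`). The classic `ward.D` variant is
available behind a flag via a direct O(n³) Lance–Williams implementation.
Worth noting: merge heights are only defined up to the implementation's
scale convention; flat cuts and the agglomerative coefficient (a ratio of
heights) are invariant to it.

The number of clusters is selected with the gap statistic: the observed
log within-cluster dispersion log W_k (sum of squared deviations from
cluster centroids, equal to the pairwise form Σ_r D_r / (2 n_r)) is compared
to its mean over B reference datasets drawn uniform over each feature's
observed range (a principal-axes bounding-box reference is available).
Reference sets are clustered with the *same* linkage as the data. The
parsimony rule is applied literally as "smallest k within one SE of the
maximizing k": with k* = argmax Gap, select min{k : Gap(k) ≥ Gap(k*) −
s(k*)}. The sequential variant (Gap(k) ≥ Gap(k+1) − s(k+1)) is provided
behind a flag. B defaults to 50 — large enough that the SE of s(k) is small
against the gap increments at the operating n, small enough to keep a full
k = 1..10 sweep under a minute at n = 3000.

Clusters are relabeled by severity: label 1 has the smallest mean
impairment-oriented deviation of its centroid from the population norm
(orientation signs as above), label k the largest. Exact ties (possible
only on degenerate inputs) break by the depression centroid. All downstream
semantics — "improvement" means moving to a lower label — rest on this
ordering.

### Separability contributions

The percent contribution of symptom j to between-centroid separability is

  100 · Σ_{(a,b)} (C_aj − C_bj)² / Σ_{j'} Σ_{(a,b)} (C_aj' − C_bj')²,

pooling squared centroid differences over all unordered cluster pairs
before normalizing. The pooled form (rather than averaging per-pair shares)
is the one under which the published per-symptom percentages reproduce
exactly from the published cluster means; it also makes contributions sum
to exactly 100 and scale quadratically in any one symptom's separation.

### Profiling statistics

Cohen's D uses the average-variance denominator √((s₁² + s₂²)/2) — again
the convention that reproduces the published clustering-symptom effect
sizes from the printed per-cluster means/SDs; n-weighted pooling does not
(e.g. it gives 1.32 instead of 1.29 for the fatigue C1–C2 contrast). The
published *pain-specific* effect sizes do not reproduce from the printed
summary statistics under any standard pooling we tried and are therefore
not used as anchors anywhere. Pairwise t-tests are pooled-variance by
default (Welch behind a flag) with Bonferroni adjustment p_adj = min(1, m·p).
One-way ANOVA is computable from summary statistics (n, M, SD per group) so
printed tables can be checked directly. The follow-up ANCOVA fits cluster
indicators plus the days-between-assessments covariate and reports the
partial F for the cluster factor with conventional dfs (k−1, n−k−1); the
result also carries a `df_printed` pair using the
(groups + covariate − 1, n − groups − 1) accounting seen in the source
tables, so rendered reports can mirror them. Chi-square association drops
sparse categories before testing: rows whose expected counts fall below 5
anywhere are removed first, then columns are re-checked on the reduced
table (a single joint pass would delete every column crossing one sparse
row).

### Classification and dynamics

The nearest-centroid classifier assigns argmin_c ‖x − C_c‖₂ with exact ties
going to the less severe cluster — deterministic and clinically
conservative. No rescaling happens at predict time.

The measurement-error null exploits the PROMIS CAT stopping rule: item
administration stops once the T-score's standard error drops below 3.0
points, so ±3.0 is the instrument's error envelope. Each bootstrap
replicate adds independent Uniform(−ε, +ε) noise (maximum entropy on the
stated support; a Gaussian σ = ε option exists) to all nine scores of every
patient, re-classifies, and records the percent whose assignment differs
from their *unjittered baseline* assignment. Comparing jittered baseline to
baseline — rather than to follow-up — is deliberate: comparing to follow-up
would mix real longitudinal change into what is meant to be a pure
measurement-error distribution. The movement test is a one-sample t of the
null distribution against the observed percent,
t = (obs − mean_null)/(sd_null/√B), df = B − 1. Change magnitude counts a
symptom as changed beyond measurement error only when |Δ| > 3.0 strictly.

## The synthetic-cohort generator

No registry data are distributable, so the generator emulates the cohort's
published statistical structure: a 3-component Gaussian mixture on the nine
symptoms with the published per-cluster means/SDs and mixture weights
(0.2571 / 0.5068 / 0.2361), pain-specific correlates and Global Health
Mental drawn per component, and follow-up membership drawn from a transition
matrix obtained by conditioning the published movement counts on baseline
cluster occupancy (rows 144/115/4 over 263, 105/627/95 over 827, 6/69/108
over 183, normalized).

Parameters that matter, with defaults:

- `n` — cohort size; acceptance-scale runs use 3000, large-sample checks
  up to 2×10⁵.
- `correlation` (ρ, default 0.3) — within-patient equicorrelation of the
  nine symptoms, sampled exactly via the one-factor construction
  z = √ρ·g₀ + √(1−ρ)·g. The source cohort's inter-symptom correlations are
  unpublished, so any value is a modeling choice; 0.3 gives the moderate
  positive coupling typical of co-reported symptom batteries, while ρ = 0
  is used wherever a test needs clean component separability.
- `followup_noise` (default 1.0) — multiplier on component SDs at the
  follow-up redraw.
- Bounded measures are truncated after sampling: intensity to [0, 10],
  catastrophizing to [0, 52], body-map segments rounded into [0, 74]. Pain
  duration is log-normal matched to the published per-component mean/SD
  (the printed SDs exceed the means — strong right skew a normal cannot
  represent).
- Global Health Mental per-cluster levels (50/43/36 ± 8/7/7) are free
  parameters — the source tables do not profile this measure — chosen to
  decline with cluster severity at plausible pain-clinic levels.
- In pipeline simulate mode only a fraction of patients (default 0.077,
  the registry's longitudinal share) receive a follow-up.

What the generator does **not** emulate: item-level CAT responses;
demographic confounding (demographics are uniform — the source cohort
showed no cluster association); any dependence between symptoms and
pain-specific measures beyond shared component membership; floor/ceiling
artifacts of real T-score distributions; informative follow-up attrition.
Consequently, passing tests demonstrate that the *methods* behave correctly
under the published group-level structure — they do not certify performance
on real registry data, where within-cluster correlation structure and
non-Gaussian tails may differ.

## Numerical choices and degenerate inputs

- Seeds: every stochastic stage of the pipeline derives its seed from a
  single master seed via named substreams (CRC32 of the stage name into a
  `SeedSequence`), so stages re-run in isolation reproduce exactly.
- Agglomeration ties: the direct Lance–Williams path merges the lowest
  (i, j) pair; continuous T-scores make exact ties measure-zero.
- All-identical points: the agglomerative coefficient and contribution
  statistic are undefined and raise, never return NaN.
- Missing data: records missing any clustering symptom are excluded, never
  imputed; non-clustering measures carry missingness through and every
  profiling statistic is complete-case, so per-measure n's vary.
- Exclusion order is fixed (noncompleted/test, missing symptoms, duplicate
  patient×timepoint keeping first, underage) and a record failing several
  rules counts once under the earliest — the report must reconcile exactly.
- The longitudinal window is the closed interval [90, 365] days; with
  several qualifying follow-ups the earliest is kept, maximizing gap
  comparability.
- PCA uses the covariance matrix by default (shared scale; correlation
  behind a flag) with the sign convention that each loading vector's
  largest-magnitude entry is positive — component-score correlations are
  otherwise sign-ambiguous.
- Global Health Mental tertile bounds are an explicit required parameter:
  the instrument's "range of possible scores" has no canonical published
  cut points, so none are baked in.

## Problem sizes

Acceptance-scale runs use n = 3000 with B = 50 gap references (k = 1..10,
~30 s per sweep); generator moment checks use n = 2×10⁵, where the 0.15
T-point tolerance is ≈4 standard errors for the smallest component's
noisiest symptom; oracle-equivalence tests for the agglomeration run
exhaustively at n ≤ 10 across all linkages against a from-scratch O(n³)
re-agglomeration.

## Known limitations

- Agglomeration is exact and O(n²) memory; cohorts beyond ~10⁵ records
  need subsampling (out of scope here).
- The ANCOVA is a fixed-effects linear model; repeated-measures or
  mixed-effects extensions are out of scope.
- The jitter null treats the ±3.0-point error bound as homogeneous across
  patients and symptoms; real CAT standard errors vary by score location.
- Severity is a single ordered scale by construction; genuinely
  non-ordered symptom profiles would be forced into the ordering.
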