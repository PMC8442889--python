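"""Centroid separability, norm deviations, and cluster-profiling statistics.

Contains the feature-importance statistic of the clustering solution (the
percent contribution of each symptom to the overall Euclidean separability
between cluster centroids), impairment-oriented deviations from the PROMIS
population norm, and the profiling statistics used to characterize clusters:
one-way ANOVA (from raw values or summary statistics), Bonferroni-adjusted
pairwise t-tests, Cohen's D, time-adjusted ANCOVA for longitudinal follow-up,
and chi-square association tests with small-expected-count category dropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import SYMPTOMS, orientation as measure_orientation


@dataclass
class ContributionTable:
    """Per-symptom percent contribution to between-centroid separability."""

    percent: pd.Series  # indexed by measure, sums to 100

    @property
    def ranking(self) -> pd.Series:
        return self.percent.sort_values(ascending=False)

    def to_frame(self) -> pd.DataFrame:
        out = self.ranking.to_frame("percent_contribution")
        out["rank"] = range(1, len(out) + 1)
        return out


@dataclass
class NormDeviationSummary:
    """Per-cluster mean impairment-oriented deviation from the norm (SD units)."""

    deviation: pd.Series  # indexed by cluster label; positive = worse than norm
    measures: tuple[str, ...]


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class AncovaResult:
    F: float
    df_effect: int
    df_resid: int
    p: float
    adjusted_means: pd.Series
    #: df pair in the published table accounting: (groups + covariates - 1,
    #: n - groups - 1).  Kept alongside the conventional effect/residual dfs.
    df_printed: tuple[int, int] = (0, 0)


def centroids(X: pd.DataFrame | np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Exact per-cluster means, rows indexed by sorted cluster label."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    out = X.groupby(labels).mean()
    if out.isna().any().any() or len(out) != len(np.unique(labels)):
        raise ValueError("empty cluster")
    return out


def percent_contribution(C: pd.DataFrame | np.ndarray) -> ContributionTable:
    """Percent contribution of each measure to between-centroid separability.

    For measure j, contribution_j = 100 * sum over unordered centroid pairs
    (a, b) of (C_aj - C_bj)^2, normalized by the same pooled sum over all
    measures.  Squared coordinate differences are pooled across pairs before
    normalizing, so contributions sum to exactly 100%.
    """
    if isinstance(C, pd.DataFrame):
        names = list(C.columns)
        arr = C.to_numpy(dtype=float)
    else:
        arr = np.asarray(C, dtype=float)
        names = list(range(arr.shape[1]))
    k = arr.shape[0]
    if k < 2:
        raise ValueError("need at least two centroids")
    pooled = np.zeros(arr.shape[1])
    for a in range(k):
        for b in range(a + 1, k):
            pooled += (arr[a] - arr[b]) ** 2
    total = pooled.sum()
    if total == 0:
        raise ValueError("all centroids identical; contributions undefined")
    return ContributionTable(pd.Series(100.0 * pooled / total, index=names))


def norm_deviation(
    C: pd.DataFrame,
    measure_set: list[str] | tuple[str, ...] | None = None,
    orientation: dict[str, int] | None = None,
    norm: float = 50.0,
    sd_unit: float = 10.0,
) -> NormDeviationSummary:
    """Mean impairment-oriented deviation of each centroid from the norm.

    Per cluster: mean over the T-scored measures of s_j * (C_j - norm) /
    sd_unit, where s_j = +1 for symptom-scored measures (higher = worse) and
    -1 for function-scored ones.  Positive values are worse than the norm.
    """
    measures = list(measure_set) if measure_set is not None else list(SYMPTOMS)
    missing = [m for m in measures if m not in C.columns]
    if missing:
        raise ValueError(f"measures not in centroid table: {missing}")
    signs = np.array(
        [
            (orientation or {}).get(m, measure_orientation(m))
            for m in measures
        ],
        dtype=float,
    )
    dev = (signs * (C[measures].to_numpy(dtype=float) - norm) / sd_unit).mean(axis=1)
    return NormDeviationSummary(pd.Series(dev, index=C.index), tuple(measures))


def cohens_d(m1: float, s1: float, m2: float, s2: float) -> float:
    """Standardized mean difference with the average-variance denominator.

    d = (m2 - m1) / sqrt((s1^2 + s2^2) / 2).  Antisymmetric under group swap;
    tables report |d|.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    return (m2 - m1) / np.sqrt((s1**2 + s2**2) / 2.0)


def anova_oneway(values: np.ndarray, labels: np.ndarray) -> AnovaResult:
    """One-way ANOVA on complete cases via the between/within decomposition."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    groups = [values[labels == l] for l in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 complete cases each")
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) for g in groups])
    return anova_from_summary(ns, means, sds)


def anova_from_summary(
    ns: np.ndarray, means: np.ndarray, sds: np.ndarray
) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, SD) summaries."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    n = ns.sum()
    grand = (ns * means).sum() / n
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df1 = len(ns) - 1
    df2 = int(n - len(ns))
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(float(F), df1, df2, p)


def pairwise_t_bonferroni(
    values: np.ndarray, labels: np.ndarray, equal_var: bool = True
) -> pd.DataFrame:
    """Pairwise two-sample t-tests with Bonferroni adjustment.

    Pooled-variance t by default (``equal_var=False`` gives Welch).  Adjusted
    p = min(1, m * p) with m the number of pairs.  Returns one row per
    unordered pair with raw t, raw p, adjusted p, and Cohen's D.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    levels = np.unique(labels)
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        ga, gb = values[labels == a], values[labels == b]
        t, p = stats.ttest_ind(ga, gb, equal_var=equal_var)
        d = cohens_d(ga.mean(), ga.std(ddof=1), gb.mean(), gb.std(ddof=1))
        rows.append(
            {
                "pair": f"{a}-{b}",
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": min(1.0, m * float(p)),
                "cohens_d": abs(d),
            }
        )
    return pd.DataFrame(rows).set_index("pair")


def ancova_time_adjusted(
    values: np.ndarray, labels: np.ndarray, gap_days: np.ndarray
) -> AncovaResult:
    """Between-cluster test adjusted for the days between assessments.

    Fits an ordinary linear model with cluster indicators plus the gap-days
    covariate and reports the partial F for the cluster factor.  The
    ``df_printed`` pair follows the published-table accounting
    (groups + covariate - 1, n - groups - 1).
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    gap_days = np.asarray(gap_days, dtype=float)
    ok = ~np.isnan(values) & ~np.isnan(gap_days)
    values, labels, gap_days = values[ok], labels[ok], gap_days[ok]

    levels = np.unique(labels)
    k = len(levels)
    n = len(values)
    dummies = np.column_stack([(labels == l).astype(float) for l in levels[1:]])
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), dummies, gap_days])) < k + 1:
        raise ValueError("covariate collinear with cluster labels")

    X_full = sm.add_constant(np.column_stack([dummies, gap_days]))
    full = sm.OLS(values, X_full).fit()
    X_red = sm.add_constant(gap_days)
    reduced = sm.OLS(values, X_red).fit()

    df_effect = k - 1
    df_resid = int(full.df_resid)
    F = ((reduced.ssr - full.ssr) / df_effect) / (full.ssr / df_resid)
    p = float(stats.f.sf(F, df_effect, df_resid))

    mean_gap = gap_days.mean()
    beta = full.params
    adj = {}
    for i, l in enumerate(levels):
        x = np.zeros(len(beta))
        x[0] = 1.0
        if i > 0:
            x[i] = 1.0
        x[-1] = mean_gap
        adj[l] = float(x @ beta)
    return AncovaResult(
        F=float(F),
        df_effect=df_effect,
        df_resid=df_resid,
        p=p,
        adjusted_means=pd.Series(adj),
        df_printed=(k, n - k - 1),
    )


def chi_square_association(
    contingency: pd.DataFrame | np.ndarray, min_expected: float = 5.0
) -> tuple[float, int, float, list]:
    """Chi-square test of association with sparse-category dropping.

    Rows or columns containing any expected count below ``min_expected``
    (under independence on the full table) are removed before testing; the
    dropped labels are returned for logging.
    """
    table = (
        contingency
        if isinstance(contingency, pd.DataFrame)
        else pd.DataFrame(np.asarray(contingency, dtype=float))
    )
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    # drop sparse row categories first, then re-check columns on the reduced
    # table (a single joint pass would remove every column crossing a sparse row)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    bad_rows = (expected < min_expected).any(axis=1)
    dropped = [("row", r) for r in table.index[bad_rows]]
    kept = table.loc[~bad_rows]
    arr = kept.to_numpy(dtype=float)
    if arr.shape[0] >= 2 and arr.sum() > 0:
        expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
        bad_cols = (expected < min_expected).any(axis=0)
        dropped += [("col", c) for c in kept.columns[bad_cols]]
        kept = kept.loc[:, ~bad_cols]
    if kept.shape[0] < 2 or kept.shape[1] < 2:
        raise ValueError("fewer than 2x2 categories remain after dropping")
    chi2, p, dof, _ = stats.chi2_contingency(kept.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p), dropped


@dataclass
class MeasureProfile:
    """Table-style profile of one measure across clusters."""

    measure: str
    per_cluster: pd.DataFrame  # index cluster, columns n/mean/sd
    anova: AnovaResult
    pairwise: pd.DataFrame


def profile_measures(
    df: pd.DataFrame, labels: np.ndarray, measures: list[str]
) -> list[MeasureProfile]:
    """Per-measure cluster profile: per-cluster M +/- SD with complete-case n,
    one-way F, and Bonferroni-adjusted pairwise comparisons with Cohen's D."""
    labels = np.asarray(labels)
    out = []
    for m in measures:
        vals = df[m].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        per = (
            pd.DataFrame({"value": vals[ok], "cluster": labels[ok]})
            .groupby("cluster")["value"]
            .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        )
        out.append(
            MeasureProfile(
                measure=m,
                per_cluster=per,
                anova=anova_oneway(vals, labels),
                pairwise=pairwise_t_bonferroni(vals[ok], labels[ok]),
            )
        )
    return out


def render_profile_table(profiles: list[MeasureProfile], floor: float = 1e-4) -> pd.DataFrame:
    """Flatten measure profiles into a report table.

    Rendered p-values below ``floor`` are printed as "<0.0001"; raw values
    remain available on the profile objects.
    """
    rows = []
    for pr in profiles:
        row: dict = {"measure": pr.measure}
        for c in pr.per_cluster.index:
            row[f"C{c}"] = (
                f"{pr.per_cluster.loc[c, 'mean']:.2f} ± "
                f"{pr.per_cluster.loc[c, 'sd']:.2f}"
            )
        row["F"] = round(pr.anova.F, 2)
        row["df"] = f"{pr.anova.df1}, {pr.anova.df2}"
        row["p"] = "<0.0001" if pr.anova.p < floor else f"{pr.anova.p:.4g}"
        for pair, r in pr.pairwise.iterrows():
            row[f"D {pair}"] = round(r["cohens_d"], 2)
            row[f"p {pair}"] = (
                "<0.0001" if r["p_bonferroni"] < floor else f"{r['p_bonferroni']:.4g}"
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")
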