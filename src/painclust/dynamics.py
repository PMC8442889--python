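"""Longitudinal cluster dynamics and the measurement-error bootstrap null.

Observed movement across severity clusters between baseline and follow-up is
compared against a null in which each baseline symptom T-score is jittered
within the PROMIS CAT measurement-error bound (the adaptive engine stops once
the score's standard error drops below 3.0 T-score points) and re-classified.
The share of patients whose cluster changes under jitter alone, over many
replicates, is the distribution of movement attributable to measurement
error; a one-sample t-test locates the observed movement against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CentroidClassifier


@dataclass
class TransitionSummary:
    """Baseline -> follow-up cluster cross-tabulation with movement totals.

    Improvement = any move to a lower severity label; worsening = higher;
    stable = same.
    """

    counts: pd.DataFrame  # rows: baseline label, cols: follow-up label
    n: int

    @property
    def percent(self) -> pd.DataFrame:
        return 100.0 * self.counts / self.n

    @property
    def improved(self) -> int:
        arr = self.counts.to_numpy()
        return int(np.tril(arr, -1).sum())

    @property
    def worsened(self) -> int:
        arr = self.counts.to_numpy()
        return int(np.triu(arr, 1).sum())

    @property
    def stable(self) -> int:
        return int(np.trace(self.counts.to_numpy()))

    @property
    def moved_percent(self) -> float:
        return 100.0 * (self.improved + self.worsened) / self.n

    def to_edge_list(self) -> list[dict]:
        edges = []
        for a in self.counts.index:
            for b in self.counts.columns:
                c = int(self.counts.loc[a, b])
                if c:
                    edges.append(
                        {
                            "origin": int(a),
                            "destination": int(b),
                            "count": c,
                            "percent": 100.0 * c / self.n,
                        }
                    )
        return edges

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "n": self.n,
                "improved": self.improved,
                "worsened": self.worsened,
                "stable": self.stable,
                "edges": self.to_edge_list(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class JitterNull:
    """Bootstrap distribution of percent moved under measurement-error jitter."""

    percent_moved: np.ndarray
    epsilon: float
    seed: int | None

    @property
    def replicates(self) -> int:
        return len(self.percent_moved)

    @property
    def mean(self) -> float:
        return float(self.percent_moved.mean())

    @property
    def sd(self) -> float:
        return float(self.percent_moved.std(ddof=1))

    def to_csv(self, path: str | Path) -> None:
        pd.Series(self.percent_moved, name="percent_moved").to_csv(path, index=False)


@dataclass
class ChangeMagnitude:
    """Per-patient symptom-change metrics and the movers-vs-stayers contrast."""

    mean_abs_change: np.ndarray   # per patient, over the nine symptoms
    n_beyond_error: np.ndarray    # per patient, count of |delta| > threshold
    moved_mask: np.ndarray
    threshold: float

    def group_summary(self) -> pd.DataFrame:
        rows = {}
        for name, mask in (("movers", self.moved_mask), ("stayers", ~self.moved_mask)):
            if mask.sum() == 0:
                rows[name] = {"n": 0, "mean_abs_change": np.nan,
                              "sd_abs_change": np.nan, "mean_n_beyond": np.nan,
                              "sd_n_beyond": np.nan}
                continue
            rows[name] = {
                "n": int(mask.sum()),
                "mean_abs_change": float(self.mean_abs_change[mask].mean()),
                "sd_abs_change": float(self.mean_abs_change[mask].std(ddof=1)),
                "mean_n_beyond": float(self.n_beyond_error[mask].mean()),
                "sd_n_beyond": float(self.n_beyond_error[mask].std(ddof=1)),
            }
        return pd.DataFrame(rows).T

    def compare_groups(self) -> pd.DataFrame:
        """Pooled-variance two-sample t (movers vs stayers), df = n - 2."""
        out = []
        for metric, vals in (
            ("mean_abs_change", self.mean_abs_change),
            ("n_beyond_error", self.n_beyond_error),
        ):
            a, b = vals[self.moved_mask], vals[~self.moved_mask]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            out.append(
                {"metric": metric, "t": float(t), "df": len(vals) - 2, "p": float(p)}
            )
        return pd.DataFrame(out).set_index("metric")


def transitions(
    baseline_labels: np.ndarray, followup_labels: np.ndarray, k: int = 3
) -> TransitionSummary:
    """Exact cross-tabulation of paired baseline/follow-up labels."""
    b = np.asarray(baseline_labels)
    f = np.asarray(followup_labels)
    if b.shape != f.shape:
        raise ValueError("label vectors differ in length")
    counts = pd.crosstab(pd.Series(b, name="baseline"), pd.Series(f, name="followup"))
    labels = list(range(1, k + 1))
    counts = counts.reindex(index=labels, columns=labels, fill_value=0)
    return TransitionSummary(counts, len(b))


def jitter_null(
    baseline_X: pd.DataFrame | np.ndarray,
    classifier: CentroidClassifier,
    epsilon: float = 3.0,
    replicates: int = 1000,
    seed: int | None = None,
    distribution: str = "uniform",
) -> JitterNull:
    """Bootstrap null of cluster movement under measurement-error jitter.

    Per replicate, independent noise is added to every symptom score of every
    patient — Uniform(-epsilon, +epsilon) by default (the maximum-entropy
    distribution on the stated error support), or Gaussian with
    sigma = epsilon when ``distribution="gaussian"`` — and the jittered
    vectors are re-classified.  The replicate records the percent of patients
    whose jittered assignment differs from their unjittered baseline
    assignment.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if distribution not in ("uniform", "gaussian"):
        raise ValueError(f"unknown jitter distribution {distribution!r}")
    if isinstance(baseline_X, pd.DataFrame):
        arr = baseline_X[classifier.measures].to_numpy(dtype=float)
    else:
        arr = np.asarray(baseline_X, dtype=float)
    rng = np.random.default_rng(seed)
    base = classifier.predict(arr)
    pct = np.empty(replicates)
    for r in range(replicates):
        if distribution == "uniform":
            noise = rng.uniform(-epsilon, epsilon, size=arr.shape)
        else:
            noise = rng.normal(0.0, epsilon, size=arr.shape)
        moved = classifier.predict(arr + noise) != base
        pct[r] = 100.0 * moved.mean()
    return JitterNull(pct, epsilon, seed)


def movement_test(
    observed_percent: float, null: JitterNull
) -> tuple[float, int, float]:
    """One-sample t of the jitter-null distribution against the observed movement.

    t = (observed - mean_null) / (sd_null / sqrt(B)), df = B - 1.  A
    degenerate null (zero SD with a nonzero difference) is signalled.
    """
    if null.replicates < 2:
        raise ValueError("need at least 2 replicates")
    diff = observed_percent - null.mean
    if null.sd == 0:
        if diff == 0:
            return 0.0, null.replicates - 1, 1.0
        raise FloatingPointError("zero-variance null with nonzero difference")
    t = diff / (null.sd / np.sqrt(null.replicates))
    df = null.replicates - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def change_magnitude(
    baseline_X: np.ndarray,
    followup_X: np.ndarray,
    moved_mask: np.ndarray,
    threshold: float = 3.0,
) -> ChangeMagnitude:
    """Per-patient change metrics between timepoints.

    Mean absolute T-score change across the symptoms, and the count of
    symptoms whose absolute change exceeds (strictly) the measurement-error
    threshold.
    """
    b = np.asarray(baseline_X, dtype=float)
    f = np.asarray(followup_X, dtype=float)
    if b.shape != f.shape:
        raise ValueError("timepoint matrices differ in shape")
    if np.isnan(b).any() or np.isnan(f).any():
        raise ValueError("change metrics require complete paired vectors")
    delta = np.abs(f - b)
    return ChangeMagnitude(
        mean_abs_change=delta.mean(axis=1),
        n_beyond_error=(delta > threshold).sum(axis=1),
        moved_mask=np.asarray(moved_mask, dtype=bool),
        threshold=threshold,
    )
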