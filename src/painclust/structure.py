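"""Latent structure of the nine clustering symptoms.

Principal component analysis of the symptom battery (covariance-matrix PCA by
default, since all nine measures share the T-score scale), per-symptom
contributions to each component, correlation of component scores with the
PROMIS Global Health Mental measure, and the congruence of the cluster
solution with severity-ordered Global Health Mental tertiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ComponentDecomposition:
    """PCA loadings, explained-variance percentages, and observation scores."""

    loadings: np.ndarray        # p x p, columns are components
    variance_explained: np.ndarray  # percent per component, sums to 100
    scores: np.ndarray          # n x p
    center: np.ndarray
    scaled: bool


@dataclass
class CongruenceMatrix:
    """Cross-tabulation of cluster labels vs severity-ordered tertiles."""

    counts: pd.DataFrame        # rows: cluster label, cols: tertile label
    per_cluster_percent: pd.Series
    overall_percent: float


def pca(X: pd.DataFrame | np.ndarray, scale: bool = False) -> ComponentDecomposition:
    """Eigendecomposition of the covariance (or correlation) matrix.

    Components are ordered by decreasing eigenvalue.  Sign convention: each
    loading vector's largest-magnitude entry is positive, so downstream
    correlations are deterministic.
    """
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    n, p = arr.shape
    if n <= p:
        raise ValueError("need more observations than variables")
    center = arr.mean(axis=0)
    centered = arr - center
    if scale:
        centered = centered / centered.std(axis=0, ddof=1)
    cov = (centered.T @ centered) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for j in range(p):
        if eigvecs[np.argmax(np.abs(eigvecs[:, j])), j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    explained = 100.0 * eigvals / eigvals.sum()
    return ComponentDecomposition(
        loadings=eigvecs,
        variance_explained=explained,
        scores=centered @ eigvecs,
        center=center,
        scaled=scale,
    )


def variable_contributions(
    decomp: ComponentDecomposition, component: int
) -> np.ndarray:
    """Percent contribution of each variable to one component (100 * loading^2)."""
    v = decomp.loadings[:, component]
    return 100.0 * v**2 / (v**2).sum()


def correlate_component(
    scores: np.ndarray, external: np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation of component scores with an external measure.

    Complete cases only; returns (r, p, n)."""
    scores = np.asarray(scores, dtype=float)
    external = np.asarray(external, dtype=float)
    ok = ~np.isnan(scores) & ~np.isnan(external)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired complete cases")
    r, p = stats.pearsonr(scores[ok], external[ok])
    return float(r), float(p), int(ok.sum())


def tertile_congruence(
    cluster_labels: np.ndarray,
    gh_scores: np.ndarray,
    bounds: tuple[float, float],
) -> CongruenceMatrix:
    """Congruence of cluster labels with Global Health Mental tertiles.

    ``bounds = (b1, b2)`` with b1 < b2 split the score range; because higher
    Global Health Mental means *better* mental health, tertile 3 (most
    severe) is gh < b1, tertile 2 is b1 <= gh < b2, tertile 1 is gh >= b2.
    The bounds are an explicit input: the instrument's published range is not
    accompanied by canonical cut points.
    """
    b1, b2 = bounds
    if not b1 < b2:
        raise ValueError("bounds must be strictly increasing")
    labels = np.asarray(cluster_labels)
    gh = np.asarray(gh_scores, dtype=float)
    ok = ~np.isnan(gh)
    labels, gh = labels[ok], gh[ok]
    tert = np.where(gh < b1, 3, np.where(gh < b2, 2, 1))
    counts = pd.crosstab(
        pd.Series(labels, name="cluster"), pd.Series(tert, name="tertile")
    ).reindex(index=[1, 2, 3], columns=[1, 2, 3], fill_value=0)
    n = counts.to_numpy().sum()
    diag = np.diag(counts.to_numpy())
    row_totals = counts.sum(axis=1).to_numpy()
    per_cluster = pd.Series(
        np.where(row_totals > 0, 100.0 * diag / np.maximum(row_totals, 1), np.nan),
        index=counts.index,
    )
    return CongruenceMatrix(counts, per_cluster, float(100.0 * diag.sum() / n))
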