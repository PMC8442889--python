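"""Agglomerative clustering, linkage quality, and gap-statistic k-selection.

The discovery engine: Euclidean distances between nine-dimensional T-score
vectors, bottom-up merging under a chosen linkage, the agglomerative
coefficient as a measure of clustering tightness, and the gap statistic with
the 1-SE parsimony rule to select the number of clusters.

Ward convention.  "Ward" here means the Lance-Williams recurrence applied to
unsquared Euclidean distances with merge heights on the distance scale
(sqrt of twice the increase in within-cluster sum of squares) — the
``ward.D2`` convention of R's ``hclust`` and SciPy's ``ward``.  The classic
``ward.D`` variant (same recurrence applied to the supplied dissimilarities
as-is) is available as method ``"ward.D"`` via a direct O(n^3)
Lance-Williams implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .schema import SYMPTOMS, default_orientation

LINKAGE_METHODS = ("ward", "single", "complete", "average", "weighted", "ward.D")

# Lance-Williams coefficients (alpha_i, alpha_j, beta, gamma) as functions of
# cluster sizes (n_i, n_j, n_k); used by the direct implementation.
_LW = {
    "single": lambda ni, nj, nk: (0.5, 0.5, 0.0, -0.5),
    "complete": lambda ni, nj, nk: (0.5, 0.5, 0.0, 0.5),
    "average": lambda ni, nj, nk: (ni / (ni + nj), nj / (ni + nj), 0.0, 0.0),
    "weighted": lambda ni, nj, nk: (0.5, 0.5, 0.0, 0.0),
    "ward.D": lambda ni, nj, nk: (
        (ni + nk) / (ni + nj + nk),
        (nj + nk) / (ni + nj + nk),
        -nk / (ni + nj + nk),
        0.0,
    ),
}


@dataclass
class MergeTree:
    """Agglomeration history in the standard 4-column linkage-matrix layout.

    Row i of ``Z`` records the i-th merge: left id, right id, height, size of
    the new cluster.  Original items are 0..n-1; merge i creates id n+i.
    """

    Z: np.ndarray
    method: str
    n: int

    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def to_linkage_matrix(self) -> np.ndarray:
        return self.Z.copy()

    def to_newick(self, leaf_names: list[str] | None = None) -> str:
        """Dendrogram as Newick text, branch lengths from merge heights."""
        names = leaf_names or [str(i) for i in range(self.n)]
        height = {i: 0.0 for i in range(self.n)}
        text = {i: names[i] for i in range(self.n)}
        for i, (a, b, h, _) in enumerate(self.Z):
            a, b = int(a), int(b)
            la, lb = h - height[a], h - height[b]
            node = self.n + i
            text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
            height[node] = h
        return text[self.n + len(self.Z) - 1] + ";"


@dataclass
class GapCurve:
    """Per-k gap values and simulation standard errors, k = 1..kmax."""

    gap: np.ndarray
    se: np.ndarray
    log_wk: np.ndarray
    ref_log_wk: np.ndarray  # mean over reference sets
    n_reference: int
    seed: int | None = None

    @property
    def kmax(self) -> int:
        return len(self.gap)


@dataclass
class ClusterModel:
    """Severity-ordered centroids plus fit provenance.

    The contract between discovery and classification: ``centroids`` rows are
    labelled 1..k with label 1 the least severe under the impairment-oriented
    norm deviation; ``labels`` are the per-item severity-ordered assignments.
    """

    k: int
    labels: np.ndarray
    centroids: pd.DataFrame  # index: 1..k, columns: measure names
    orientation: dict[str, int] = field(default_factory=default_orientation)
    linkage: str = "ward"
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "k": self.k,
            "measures": list(self.centroids.columns),
            "centroids": {
                str(c): [float(v) for v in self.centroids.loc[c]]
                for c in self.centroids.index
            },
            "orientation": self.orientation,
            "linkage": self.linkage,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClusterModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        centroids = pd.DataFrame(
            {int(c): v for c, v in payload["centroids"].items()},
            index=payload["measures"],
        ).T.sort_index()
        return cls(
            k=payload["k"],
            labels=np.empty(0, dtype=int),
            centroids=centroids,
            orientation=dict(payload["orientation"]),
            linkage=payload["linkage"],
            seed=payload["seed"],
        )


def pairwise_distance(X: np.ndarray) -> np.ndarray:
    """Square symmetric matrix of Euclidean distances between rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any():
        raise ValueError("missing values in input; exclude incomplete records first")
    return squareform(pdist(X))


def _lance_williams(D: np.ndarray, method: str) -> np.ndarray:
    """Direct O(n^3) Lance-Williams agglomeration; ties to lowest (i, j)."""
    coeff = _LW[method]
    n = D.shape[0]
    d = D.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    size = np.ones(n)
    ids = np.arange(n)
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = d[np.ix_(sub, sub)]
        flat = np.argmin(block)
        i, j = sorted((sub[flat // len(sub)], sub[flat % len(sub)]))
        h = d[i, j]
        ni, nj = size[i], size[j]
        left, right = sorted((ids[i], ids[j]))
        Z[step] = (left, right, h, ni + nj)
        for k in sub:
            if k in (i, j):
                continue
            ai, aj, beta, gamma = coeff(ni, nj, size[k])
            d[i, k] = d[k, i] = (
                ai * d[i, k] + aj * d[j, k] + beta * h + gamma * abs(d[i, k] - d[j, k])
            )
        active[j] = False
        d[j, :] = d[:, j] = np.inf
        size[i] = ni + nj
        ids[i] = n + step
    return Z


def agglomerate(D: np.ndarray, method: str = "ward") -> MergeTree:
    """Agglomerative clustering of a distance matrix under ``method``.

    ``D`` may be a square symmetric distance matrix or a condensed vector.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}")
    D = np.asarray(D, dtype=float)
    condensed = D if D.ndim == 1 else squareform(D, checks=False)
    n = int(round((1 + np.sqrt(1 + 8 * len(condensed))) / 2))
    if n < 2:
        raise ValueError("need at least two items")
    if method == "ward.D":
        Z = _lance_williams(squareform(condensed), method)
    else:
        Z = sch.linkage(condensed, method=method)
    return MergeTree(Z, method, n)


def agglomerate_points(X: np.ndarray, method: str = "ward") -> MergeTree:
    """Convenience: Euclidean distances + :func:`agglomerate`."""
    return agglomerate(pairwise_distance(X), method)


def agglomerative_coefficient(tree: MergeTree) -> float:
    """Mean over items of 1 - (first-merge height / final-merge height).

    Values near 1 indicate tight, well-separated clustering structure.
    Undefined when all points are identical (final height 0).
    """
    h_final = tree.Z[-1, 2]
    if h_final <= 0:
        raise ValueError("all points identical; agglomerative coefficient undefined")
    first = np.full(tree.n, np.nan)
    for a, b, h, _ in tree.Z:
        for leaf in (int(a), int(b)):
            if leaf < tree.n and np.isnan(first[leaf]):
                first[leaf] = h
    return float(np.mean(1.0 - first / h_final))


def cut_tree(tree: MergeTree, k: int) -> np.ndarray:
    """Flat clustering with k clusters obtained by undoing the last k-1 merges.

    Labels are 1..k in order of first appearance; severity ordering is applied
    downstream by :func:`fit_model`.
    """
    if not 1 <= k <= tree.n:
        raise ValueError(f"k must lie in [1, {tree.n}]")
    n = tree.n
    # apply the first n-k merges with a union-find; the k surviving roots
    # are the flat clusters (exactly "undo the last k-1 merges")
    parent = np.arange(n + n - 1)
    for i in range(n - k):
        a, b = int(tree.Z[i, 0]), int(tree.Z[i, 1])
        parent[a] = parent[b] = n + i

    def find(x: int) -> int:
        path = []
        while parent[x] != x:
            path.append(x)
            x = parent[x]
        for p in path:
            parent[p] = x
        return x

    seen: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        if r not in seen:
            seen[r] = len(seen) + 1
        out[i] = seen[r]
    return out


def within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared deviations from cluster centroids.

    Equals the pairwise form sum_r D_r / (2 n_r) with D_r the sum of pairwise
    squared Euclidean distances within cluster r.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    total = 0.0
    for l in np.unique(labels):
        member = X[labels == l]
        if len(member) == 0:
            raise ValueError("empty cluster")
        total += float(((member - member.mean(axis=0)) ** 2).sum())
    return total


def _log_dispersion_curve(X: np.ndarray, kmax: int, method: str) -> np.ndarray:
    tree = agglomerate_points(X, method)
    return np.array(
        [np.log(within_dispersion(X, cut_tree(tree, k))) for k in range(1, kmax + 1)]
    )


def gap_statistic(
    X: np.ndarray,
    kmax: int = 10,
    B: int = 50,
    reference: str = "uniform",
    seed: int | None = None,
    method: str = "ward",
) -> GapCurve:
    """Gap statistic of Tibshirani et al. for k = 1..kmax.

    Gap(k) = mean_b log W*_kb - log W_k with W the within-cluster dispersion;
    s(k) = sd_b(log W*_kb) * sqrt(1 + 1/B).  Reference sets are drawn uniform
    over each feature's observed range (``reference="uniform"``) or uniform in
    the principal-axes bounding box (``reference="pca"``), and are clustered
    by the same agglomeration procedure as the observed data.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if kmax >= n:
        raise ValueError("kmax must be smaller than the number of observations")
    if B < 2:
        raise ValueError("need at least 2 reference sets for a standard error")
    if reference not in ("uniform", "pca"):
        raise ValueError(f"unknown reference distribution {reference!r}")

    rng = np.random.default_rng(seed)
    obs = _log_dispersion_curve(X, kmax, method)

    if reference == "pca":
        center = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - center, full_matrices=False)
        rotated = (X - center) @ Vt.T
        lo, hi = rotated.min(axis=0), rotated.max(axis=0)
    else:
        lo, hi = X.min(axis=0), X.max(axis=0)

    ref = np.empty((B, kmax))
    for b in range(B):
        draw = rng.uniform(lo, hi, size=X.shape)
        if reference == "pca":
            draw = draw @ Vt + center
        ref[b] = _log_dispersion_curve(draw, kmax, method)

    gap = ref.mean(axis=0) - obs
    se = ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    return GapCurve(gap, se, obs, ref.mean(axis=0), B, seed)


def select_k(curve: GapCurve, rule: str = "max-se") -> int:
    """Number of clusters under the 1-SE parsimony rule.

    ``"max-se"`` (default): with k* = argmax Gap, the smallest k with
    Gap(k) >= Gap(k*) - s(k*).  ``"first-se"``: the smallest k with
    Gap(k) >= Gap(k+1) - s(k+1), the sequential variant.
    """
    gap, se = curve.gap, curve.se
    if len(gap) == 0:
        raise ValueError("empty gap curve")
    if rule == "max-se":
        k_star = int(np.argmax(gap))
        qualifying = np.flatnonzero(gap >= gap[k_star] - se[k_star])
        return int(qualifying[0]) + 1
    if rule == "first-se":
        for k in range(len(gap) - 1):
            if gap[k] >= gap[k + 1] - se[k + 1]:
                return k + 1
        return len(gap)
    raise ValueError(f"unknown selection rule {rule!r}")


def fit_model(
    X: pd.DataFrame | np.ndarray,
    k: int,
    method: str = "ward",
    orientation: dict[str, int] | None = None,
    seed: int | None = None,
) -> ClusterModel:
    """Cluster, compute centroids, and relabel clusters by severity.

    Severity = mean impairment-oriented deviation of the centroid from the
    population norm (T = 50, SD 10) over the clustering measures; label 1 is
    least severe.  Exact severity ties are broken by the depression centroid.
    """
    if isinstance(X, pd.DataFrame):
        measures = list(X.columns)
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        measures = (
            list(SYMPTOMS) if values.shape[1] == len(SYMPTOMS)
            else [f"x{i}" for i in range(values.shape[1])]
        )
    orientation = orientation or default_orientation()

    tree = agglomerate_points(values, method)
    raw = cut_tree(tree, k)
    cents = np.vstack([values[raw == l].mean(axis=0) for l in range(1, k + 1)])

    signs = np.array([orientation.get(m, 1) for m in measures], dtype=float)
    severity = (signs * (cents - 50.0) / 10.0).mean(axis=1)
    tie_break = (
        cents[:, measures.index("depression")]
        if "depression" in measures
        else cents[:, 0]
    )
    order = np.lexsort((tie_break, severity))  # ascending severity
    relabel = {old + 1: rank + 1 for rank, old in enumerate(order)}
    labels = np.array([relabel[l] for l in raw])
    centroids = pd.DataFrame(cents[order], index=range(1, k + 1), columns=measures)
    return ClusterModel(
        k=k,
        labels=labels,
        centroids=centroids,
        orientation={m: orientation.get(m, 1) for m in measures},
        linkage=method,
        seed=seed,
    )
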