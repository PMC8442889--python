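"""Nearest-centroid classification of patients against a fitted cluster model.

Assignment is the argmin of the Euclidean distance between a patient's nine
clustering-symptom T-scores and each severity-ordered cluster centroid.
Exact distance ties go to the less severe cluster (deterministic and
clinically conservative).  No rescaling happens at predict time: the model
and its inputs share the T-score metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchy import ClusterModel


@dataclass
class CentroidClassifier:
    model: ClusterModel

    @property
    def centroids(self) -> np.ndarray:
        return self.model.centroids.to_numpy(dtype=float)

    @property
    def measures(self) -> list[str]:
        return list(self.model.centroids.columns)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Severity labels for one vector or a batch of rows.

        A DataFrame is aligned to the model's measure columns; a bare array
        must already be in model column order.  Missing values are an error —
        incomplete records are excluded upstream, never imputed.
        """
        if isinstance(X, pd.DataFrame):
            missing = [m for m in self.measures if m not in X.columns]
            if missing:
                raise ValueError(f"input lacks model measures: {missing}")
            arr = X[self.measures].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
        single = arr.ndim == 1
        if single:
            arr = arr[None, :]
        if arr.shape[1] != self.centroids.shape[1]:
            raise ValueError("input dimension does not match model centroids")
        if np.isnan(arr).any():
            raise ValueError("missing symptom values; cannot classify")
        # squared distances suffice for the argmin
        d2 = ((arr[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        # ties: argmin returns the first (lowest severity) index
        labels = np.asarray(self.model.centroids.index)[np.argmin(d2, axis=1)]
        return labels[0] if single else labels


def fit(model: ClusterModel) -> CentroidClassifier:
    """Wrap a fitted cluster model; centroids are used unchanged."""
    if len(model.centroids) < 2:
        raise ValueError("need at least two centroids to classify")
    return CentroidClassifier(model)


def concordance(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of positions where two label vectors agree."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if len(a) == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(a == b))
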