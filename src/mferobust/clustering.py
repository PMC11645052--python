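"""Unsupervised evaluation: 2-means on subject MFE features.

Each subject is reduced to a 19-dimensional feature vector — the mean of
the MFE profile across scale factors, per channel — giving a 60 x 19
feature matrix at the default cohort size. k-means with k = 2 partitions
the subjects, and the partition is scored against the true HS/AD labels
with three external validity indices: V-measure (harmonic mean of
homogeneity and completeness), Adjusted Rand Index and Adjusted Mutual
Information (arithmetic-mean normalization). No feature standardization is
applied by default: the amplitude transformation already brings subjects
to a common scale, and z-scoring would mask precisely the amplitude
pathology the raw arm is meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import (adjusted_mutual_info_score, adjusted_rand_score,
                             v_measure_score)

from .cohort import Group
from .entropy import EntropyGrid

__all__ = [
    "FeatureMatrix",
    "ClusterMetrics",
    "build_feature_matrix",
    "kmeans_2",
    "cluster_metrics",
]


@dataclass
class FeatureMatrix:
    """Subjects x channels matrix of scale-averaged MFE."""

    X: np.ndarray
    labels_true: np.ndarray
    combination_id: int | None = None
    amplitude_state: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels_true = np.asarray(self.labels_true)
        if self.X.ndim != 2:
            raise ValueError("X must be subjects x channels")
        if len(self.labels_true) != self.X.shape[0]:
            raise ValueError("labels_true length must match the number of rows")


@dataclass
class ClusterMetrics:
    v_measure: float
    ari: float
    ami: float


def build_feature_matrix(grid: EntropyGrid, standardize: bool = False) -> FeatureMatrix:
    """Scale-average each subject-channel MFE profile into one feature."""
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("entropy grid contains missing/non-finite profiles")
    X = grid.values.mean(axis=2)  # subjects x channels
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    labels = np.array([1 if g == Group.AD else 0 for g in grid.groups]) \
        if grid.groups else np.zeros(X.shape[0], dtype=int)
    return FeatureMatrix(X=X, labels_true=labels,
                         combination_id=grid.combination_id,
                         amplitude_state=grid.amplitude_state.value)


def kmeans_2(fm: FeatureMatrix, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Deterministic 2-means partition (k-means++, best of ``n_init`` restarts)."""
    if np.unique(fm.X, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct feature rows")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    return km.fit_predict(fm.X)


def cluster_metrics(labels_true: np.ndarray, labels_pred: np.ndarray) -> ClusterMetrics:
    """External validity of a predicted partition against true group labels."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if len(labels_true) != len(labels_pred):
        raise ValueError("label vectors must have equal length")
    return ClusterMetrics(
        v_measure=float(v_measure_score(labels_true, labels_pred)),
        ari=float(adjusted_rand_score(labels_true, labels_pred)),
        ami=float(adjusted_mutual_info_score(labels_true, labels_pred,
                                             average_method="arithmetic")),
    )
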