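"""Mining consistent distance constraints from conformer ensembles.

Conformers are featurized as flattened upper-triangular pairwise-distance
vectors, partitioned with k-means, and each cluster's characteristic atom
pairs are ranked by the significance

    Delta_k(i, j) = | mean_k d(i, j) - mean d(i, j) |,

the absolute deviation of the cluster-mean distance from the global mean.
The top-T pairs of a cluster, with the cluster-mean distances as targets,
form a constraint set that co-occurs in real conformers of that cluster and
is therefore simultaneously satisfiable ("consistent").  A PCA variant
ranks pairs by the magnitude of their loading on each principal component
of the distance features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .constraints import Conformation, ConstraintSet, GeometricConstraint, _coords_of

__all__ = [
    "DistanceFeatureMatrix",
    "ClusterConstraintReport",
    "PCAComponentReport",
    "featurize",
    "cluster",
    "significance",
    "top_constraints",
    "pca_constraint_loadings",
    "suggest_n_clusters",
]


@dataclass
class DistanceFeatureMatrix:
    """C x m matrix of upper-triangular pairwise distances (Angstrom),
    m = n(n-1)/2, with the column -> (i, j) map in row-major order."""

    vectors: np.ndarray
    pair_index: List[tuple]
    n_atoms: int


@dataclass
class ClusterConstraintReport:
    labels: np.ndarray
    cluster_means: np.ndarray       # (K, m)
    global_mean: np.ndarray         # (m,)
    significance: np.ndarray        # (K, m), Delta_k
    cluster_stds: np.ndarray        # (K, m), within-cluster standard deviation
    pair_index: List[tuple]


@dataclass
class PCAComponentReport:
    component: int
    loadings: np.ndarray
    ranked_pairs: List[tuple]       # (pair, |loading|) descending
    representative_conformer: int
    degenerate: bool


def featurize(ensemble: Sequence) -> DistanceFeatureMatrix:
    """Flatten each conformer's pairwise distance matrix (upper triangle)."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    coords0 = _coords_of(ensemble[0])
    n = coords0.shape[0]
    pair_index = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rows = []
    for c, conf in enumerate(ensemble):
        coords = _coords_of(conf)
        if coords.shape[0] != n:
            raise ValueError(
                f"conformer {c} has {coords.shape[0]} atoms, expected {n}"
            )
        rows.append(pdist(coords))  # pdist order == row-major upper triangle
    return DistanceFeatureMatrix(np.asarray(rows), pair_index, n)


def cluster(features: DistanceFeatureMatrix, n_clusters: int, seed: int = 0
            ) -> np.ndarray:
    """k-means labels (k-means++ init, 10 restarts, fixed seed)."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > features.vectors.shape[0]:
        raise ValueError("more clusters than conformers")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(features.vectors)


def significance(features: DistanceFeatureMatrix, labels: np.ndarray
                 ) -> ClusterConstraintReport:
    """Cluster means, global mean and per-pair significance Delta_k."""
    X = features.vectors
    labels = np.asarray(labels)
    ks = np.unique(labels)
    n_clusters = int(labels.max()) + 1
    means = np.zeros((n_clusters, X.shape[1]))
    stds = np.zeros_like(means)
    for k in range(n_clusters):
        members = X[labels == k]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {k} is empty")
        means[k] = members.mean(axis=0)
        stds[k] = members.std(axis=0)
    global_mean = X.mean(axis=0)
    delta = np.abs(means - global_mean[None, :])
    return ClusterConstraintReport(labels, means, global_mean, delta, stds,
                                   features.pair_index)


def top_constraints(report: ClusterConstraintReport, top: int, cluster_id: int,
                    bounded: bool = False) -> ConstraintSet:
    """Top-``top`` distance constraints of one cluster, ordered by
    significance (ties broken lexicographically by pair).

    Targets are the cluster-mean distances; with ``bounded=True`` each
    constraint gets slack_max set to the within-cluster standard deviation
    of that pair, yielding bounded rather than strict constraints.
    """
    if not 0 <= cluster_id < report.cluster_means.shape[0]:
        raise ValueError(f"invalid cluster id {cluster_id}")
    if top > len(report.pair_index):
        raise ValueError("top exceeds the number of atom pairs")
    delta = report.significance[cluster_id]
    order = sorted(
        range(len(delta)), key=lambda c: (-delta[c], report.pair_index[c])
    )
    constraints = []
    for col in order[:top]:
        i, j = report.pair_index[col]
        slack = float(report.cluster_stds[cluster_id, col]) if bounded else 0.0
        constraints.append(
            GeometricConstraint(
                "distance", (i, j), float(report.cluster_means[cluster_id, col]),
                slack_max=slack,
            )
        )
    return ConstraintSet(constraints)


def pca_constraint_loadings(features: DistanceFeatureMatrix, n_components: int,
                            top: int) -> List[PCAComponentReport]:
    """Principal components of the mean-centered distance features.

    Per component, atom pairs are ranked by |loading| (contribution to the
    ensemble variance along that component) and the conformer with the most
    extreme score is reported as the component's representative.
    """
    X = features.vectors
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X - X.mean(axis=0))
    reports = []
    for comp in range(n_components):
        load = pca.components_[comp]
        order = sorted(
            range(load.size), key=lambda c: (-abs(load[c]), features.pair_index[c])
        )
        ranked = [(features.pair_index[c], abs(load[c])) for c in order[:top]]
        rep = int(np.argmax(np.abs(scores[:, comp])))
        degenerate = bool(pca.explained_variance_[comp] < 1e-12)
        reports.append(PCAComponentReport(comp, load, ranked, rep, degenerate))
    return reports


def suggest_n_clusters(features: DistanceFeatureMatrix, k_max: int = 8,
                       seed: int = 0) -> int:
    """Silhouette-score heuristic for the cluster count.

    A convenience helper only — the number of clusters properly corresponds
    to the number of conformational minima, which the caller usually knows.
    """
    best_k, best_s = 2, -np.inf
    for k in range(2, min(k_max, features.vectors.shape[0] - 1) + 1):
        labels = cluster(features, k, seed)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(features.vectors, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k
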