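"""Patient-patient dissimilarities, k-means / PAM clustering, silhouette.

Patients are compared in the bottleneck embedding either by Euclidean
distance or by Spearman correlation distance d = 1 - rho (range [0, 2]).
Two algorithm/metric pairings are swept over k = 3..6 — PAM on the
Spearman distance and k-means on the Euclidean embedding — and every
solution is scored by its mean silhouette width under the same
dissimilarity used for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = [
    "DEFAULT_PAIRINGS",
    "DissimilarityMatrix",
    "ClusterSolution",
    "euclidean_dissimilarity",
    "spearman_dissimilarity",
    "pam",
    "kmeans",
    "silhouette",
    "sweep",
]

#: (algorithm, metric) pairings used throughout the analysis
DEFAULT_PAIRINGS = (("pam", "spearman"), ("kmeans", "euclidean"))


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative patient dissimilarities with zero diagonal."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity diagonal must be exactly zero")
        if v.min(initial=0.0) < 0:
            raise ValueError("dissimilarities must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterSolution:
    """Labels and quality scores of one (algorithm, metric, k) run."""

    labels: np.ndarray
    k: int
    algorithm: str
    metric: str
    cost: float  # PAM total dissimilarity to medoids, or k-means inertia
    medoids: np.ndarray | None = None  # sample indices (PAM)
    centroids: np.ndarray | None = None  # latent coordinates (k-means)
    silhouette_values: np.ndarray | None = None
    mean_silhouette: float | None = None
    variant: str | None = None  # filled by the pipeline

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(np.unique(self.labels)) != self.k:
            raise ValueError(f"expected exactly {self.k} non-empty clusters")


def euclidean_dissimilarity(embedding: np.ndarray) -> DissimilarityMatrix:
    emb = np.asarray(embedding, dtype=float)
    return DissimilarityMatrix(squareform(pdist(emb)), metric="euclidean")


def spearman_dissimilarity(embedding: np.ndarray) -> DissimilarityMatrix:
    """d(i, j) = 1 - Spearman rank correlation of the two patients' latent
    vectors (average ranks on ties); range [0, 2]."""
    emb = np.asarray(embedding, dtype=float)
    if emb.ndim != 2 or emb.shape[1] < 2:
        raise ValueError("Spearman distance needs >= 2 latent dimensions")
    flat = np.flatnonzero(np.ptp(emb, axis=1) == 0)
    if flat.size:
        raise ValueError(
            f"constant latent vector for sample index {int(flat[0])}: "
            "Spearman ranks are undefined"
        )
    ranks = rankdata(emb, axis=1)
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    d = (d + d.T) / 2.0
    np.clip(d, 0.0, 2.0, out=d)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, metric="spearman")


# ---------------------------------------------------------------------------
# PAM (BUILD + SWAP)
# ---------------------------------------------------------------------------

def pam(d: DissimilarityMatrix, k: int) -> ClusterSolution:
    """Classic Partitioning Around Medoids on a precomputed dissimilarity.

    BUILD seeds the k medoids greedily; SWAP exchanges (medoid, non-medoid)
    pairs while any exchange strictly lowers the total dissimilarity of
    samples to their nearest medoid. Fully deterministic (ties resolve to
    the lowest index); the k=1 edge case returns the column-sum-minimising
    medoid directly.
    """
    dm = d.values
    n = dm.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")

    # BUILD
    medoids = [int(np.argmin(dm.sum(axis=0)))]
    nearest = dm[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - dm, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, dm[best])

    def total_cost(meds: list[int]) -> float:
        return float(dm[meds].min(axis=0).sum())

    # SWAP: accept the best strictly-improving exchange until none remains
    cost = total_cost(medoids)
    improved = True
    while improved and k < n:
        improved = False
        best_swap, best_cost = None, cost
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            for h in range(n):
                if h in med_set:
                    continue
                c = float(dm[others + [h]].min(axis=0).sum()) if others else float(
                    dm[h].sum()
                )
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            cost = best_cost
            improved = True

    medoid_arr = np.asarray(sorted(medoids))
    labels = np.argmin(dm[medoid_arr], axis=0)
    return ClusterSolution(
        labels=labels,
        k=k,
        algorithm="pam",
        metric=d.metric,
        cost=float(dm[medoid_arr].min(axis=0).sum()),
        medoids=medoid_arr,
    )


def kmeans(embedding: np.ndarray, k: int, seed: int = 0, n_init: int = 10
           ) -> ClusterSolution:
    """Seeded k-means (k-means++ init, best of ``n_init`` restarts)."""
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(emb)
    return ClusterSolution(
        labels=labels,
        k=k,
        algorithm="kmeans",
        metric="euclidean",
        cost=float(km.inertia_),
        centroids=km.cluster_centers_,
    )


def silhouette(
    d: DissimilarityMatrix, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths s = (b - a)/max(a, b) on a precomputed
    dissimilarity, and their mean; singleton clusters score 0."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if uniq.size > d.n - 1 and uniq.size == d.n:
        # all-singleton convention: every width is 0 by definition
        values = np.zeros(d.n)
        return values, 0.0
    values = silhouette_samples(d.values, labels, metric="precomputed")
    return values, float(values.mean())


def sweep(
    embedding: np.ndarray,
    k_range=range(3, 7),
    pairings=DEFAULT_PAIRINGS,
    seed: int = 0,
) -> list[ClusterSolution]:
    """Cluster the embedding for every (pairing, k) and attach silhouettes.

    Silhouette is computed with the same dissimilarity used for clustering
    (Spearman distance for PAM/Spearman, Euclidean for k-means).
    """
    emb = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(emb)):
        raise ValueError("embedding contains non-finite entries")
    dmats = {}
    solutions: list[ClusterSolution] = []
    for algorithm, metric in pairings:
        if metric not in dmats:
            dmats[metric] = (
                spearman_dissimilarity(emb)
                if metric == "spearman"
                else euclidean_dissimilarity(emb)
            )
        d = dmats[metric]
        for k in k_range:
            if algorithm == "pam":
                sol = pam(d, k)
            elif algorithm == "kmeans":
                sol = kmeans(emb, k, seed=seed)
                sol.metric = metric
            else:
                raise ValueError(f"unknown algorithm {algorithm!r}")
            sol.silhouette_values, sol.mean_silhouette = silhouette(d, sol.labels)
            solutions.append(sol)
    return solutions
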