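"""Correlation distance and the composite cluster-validity criterion.

The criterion multiplicatively combines the WB-index (within/between distance
ratio) with the reciprocal of the Calinski-Harabasz ratio:

    QC_int = K (K - 1) QC_W^2 / ((N - K) QC_B^2)

where QC_W is the mean correlation distance from objects to the centers of
their clusters and QC_B the mean pairwise distance between cluster centers.
Smaller values indicate a better partition: compact clusters (small QC_W)
with well-separated centers (large QC_B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Partition",
    "QcBreakdown",
    "correlation_distance",
    "cluster_centers",
    "qc_w",
    "qc_b",
    "qc_int",
    "sample_space_score",
]


@dataclass
class Partition:
    """Assignment of N objects to K non-empty clusters labelled 0..K-1."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1 or self.assignment.size == 0:
            raise ValueError("assignment must be a non-empty 1-D integer array")
        labels = np.unique(self.assignment)
        if not np.array_equal(labels, np.arange(labels.size)):
            # relabel to contiguous 0..K-1 preserving order of first appearance
            remap = {lab: i for i, lab in enumerate(labels)}
            self.assignment = np.array([remap[a] for a in self.assignment])

    @property
    def n_objects(self) -> int:
        return self.assignment.size

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_clusters)


@dataclass
class QcBreakdown:
    """Audit trail of one criterion evaluation."""

    qc_w: float
    qc_b: float
    qc_int: float
    centers: np.ndarray


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation distance d = 1 - r(x, y), in [0, 2].

    A constant vector has undefined correlation; by convention its distance to
    anything is 1 (neutral), with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("correlation distance needs 1-D vectors of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        warnings.warn("constant vector in correlation distance; using d = 1")
        return 1.0
    r = float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))
    return 1.0 - r


def _pairwise_to_centers(X: np.ndarray, centers: np.ndarray,
                         assignment: np.ndarray) -> np.ndarray:
    """d(x_i, C_{a(i)}) for every object, vectorised over rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = centers - centers.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    cn = np.linalg.norm(Cc, axis=1)
    C_per_obj = Cc[assignment]
    cn_per_obj = cn[assignment]
    num = np.einsum("ij,ij->i", Xc, C_per_obj)
    denom = xn * cn_per_obj
    d = np.ones(X.shape[0])
    ok = denom > 0
    if not ok.all():
        warnings.warn("constant vector in correlation distance; using d = 1")
    r = np.clip(num[ok] / denom[ok], -1.0, 1.0)
    d[ok] = 1.0 - r
    return d


def cluster_centers(X: np.ndarray, partition: Partition) -> np.ndarray:
    """Component-wise mean profile of each cluster, shape (K, n_features)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != partition.n_objects:
        raise ValueError("matrix rows must match partition size")
    K = partition.n_clusters
    centers = np.empty((K, X.shape[1]))
    for k in range(K):
        members = partition.assignment == k
        if not members.any():
            raise ValueError(f"cluster {k} is empty")
        centers[k] = X[members].mean(axis=0)
    return centers


def qc_w(X: np.ndarray, partition: Partition,
         centers: np.ndarray | None = None) -> float:
    """Mean correlation distance from each object to its cluster center."""
    X = np.asarray(X, dtype=float)
    if centers is None:
        centers = cluster_centers(X, partition)
    d = _pairwise_to_centers(X, centers, partition.assignment)
    return float(d.mean())


def qc_b(centers: np.ndarray) -> float:
    """Mean pairwise correlation distance between cluster centers."""
    centers = np.asarray(centers, dtype=float)
    K = centers.shape[0]
    if K < 2:
        raise ValueError("between-center distance needs at least 2 clusters")
    total = 0.0
    for i in range(K - 1):
        for j in range(i + 1, K):
            total += correlation_distance(centers[i], centers[j])
    return 2.0 * total / (K * (K - 1))


def qc_int(X: np.ndarray, partition: Partition) -> QcBreakdown:
    """Composite criterion K(K-1) QC_W^2 / ((N-K) QC_B^2); lower is better."""
    X = np.asarray(X, dtype=float)
    N = partition.n_objects
    K = partition.n_clusters
    if K < 2:
        raise ValueError("criterion needs at least 2 clusters")
    if N <= K:
        raise ValueError(f"criterion needs more objects ({N}) than clusters ({K})")
    centers = cluster_centers(X, partition)
    w = qc_w(X, partition, centers)
    b = qc_b(centers)
    if b == 0.0:
        warnings.warn("coincident cluster centers: criterion is infinite")
        value = float("inf")
    else:
        value = K * (K - 1) * w * w / ((N - K) * b * b)
    return QcBreakdown(qc_w=w, qc_b=b, qc_int=value, centers=centers)


def sample_space_score(dataset, labels, gene_subset: np.ndarray) -> QcBreakdown:
    """Score how well a gene subset separates the two known sample classes.

    The objects are the samples restricted to ``gene_subset`` columns and the
    partition is the known class labels (K = 2); returns the full breakdown.
    """
    gene_subset = np.asarray(gene_subset)
    if gene_subset.dtype == bool:
        gene_subset = np.flatnonzero(gene_subset)
    if gene_subset.size < 3:
        raise ValueError(
            f"gene subset too small for correlation distance: {gene_subset.size} < 3"
        )
    X = dataset.values[:, gene_subset]
    y = labels.vector(dataset.sample_ids)
    if len(np.unique(y)) < 2:
        raise ValueError("both sample classes required")
    return qc_int(X, Partition(y))
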