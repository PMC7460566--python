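"""Self-Organizing Tree (SOTA) clustering of gene-expression profiles.

Each division step trains a two-cell competitive layer: two daughter
prototypes seeded from the parent centroid compete for the profiles under the
correlation distance, the winner moving toward each presented profile.  The
tree is grown level by level — at level L every leaf large enough to split is
divided — so level L holds at most 2^L clusters, and each deeper cluster is
nested inside exactly one cluster of the previous level.  There is no
randomness anywhere: presentation order is the input order and the daughter
seeds are deterministic perturbations of the parent centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .quality import sample_space_score

__all__ = [
    "SotaParams",
    "SotaTree",
    "LevelSelection",
    "sota_two_cell",
    "grow_levels",
    "select_per_level",
    "SotaHierarchy",
]


@dataclass
class SotaParams:
    """Training constants for one two-cell division step.

    lr_winner moves the winning cell toward the presented profile; lr_sister
    nudges the losing sibling; lr_mother is retained for deeper-tree SOTA
    variants where the parent also updates (a no-op in a pure two-cell split).
    """

    lr_winner: float = 0.1
    lr_mother: float = 0.05
    lr_sister: float = 0.01
    max_epochs: int = 100
    tol: float = 1e-6
    min_split_size: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.lr_sister < self.lr_mother < self.lr_winner < 1):
            raise ValueError("learning rates must satisfy 0 < sister < mother < winner < 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.min_split_size < 2:
            raise ValueError("min_split_size must be >= 2")


@dataclass
class SotaTree:
    """Nested per-level partitions of the profiles.

    ``levels[L]`` (L >= 1) is an int array assigning each profile to a cluster
    id contiguous in 0..K_L-1; ``prototypes[L]`` maps cluster id -> prototype.
    Level 0 is the root (single cluster).
    """

    n_objects: int
    levels: dict[int, np.ndarray] = field(default_factory=dict)
    prototypes: dict[int, dict[int, np.ndarray]] = field(default_factory=dict)

    def n_clusters(self, level: int) -> int:
        return int(self.levels[level].max()) + 1

    def members(self, level: int, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.levels[level] == cluster)

    def to_dict(self, gene_ids: list[str] | None = None) -> dict:
        """JSON-serialisable view: level -> cluster id -> member ids."""
        out: dict = {}
        for level, assign in self.levels.items():
            ids = {}
            for k in range(self.n_clusters(level)):
                idx = np.flatnonzero(assign == k)
                ids[str(k)] = (
                    [gene_ids[i] for i in idx] if gene_ids is not None
                    else idx.tolist()
                )
            out[str(level)] = ids
        return out


@dataclass
class LevelSelection:
    """Best cluster per hierarchical level under the sample-space criterion."""

    levels: list[int]
    cluster_ids: list[int | None]
    gene_counts: list[int]
    scores: list[float]

    def best_cluster(self, level: int) -> int | None:
        return self.cluster_ids[self.levels.index(level)]


def _normalise_rows(X: np.ndarray) -> np.ndarray:
    """Center and unit-scale rows so correlation distance is 1 - dot product."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0  # constant profiles: distance convention d = 1
    return Xc / norms


def _corr_dist_to_cells(profile_hat: np.ndarray, cells: np.ndarray) -> np.ndarray:
    cc = cells - cells.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(cc, axis=1)
    d = np.ones(cells.shape[0])
    ok = cn > 0
    d[ok] = 1.0 - (cc[ok] @ profile_hat) / cn[ok]
    return d


def sota_two_cell(
    profiles: np.ndarray, params: SotaParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split profiles into two clusters with a two-cell competitive layer.

    Daughter cells start at the parent centroid displaced by +/-1e-6 on
    alternating coordinates.  Per epoch the profiles are presented in input
    order; the nearer cell (correlation distance) moves toward the profile
    with ``lr_winner`` and its sister with ``lr_sister``.  Training stops when
    the relative change of the total error sum d(profile, winner) drops below
    ``tol`` or after ``max_epochs``.  Returns (assignment in {0,1}, cells).
    """
    if params is None:
        params = SotaParams()
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 profiles to split")
    if X.shape[1] < 3:
        raise ValueError("correlation distance needs at least 3 features")
    centroid = X.mean(axis=0)
    eps = 1e-6 * np.where(np.arange(X.shape[1]) % 2 == 0, 1.0, -1.0)
    cells = np.vstack([centroid + eps, centroid - eps])
    X_hat = _normalise_rows(X)
    prev_error = np.inf
    for _ in range(params.max_epochs):
        error = 0.0
        for i in range(X.shape[0]):
            d = _corr_dist_to_cells(X_hat[i], cells)
            winner = int(np.argmin(d))
            error += d[winner]
            delta = X[i] - cells
            cells[winner] += params.lr_winner * delta[winner]
            cells[1 - winner] += params.lr_sister * delta[1 - winner]
        if prev_error < np.inf:
            denom = prev_error if prev_error > 0 else 1.0
            if abs(prev_error - error) / denom < params.tol:
                break
        prev_error = error
    cc = _normalise_rows(cells)
    d_all = 1.0 - X_hat @ cc.T
    assignment = np.argmin(d_all, axis=1).astype(int)
    if len(np.unique(assignment)) < 2:
        warnings.warn("degenerate split: all profiles fell to one cell")
    return assignment, cells


def grow_levels(
    profiles: np.ndarray, max_level: int, params: SotaParams | None = None
) -> SotaTree:
    """Grow the binary hierarchy: split every eligible leaf at each level.

    Leaves smaller than ``min_split_size`` (and degenerate splits, which
    collapse back to the unsplit leaf) carry through unchanged, so the cluster
    count at level L is bounded by 2^L but need not attain it.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    if params is None:
        params = SotaParams()
    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    tree = SotaTree(n_objects=n)
    assign = np.zeros(n, dtype=int)
    protos = {0: X.mean(axis=0)}
    tree.levels[0] = assign.copy()
    tree.prototypes[0] = dict(protos)
    for level in range(1, max_level + 1):
        new_assign = np.empty(n, dtype=int)
        new_protos: dict[int, np.ndarray] = {}
        next_id = 0
        any_split = False
        for k in range(int(assign.max()) + 1):
            members = np.flatnonzero(assign == k)
            if members.size < params.min_split_size:
                new_assign[members] = next_id
                new_protos[next_id] = protos[k]
                next_id += 1
                continue
            sub_assign, cells = sota_two_cell(X[members], params)
            if len(np.unique(sub_assign)) < 2:
                new_assign[members] = next_id  # collapse degenerate split
                new_protos[next_id] = protos[k]
                next_id += 1
                continue
            any_split = True
            for side in (0, 1):
                new_assign[members[sub_assign == side]] = next_id
                new_protos[next_id] = cells[side]
                next_id += 1
        assign, protos = new_assign, new_protos
        tree.levels[level] = assign.copy()
        tree.prototypes[level] = dict(protos)
        if not any_split and level < max_level:
            warnings.warn(
                f"no leaf could split at level {level}; deeper levels repeat"
            )
    return tree


def select_per_level(
    tree: SotaTree,
    dataset,
    labels,
    size_bounds: tuple[int, float] = (10, np.inf),
) -> LevelSelection:
    """Pick the cluster with minimal sample-space criterion at every level.

    Each cluster's genes define a restricted sample matrix; the known class
    partition of the samples is scored with the composite criterion and the
    minimum within ``size_bounds`` wins (first cluster id on ties).  A level
    with no cluster inside the bounds is marked unselectable (cluster ``None``).
    """
    min_genes, max_genes = size_bounds
    levels, cluster_ids, gene_counts, scores = [], [], [], []
    for level in sorted(k for k in tree.levels if k >= 1):
        best_id, best_score, best_count = None, np.inf, 0
        for k in range(tree.n_clusters(level)):
            members = tree.members(level, k)
            if not (min_genes <= members.size <= max_genes) or members.size < 3:
                continue
            score = sample_space_score(dataset, labels, members).qc_int
            if score < best_score:
                best_id, best_score, best_count = k, score, members.size
        levels.append(level)
        cluster_ids.append(best_id)
        gene_counts.append(best_count)
        scores.append(best_score if best_id is not None else float("nan"))
    return LevelSelection(levels, cluster_ids, gene_counts, scores)


class SotaHierarchy(ClusterMixin, BaseEstimator):
    """Scikit-learn wrapper around the level-wise SOTA hierarchy.

    ``fit(X)`` clusters the rows of X (for gene profiles, pass the expression
    matrix transposed so rows are genes and columns samples).  ``labels_`` is
    the partition at the deepest level; ``tree_`` holds every level.

    Parameters
    ----------
    max_level : int, default=10
        Depth of the hierarchy; at most 2**max_level clusters.
    lr_winner, lr_mother, lr_sister : float
        Competitive-learning rates, winner > mother > sister > 0.
    max_epochs : int, default=100
    tol : float, default=1e-6
        Relative-change convergence threshold on the total training error.
    min_split_size : int, default=2
        Leaves smaller than this carry through unsplit.
    """

    def __init__(
        self,
        max_level: int = 10,
        lr_winner: float = 0.1,
        lr_mother: float = 0.05,
        lr_sister: float = 0.01,
        max_epochs: int = 100,
        tol: float = 1e-6,
        min_split_size: int = 2,
    ):
        self.max_level = max_level
        self.lr_winner = lr_winner
        self.lr_mother = lr_mother
        self.lr_sister = lr_sister
        self.max_epochs = max_epochs
        self.tol = tol
        self.min_split_size = min_split_size

    def _params(self) -> SotaParams:
        return SotaParams(
            lr_winner=self.lr_winner,
            lr_mother=self.lr_mother,
            lr_sister=self.lr_sister,
            max_epochs=self.max_epochs,
            tol=self.tol,
            min_split_size=self.min_split_size,
        )

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=2, ensure_min_features=3)
        self.tree_ = grow_levels(X, self.max_level, self._params())
        self.labels_ = self.tree_.levels[self.max_level]
        return self

    def level_labels(self, level: int) -> np.ndarray:
        check_is_fitted(self, "tree_")
        return self.tree_.levels[level]
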