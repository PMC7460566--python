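"""Boundary-scan removal of non-informative gene-expression profiles.

Three per-gene summaries drive the filter: sample variance, mean absolute
expression, and Shannon entropy of the discretised profile estimated with the
James-Stein shrinkage estimator.  Genes with low variance or low absolute
expression cannot distinguish the sample classes, and genes whose values vary
chaotically across samples have high entropy; all three boundaries are
advanced together along a shared linear grid (variance and mean upward,
entropy downward) and the step whose surviving gene set minimises the
sample-space clustering-quality criterion is fixed as the filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ExpressionDataset, SampleLabels
from .quality import Partition, qc_int

__all__ = [
    "GeneStats",
    "BoundaryGrid",
    "FilterResult",
    "gene_statistics",
    "shannon_entropy_js",
    "build_grid",
    "apply_boundaries",
    "scan_boundaries",
    "EntropyBoundaryFilter",
]


@dataclass
class GeneStats:
    """Per-gene variance, mean absolute expression and shrinkage entropy (nats)."""

    variance: np.ndarray
    mean_abs: np.ndarray
    entropy: np.ndarray


@dataclass
class BoundaryGrid:
    """Parallel boundary schedules sharing one step index."""

    v_grid: np.ndarray   # variance boundaries, non-decreasing
    m_grid: np.ndarray   # mean-absolute boundaries, non-decreasing
    h_grid: np.ndarray   # entropy boundaries, non-increasing

    def __post_init__(self) -> None:
        self.v_grid = np.asarray(self.v_grid, dtype=float)
        self.m_grid = np.asarray(self.m_grid, dtype=float)
        self.h_grid = np.asarray(self.h_grid, dtype=float)
        if not (len(self.v_grid) == len(self.m_grid) == len(self.h_grid)):
            raise ValueError("boundary grids must share one length")
        if np.any(np.diff(self.v_grid) < 0) or np.any(np.diff(self.m_grid) < 0):
            raise ValueError("variance/mean grids must be non-decreasing")
        if np.any(np.diff(self.h_grid) > 0):
            raise ValueError("entropy grid must be non-increasing")

    @property
    def n_steps(self) -> int:
        return len(self.v_grid)


@dataclass
class FilterResult:
    """Outcome of a boundary scan."""

    qc_per_step: np.ndarray
    genes_per_step: np.ndarray
    best_step: int
    kept_mask: np.ndarray
    boundaries_at_best: tuple[float, float, float]


def shannon_entropy_js(profile: np.ndarray, n_bins: int = 10) -> float:
    """Shannon entropy (nats) of a profile via the James-Stein shrinkage estimator.

    The profile is discretised into ``n_bins`` equal-width bins over its own
    [min, max] range.  Raw bin frequencies theta_hat are shrunk toward the
    uniform target 1/B with intensity

        lambda = (1 - sum theta_hat^2) / ((n - 1) sum (1/B - theta_hat)^2)

    clipped to [0, 1] (lambda = 1 when the denominator vanishes), and the
    entropy is -sum theta ln theta of the shrunk frequencies.  A constant
    profile returns 0 by convention.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    n = profile.size
    if n < 2:
        raise ValueError("entropy needs at least 2 values")
    if n_bins < 2:
        raise ValueError("entropy needs at least 2 bins")
    lo, hi = profile.min(), profile.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(profile, bins=n_bins, range=(lo, hi))
    theta_hat = counts / n
    target = 1.0 / n_bins
    denom = (n - 1) * np.sum((target - theta_hat) ** 2)
    if denom == 0.0:
        lam = 1.0
    else:
        lam = float(np.clip((1.0 - np.sum(theta_hat**2)) / denom, 0.0, 1.0))
    theta = lam * target + (1.0 - lam) * theta_hat
    nz = theta > 0
    return float(-np.sum(theta[nz] * np.log(theta[nz])))


def gene_statistics(dataset: ExpressionDataset, n_bins: int = 10) -> GeneStats:
    """Variance (n-1 denominator), mean |expression| and shrinkage entropy per gene."""
    X = dataset.values
    if X.shape[0] < 2:
        raise ValueError("gene statistics need at least 2 samples")
    variance = X.var(axis=0, ddof=1)
    mean_abs = np.abs(X).mean(axis=0)
    entropy = np.array([shannon_entropy_js(X[:, j], n_bins) for j in range(X.shape[1])])
    return GeneStats(variance=variance, mean_abs=mean_abs, entropy=entropy)


def build_grid(stats: GeneStats, n_steps: int = 50) -> BoundaryGrid:
    """Linear boundary schedules from observed min to max of each statistic.

    Variance and mean-absolute boundaries rise from their minima; the entropy
    boundary falls from its maximum, so boundaries only ever tighten along the
    shared step index.
    """
    if n_steps < 1:
        raise ValueError("need at least one grid step")

    def _lin(lo: float, hi: float) -> np.ndarray:
        if lo == hi:
            warnings.warn("degenerate statistic range; constant boundary grid")
            return np.full(n_steps, lo)
        return np.linspace(lo, hi, n_steps)

    return BoundaryGrid(
        v_grid=_lin(float(stats.variance.min()), float(stats.variance.max())),
        m_grid=_lin(float(stats.mean_abs.min()), float(stats.mean_abs.max())),
        h_grid=_lin(float(stats.entropy.max()), float(stats.entropy.min())),
    )


def apply_boundaries(
    stats: GeneStats,
    v_b: float,
    m_b: float,
    h_b: float,
    mode: str = "all_pass",
) -> np.ndarray:
    """Boolean kept-mask for one boundary triple.

    ``all_pass`` keeps a gene iff variance > v_b AND mean_abs > m_b AND
    entropy < h_b (strict).  ``all_fail_removed`` removes a gene only when it
    fails all three, i.e. keeps it if any single criterion passes; the two
    semantics differ for genes failing some but not all criteria.
    """
    passes = np.stack(
        [stats.variance > v_b, stats.mean_abs > m_b, stats.entropy < h_b]
    )
    if mode == "all_pass":
        return passes.all(axis=0)
    if mode == "all_fail_removed":
        return passes.any(axis=0)
    raise ValueError(f"unknown filter mode {mode!r}")


def scan_boundaries(
    dataset: ExpressionDataset,
    labels: SampleLabels,
    grid: BoundaryGrid,
    n_bins: int = 10,
    mode: str = "all_pass",
    stats: GeneStats | None = None,
) -> FilterResult:
    """Scan the boundary grid and fix the step minimising the quality criterion.

    At each step the surviving genes define a restricted sample x gene matrix;
    the samples, partitioned by their known class labels (K = 2), are scored
    with the composite criterion.  Steps leaving fewer than 3 genes (too few
    features for a correlation distance) are recorded as +inf rather than
    aborting.  The first step keeps every gene by construction, so its value
    is the criterion of the full data.  Ties in the minimum break toward the
    earliest step, which retains the most genes.
    """
    if stats is None:
        stats = gene_statistics(dataset, n_bins)
    y = labels.vector(dataset.sample_ids)
    if len(np.unique(y)) < 2:
        raise ValueError("both sample classes required for the scan")
    part = Partition(y)
    n_steps = grid.n_steps
    qc_per_step = np.full(n_steps, np.inf)
    genes_per_step = np.zeros(n_steps, dtype=int)
    masks = []
    for s in range(n_steps):
        if s == 0:
            mask = np.ones(dataset.n_genes, dtype=bool)
        else:
            mask = apply_boundaries(
                stats, grid.v_grid[s], grid.m_grid[s], grid.h_grid[s], mode
            )
        masks.append(mask)
        genes_per_step[s] = int(mask.sum())
        if genes_per_step[s] < 3:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            qc_per_step[s] = qc_int(dataset.values[:, mask], part).qc_int
    if not np.isfinite(qc_per_step).any():
        raise ValueError("every scan step was infeasible")
    best = int(np.argmin(qc_per_step))  # argmin takes the first minimum
    return FilterResult(
        qc_per_step=qc_per_step,
        genes_per_step=genes_per_step,
        best_step=best,
        kept_mask=masks[best],
        boundaries_at_best=(
            float(grid.v_grid[best]),
            float(grid.m_grid[best]),
            float(grid.h_grid[best]),
        ),
    )


class EntropyBoundaryFilter(SelectorMixin, BaseEstimator):
    """Feature selector running the variance/mean/entropy boundary scan.

    A scikit-learn transformer: ``fit(X, y)`` takes a samples x genes matrix
    and binary sample labels, scans the boundary grid, and exposes the kept
    genes through ``get_support``/``transform``.

    Parameters
    ----------
    n_steps : int, default=50
        Number of grid steps; all three boundaries advance together.
    n_bins : int, default=10
        Equal-width bins per profile for the entropy estimate.
    mode : {"all_pass", "all_fail_removed"}, default="all_pass"
        Keep-if-all-pass, or remove-only-if-all-fail.

    Attributes
    ----------
    stats_ : GeneStats
        Per-gene statistics computed on the training data.
    grid_ : BoundaryGrid
    result_ : FilterResult
    support_mask_ : ndarray of bool, shape (n_genes,)
    """

    def __init__(self, n_steps: int = 50, n_bins: int = 10, mode: str = "all_pass"):
        self.n_steps = n_steps
        self.n_bins = n_bins
        self.mode = mode

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=2, ensure_min_features=2)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise ValueError("labels must align with the matrix rows")
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
        gene_ids = [f"g{j}" for j in range(X.shape[1])]
        dataset = ExpressionDataset(X, sample_ids, gene_ids)
        labels = SampleLabels(dict(zip(sample_ids, (int(v) for v in y))))
        self.stats_ = gene_statistics(dataset, self.n_bins)
        self.grid_ = build_grid(self.stats_, self.n_steps)
        self.result_ = scan_boundaries(
            dataset, labels, self.grid_, self.n_bins, self.mode, stats=self.stats_
        )
        self.support_mask_ = self.result_.kept_mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def scan_table(self):
        """Per-step scan trace as a DataFrame (step, boundaries, genes, criterion)."""
        import pandas as pd

        check_is_fitted(self, "result_")
        r, g = self.result_, self.grid_
        return pd.DataFrame(
            {
                "step": np.arange(g.n_steps),
                "v_b": g.v_grid,
                "m_b": g.m_grid,
                "h_b": g.h_grid,
                "genes_kept": r.genes_per_step,
                "qc_int": r.qc_per_step,
            }
        )
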