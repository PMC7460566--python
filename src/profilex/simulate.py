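"""Seeded two-class expression simulator with planted gene structure.

Three gene regimes emulate what the extraction pipeline must separate:

* **block genes** — correlated blocks whose class means differ: gene g of
  block k in sample s is ``base_mean + class_s * delta * sign_k +
  rho * z_{k,s} + eps``, with a shared per-block latent factor z inducing the
  within-block correlation and ``sign_k`` alternating so blocks are up- or
  down-regulated in turn;
* **noise genes** — chaotic, class-independent values drawn uniformly over
  ``base_mean +/- 3 delta``; the uniform law guarantees near-maximal
  per-profile entropy;
* **low genes** — weakly expressed, low-variance genes at a tenth of the base
  mean.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionDataset, SampleLabels

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate",
    "make_hierarchical_blocks",
]


@dataclass
class SynthConfig:
    """Simulator settings (log-expression units throughout).

    Defaults: 50 samples per class, 4 blocks of 25 genes, 50 noise and 50 low
    genes, a between-class shift of 2 log-units, latent-factor loading 0.45
    and residual noise SD 0.5 around a base mean of 8 (a typical log2
    microarray intensity).  The loading puts just under half of the non-class
    residual variance in the shared module factor, i.e. within-block
    co-expression around 0.8 with per-gene class separation d' around 3 — the
    tight-module, strong-effect regime the extraction method targets.
    """

    n_samples_per_class: int = 50
    n_blocks: int = 4
    genes_per_block: int = 25
    n_noise_genes: int = 50
    n_low_genes: int = 50
    effect: float = 2.0
    within_block_rho: float = 0.45
    noise_sd: float = 0.5
    base_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_samples_per_class, self.n_blocks, self.genes_per_block,
            self.n_noise_genes, self.n_low_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.effect < 0:
            raise ValueError("effect size must be non-negative")
        if not 0 <= self.within_block_rho <= 1:
            raise ValueError("within_block_rho must lie in [0, 1]")
        if self.n_blocks * self.genes_per_block + self.n_noise_genes + self.n_low_genes == 0:
            raise ValueError("configuration generates zero genes")


@dataclass
class GroundTruth:
    """Planted gene roles and sample classes."""

    gene_roles: list[str]           # "block<k>", "noise" or "low"
    sample_classes: np.ndarray
    block_index: np.ndarray = field(default=None)  # block id per gene, -1 otherwise

    def __post_init__(self) -> None:
        if self.block_index is None:
            self.block_index = np.array(
                [int(r[5:]) if r.startswith("block") else -1 for r in self.gene_roles]
            )

    @property
    def informative_mask(self) -> np.ndarray:
        return self.block_index >= 0

    def as_frame(self, gene_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": gene_ids, "role": self.gene_roles})


def generate(config: SynthConfig | None = None) -> tuple[ExpressionDataset, SampleLabels, GroundTruth]:
    """Draw one dataset; same config (and seed) always returns the same data."""
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_samples_per_class
    classes = np.repeat([0, 1], config.n_samples_per_class)
    columns: list[np.ndarray] = []
    roles: list[str] = []

    z = rng.normal(size=(config.n_blocks, n))  # latent factor per block/sample
    for k in range(config.n_blocks):
        sign = 1.0 if k % 2 == 0 else -1.0
        shift = config.base_mean + classes * config.effect * sign
        for _ in range(config.genes_per_block):
            eps = rng.normal(scale=config.noise_sd, size=n)
            columns.append(shift + config.within_block_rho * z[k] + eps)
            roles.append(f"block{k}")
    half_width = 3.0 * config.effect
    for _ in range(config.n_noise_genes):
        columns.append(
            rng.uniform(config.base_mean - half_width, config.base_mean + half_width, size=n)
        )
        roles.append("noise")
    for _ in range(config.n_low_genes):
        columns.append(
            rng.normal(0.1 * config.base_mean, 0.1 * config.noise_sd, size=n)
        )
        roles.append("low")

    values = np.column_stack(columns)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    gene_ids = [f"G{j:04d}" for j in range(values.shape[1])]
    dataset = ExpressionDataset(values, sample_ids, gene_ids)
    labels = SampleLabels({s: int(c) for s, c in zip(sample_ids, classes)})
    truth = GroundTruth(gene_roles=roles, sample_classes=classes)
    return dataset, labels, truth


def make_hierarchical_blocks(
    depth: int = 10,
    genes_per_block: int = 2,
    n_features: int = 64,
    weight_decay: float = 0.7,
    noise_sd: float = 1e-3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Profiles forming 2**depth well-separated blocks with a binary geometry.

    Block prototypes are signed sums of ``depth`` orthogonal +/-1 Hadamard
    patterns over the feature axis with geometrically decreasing weights, so
    the blocks nest into a perfect binary tree: the heaviest pattern splits
    the set into two anti-correlated halves, the next splits each half, and
    so on.  Each block contributes ``genes_per_block`` noisy copies of its
    prototype.  Returns ``(profiles, block_labels)``.
    """
    from scipy.linalg import hadamard

    if n_features & (n_features - 1) or n_features <= depth:
        raise ValueError("n_features must be a power of 2 greater than depth")
    n_blocks = 2**depth
    # rows 1..depth of the Hadamard matrix: orthogonal, zero-sum +/-1 patterns
    patterns = hadamard(n_features)[1 : depth + 1].astype(float)
    weights = weight_decay ** np.arange(depth)
    rng = np.random.default_rng(seed)
    profiles = np.empty((n_blocks * genes_per_block, n_features))
    labels = np.repeat(np.arange(n_blocks), genes_per_block)
    for b in range(n_blocks):
        bits = np.array([1.0 if (b >> (depth - 1 - lvl)) & 1 == 0 else -1.0
                         for lvl in range(depth)])
        proto = (weights * bits) @ patterns
        rows = slice(b * genes_per_block, (b + 1) * genes_per_block)
        profiles[rows] = proto + rng.normal(scale=noise_sd, size=(genes_per_block, n_features))
    return profiles, labels
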