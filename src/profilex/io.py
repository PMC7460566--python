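"""Reading, validating and writing expression matrices and sample labels.

The in-memory convention throughout the package is samples x genes: rows are
the examined samples, columns are genes, entries are (log-scale) expression
values.  On-disk tables may be stored either way round, so the readers take an
explicit orientation flag rather than guessing from the shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SampleLabels",
    "read_expression_table",
    "read_labels",
    "write_expression_table",
    "write_gene_subset",
]


class ValidationError(ValueError):
    """Raised when a dataset or label file violates a structural invariant."""


@dataclass
class ExpressionDataset:
    """A samples x genes expression matrix with string identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression values; must be finite.
    sample_ids : list of str
        Unique identifiers for the rows.
    gene_ids : list of str
        Unique identifiers for the columns.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} matrix columns"
            )
        for kind, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValidationError(f"duplicate {kind} id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if n < 4:
            raise ValidationError(f"need at least 4 samples, got {n}")
        if m < 2:
            raise ValidationError(f"need at least 2 genes, got {m}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_mask: np.ndarray) -> "ExpressionDataset":
        """Return a new dataset restricted to the genes where ``gene_mask`` is True."""
        gene_mask = np.asarray(gene_mask, dtype=bool)
        if gene_mask.shape != (self.n_genes,):
            raise ValidationError(
                f"gene mask length {gene_mask.size} != number of genes {self.n_genes}"
            )
        if not gene_mask.any():
            raise ValidationError("gene mask selects no genes")
        kept = [g for g, keep in zip(self.gene_ids, gene_mask) if keep]
        return ExpressionDataset(self.values[:, gene_mask], list(self.sample_ids), kept)


@dataclass
class SampleLabels:
    """Binary class labels (0 = healthy, 1 = tumor) keyed by sample id."""

    mapping: dict[str, int]
    class_names: dict[int, str] = field(
        default_factory=lambda: {0: "healthy", 1: "tumor"}
    )

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - {0, 1}
        if bad:
            raise ValidationError(f"labels must be 0 or 1, got {sorted(bad)}")
        present = set(self.mapping.values())
        if present != {0, 1}:
            raise ValidationError("both classes required in the label set")

    def vector(self, sample_ids: list[str]) -> np.ndarray:
        """Class labels as an int array aligned with ``sample_ids``."""
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ValidationError(f"samples without labels: {missing}")
        return np.array([self.mapping[s] for s in sample_ids], dtype=int)

    def counts(self) -> tuple[int, int]:
        vals = list(self.mapping.values())
        return vals.count(0), vals.count(1)


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a delimited table, auto-detecting tab vs comma from the header."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def read_expression_table(
    path: str | Path, orientation: str = "genes_in_rows"
) -> ExpressionDataset:
    """Load an expression table into the samples x genes convention.

    Parameters
    ----------
    path : path
        Delimited text file (tab or comma) with one header row of ids and one
        leading id column.
    orientation : {"genes_in_rows", "samples_in_rows"}
        How the on-disk table is laid out.  GEO series-matrix-style exports
        are gene-major (``genes_in_rows``, the default).
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    try:
        body = df.astype(float)
    except ValueError:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.argmax(bad.values)]
                raise ValidationError(
                    f"non-numeric value {df.loc[row, col]!r} at row {row!r}, "
                    f"column {col!r} in {path}"
                ) from None
        raise
    if body.isna().any().any():
        row = body.index[body.isna().any(axis=1)][0]
        raise ValidationError(f"missing value in row {row!r} of {path}")
    if orientation == "genes_in_rows":
        values = body.values.T
        sample_ids, gene_ids = list(body.columns), list(body.index)
    else:
        values = body.values
        sample_ids, gene_ids = list(body.index), list(body.columns)
    return ExpressionDataset(values, sample_ids, gene_ids)


def write_expression_table(
    dataset: ExpressionDataset,
    path: str | Path,
    orientation: str = "genes_in_rows",
    sep: str = "\t",
) -> None:
    """Write a dataset back to delimited text with 6 significant digits."""
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.DataFrame(
        dataset.values, index=dataset.sample_ids, columns=dataset.gene_ids
    )
    if orientation == "genes_in_rows":
        df = df.T
    df.to_csv(path, sep=sep, float_format="%.6g")


def read_labels(
    path: str | Path,
    dataset: ExpressionDataset,
    class_alphabet: dict[str, int] | None = None,
) -> SampleLabels:
    """Load a two-column ``sample_id,class`` file covering the dataset's samples.

    ``class_alphabet`` maps the on-disk class strings to {0, 1}; the default
    accepts "healthy"/"tumor" and literal "0"/"1".
    """
    if class_alphabet is None:
        class_alphabet = {"healthy": 0, "tumor": 1, "0": 0, "1": 1}
    df = _read_delimited(path)
    if df.shape[1] != 1:
        raise ValidationError(
            f"label file must have exactly two columns, got {df.shape[1] + 1}"
        )
    raw = df.iloc[:, 0].astype(str).str.strip()
    mapping: dict[str, int] = {}
    for sample_id, cls in raw.items():
        sample_id = str(sample_id)
        if cls not in class_alphabet:
            raise ValidationError(
                f"unknown class {cls!r} for sample {sample_id!r}; "
                f"expected one of {sorted(class_alphabet)}"
            )
        mapping[sample_id] = class_alphabet[cls]
    unknown = sorted(set(mapping) - set(dataset.sample_ids))
    if unknown:
        raise ValidationError(f"labels for unknown samples: {unknown}")
    missing = sorted(set(dataset.sample_ids) - set(mapping))
    if missing:
        raise ValidationError(f"samples missing from label file: {missing}")
    present = set(mapping.values())
    if present != {0, 1}:
        raise ValidationError("both classes required in the label file")
    names = {v: k for k, v in class_alphabet.items() if k not in ("0", "1")}
    return SampleLabels({s: mapping[s] for s in dataset.sample_ids},
                        class_names=names or {0: "healthy", 1: "tumor"})


def write_gene_subset(
    dataset: ExpressionDataset,
    gene_mask: np.ndarray,
    path: str | Path,
    orientation: str = "genes_in_rows",
) -> None:
    """Write the columns selected by ``gene_mask`` (original gene order kept)."""
    write_expression_table(dataset.subset_genes(gene_mask), path, orientation)
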