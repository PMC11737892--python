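"""Cell-by-gene expression container and the standard log-normalization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionMatrix:
    """Dense cells x genes matrix with vocabularies.

    Values are expected to be non-negative (raw counts or log-normalized
    expression); gene names must be unique.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.gene_names):
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but "
                f"{len(self.gene_names)} gene names"
            )
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.values.shape[0])]
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length does not match matrix rows")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if self.values.size and self.values.min() < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], list(genes), list(self.cell_ids))


def log_normalize(
    counts: np.ndarray | ExpressionMatrix,
    scale_factor: float = 10_000.0,
    gene_names: list[str] | None = None,
    cell_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Per-cell depth normalization to ``scale_factor`` followed by log1p.

    Each entry becomes ``log(1 + scale_factor * count / total_counts_of_cell)``
    — the standard scRNA-seq convention.  All-zero cells are dropped with a
    warning (their depth is undefined).
    """
    if isinstance(counts, ExpressionMatrix):
        gene_names = counts.gene_names
        cell_ids = counts.cell_ids
        counts = counts.values
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise ValueError("all cells have zero total counts")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} all-zero cell(s)")
    counts = counts[keep]
    totals = totals[keep]
    values = np.log1p(scale_factor * counts / totals[:, None])
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(counts.shape[1])]
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(len(totals))]
    else:
        cell_ids = [c for c, k in zip(cell_ids, keep) if k]
    return ExpressionMatrix(values, list(gene_names), list(cell_ids))
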