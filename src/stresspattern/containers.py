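"""Core data containers shared across the pipeline.

The expression arm of the pipeline operates on a gene x cell sparse count
matrix with per-cell and per-gene annotation tables, mirroring the on-disk
layout (Matrix Market file plus two tab-delimited tables).  Conditions form
a closed vocabulary -- the four arms of the 2x2 early-life adversity (ELA)
by acute-stress design -- and unknown labels are rejected rather than
coerced, because silent label drift is the classic failure mode of
factorial designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: The four experimental conditions, in canonical order.
CONDITIONS: tuple[str, ...] = ("Bl Ctrl", "Bl Stress", "ELA Ctrl", "ELA Stress")

#: The four pairwise comparisons used throughout: label -> (reference, test).
COMPARISONS: dict[str, tuple[str, str]] = {
    "a": ("Bl Ctrl", "Bl Stress"),
    "b": ("Bl Ctrl", "ELA Ctrl"),
    "c": ("Bl Stress", "ELA Stress"),
    "d": ("ELA Ctrl", "ELA Stress"),
}

CELL_COLUMNS = ("sample", "condition", "group", "cluster")
GENE_COLUMNS = ("symbol", "mito")


class InputError(ValueError):
    """Raised when an input violates a container or operation contract."""


def _check_conditions(values: pd.Series) -> None:
    bad = sorted(set(values.unique()) - set(CONDITIONS))
    if bad:
        raise InputError(
            f"unknown condition label(s) {bad!r}; allowed labels are {list(CONDITIONS)!r}"
        )


@dataclass
class CountMatrix:
    """Sparse gene x cell count matrix with cell and gene annotations.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes in rows, cells in columns.
    cells
        One row per cell (index = barcode) with columns ``sample``,
        ``condition``, ``group`` and ``cluster``.
    genes
        One row per gene (index = gene id) with columns ``symbol`` and the
        boolean mitochondrial flag ``mito``.
    """

    counts: sp.spmatrix
    cells: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes:
            raise InputError(
                f"gene annotation has {len(self.genes)} rows for a "
                f"{n_genes}-gene matrix"
            )
        if len(self.cells) != n_cells:
            raise InputError(
                f"cell annotation has {len(self.cells)} rows for a "
                f"{n_cells}-cell matrix"
            )
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                raise InputError(f"cell annotation is missing column {col!r}")
        for col in GENE_COLUMNS:
            if col not in self.genes.columns:
                raise InputError(f"gene annotation is missing column {col!r}")
        _check_conditions(self.cells["condition"])
        if self.counts.nnz and self.counts.data.min() < 0:
            raise InputError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> np.ndarray:
        """Per-cell total counts (count depth)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected (count > 0) genes per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of counts in mitochondrial genes.

        Cells with zero depth get fraction 0.
        """
        mito_mask = self.genes["mito"].to_numpy(dtype=bool)
        mito_counts = np.asarray(self.counts[mito_mask, :].sum(axis=0)).ravel()
        depths = self.depths()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depths > 0, mito_counts / np.maximum(depths, 1), 0.0)
        return frac

    def subset(self, gene_mask: np.ndarray | None = None,
               cell_mask: np.ndarray | None = None) -> "CountMatrix":
        """Return a submatrix; values are never altered, only dropped."""
        counts = self.counts
        genes = self.genes
        cells = self.cells
        if gene_mask is not None:
            counts = counts[gene_mask, :]
            genes = genes.loc[gene_mask]
        if cell_mask is not None:
            counts = counts[:, cell_mask]
            cells = cells.loc[cell_mask]
        return CountMatrix(counts, cells.copy(), genes.copy())


@dataclass
class NormalizedMatrix:
    """Log-transformed size-factor-normalized expression.

    ``values[g, c] = log(counts[g, c] / size_factors[c] + 1)`` (natural log
    by default; the base is recorded in ``provenance``).  Sparsity is
    preserved because a zero count maps to zero.
    """

    values: sp.spmatrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    size_factors: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise InputError("size factors must be strictly positive")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise InputError("values shape does not match annotations")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]
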