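"""Cell and gene quality filtering, log normalization, cluster eligibility.

Filtering uses strict inequalities: a cell sitting exactly on a threshold
(1000 counts, 500 genes, mitochondrial fraction 0.2) is kept, and a gene
must be expressed in strictly fewer than ``min_cells_per_gene`` remaining
cells to be removed.  Doublet detection is deliberately not part of this
stage (it is a published algorithm run upstream of this pipeline); the
report records the stage as skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from stresspattern.containers import CountMatrix, InputError, NormalizedMatrix


@dataclass
class QCThresholds:
    min_counts: int = 1000
    max_counts: int = 30000
    min_genes: int = 500
    max_mito_fraction: float = 0.2
    min_cells_per_gene: int = 10

    def __post_init__(self) -> None:
        if self.min_counts >= self.max_counts:
            raise InputError("min_counts must be below max_counts")
        if not 0 <= self.max_mito_fraction <= 1:
            raise InputError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    n_cells_in: int = 0
    n_cells_out: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0
    removed_low_counts: int = 0
    removed_high_counts: int = 0
    removed_few_genes: int = 0
    removed_high_mito: int = 0
    removed_genes_few_cells: int = 0
    doublet_stage: str = "skipped (not part of this pipeline)"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter(matrix: CountMatrix,
              thresholds: QCThresholds | None = None,
              ) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells, then sparsely expressed genes.

    Cells are dropped when count depth < ``min_counts`` or > ``max_counts``,
    detected genes < ``min_genes``, or mitochondrial fraction >
    ``max_mito_fraction`` (all strict).  Genes expressed in fewer than
    ``min_cells_per_gene`` of the surviving cells are then removed.  Counts
    are never modified, only subset.
    """
    thresholds = thresholds or QCThresholds()
    depths = matrix.depths()
    n_genes_detected = matrix.genes_per_cell()
    mito = matrix.mito_fraction()

    low = depths < thresholds.min_counts
    high = depths > thresholds.max_counts
    few = n_genes_detected < thresholds.min_genes
    mito_bad = mito > thresholds.max_mito_fraction
    keep_cells = ~(low | high | few | mito_bad)

    report = QCReport(
        n_cells_in=matrix.n_cells,
        n_genes_in=matrix.n_genes,
        removed_low_counts=int(low.sum()),
        removed_high_counts=int(high.sum()),
        removed_few_genes=int(few.sum()),
        removed_high_mito=int(mito_bad.sum()),
    )
    if not keep_cells.any():
        raise InputError("empty after QC: every cell failed the filters")

    filtered = matrix.subset(cell_mask=keep_cells)
    cells_per_gene = np.asarray((filtered.counts > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= thresholds.min_cells_per_gene
    report.removed_genes_few_cells = int((~keep_genes).sum())
    filtered = filtered.subset(gene_mask=keep_genes)

    report.n_cells_out = filtered.n_cells
    report.n_genes_out = filtered.n_genes
    return filtered, report


def normalize_log(matrix: CountMatrix,
                  method: str = "library_size",
                  size_factors: np.ndarray | None = None,
                  ) -> NormalizedMatrix:
    """Divide counts by per-cell size factors, then log(x + 1) transform.

    ``method="library_size"`` sets each cell's factor to its depth divided
    by the median depth across cells.  ``method="external_factors"`` takes
    caller-supplied positive per-cell factors -- the injection point for
    factors computed by pooled-deconvolution tools.
    """
    if method == "library_size":
        depths = matrix.depths().astype(float)
        med = float(np.median(depths))
        if med <= 0:
            raise InputError("median depth is zero; cannot derive size factors")
        factors = depths / med
        if np.any(factors <= 0):
            raise InputError("cells with zero depth present; run QC first")
    elif method == "external_factors":
        if size_factors is None:
            raise InputError("external_factors requires size_factors")
        factors = np.asarray(size_factors, dtype=float)
        if factors.shape != (matrix.n_cells,):
            raise InputError("size_factors length must equal the number of cells")
        if np.any(factors <= 0):
            raise InputError("size factors must be strictly positive")
    else:
        raise InputError(f"unknown normalization method {method!r}")

    values = sp.csr_matrix(matrix.counts, dtype=float, copy=True)
    # scale columns by 1/factor; log1p preserves sparsity (log1p(0) = 0)
    values = values @ sp.diags(1.0 / factors)
    values.data = np.log1p(values.data)
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        cells=matrix.cells.copy(),
        genes=matrix.genes.copy(),
        size_factors=factors,
        provenance={"method": method, "log_base": "e", "pseudocount": 1},
    )


def eligible_clusters(matrix: CountMatrix | NormalizedMatrix,
                      min_total_cells: int = 300) -> list[str]:
    """Clusters with at least ``min_total_cells`` cells, sorted by label."""
    counts = matrix.cells["cluster"].value_counts()
    return sorted(counts.index[counts >= min_total_cells].tolist())
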