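import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from stresspattern import (
    CountMatrix,
    NormalizedMatrix,
    SimDesign,
    generate_counts,
    normalize_log,
    qc_filter,
    eligible_clusters,
    run_all_comparisons,
)
from stresspattern.simulate import default_patterns


def make_cell_matrix(depths, genes_detected, mito_fracs, n_genes=1000):
    """Build a count matrix realizing exact per-cell depth / detected-gene /
    mito-fraction values.  Gene 0 is the only mitochondrial gene."""
    depths = list(depths)
    n_cells = len(depths)
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    for j, (d, g, f) in enumerate(zip(depths, genes_detected, mito_fracs)):
        mito = int(round(f * d))
        bulk = d - mito - (g - 2)  # gene 1 takes the slack, genes 2..g-1 get 1
        assert bulk >= 1 and g >= 3
        counts[0, j] = mito
        counts[1, j] = bulk
        counts[2:g, j] = 1
    cells = pd.DataFrame(
        {
            "sample": ["s1"] * n_cells,
            "condition": ["Bl Ctrl"] * n_cells,
            "group": ["g1"] * n_cells,
            "cluster": ["c1"] * n_cells,
        },
        index=pd.Index([f"cell{j + 1}" for j in range(n_cells)], name="barcode"),
    )
    genes = pd.DataFrame(
        {"symbol": [f"gene{i}" for i in range(n_genes)],
         "mito": [i == 0 for i in range(n_genes)]},
        index=pd.Index([f"gene{i:04d}" for i in range(n_genes)], name="gene"),
    )
    return CountMatrix(sp.csr_matrix(counts), cells, genes)


def make_norm(values, conditions, groups=None, clusters=None, gene_ids=None):
    """NormalizedMatrix straight from a dense genes x cells value array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    groups = groups if groups is not None else ["g1"] * n_cells
    clusters = clusters if clusters is not None else ["c1"] * n_cells
    cells = pd.DataFrame(
        {"sample": groups, "condition": conditions, "group": groups,
         "cluster": clusters},
        index=pd.Index([f"cell{j}" for j in range(n_cells)], name="barcode"),
    )
    ids = gene_ids or [f"gene{i:04d}" for i in range(n_genes)]
    genes = pd.DataFrame(
        {"symbol": ids, "mito": [False] * n_genes},
        index=pd.Index(ids, name="gene"),
    )
    return NormalizedMatrix(sp.csr_matrix(values), cells, genes,
                            size_factors=np.ones(n_cells))


@pytest.fixture(scope="session")
def default_run():
    """One full analysis of the default synthetic fixture, shared read-only."""
    design = SimDesign(seed=11)
    patterns = default_patterns(design, n_per_type=4, effect_size=1.5)
    matrix, truth = generate_counts(design, patterns)
    filtered, report = qc_filter(matrix)
    norm = normalize_log(filtered)
    clusters = eligible_clusters(norm)
    results, degsets, counts = run_all_comparisons(norm, clusters)
    return {
        "design": design, "patterns": patterns, "matrix": matrix,
        "truth": truth, "filtered": filtered, "report": report,
        "norm": norm, "clusters": clusters, "results": results,
        "degsets": degsets, "counts": counts,
    }
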