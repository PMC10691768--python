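"""Disk formats: Matrix Market counts with annotation tables, CSV matrices.

A count matrix lives in a directory as ``matrix.mtx`` (gene x cell,
1-based indices as the format prescribes), ``cells.tsv`` (barcode, sample,
condition, group, cluster) and ``genes.tsv`` (gene id, symbol, mito flag).
Interaction matrices are CSV with animal ids in the header row and first
column.  Condition labels are validated strictly on read; a near-miss like
``"ELA_Stress"`` is an error naming the offending label, never coerced.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from stresspattern.containers import CountMatrix, InputError

MTX_NAME = "matrix.mtx"
CELLS_NAME = "cells.tsv"
GENES_NAME = "genes.tsv"


def write_count_matrix(matrix: CountMatrix, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    mmwrite(os.path.join(directory, MTX_NAME), sp.coo_matrix(matrix.counts))
    matrix.cells.to_csv(os.path.join(directory, CELLS_NAME), sep="\t",
                        index_label="barcode")
    matrix.genes.to_csv(os.path.join(directory, GENES_NAME), sep="\t",
                        index_label="gene")


def read_count_matrix(directory: str) -> CountMatrix:
    """Read and validate a count matrix directory.

    Raises a descriptive error on malformed files, dimension mismatches or
    unknown condition labels.
    """
    mtx_path = os.path.join(directory, MTX_NAME)
    if not os.path.exists(mtx_path):
        raise InputError(f"missing {MTX_NAME} in {directory}")
    try:
        counts = sp.csr_matrix(mmread(mtx_path))
    except Exception as exc:  # malformed header / body
        raise InputError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    cells = pd.read_csv(os.path.join(directory, CELLS_NAME), sep="\t",
                        index_col="barcode")
    genes = pd.read_csv(os.path.join(directory, GENES_NAME), sep="\t",
                        index_col="gene")
    if "mito" in genes.columns:
        genes["mito"] = genes["mito"].astype(bool)
    if counts.shape[1] != len(cells):
        raise InputError(
            f"cell annotation has {len(cells)} rows but the matrix has "
            f"{counts.shape[1]} columns")
    if counts.shape[0] != len(genes):
        raise InputError(
            f"gene annotation has {len(genes)} rows but the matrix has "
            f"{counts.shape[0]} rows")
    return CountMatrix(counts.astype(np.int64), cells, genes)


def write_interaction_matrix(m: pd.DataFrame, path: str) -> None:
    m.to_csv(path, index_label="animal")


def read_interaction_matrix(path: str) -> pd.DataFrame:
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    if list(m.index) != list(m.columns):
        raise InputError(
            f"interaction matrix {path}: row ids {list(m.index)} differ from "
            f"column ids {list(m.columns)}")
    return m
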