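"""Readers and writers for count matrices and label files.

Supported inputs: delimited text (comma or tab, autodetected) with cells in
rows or genes in rows, and MatrixMarket ``.mtx`` sparse triplets with
companion ``genes.tsv`` / ``barcodes.tsv`` lists (10x convention: genes in
rows). All matrices are held and written cells × genes.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .preprocessing import CountMatrix


def _sniff_delimiter(path: str | os.PathLike) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") >= first.count("\t") else "\t"


def read_delimited(path: str | os.PathLike,
                   cells_in_rows: bool = True) -> CountMatrix:
    """Read a dense delimited matrix with row and column identifiers."""
    df = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0)
    if not cells_in_rows:
        df = df.T
    return CountMatrix(values=df.to_numpy(dtype=float),
                       cell_ids=[str(i) for i in df.index],
                       gene_ids=[str(c) for c in df.columns])


def write_delimited(path: str | os.PathLike, values: np.ndarray,
                    cell_ids: list[str], gene_ids: list[str],
                    sep: str = "\t") -> None:
    pd.DataFrame(values, index=cell_ids, columns=gene_ids).to_csv(path, sep=sep)


def read_mtx(mtx_path: str | os.PathLike,
             genes_path: str | os.PathLike | None = None,
             barcodes_path: str | os.PathLike | None = None) -> CountMatrix:
    """Read a MatrixMarket triplet (genes × cells, 10x layout) as cells × genes.

    `genes.tsv` / `barcodes.tsv` beside the .mtx are used when paths are not
    given explicitly.
    """
    mtx_path = Path(mtx_path)
    genes_path = genes_path or mtx_path.with_name("genes.tsv")
    barcodes_path = barcodes_path or mtx_path.with_name("barcodes.tsv")
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    values = np.asarray(mat, dtype=float).T  # genes × cells -> cells × genes
    return CountMatrix(values=values, cell_ids=barcodes, gene_ids=genes)


def write_mtx(out_dir: str | os.PathLike, X: CountMatrix) -> None:
    """Write counts as matrix.mtx (genes × cells) with genes.tsv/barcodes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(X.values.T)
    scipy.io.mmwrite(out / "matrix.mtx", sparse)
    (out / "genes.tsv").write_text("\n".join(X.gene_ids) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(X.cell_ids) + "\n")


def read_labels(path: str | os.PathLike) -> np.ndarray:
    """Read a label file: one label per line, or two-column (cell_id, label)."""
    df = pd.read_csv(path, sep=_sniff_delimiter(path), header=None)
    col = df.iloc[:, -1]
    codes, _ = pd.factorize(col)
    return codes.astype(int)


def write_labels(path: str | os.PathLike, cell_ids: list[str],
                 labels: np.ndarray) -> None:
    pd.DataFrame({"cell_id": cell_ids, "cluster": labels}).to_csv(
        path, sep="\t", index=False, header=False)
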