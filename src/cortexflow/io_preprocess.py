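"""Reading, writing and preprocessing of 10x-style count matrices.

The module provides the light-weight containers used throughout the
package — :class:`CountMatrix`, :class:`NormExpr` and :class:`Embedding` —
together with the standard preprocessing chain: quality filtering,
library-size log-normalization, highly-variable-gene selection and PCA.
All downstream analyses (signature scoring, pseudobulk differential
expression, optimal-transport trajectories, GRN inference) consume these
containers.

Counts are stored sparse (CSR) but every operation accepts dense arrays
interchangeably and produces identical results.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormExpr",
    "Embedding",
    "read_10x_mtx",
    "write_10x_mtx",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "pca_embed",
    "concat_counts",
]


def _as_2d(x):
    """Return a 2-D numpy array view of a dense/sparse matrix row or result."""
    return np.asarray(x).ravel()


def _check_ids(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()[:5]
        raise ValueError(f"duplicate {what} identifiers: {dup}")
    return ids


@dataclass
class CountMatrix:
    """Cells × genes UMI count matrix with aligned identifiers.

    ``counts`` may be a scipy sparse matrix or a dense ndarray; entries must
    be non-negative integers. ``cell_ids`` and ``gene_ids`` are unique and
    matched to the matrix dimensions (case-sensitive, order-preserving).
    """

    counts: "sp.spmatrix | np.ndarray"
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self):
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells / {len(self.gene_ids)} genes"
            )
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if data.size and data.min() < 0:
            raise ValueError("negative count entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        c = self.counts
        return np.asarray(c.todense()) if sp.issparse(c) else np.asarray(c)

    def cell_totals(self) -> np.ndarray:
        return _as_2d(self.counts.sum(axis=1))

    def genes_detected(self) -> np.ndarray:
        c = self.counts
        if sp.issparse(c):
            return _as_2d((c > 0).sum(axis=1))
        return (np.asarray(c) > 0).sum(axis=1)

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = _resolve_cells(self.cell_ids, mask_or_ids)
        return CountMatrix(self.counts[idx], self.cell_ids[idx], self.gene_ids)


def _resolve_cells(cell_ids, mask_or_ids):
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        return np.where(arr)[0]
    pos = pd.Index(cell_ids).get_indexer(arr)
    if (pos < 0).any():
        missing = np.asarray(arr)[pos < 0][:5]
        raise KeyError(f"unknown cell ids: {list(missing)}")
    return pos


@dataclass
class NormExpr:
    """Log-transformed, library-size scaled expression values.

    value = log(1 + scale · count / cell_total); zeros stay zero, so sparse
    storage is preserved.
    """

    values: "sp.spmatrix | np.ndarray"
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    scale_factor: float = 1e4

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        v = self.values
        return np.asarray(v.todense()) if sp.issparse(v) else np.asarray(v)

    def subset_cells(self, mask_or_ids) -> "NormExpr":
        idx = _resolve_cells(self.cell_ids, mask_or_ids)
        return NormExpr(self.values[idx], self.cell_ids[idx], self.gene_ids,
                        self.scale_factor)

    def gene_column(self, gene_id: str) -> np.ndarray:
        j = int(np.where(self.gene_ids == gene_id)[0][0])
        col = self.values[:, j]
        return _as_2d(col.todense()) if sp.issparse(col) else _as_2d(col)


@dataclass
class Embedding:
    """Low-dimensional PCA coordinates used as transport-cost substrate."""

    coords: np.ndarray
    cell_ids: np.ndarray
    explained_variance: np.ndarray = field(default=None)

    @property
    def K(self) -> int:
        return self.coords.shape[1]

    def subset_cells(self, mask_or_ids) -> "Embedding":
        idx = _resolve_cells(self.cell_ids, mask_or_ids)
        return Embedding(self.coords[idx], self.cell_ids[idx],
                         self.explained_variance)


# ---------------------------------------------------------------------------
# 10x Matrix Market triplet directory I/O
# ---------------------------------------------------------------------------

def _find(directory, stem):
    for name in (stem, stem + ".gz"):
        p = os.path.join(directory, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")


def _open_maybe_gz(path, mode="rt"):
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_10x_mtx(directory: str) -> CountMatrix:
    """Read a 10x triplet directory (matrix.mtx + barcodes.tsv + features.tsv).

    Gzip-tolerant; cell order follows barcodes.tsv, gene order features.tsv.
    Raises ``FileNotFoundError`` for a missing member and ``ValueError`` on a
    header/identifier dimension mismatch or duplicated identifiers.
    """
    mtx_path = _find(directory, "matrix.mtx")
    bc_path = _find(directory, "barcodes.tsv")
    ft_path = _find(directory, "features.tsv")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(io.BytesIO(fh.read()))
    # 10x convention stores genes × cells; we use cells × genes.
    mat = sp.csr_matrix(mat.T) if sp.issparse(mat) else np.asarray(mat).T

    def _read_ids(path):
        try:
            return pd.read_csv(path, sep="\t", header=None)[0].astype(str).to_numpy()
        except pd.errors.EmptyDataError:
            return np.array([], dtype=object)

    barcodes = _read_ids(bc_path)
    gene_ids = _read_ids(ft_path)

    n_genes, n_cells = mat.shape[1], mat.shape[0]
    if len(barcodes) != n_cells:
        raise ValueError(
            f"matrix header declares {n_cells} cells but barcodes.tsv has "
            f"{len(barcodes)} entries")
    if len(gene_ids) != n_genes:
        raise ValueError(
            f"matrix header declares {n_genes} genes but features.tsv has "
            f"{len(gene_ids)} entries")
    if sp.issparse(mat):
        mat = mat.astype(np.int64)
    else:
        mat = mat.astype(np.int64)
    return CountMatrix(mat, barcodes, gene_ids)


def write_10x_mtx(cm: CountMatrix, directory: str) -> str:
    """Write a CountMatrix as an uncompressed 10x triplet directory.

    Round-trips bit-exactly through :func:`read_10x_mtx`.
    """
    os.makedirs(directory, exist_ok=True)
    mat = cm.counts if sp.issparse(cm.counts) else sp.csr_matrix(np.asarray(cm.counts))
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"),
                     sp.coo_matrix(mat.T.astype(np.int64)), field="integer")
    pd.Series(cm.cell_ids).to_csv(os.path.join(directory, "barcodes.tsv"),
                                  sep="\t", header=False, index=False)
    feats = pd.DataFrame({0: cm.gene_ids, 1: cm.gene_ids,
                          2: ["Gene Expression"] * cm.n_genes})
    feats.to_csv(os.path.join(directory, "features.tsv"),
                 sep="\t", header=False, index=False)
    return directory


def read_cell_meta(path: str) -> pd.DataFrame:
    """Read a per-cell metadata TSV keyed by cell id (first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cell_meta(meta: pd.DataFrame, path: str) -> str:
    meta.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def qc_filter(cm: CountMatrix, min_counts: int = 0, min_genes: int = 0) -> CountMatrix:
    """Retain cells with ≥ min_counts total UMIs and ≥ min_genes detected genes.

    The gene set is never altered. Removing every cell is a warning, not an
    error.
    """
    if min_counts < 0 or min_genes < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (cm.cell_totals() >= min_counts) & (cm.genes_detected() >= min_genes)
    if not keep.any():
        import warnings

        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return cm.subset_cells(keep)


def normalize_log(cm: CountMatrix, scale: float = 1e4) -> NormExpr:
    """Library-size scaling followed by log1p.

    value = log(1 + scale · count / cell_total). Cells with zero total counts
    are rejected; run :func:`qc_filter` first.
    """
    totals = cm.cell_totals().astype(float)
    if (totals == 0).any():
        raise ValueError(
            "cells with zero total counts present; apply qc_filter(min_counts>=1) first")
    if sp.issparse(cm.counts):
        mat = sp.csr_matrix(cm.counts, dtype=float)
        inv = scale / totals
        mat = sp.diags(inv) @ mat
        mat.data = np.log1p(mat.data)
        values = mat
    else:
        values = np.log1p(np.asarray(cm.counts, dtype=float) * (scale / totals)[:, None])
    return NormExpr(values, cm.cell_ids, cm.gene_ids, scale_factor=scale)


def gene_means(ne: NormExpr) -> np.ndarray:
    """Per-gene mean of normalized values across cells."""
    return _as_2d(ne.values.mean(axis=0))


def select_hvg(ne: NormExpr, n: int = 2000) -> list:
    """Top-n genes by dispersion (variance/mean of normalized values).

    Zero-mean genes get dispersion 0. Ties break by gene id order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > ne.n_genes:
        raise ValueError(f"n={n} exceeds the {ne.n_genes} available genes")
    mu = gene_means(ne)
    if sp.issparse(ne.values):
        sq = _as_2d(ne.values.multiply(ne.values).mean(axis=0))
    else:
        sq = np.mean(np.asarray(ne.values) ** 2, axis=0)
    var = np.maximum(sq - mu**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu > 0, var / mu, 0.0)
    order = np.lexsort((ne.gene_ids, -disp))
    return list(ne.gene_ids[order[:n]])


def pca_embed(ne: NormExpr, K: int = 30, seed: int = 0) -> Embedding:
    """Exact PCA of gene-centered normalized expression.

    Deterministic (full SVD; the seed is accepted for API symmetry with the
    randomized-solver escape hatch but does not influence the exact path).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(ne.n_cells, ne.n_genes):
        raise ValueError(f"K={K} exceeds min(cells, genes)")
    X = ne.dense()
    X = X - X.mean(axis=0, keepdims=True)
    # economy SVD: X = U S Vt; coords = U S
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| coordinate positive, for determinism
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    ev = S**2 / max(ne.n_cells - 1, 1)
    return Embedding(U[:, :K] * S[:K], ne.cell_ids, ev[:K])


def concat_counts(mats: list) -> CountMatrix:
    """Vertically concatenate CountMatrix objects sharing one gene universe."""
    first = mats[0]
    for m in mats[1:]:
        if not np.array_equal(m.gene_ids, first.gene_ids):
            raise ValueError("gene id mismatch between matrices")
    stacked = sp.vstack([sp.csr_matrix(m.counts) for m in mats])
    cells = np.concatenate([m.cell_ids for m in mats])
    return CountMatrix(stacked, cells, first.gene_ids)
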