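"""Expression-matrix loading, QC filtering and reduction to a PCA point cloud.

The scoring metrics operate on generic point clouds. For scRNA-seq input this
module provides the conventional path from a raw count matrix to such a cloud:
gene/cell QC filtering, library-size normalization to the median library size,
log1p transform, dispersion-based selection of highly variable genes (HVGs),
and PCA down to (by default) 20 components.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread
from sklearn.decomposition import PCA

from .exceptions import (
    ConsistencyError,
    DegenerateInputError,
    DegenerateOutputError,
    FormatError,
)

__all__ = [
    "PointCloud",
    "ExpressionMatrix",
    "QCConfig",
    "load_expression",
    "qc_filter",
    "normalize_and_reduce",
    "load_pointcloud",
    "save_pointcloud",
]


@dataclass
class PointCloud:
    """An n x d coordinate matrix; the universal input to all metrics.

    All entries must be finite. Most downstream operations require n >= 3.
    """

    coords: np.ndarray
    point_ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise DegenerateInputError(
                f"point cloud must be 2-dimensional (n x d), got shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise DegenerateInputError("point cloud contains non-finite coordinates")
        if self.point_ids is not None and len(self.point_ids) != self.coords.shape[0]:
            raise ConsistencyError(
                f"{len(self.point_ids)} point ids for {self.coords.shape[0]} points"
            )

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class ExpressionMatrix:
    """Cell x gene count matrix with id lists.

    Counts are stored dense in cell x gene orientation regardless of the
    on-disk orientation of the source file.
    """

    counts: np.ndarray
    cell_ids: Sequence[str]
    gene_ids: Sequence[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        n, g = self.counts.shape
        if n != len(self.cell_ids):
            raise ConsistencyError(f"{n} rows but {len(self.cell_ids)} cell ids")
        if g != len(self.gene_ids):
            raise ConsistencyError(f"{g} columns but {len(self.gene_ids)} gene ids")
        if np.any(self.counts < 0):
            raise ConsistencyError("negative entries in count matrix")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ConsistencyError("duplicate cell ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class QCConfig:
    """Quality-control and reduction parameters.

    min_cells_per_gene: a gene must be nonzero in at least this many cells.
    libsize_mad_window: cells outside median +/- window * MAD of library size
        are removed (MAD = median absolute deviation from the median).
    max_mito_fraction: cells whose mitochondrial count fraction exceeds this
        are removed; mitochondrial genes are those whose id starts with
        ``mito_prefix``.
    n_hvg: number of highly variable genes kept (by dispersion).
    n_pcs: PCA dimensionality of the output point cloud.
    """

    min_cells_per_gene: int = 3
    libsize_mad_window: float = 3.0
    max_mito_fraction: float = 0.2
    mito_prefix: str = "MT-"
    n_hvg: int = 2000
    n_pcs: int = 20

    def __post_init__(self):
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.n_hvg < self.n_pcs:
            raise ValueError("n_hvg must be >= n_pcs")


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def load_expression(path: str, format: str = "delimited") -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``format="mtx_dir"``: *path* is a directory holding a Matrix Market file
    (``*.mtx``) in the 10x gene x cell orientation plus gene and barcode
    lists; the matrix is transposed to cell x gene on load.

    ``format="delimited"``: *path* is a CSV/TSV table, first row gene ids,
    first column cell ids, already cell x gene.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        return _load_mtx_dir(path)
    if format == "delimited":
        return _load_delimited(path)
    raise ValueError(f"unknown format {format!r}")


def _find_one(directory: str, candidates: Sequence[str], what: str) -> str:
    for name in candidates:
        p = os.path.join(directory, name)
        if os.path.exists(p):
            return p
    raise FormatError(f"no {what} file found in {directory} (tried {', '.join(candidates)})")


def _read_id_list(path: str) -> list:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            # 10x gene files may have two+ columns (id, symbol); take the first
            ids.append(line.split("\t")[0].split(",")[0])
    return ids


def _load_mtx_dir(directory: str) -> ExpressionMatrix:
    mtx_path = _find_one(directory, ["matrix.mtx"], "matrix")
    if not os.path.exists(mtx_path):  # pragma: no cover - _find_one already checks
        raise FormatError(f"missing matrix.mtx in {directory}")
    try:
        mat = mmread(mtx_path)
    except ValueError as exc:
        raise FormatError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    genes = _read_id_list(_find_one(directory, ["genes.tsv", "features.tsv"], "gene list"))
    barcodes = _read_id_list(_find_one(directory, ["barcodes.tsv"], "barcode list"))
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    if dense.shape != (len(genes), len(barcodes)):
        raise ConsistencyError(
            f"matrix is {dense.shape[0]} x {dense.shape[1]} but found "
            f"{len(genes)} genes and {len(barcodes)} barcodes"
        )
    return ExpressionMatrix(counts=dense.T, cell_ids=barcodes, gene_ids=genes)


def _load_delimited(path: str) -> ExpressionMatrix:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"empty header line in {path}")
    sep = _detect_delimiter(first)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    cell_ids = [str(c) for c in df.index]
    if len(set(cell_ids)) != len(cell_ids):
        raise ConsistencyError(f"duplicate cell ids in {path}")
    return ExpressionMatrix(counts=counts, cell_ids=cell_ids, gene_ids=[str(g) for g in df.columns])


def qc_filter(x: ExpressionMatrix, cfg: QCConfig = QCConfig()) -> ExpressionMatrix:
    """Remove low-information genes and outlier cells.

    Genes nonzero in fewer than ``min_cells_per_gene`` cells are dropped.
    Cells are dropped when their library size falls outside
    median +/- ``libsize_mad_window`` * MAD, or when their mitochondrial
    count fraction exceeds ``max_mito_fraction``. Remaining order is preserved.
    """
    if x.n_cells == 0 or x.n_genes == 0:
        raise DegenerateInputError("empty expression matrix")
    counts = x.counts
    gene_keep = (counts > 0).sum(axis=0) >= cfg.min_cells_per_gene
    counts = counts[:, gene_keep]
    gene_ids = [g for g, k in zip(x.gene_ids, gene_keep) if k]

    libsize = counts.sum(axis=1)
    med = np.median(libsize)
    mad = np.median(np.abs(libsize - med))
    lo = med - cfg.libsize_mad_window * mad
    hi = med + cfg.libsize_mad_window * mad
    cell_keep = (libsize >= lo) & (libsize <= hi)

    mito_cols = [i for i, g in enumerate(gene_ids) if g.startswith(cfg.mito_prefix)]
    if mito_cols:
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = counts[:, mito_cols].sum(axis=1) / np.where(libsize > 0, libsize, 1.0)
        cell_keep &= mito_frac <= cfg.max_mito_fraction

    if not cell_keep.any():
        raise DegenerateOutputError("QC filtering removed all cells")
    counts = counts[cell_keep]
    cell_ids = [c for c, k in zip(x.cell_ids, cell_keep) if k]
    return ExpressionMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids)


def normalize_and_reduce(x: ExpressionMatrix, cfg: QCConfig = QCConfig()) -> PointCloud:
    """Library-size normalize, log1p, select HVGs and PCA-reduce.

    Each cell is scaled to the median library size, log1p-transformed, the
    top ``n_hvg`` genes by dispersion (variance/mean of the log-normalized
    values) are kept, and PCA reduces the result to
    d = min(n_pcs, n_hvg, n-1) components ordered by explained variance.
    """
    if x.n_cells < 3:
        raise DegenerateOutputError(f"only {x.n_cells} cells after QC; need >= 3")
    counts = x.counts
    libsize = counts.sum(axis=1)
    if np.any(libsize == 0):
        raise DegenerateInputError("cells with zero library size; run qc_filter first")
    target = np.median(libsize)
    norm = counts * (target / libsize)[:, None]
    logn = np.log1p(norm)

    mean = logn.mean(axis=0)
    var = logn.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    n_hvg = min(cfg.n_hvg, x.n_genes)
    # stable top-n: sort by (-dispersion, index) so ties keep gene order
    hvg_idx = np.lexsort((np.arange(len(dispersion)), -dispersion))[:n_hvg]
    hvg_idx.sort()
    hv = logn[:, hvg_idx]

    d = min(cfg.n_pcs, n_hvg, x.n_cells - 1)
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(hv)
    return PointCloud(coords=coords, point_ids=list(x.cell_ids))


def load_pointcloud(path: str) -> PointCloud:
    """Read a point cloud from a headerless delimited numeric table."""
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"empty file {path}")
    sep = _detect_delimiter(first)
    try:
        coords = np.loadtxt(path, delimiter=sep, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse {path} as a numeric table: {exc}") from exc
    return PointCloud(coords=coords)


def save_pointcloud(pc: PointCloud, path: str, sep: str = ",") -> None:
    np.savetxt(path, pc.coords, delimiter=sep, fmt="%.10g")
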