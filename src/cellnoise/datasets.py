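"""Expression data container, file I/O, and the standard preprocessing chain.

Everything downstream (membership scoring, distance-to-centroid noise,
GCL, composition analysis) consumes an :class:`ExpressionDataset` holding a
cells x genes raw count matrix, an optional normalized/log layer, per-cell
metadata, and a boolean mask flagging ERCC spike-in genes.

Preprocessing follows the standard single-cell chain: depth normalization +
log1p, highly-variable-gene selection by mean-binned dispersion, PCA, and a
shared-nearest-neighbor (SNN) graph with Jaccard edge weights.  All steps
are deterministic given the same input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "Embedding",
    "NeighborGraph",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_dense_table",
    "read_h5ad",
    "write_h5ad",
    "flag_ercc",
    "normalize_log1p",
    "select_hvg",
    "compute_pca",
    "build_neighbor_graph",
]


@dataclass
class ExpressionDataset:
    """Cells x genes count matrix with metadata and optional normalized layer.

    Parameters
    ----------
    counts
        Non-negative raw counts, shape ``(n_cells, n_genes)``, dense float array.
    cell_ids, gene_ids
        Unique string identifiers for rows / columns.
    cell_meta
        Per-cell metadata indexed by ``cell_ids`` (columns such as
        ``cell_type``, ``individual``, ``age_group``).
    ercc_mask
        Boolean per gene; True marks ERCC spike-in controls.
    norm_layer
        Normalized + log-transformed values, same shape as ``counts``, or None.
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    ercc_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    norm_layer: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes matrix")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells / {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative entries")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite entries")
        if self.ercc_mask is None:
            self.ercc_mask = np.zeros(n_genes, dtype=bool)
        self.ercc_mask = np.asarray(self.ercc_mask, dtype=bool)
        if len(self.ercc_mask) != n_genes:
            raise ValueError("ercc_mask length does not match number of genes")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.loc[list(self.cell_ids)].copy()
            self.cell_meta.index = pd.Index(self.cell_ids, name="cell_id")
        if self.norm_layer is not None:
            self.norm_layer = np.asarray(self.norm_layer, dtype=float)
            if self.norm_layer.shape != self.counts.shape:
                raise ValueError("norm_layer shape does not match counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "ExpressionDataset":
        """Row-subset (positional indices); metadata sliced consistently."""
        idx = np.asarray(idx)
        return ExpressionDataset(
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.iloc[idx],
            ercc_mask=self.ercc_mask,
            norm_layer=None if self.norm_layer is None else self.norm_layer[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[idx],
            cell_meta=self.cell_meta,
            ercc_mask=self.ercc_mask[idx],
            norm_layer=None if self.norm_layer is None else self.norm_layer[:, idx],
        )

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame({"ercc": self.ercc_mask}, index=pd.Index(self.gene_ids, name="gene_id")),
        )
        if self.norm_layer is not None:
            adata.layers["lognorm"] = self.norm_layer.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "ExpressionDataset":
        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        ercc = (
            np.asarray(adata.var["ercc"], dtype=bool)
            if "ercc" in adata.var.columns
            else np.zeros(adata.n_vars, dtype=bool)
        )
        norm = None
        if "lognorm" in adata.layers:
            norm = adata.layers["lognorm"]
            if sp.issparse(norm):
                norm = norm.toarray()
        return cls(
            counts=np.asarray(X, dtype=float),
            cell_ids=np.asarray(adata.obs_names, dtype=object),
            gene_ids=np.asarray(adata.var_names, dtype=object),
            cell_meta=adata.obs.copy(),
            ercc_mask=ercc,
            norm_layer=norm,
        )


@dataclass
class Embedding:
    """PCA scores aligned 1:1 with dataset cells."""

    coords: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_comps(self) -> int:
        return self.coords.shape[1]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValueError("explained_variance must be non-increasing")


@dataclass
class NeighborGraph:
    """Undirected SNN graph over cells with Jaccard edge weights."""

    adjacency: sp.csr_matrix
    k_neighbors: int

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency)

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def total_edge_weight(self) -> float:
        """m: half the sum of all directed weights."""
        return float(self.adjacency.sum()) / 2.0


# ---------------------------------------------------------------------------
# I/O


def _read_id_column(path: Path) -> np.ndarray:
    tab = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if tab.shape[1] < 1 or tab.shape[0] == 0:
        raise ValueError(f"{path}: expected at least one column of ids")
    return tab.iloc[:, 0].to_numpy(dtype=object)


def read_mtx_bundle(
    matrix_path,
    genes_path,
    barcodes_path,
    meta_path=None,
    cells_in: Optional[str] = None,
) -> ExpressionDataset:
    """Read a MatrixMarket triplet bundle (matrix.mtx + genes.tsv + barcodes.tsv).

    Orientation is inferred: if the number of matrix columns equals the number
    of barcodes, columns are cells (the common genes x cells layout is
    transposed).  A square matrix is ambiguous and requires ``cells_in``
    ("rows" or "columns").
    """
    mat = scipy.io.mmread(str(matrix_path))
    mat = np.asarray(sp.coo_matrix(mat).todense(), dtype=float)
    genes = _read_id_column(Path(genes_path))
    barcodes = _read_id_column(Path(barcodes_path))
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    nr, nc = mat.shape
    if nr == nc:
        if cells_in not in ("rows", "columns"):
            raise ValueError("square matrix: orientation ambiguous, pass cells_in='rows' or 'columns'")
        if cells_in == "columns":
            mat = mat.T
    elif nc == len(barcodes) and nr == len(genes):
        mat = mat.T  # genes x cells on disk
    elif nr == len(barcodes) and nc == len(genes):
        pass
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither ({len(barcodes)} barcodes, "
            f"{len(genes)} genes) orientation"
        )
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep=None, engine="python", index_col=0)
        missing = set(barcodes) - set(meta.index.astype(str))
        if missing:
            raise ValueError(f"barcodes missing from metadata: {sorted(missing)[:5]}")
        meta = meta.loc[list(barcodes)]
    return ExpressionDataset(counts=mat, cell_ids=barcodes, gene_ids=genes, cell_meta=meta)


def write_mtx_bundle(ds: ExpressionDataset, matrix_path, genes_path, barcodes_path) -> None:
    """Write counts as integer MatrixMarket (genes x cells, the common layout)."""
    mat = sp.coo_matrix(ds.counts.T)
    scipy.io.mmwrite(str(matrix_path), mat, field="integer" if np.allclose(ds.counts, np.round(ds.counts)) else "real")
    pd.Series(ds.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(ds.cell_ids).to_csv(barcodes_path, sep="\t", header=False, index=False)


def read_dense_table(path, cells_in: str = "rows", sep: Optional[str] = None) -> ExpressionDataset:
    """Read a delimited numeric table with an ID header row and index column."""
    tab = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=0)
    if tab.shape[0] == 0 or tab.shape[1] == 0:
        raise ValueError("empty table")
    body = tab.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        raise ValueError("non-numeric body cells")
    if np.isnan(body).any():
        raise ValueError("table contains NaN body cells")
    if cells_in == "columns":
        tab = tab.T
    elif cells_in != "rows":
        raise ValueError("cells_in must be 'rows' or 'columns'")
    return ExpressionDataset(
        counts=tab.to_numpy(dtype=float),
        cell_ids=tab.index.to_numpy(dtype=object),
        gene_ids=tab.columns.to_numpy(dtype=object),
    )


def read_h5ad(path) -> ExpressionDataset:
    import anndata as ad

    return ExpressionDataset.from_anndata(ad.read_h5ad(path))


def write_h5ad(ds: ExpressionDataset, path) -> None:
    ds.to_anndata().write_h5ad(path)


# ---------------------------------------------------------------------------
# Preprocessing


def flag_ercc(ds: ExpressionDataset, prefix: str = "ERCC-") -> ExpressionDataset:
    """Flag spike-in genes whose id starts with ``prefix`` (case-sensitive)."""
    mask = np.array([str(g).startswith(prefix) for g in ds.gene_ids], dtype=bool)
    return replace(ds, ercc_mask=mask)


def normalize_log1p(ds: ExpressionDataset, target_sum: float = 1e4) -> ExpressionDataset:
    """Depth-normalize each cell to ``target_sum`` total counts, then ln(1+x)."""
    totals = ds.counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if len(zero):
        raise ValueError(f"cells with zero total counts: {list(ds.cell_ids[zero[:5]])}")
    norm = np.log1p(ds.counts * (target_sum / totals)[:, None])
    return replace(ds, norm_layer=norm)


def select_hvg(ds: ExpressionDataset, n_top: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Select highly variable genes by mean-binned normalized dispersion.

    Genes are binned into ``n_bins`` equal-frequency bins of mean normalized
    expression; within each bin the dispersion (variance/mean) is z-scored and
    genes are ranked globally by that normalized dispersion.  ERCC spike-ins
    are never selected.  Returns a boolean gene mask with exactly ``n_top``
    True entries.
    """
    if ds.norm_layer is None:
        raise ValueError("norm_layer absent: run normalize_log1p first")
    candidates = np.where(~ds.ercc_mask)[0]
    if n_top > len(candidates):
        raise ValueError(f"n_top={n_top} exceeds {len(candidates)} available (non-ERCC) genes")
    X = ds.norm_layer[:, candidates]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # equal-frequency mean bins, keeping >=10 genes per bin so the within-bin
    # z-score is meaningful on small gene sets
    n_cand = len(candidates)
    n_bins = max(1, min(n_bins, n_cand // 10))
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(n_cand, dtype=int)
    bin_of[order] = np.minimum((np.arange(n_cand) * n_bins) // max(n_cand, 1), n_bins - 1)
    zdisp = np.empty_like(disp)
    for b in range(n_bins):
        in_b = bin_of == b
        if not in_b.any():
            continue
        mu, sd = disp[in_b].mean(), disp[in_b].std(ddof=0)
        zdisp[in_b] = (disp[in_b] - mu) / sd if sd > 0 else 0.0
    top = np.argsort(-zdisp, kind="stable")[:n_top]
    mask = np.zeros(ds.n_genes, dtype=bool)
    mask[candidates[top]] = True
    return mask


def compute_pca(
    ds: ExpressionDataset,
    n_comps: int = 50,
    gene_mask: Optional[np.ndarray] = None,
) -> Embedding:
    """PCA scores of per-gene-centered normalized data.

    Deterministic: full SVD with the sign of each component fixed so that its
    largest-magnitude gene loading is positive.  ERCC genes are always
    excluded.
    """
    if ds.norm_layer is None:
        raise ValueError("norm_layer absent: run normalize_log1p first")
    if gene_mask is None:
        gene_mask = ~ds.ercc_mask
    else:
        gene_mask = np.asarray(gene_mask, dtype=bool) & ~ds.ercc_mask
    X = ds.norm_layer[:, gene_mask]
    n, p = X.shape
    if n_comps > min(n, p):
        raise ValueError(f"n_comps={n_comps} exceeds min(cells, genes)={min(n, p)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_comps], s[:n_comps], Vt[:n_comps]
    # sign convention: largest-|loading| positive per component
    flip = np.sign(Vt[np.arange(n_comps), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    coords = U * s * flip
    expl = s**2 / max(n - 1, 1)
    return Embedding(coords=coords, explained_variance=expl)


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors per point (self excluded), ties broken by index."""
    n = coords.shape[0]
    out = np.empty((n, k), dtype=np.int64)
    chunk = max(1, int(2**25 // max(n, 1)))
    sq = (coords**2).sum(axis=1)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[None, :] - 2.0 * coords[start:stop] @ coords.T + sq[start:stop, None]
        np.maximum(d2, 0.0, out=d2)
        for i in range(start, stop):
            row = d2[i - start]
            row[i] = -np.inf  # self sorts first, then dropped
            order = np.argsort(row, kind="stable")
            out[i] = order[1 : k + 1]
    return out


def build_neighbor_graph(emb: Embedding, k: int = 15, prune: float = 1.0 / 15.0) -> NeighborGraph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Support is the union of k-NN relations (edge i-j if j is among i's k
    nearest in the embedding, or vice versa); each edge is weighted by the
    Jaccard overlap of the two k-NN sets, and weights below ``prune`` are
    dropped.  The graph is symmetric and self-loop-free.
    """
    n = emb.coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    knn = _knn_indices(emb.coords, k)
    sets = [set(row) for row in knn]
    rows, cols, vals = [], [], []
    pairs = set()
    for i in range(n):
        for j in knn[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            pairs.add((a, b))
    for a, b in pairs:
        inter = len(sets[a] & sets[b])
        union = len(sets[a] | sets[b])
        w = inter / union if union else 0.0
        if w >= prune and w > 0:
            rows += [a, b]
            cols += [b, a]
            vals += [w, w]
    adj = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return NeighborGraph(adjacency=adj, k_neighbors=k)


def preprocess(
    ds: ExpressionDataset,
    n_top: int = 2000,
    n_comps: int = 50,
    k: int = 15,
    target_sum: float = 1e4,
) -> tuple[ExpressionDataset, Embedding, NeighborGraph]:
    """Standard chain: normalize -> HVG -> PCA -> SNN graph.

    Sizes are clipped to the dataset where necessary (n_top to the number of
    non-ERCC genes, n_comps to min(cells, selected genes)).
    """
    if ds.norm_layer is None:
        ds = normalize_log1p(ds, target_sum=target_sum)
    n_avail = int((~ds.ercc_mask).sum())
    mask = select_hvg(ds, n_top=min(n_top, n_avail))
    n_comps = min(n_comps, ds.n_cells - 1, int(mask.sum()))
    emb = compute_pca(ds, n_comps=n_comps, gene_mask=mask)
    graph = build_neighbor_graph(emb, k=min(k, ds.n_cells - 1))
    return ds, emb, graph
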