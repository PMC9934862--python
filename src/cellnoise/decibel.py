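"""Distance-based transcriptional-noise estimators.

Three per-cell estimators, each measuring how far a cell's expression
profile sits from a reference mean:

* ``ercc_noise`` — biological variation (distance of the whole-transcriptome
  profile to the cell-type/individual mean) divided by technical variation
  (the same distance computed on ERCC spike-in controls only).  Requires
  spike-ins in the experiment.
* ``euclid_dtc`` — Euclidean distance of each cell to its
  (cell_type, individual) mean expression vector.
* ``invariant_dtc`` — Euclidean distance of each cell to the tissue mean
  (average across cell-type centroids), restricted to a pre-selected set of
  expression-invariant genes.

All distances operate on the normalized/log layer; ERCC genes are excluded
from transcriptome distances and used exclusively by the technical term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

__all__ = [
    "NoiseScores",
    "InvariantGeneSet",
    "centroid_expression",
    "ercc_noise",
    "euclid_dtc",
    "select_invariant_genes",
    "invariant_dtc",
]

GroupKey = Tuple[str, str]


@dataclass
class NoiseScores:
    """Per-cell noise values for one estimator.

    ``values`` is indexed by cell id; cells in groups below the minimum group
    size (or with undefined scores) are NaN.  For the ERCC estimator the
    per-cell Pearson correlation with the centroid is kept in ``pearson_rho``.
    """

    method: str
    values: pd.Series
    pearson_rho: Optional[pd.Series] = None
    flags: dict = field(default_factory=dict)


@dataclass
class InvariantGeneSet:
    """Genes with extreme-CV rank inside mean-expression bins."""

    gene_ids: np.ndarray
    n_bins: int
    bin_assignments: pd.Series  # per candidate gene
    cv_per_gene: pd.Series


def _require_labels(ds: ExpressionDataset, cols=("cell_type", "individual")) -> None:
    for c in cols:
        if c not in ds.cell_meta.columns:
            raise ValueError(f"cell_meta is missing required column '{c}'")
        if ds.cell_meta[c].isna().any():
            raise ValueError(f"cell_meta column '{c}' has missing labels")


def _groups(ds: ExpressionDataset) -> Dict[GroupKey, np.ndarray]:
    keys = list(zip(ds.cell_meta["cell_type"], ds.cell_meta["individual"]))
    out: Dict[GroupKey, list] = {}
    for i, k in enumerate(keys):
        out.setdefault(k, []).append(i)
    return {k: np.asarray(v) for k, v in out.items()}


def centroid_expression(
    ds: ExpressionDataset, min_cells: int = 10
) -> Tuple[Dict[GroupKey, np.ndarray], Dict[GroupKey, bool]]:
    """Mean normalized expression per (cell_type, individual) group.

    Returns the centroid map (over all genes, ERCC included) and a flag map
    marking groups smaller than ``min_cells``; flagged groups are excluded
    from downstream scoring.
    """
    if ds.norm_layer is None:
        raise ValueError("norm_layer absent: run normalize_log1p first")
    _require_labels(ds)
    groups = _groups(ds)
    centroids = {k: ds.norm_layer[idx].mean(axis=0) for k, idx in groups.items()}
    small = {k: len(idx) < min_cells for k, idx in groups.items()}
    return centroids, small


def _pearson_to_centroid(X: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of X with a fixed vector (NaN if degenerate)."""
    xc = X - X.mean(axis=1, keepdims=True)
    cc = centroid - centroid.mean()
    num = xc @ cc
    den = np.sqrt((xc**2).sum(axis=1) * (cc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(den > 0, num / den, np.nan)
    return rho


def ercc_noise(
    ds: ExpressionDataset,
    metric: str = "correlation",
    min_cells: int = 10,
) -> NoiseScores:
    """Biological over technical variation using ERCC spike-ins.

    Per cell: ``biological = 1 - rho(cell, centroid)`` over non-ERCC genes and
    ``technical`` the same quantity over ERCC genes only; the score is their
    ratio.  ``metric="euclidean"`` switches both terms to Euclidean distance.
    Cells whose technical term is zero (or with a degenerate correlation) get
    a NaN score and a warning.
    """
    if metric not in ("correlation", "euclidean"):
        raise ValueError("metric must be 'correlation' or 'euclidean'")
    n_ercc = int(ds.ercc_mask.sum())
    if n_ercc < 2:
        raise ValueError(f"need >=2 ERCC spike-in genes, found {n_ercc}")
    centroids, small = centroid_expression(ds, min_cells=min_cells)
    bio_idx = ~ds.ercc_mask
    tech_idx = ds.ercc_mask
    values = np.full(ds.n_cells, np.nan)
    rhos = np.full(ds.n_cells, np.nan)
    n_degenerate = 0
    groups = _groups(ds)
    for key, idx in groups.items():
        if small[key]:
            continue
        cent = centroids[key]
        X = ds.norm_layer[idx]
        if metric == "correlation":
            rho_b = _pearson_to_centroid(X[:, bio_idx], cent[bio_idx])
            rho_t = _pearson_to_centroid(X[:, tech_idx], cent[tech_idx])
            bio = 1.0 - rho_b
            tech = 1.0 - rho_t
            rhos[idx] = rho_b
        else:
            bio = np.linalg.norm(X[:, bio_idx] - cent[bio_idx], axis=1)
            tech = np.linalg.norm(X[:, tech_idx] - cent[tech_idx], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(tech > 0, bio / tech, np.nan)
        n_degenerate += int(np.isnan(score).sum())
        values[idx] = score
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} cells have zero technical variation or a degenerate "
            "correlation; their ERCC noise is missing",
            stacklevel=2,
        )
    index = pd.Index(ds.cell_ids, name="cell_id")
    return NoiseScores(
        method="ercc_ratio",
        values=pd.Series(values, index=index),
        pearson_rho=pd.Series(rhos, index=index) if metric == "correlation" else None,
        flags={"metric": metric, "small_groups": [k for k, s in small.items() if s]},
    )


def euclid_dtc(ds: ExpressionDataset, min_cells: int = 10) -> NoiseScores:
    """Euclidean distance of each cell to its (cell_type, individual) centroid."""
    centroids, small = centroid_expression(ds, min_cells=min_cells)
    bio_idx = ~ds.ercc_mask
    values = np.full(ds.n_cells, np.nan)
    for key, idx in _groups(ds).items():
        if small[key]:
            continue
        diff = ds.norm_layer[idx][:, bio_idx] - centroids[key][bio_idx]
        values[idx] = np.linalg.norm(diff, axis=1)
    return NoiseScores(
        method="euclid_dtc",
        values=pd.Series(values, index=pd.Index(ds.cell_ids, name="cell_id")),
        flags={"small_groups": [k for k, s in small.items() if s]},
    )


def select_invariant_genes(
    ds: ExpressionDataset,
    n_bins: int = 10,
    fraction: float = 0.10,
    direction: str = "lowest",
) -> InvariantGeneSet:
    """Select invariant genes by coefficient of variation inside mean bins.

    Non-ERCC genes are ranked by mean normalized expression and split into
    ``n_bins`` equal-size bins (the remainder, when the gene count is not
    divisible, goes to the highest-expression bins).  The two extreme bins
    are dropped, and within each remaining bin the ``fraction`` of genes with
    the lowest CV (sd/mean; flip with ``direction="highest"``) is selected,
    at least one gene per bin.  Zero-mean genes are never selected.
    """
    if ds.norm_layer is None:
        raise ValueError("norm_layer absent: run normalize_log1p first")
    if direction not in ("lowest", "highest"):
        raise ValueError("direction must be 'lowest' or 'highest'")
    candidates = np.where(~ds.ercc_mask)[0]
    n = len(candidates)
    if n < 3 * n_bins:
        raise ValueError(f"need at least {3 * n_bins} non-ERCC genes, found {n}")
    X = ds.norm_layer[:, candidates]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    order = np.argsort(mean, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base] * (n_bins - rem) + [base + 1] * rem  # remainder to highest bins
    bin_of = np.empty(n, dtype=int)
    pos = 0
    for b, size in enumerate(sizes):
        bin_of[order[pos : pos + size]] = b
        pos += size
    selected = []
    for b in range(1, n_bins - 1):  # drop the two extreme bins
        in_b = np.where(bin_of == b)[0]
        cvs = cv[in_b]
        valid = in_b[~np.isnan(cvs)]
        if len(valid) == 0:
            continue
        n_take = max(1, int(np.floor(fraction * len(in_b))))
        key = cv[valid] if direction == "lowest" else -cv[valid]
        picked = valid[np.argsort(key, kind="stable")[:n_take]]
        selected.extend(picked.tolist())
    sel = np.asarray(sorted(selected), dtype=int)
    gidx = pd.Index(ds.gene_ids[candidates], name="gene_id")
    return InvariantGeneSet(
        gene_ids=ds.gene_ids[candidates[sel]],
        n_bins=n_bins,
        bin_assignments=pd.Series(bin_of, index=gidx),
        cv_per_gene=pd.Series(cv, index=gidx),
    )


def invariant_dtc(
    ds: ExpressionDataset,
    genes: InvariantGeneSet,
    min_cells: int = 10,
    pooled: bool = False,
) -> NoiseScores:
    """Euclidean distance to the tissue mean on invariant genes.

    The tissue reference per individual is the unweighted mean of that
    individual's cell-type centroids (``pooled=True`` uses the plain all-cell
    mean instead), restricted to the invariant gene set.
    """
    if len(genes.gene_ids) == 0:
        raise ValueError("invariant gene set is empty")
    centroids, small = centroid_expression(ds, min_cells=min_cells)
    gene_pos = {g: i for i, g in enumerate(ds.gene_ids)}
    cols = np.asarray([gene_pos[g] for g in genes.gene_ids])
    values = np.full(ds.n_cells, np.nan)
    individuals = ds.cell_meta["individual"].to_numpy()
    for ind in pd.unique(individuals):
        cell_idx = np.where(individuals == ind)[0]
        if pooled:
            ref = ds.norm_layer[np.ix_(cell_idx, cols)].mean(axis=0)
        else:
            cents = [
                centroids[key][cols]
                for key in centroids
                if key[1] == ind and not small[key]
            ]
            if not cents:
                continue
            ref = np.mean(cents, axis=0)
        keep = cell_idx[
            ~np.asarray(
                [small[(ct, ind)] for ct in ds.cell_meta["cell_type"].to_numpy()[cell_idx]]
            )
        ]
        diff = ds.norm_layer[np.ix_(keep, cols)] - ref
        values[keep] = np.linalg.norm(diff, axis=1)
    return NoiseScores(
        method="invariant_dtc",
        values=pd.Series(values, index=pd.Index(ds.cell_ids, name="cell_id")),
        flags={"pooled": pooled, "n_invariant_genes": len(genes.gene_ids)},
    )
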