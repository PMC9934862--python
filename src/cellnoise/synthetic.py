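"""Gamma-Poisson group-structured count simulator and marker analyses.

The generator emulates the standard hierarchical scRNA-seq count model:
baseline gene means are gamma-distributed, each gene is differentially
expressed in a given group with probability ``de_prob`` (log-normal
multiplicative factor), per-group mean vectors are normalised to relative
abundances, and each cell draws Poisson counts at a log-normally distributed
library depth.  Lowering ``de_prob`` weakens group signatures and produces
"noisy" populations whose cells do not cluster robustly — the dial used to
build the low/medium/high-noise validation fixtures.

The default composition is nine populations of 10,000 cells at
25/20/15/10/10/7/5.5/4/3.5 %.

Also here: gene subsampling/marker-removal ablations, one-vs-rest Wilcoxon
marker ranking, and the stable-vs-unstable differential-expression contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .datasets import ExpressionDataset
from .scallop import MembershipResult

__all__ = [
    "SimSpec",
    "GroundTruth",
    "simulate_counts",
    "simulate_bridged_pair",
    "noise_ladder",
    "NOISE_LADDER_DE_PROB",
    "subsample",
    "rank_markers",
    "remove_top_markers",
    "stable_unstable_contrast",
]

DEFAULT_PROPORTIONS = (0.25, 0.20, 0.15, 0.10, 0.10, 0.07, 0.055, 0.04, 0.035)

#: de_prob per noise rung; the medium_high rung (0.001) is the anchor the
#: validation fixtures are built around, the others bracket it monotonically.
NOISE_LADDER_DE_PROB = {
    "low": 0.1,
    "medium_low": 0.01,
    "medium_high": 0.001,
    "high": 0.0003,
}


@dataclass
class SimSpec:
    """Simulation parameters.

    de_prob is the probability that a gene is differentially expressed in a
    given group; de_logfc_sd the sd of its log fold change.  Library sizes
    are log-normal (default median 2000 counts).  Setting ``n_ercc`` > 0
    appends that many ERCC spike-in genes with shared (group-independent)
    abundances.
    """

    n_cells: int = 10_000
    n_genes: int = 5_000
    proportions: Tuple[float, ...] = DEFAULT_PROPORTIONS
    de_prob: float = 0.1
    de_logfc_sd: float = 1.0
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_logmean: float = float(np.log(2000.0))
    libsize_logsd: float = 0.25
    n_ercc: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if not (0.0 <= self.de_prob <= 1.0):
            raise ValueError("de_prob must be in [0, 1]")


@dataclass
class GroundTruth:
    """Truth channel: per-cell group labels and the genes x groups DE structure."""

    group_label: np.ndarray
    de_mask: np.ndarray  # genes x groups bool
    de_factor: np.ndarray  # genes x groups positive, 1 where not DE

    def subset_genes(self, idx: np.ndarray) -> "GroundTruth":
        return GroundTruth(self.group_label, self.de_mask[idx], self.de_factor[idx])

    def subset_cells(self, idx: np.ndarray) -> "GroundTruth":
        return GroundTruth(self.group_label[idx], self.de_mask, self.de_factor)


def largest_remainder(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Deterministic apportionment of n into integer group sizes."""
    quotas = np.asarray(proportions, dtype=float) * n
    sizes = np.floor(quotas).astype(int)
    short = n - sizes.sum()
    order = np.argsort(-(quotas - np.floor(quotas)), kind="stable")
    sizes[order[:short]] += 1
    return sizes


def simulate_counts(spec: SimSpec) -> Tuple[ExpressionDataset, GroundTruth]:
    """Draw a (cells x genes) count matrix with group structure.

    Group sizes are the largest-remainder apportionment of the proportions
    (composition is exact, not multinomial).  Counts are
    Poisson(L_c * pi_{g, group(c)}) with pi the group's mean vector
    normalised to sum 1 and L_c the cell's log-normal library depth.
    """
    rng = np.random.default_rng(spec.seed)
    n_groups = len(spec.proportions)
    sizes = largest_remainder(spec.n_cells, spec.proportions)
    group_of = np.repeat(np.arange(n_groups), sizes)

    mu = rng.gamma(shape=spec.mean_shape, scale=1.0 / spec.mean_rate, size=spec.n_genes)
    de_mask = rng.random((spec.n_genes, n_groups)) < spec.de_prob
    lfc = rng.normal(0.0, spec.de_logfc_sd, size=(spec.n_genes, n_groups))
    de_factor = np.where(de_mask, np.exp(lfc), 1.0)

    group_means = mu[:, None] * de_factor  # genes x groups
    if spec.n_ercc:
        ercc_mu = rng.gamma(spec.mean_shape, 1.0 / spec.mean_rate, size=spec.n_ercc)
        group_means = np.vstack([group_means, np.tile(ercc_mu[:, None], (1, n_groups))])
    rel = group_means / group_means.sum(axis=0, keepdims=True)

    lib = rng.lognormal(spec.libsize_logmean, spec.libsize_logsd, size=spec.n_cells)
    lam = lib[:, None] * rel[:, group_of].T
    counts = rng.poisson(lam).astype(float)

    n_total_genes = spec.n_genes + spec.n_ercc
    gene_ids = np.array(
        [f"Gene{i + 1}" for i in range(spec.n_genes)]
        + [f"ERCC-{i + 1:05d}" for i in range(spec.n_ercc)],
        dtype=object,
    )
    cell_ids = np.array([f"Cell{i + 1}" for i in range(spec.n_cells)], dtype=object)
    labels = np.array([f"Group{g + 1}" for g in group_of], dtype=object)
    meta = pd.DataFrame(
        {"cell_type": labels, "individual": "sim1", "group": labels},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    ercc_mask = np.zeros(n_total_genes, dtype=bool)
    ercc_mask[spec.n_genes :] = True
    ds = ExpressionDataset(
        counts=counts, cell_ids=cell_ids, gene_ids=gene_ids, cell_meta=meta, ercc_mask=ercc_mask
    )
    truth = GroundTruth(group_label=labels, de_mask=de_mask, de_factor=de_factor)
    return ds, truth


def simulate_bridged_pair(
    n_pure: int = 300,
    n_trans: int = 200,
    n_genes: int = 500,
    de_prob: float = 0.1,
    w_range: Tuple[float, float] = (0.2, 0.8),
    libsize_logmean: float = float(np.log(2000.0)),
    libsize_logsd: float = 0.25,
    seed: int = 0,
) -> ExpressionDataset:
    """Two marked populations joined by a smear of transitional cells.

    Populations A and B each get an independent DE signature (probability
    ``de_prob`` per gene, log-normal factor).  ``n_trans`` additional cells,
    labelled A, sit on the A-B bridge: each draws a mixing weight w from
    ``w_range`` and expresses the log-interpolated mean ``mA^w * mB^(1-w)``.
    Bridge cells have genuinely ambiguous neighborhoods, so their cluster
    assignment is unstable and their marker expression weak — the planted
    analogue of transcriptionally noisy cells within a cell type.
    """
    rng = np.random.default_rng(seed)
    mu = rng.gamma(0.6, 1.0 / 0.3, size=n_genes)
    de = lambda: np.where(rng.random(n_genes) < de_prob, np.exp(rng.normal(0.0, 1.0, n_genes)), 1.0)
    mA, mB = mu * de(), mu * de()
    w = rng.uniform(*w_range, size=n_trans)
    means = [mA] * n_pure + [mB] * n_pure + [mA**wi * mB ** (1 - wi) for wi in w]
    labels = ["A"] * n_pure + ["B"] * n_pure + ["A"] * n_trans
    n = len(means)
    lib = rng.lognormal(libsize_logmean, libsize_logsd, size=n)
    counts = np.vstack([rng.poisson(l * m / m.sum()) for l, m in zip(lib, means)]).astype(float)
    cell_ids = np.array([f"Cell{i + 1}" for i in range(n)], dtype=object)
    meta = pd.DataFrame(
        {
            "cell_type": labels,
            "individual": "sim1",
            "is_bridge": [False] * (2 * n_pure) + [True] * n_trans,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return ExpressionDataset(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=np.array([f"Gene{j + 1}" for j in range(n_genes)], dtype=object),
        cell_meta=meta,
    )


def noise_ladder(level: str, **overrides) -> SimSpec:
    """SimSpec for one rung of the low..high noise ladder.

    Rungs share composition and seed and differ only in de_prob; higher
    noise means lower de_prob (weaker cluster signatures).  The medium_high
    rung is pinned at de_prob = 0.001.
    """
    if level not in NOISE_LADDER_DE_PROB:
        raise ValueError(f"unknown noise level '{level}'; choose from {sorted(NOISE_LADDER_DE_PROB)}")
    return SimSpec(de_prob=NOISE_LADDER_DE_PROB[level], **overrides)


def subsample(
    ds: ExpressionDataset,
    n_cells: Optional[int] = None,
    n_genes: Optional[int] = None,
    seed: int = 0,
    truth: Optional[GroundTruth] = None,
):
    """Uniform subsampling of cells and/or genes without replacement.

    Row/column order is preserved.  Downstream preprocessing must be re-run
    on the result.  If ``truth`` is given, it is sliced consistently and
    returned alongside.
    """
    rng = np.random.default_rng(seed)
    out = ds
    if n_cells is not None:
        if n_cells > ds.n_cells:
            raise ValueError(f"n_cells={n_cells} exceeds {ds.n_cells}")
        idx = np.sort(rng.choice(ds.n_cells, size=n_cells, replace=False))
        out = out.subset_cells(idx)
        if truth is not None:
            truth = truth.subset_cells(idx)
    if n_genes is not None:
        if n_genes > ds.n_genes:
            raise ValueError(f"n_genes={n_genes} exceeds {ds.n_genes}")
        gidx = np.sort(rng.choice(ds.n_genes, size=n_genes, replace=False))
        out = out.subset_genes(gidx)
        if truth is not None:
            non_ercc = np.where(~ds.ercc_mask)[0]
            pos = {g: i for i, g in enumerate(non_ercc)}
            kept = [pos[g] for g in gidx if g in pos]
            truth = truth.subset_genes(np.asarray(kept, dtype=int))
    return (out, truth) if truth is not None else out


# ---------------------------------------------------------------------------
# marker ranking


def _ranksum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p (no-tie null)."""
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return float(res.pvalue)


def rank_markers(ds: ExpressionDataset, group_col: str = "cell_type") -> Dict[str, pd.DataFrame]:
    """One-vs-rest Wilcoxon rank-sum marker ranking per group.

    Per group and gene, a rank-sum test of the group against all other cells
    on the normalized layer (normal approximation with tie correction;
    exact null when both sides have <= 8 cells), Benjamini-Hochberg adjusted
    p-values, and the difference of group means (natural-log scale) as LFC.
    Genes are ranked by p-value, then by |LFC| descending.
    """
    from statsmodels.stats.multitest import multipletests

    if ds.norm_layer is None:
        raise ValueError("norm_layer absent: run normalize_log1p first")
    labels = ds.cell_meta[group_col].to_numpy()
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    X = ds.norm_layer[:, ~ds.ercc_mask]
    gene_ids = ds.gene_ids[~ds.ercc_mask]
    n, p = X.shape
    ranks = scipy.stats.rankdata(X, axis=0)
    # tie correction term per gene
    tie_term = np.zeros(p)
    for j in range(p):
        _, cnt = np.unique(X[:, j], return_counts=True)
        tie_term[j] = (cnt**3 - cnt).sum()
    out: Dict[str, pd.DataFrame] = {}
    for g in groups:
        in_g = labels == g
        n1 = int(in_g.sum())
        n2 = n - n1
        if n1 < 3:
            raise ValueError(f"group '{g}' has fewer than 3 cells")
        if max(n1, n2) <= 8:
            pvals = np.array([_ranksum_exact_p(X[in_g, j], X[~in_g, j]) for j in range(p)])
        else:
            R1 = ranks[in_g].sum(axis=0)
            U = R1 - n1 * (n1 + 1) / 2.0
            mean_u = n1 * n2 / 2.0
            var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (U - mean_u) / np.sqrt(var_u)
            pvals = np.where(var_u > 0, 2 * scipy.stats.norm.sf(np.abs(z)), 1.0)
        padj = multipletests(pvals, method="fdr_bh")[1]
        lfc = X[in_g].mean(axis=0) - X[~in_g].mean(axis=0)
        tab = pd.DataFrame(
            {"gene_id": gene_ids, "lfc": lfc, "p_value": pvals, "p_adj": padj}
        )
        tab = tab.sort_values(
            by=["p_value", "lfc"],
            key=lambda s: -s.abs() if s.name == "lfc" else s,
            kind="stable",
        ).reset_index(drop=True)
        out[str(g)] = tab
    return out


def remove_top_markers(
    ds: ExpressionDataset, group: str, k: int = 10, group_col: str = "cell_type"
) -> List[ExpressionDataset]:
    """Cumulative marker-removal ablation.

    Markers of ``group`` are ranked one-vs-rest; dataset i (1..k) in the
    returned list has the top-i markers (restricted to positively enriched
    genes) removed.  Preprocessing must be re-run on each.
    """
    if group not in set(map(str, ds.cell_meta[group_col])):
        raise ValueError(f"unknown group '{group}'")
    if k > ds.n_genes:
        raise ValueError("k exceeds gene count")
    markers = rank_markers(ds, group_col=group_col)[group]
    markers = markers[markers["lfc"] > 0]
    top = markers["gene_id"].to_numpy()[:k]
    gene_pos = {g: i for i, g in enumerate(ds.gene_ids)}
    out = []
    for i in range(1, k + 1):
        drop = {gene_pos[g] for g in top[:i]}
        keep = np.asarray([j for j in range(ds.n_genes) if j not in drop])
        out.append(ds.subset_genes(keep))
    return out


def stable_unstable_contrast(
    ds: ExpressionDataset,
    membership: MembershipResult,
    group_col: str = "cell_type",
) -> Dict[str, Dict[str, pd.DataFrame]]:
    """Marker tables using all, stable-half, and unstable-half cells.

    Per group, cells above the median membership form the stable half; the
    two compared sets have the same size (ties at the median are broken by
    membership rank, then cell index, so the split is deterministic even for
    discrete membership values).  Markers are re-ranked within each subset
    against all other cells.  Returns {"all": ..., "stable": ..., "unstable": ...}
    marker-table dicts.
    """
    mem = membership.membership.reindex(ds.cell_ids).to_numpy()
    labels = ds.cell_meta[group_col].to_numpy()
    stable = np.zeros(ds.n_cells, dtype=bool)
    for g in pd.unique(labels):
        in_g = np.where(labels == g)[0]
        if len(in_g) < 4:
            raise ValueError(f"group '{g}' too small to split")
        order = in_g[np.argsort(-mem[in_g], kind="stable")]
        stable[order[: len(in_g) // 2]] = True
    out: Dict[str, Dict[str, pd.DataFrame]] = {"all": rank_markers(ds, group_col)}
    for name, half in (("stable", stable), ("unstable", ~stable)):
        sub_tables: Dict[str, pd.DataFrame] = {}
        for g in pd.unique(labels):
            in_g = labels == g
            keep = np.where(~in_g | (in_g & half))[0]
            sub = ds.subset_cells(keep)
            sub_tables[str(g)] = rank_markers(sub, group_col)[str(g)]
        out[name] = sub_tables
    return out
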