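"""Bootstrap cluster-membership scoring (the Scallop algorithm).

A reference clustering is computed on all cells; then the clustering is
re-run on random subsets of cells (drawn with replacement) n_trials times.
Cluster labels from each trial are harmonized with the reference through an
overlap-score contingency matrix and the Hungarian assignment, with a second
pass that reconciles unmapped surplus clusters across trials (minimum scaled
overlap 0.1).  Each cell's membership is the frequency with which it
received its most frequent (consensus) label, counted over the trials in
which it was sampled; transcriptional noise is 1 − membership.

Clustering is a pluggable contract: any deterministic-given-seed partitioner
of a weighted graph at a resolution works; the default is Leiden
modularity optimization (resolution-scaled configuration-model null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from .datasets import ExpressionDataset, NeighborGraph, preprocess

__all__ = [
    "NOT_SAMPLED",
    "UNMAPPED",
    "ClusterParams",
    "ClusteringSolution",
    "BootstrapRun",
    "MembershipResult",
    "cluster_graph",
    "run_bootstrap",
    "overlap_score",
    "overlap_matrix",
    "hungarian_map",
    "relabel_trials",
    "resolve_unmapped",
    "membership_scores",
    "scallop_pipeline",
    "multires_noise",
    "aging_noise_contrast",
]

NOT_SAMPLED = -1
UNMAPPED = -2


@dataclass
class ClusterParams:
    """Community-detection settings: resolution r > 0, seed, backend name."""

    resolution: float = 1.0
    seed: int = 0
    algorithm: str = "leiden"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


@dataclass
class ClusteringSolution:
    """Partition of graph nodes with per-cluster modularity bookkeeping.

    Labels run 0..C-1 ordered by non-increasing cluster size (label 0 is the
    largest cluster; ties broken by smallest member index).  ``modularity``
    is Q = sum_c (e_c - r * K_c^2 / (4 m)) with e_c the intra-cluster edge
    weight, K_c the total degree of the cluster, and m the total edge weight.
    """

    labels: np.ndarray
    n_clusters: int
    cluster_edge_weight: np.ndarray
    cluster_degree: np.ndarray
    modularity: float
    resolution: float


@dataclass
class BootstrapRun:
    """Reference clustering + cells x trials bootstrap label matrix.

    ``assignments[c, t]`` is the (trial-local, un-harmonized) cluster label
    of cell c in trial t, or NOT_SAMPLED.  ``relabeled`` is filled by the
    harmonization pass.
    """

    reference: ClusteringSolution
    assignments: np.ndarray
    frac_cells: float
    n_trials: int
    seed: int
    trial_solutions: List[ClusteringSolution] = field(default_factory=list)
    relabeled: Optional[np.ndarray] = None


@dataclass
class MembershipResult:
    """Per-cell consensus label, membership in (0,1], and noise = 1 - membership."""

    consensus_label: pd.Series
    membership: pd.Series
    noise: pd.Series
    n_sampled: pd.Series
    score_kind: str = "freq"


# ---------------------------------------------------------------------------
# clustering backend


def _leiden_backend(adj: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    import igraph as ig
    import leidenalg

    coo = sp.triu(adj, k=1).tocoo()
    g = ig.Graph(
        n=adj.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


_BACKENDS: Dict[str, Callable[[sp.csr_matrix, float, int], np.ndarray]] = {
    "leiden": _leiden_backend,
}


def register_backend(name: str, fn: Callable[[sp.csr_matrix, float, int], np.ndarray]) -> None:
    """Register a clustering backend: fn(adjacency, resolution, seed) -> labels."""
    _BACKENDS[name] = fn


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Re-index labels by descending cluster size; ties by smallest member index."""
    uniq = np.unique(labels)
    stats = []
    for u in uniq:
        members = np.where(labels == u)[0]
        stats.append((-len(members), members[0], u))
    stats.sort()
    mapping = {old: new for new, (_, _, old) in enumerate(stats)}
    return np.asarray([mapping[x] for x in labels], dtype=int)


def cluster_graph(g: NeighborGraph | sp.spmatrix, params: ClusterParams) -> ClusteringSolution:
    """Cluster a weighted graph and report per-cluster modularity terms."""
    adj = g.adjacency if isinstance(g, NeighborGraph) else sp.csr_matrix(g)
    if adj.shape[0] == 0:
        raise ValueError("empty graph")
    backend = _BACKENDS.get(params.algorithm)
    if backend is None:
        raise ValueError(f"unknown clustering backend '{params.algorithm}'")
    labels = _relabel_by_size(backend(adj, params.resolution, params.seed))
    n_clusters = int(labels.max()) + 1
    degree = np.asarray(adj.sum(axis=1)).ravel()
    m = degree.sum() / 2.0
    e = np.zeros(n_clusters)
    K = np.zeros(n_clusters)
    coo = sp.triu(adj, k=1).tocoo()
    same = labels[coo.row] == labels[coo.col]
    np.add.at(e, labels[coo.row[same]], coo.data[same])
    np.add.at(K, labels, degree)
    Q = float(np.sum(e - params.resolution * K**2 / (4.0 * m))) if m > 0 else 0.0
    return ClusteringSolution(
        labels=labels,
        n_clusters=n_clusters,
        cluster_edge_weight=e,
        cluster_degree=K,
        modularity=Q,
        resolution=params.resolution,
    )


# ---------------------------------------------------------------------------
# bootstrap


def run_bootstrap(
    graph: NeighborGraph,
    params: ClusterParams,
    frac_cells: float = 0.95,
    n_trials: int = 30,
    seed: int = 0,
) -> BootstrapRun:
    """Reference clustering plus n_trials clusterings of bootstrap subsets.

    Each trial draws round(frac_cells * n) cell indices with replacement;
    duplicates collapse to one graph node, the induced subgraph is clustered,
    and sampled cells receive that trial's labels (others NOT_SAMPLED).
    The reference uses an independent seed stream.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 < frac_cells <= 1):
        raise ValueError("frac_cells must be in (0, 1]")
    n = graph.n_cells
    root = np.random.SeedSequence(seed)
    ref_seed, *trial_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_trials + 1)]
    reference = cluster_graph(graph, ClusterParams(params.resolution, ref_seed, params.algorithm))
    n_draw = int(round(frac_cells * n))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2**20,)))
    assignments = np.full((n, n_trials), NOT_SAMPLED, dtype=int)
    solutions: List[ClusteringSolution] = []
    for t in range(n_trials):
        draws = rng.integers(0, n, size=n_draw)
        idx = np.unique(draws)
        sub = graph.adjacency[np.ix_(idx, idx)]
        sol = cluster_graph(sub, ClusterParams(params.resolution, trial_seeds[t], params.algorithm))
        assignments[idx, t] = sol.labels
        solutions.append(sol)
    return BootstrapRun(
        reference=reference,
        assignments=assignments,
        frac_cells=frac_cells,
        n_trials=n_trials,
        seed=seed,
        trial_solutions=solutions,
    )


# ---------------------------------------------------------------------------
# relabeling


def overlap_score(size_a: int, size_b: int, inter: int, scaled: bool = True) -> float:
    """Two-term cluster overlap score S = inter/|A| + inter/|B|.

    The unscaled score reaches its maximum, 2, for identical clusters; with
    ``scaled=True`` (default) it is divided by 2 to lie in [0, 1].
    """
    if size_a <= 0 or size_b <= 0:
        raise ValueError("cluster sizes must be positive")
    if not (0 <= inter <= min(size_a, size_b)):
        raise ValueError("intersection must be between 0 and the smaller cluster size")
    s = inter / size_a + inter / size_b
    return s / 2.0 if scaled else s


def overlap_matrix(labels_a: np.ndarray, labels_b: np.ndarray) -> pd.DataFrame:
    """Scaled overlap scores between clusters of two label vectors.

    Both vectors must be aligned to the same cells; entries < 0 (NOT_SAMPLED)
    are excluded from both sides.  Rows are clusters of ``labels_a``
    (reference), columns clusters of ``labels_b``.
    """
    keep = (labels_a >= 0) & (labels_b >= 0)
    a, b = labels_a[keep], labels_b[keep]
    ua, ub = np.unique(a), np.unique(b)
    mat = np.zeros((len(ua), len(ub)))
    ct = pd.crosstab(pd.Series(a), pd.Series(b))
    for i, ca in enumerate(ua):
        for j, cb in enumerate(ub):
            inter = int(ct.loc[ca, cb]) if (ca in ct.index and cb in ct.columns) else 0
            mat[i, j] = overlap_score(int((a == ca).sum()), int((b == cb).sum()), inter)
    return pd.DataFrame(mat, index=ua, columns=ub)


def hungarian_map(scores: pd.DataFrame | np.ndarray) -> Dict[int, int]:
    """Maximum-total-overlap one-to-one assignment trial-cluster -> reference label.

    With more trial clusters than reference clusters the surplus ones map to
    UNMAPPED; with fewer, some reference labels stay unused.
    """
    if isinstance(scores, pd.DataFrame):
        mat = scores.to_numpy(dtype=float)
        ref_ids = list(scores.index)
        trial_ids = list(scores.columns)
    else:
        mat = np.asarray(scores, dtype=float)
        ref_ids = list(range(mat.shape[0]))
        trial_ids = list(range(mat.shape[1]))
    if not np.all(np.isfinite(mat)):
        raise ValueError("overlap scores must be finite")
    rows, cols = linear_sum_assignment(-mat)
    out: Dict[int, int] = {int(t): UNMAPPED for t in trial_ids}
    for r, c in zip(rows, cols):
        out[int(trial_ids[c])] = int(ref_ids[r])
    return out


def relabel_trials(run: BootstrapRun) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Harmonize each trial's labels with the reference via Hungarian mapping.

    Per trial, the reference labels are restricted to that trial's sampled
    cells when computing overlaps.  Returns the relabeled matrix (UNMAPPED
    entries for surplus clusters) and a registry of (trial, trial_label)
    pairs left unmapped, in first-seen order.
    """
    ref = run.reference.labels
    out = np.full_like(run.assignments, NOT_SAMPLED)
    registry: List[Tuple[int, int]] = []
    for t in range(run.n_trials):
        col = run.assignments[:, t]
        sampled = col != NOT_SAMPLED
        ref_col = np.where(sampled, ref, NOT_SAMPLED)
        scores = overlap_matrix(ref_col, col)
        mapping = hungarian_map(scores)
        unmapped_here = sorted(l for l, tgt in mapping.items() if tgt == UNMAPPED)
        registry.extend((t, l) for l in unmapped_here)
        out[sampled, t] = [mapping[l] for l in col[sampled]]
    return out, registry


def resolve_unmapped(
    run: BootstrapRun,
    relabeled: np.ndarray,
    registry: Sequence[Tuple[int, int]],
    min_overlap: float = 0.1,
) -> np.ndarray:
    """Second mapping pass: give recurring unmapped clusters a shared label.

    Unmapped clusters from all trials are cross-scored; a cluster joins the
    first previously-seen unmapped cluster with scaled overlap >= ``min_overlap``,
    otherwise it founds a new label.  New labels are numbered from the number
    of reference clusters upward in first-seen order.
    """
    if not registry:
        return relabeled
    next_label = run.reference.n_clusters
    groups: List[Tuple[int, frozenset]] = []  # (new label, representative cell set)
    out = relabeled.copy()
    for trial, old_label in registry:
        cells = frozenset(np.where(run.assignments[:, trial] == old_label)[0].tolist())
        target = None
        best = min_overlap
        for lbl, rep in groups:
            s = overlap_score(len(rep), len(cells), len(rep & cells))
            if s >= best:
                best, target = s, lbl
        if target is None:
            target = next_label
            next_label += 1
            groups.append((target, cells))
        out[list(cells), trial] = target
    return out


def _entropy_score(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    c_used = (counts > 0).sum()
    if c_used <= 1:
        return 1.0
    h = -(p[p > 0] * np.log(p[p > 0])).sum()
    return float(1.0 - h / np.log(c_used))


def _kl_score(counts: np.ndarray, consensus_pos: int, alpha: float = 0.01) -> float:
    # exp(-KL(q_alpha || p)) for a smoothed consensus-concentrated q; an
    # explicit extension of the frequency score, defaulted off.
    p = counts / counts.sum()
    k = len(counts)
    q = np.full(k, alpha / k)
    q[consensus_pos] += 1.0 - alpha
    mask = q > 0
    with np.errstate(divide="ignore"):
        kl = np.sum(np.where(p[mask] > 0, q[mask] * np.log(q[mask] / p[mask]), np.inf))
    return float(np.exp(-kl))


def membership_scores(
    run: BootstrapRun,
    relabeled: Optional[np.ndarray] = None,
    kind: str = "freq",
    cell_ids: Optional[Sequence] = None,
) -> MembershipResult:
    """Consensus label and membership score per cell from harmonized labels.

    freq: fraction of sampled trials assigning the consensus (most frequent,
    smallest-on-tie) label.  Cells never sampled are missing, with a warning.
    """
    if kind not in ("freq", "entropy", "kl"):
        raise ValueError("kind must be 'freq', 'entropy', or 'kl'")
    if relabeled is None:
        relabeled = run.relabeled
    if relabeled is None:
        raise ValueError("relabeled assignments missing: run the harmonization pass first")
    n = relabeled.shape[0]
    index = pd.Index(cell_ids if cell_ids is not None else np.arange(n), name="cell_id")
    consensus = np.full(n, np.nan)
    member = np.full(n, np.nan)
    n_sampled = np.zeros(n, dtype=int)
    for c in range(n):
        row = relabeled[c]
        row = row[row != NOT_SAMPLED]
        n_sampled[c] = len(row)
        if len(row) == 0:
            continue
        labels, counts = np.unique(row, return_counts=True)
        best = int(np.argmax(counts))  # np.unique sorts labels: ties -> smallest label
        consensus[c] = labels[best]
        if kind == "freq":
            member[c] = counts[best] / counts.sum()
        elif kind == "entropy":
            member[c] = _entropy_score(counts)
        else:
            member[c] = _kl_score(counts, best)
    n_missing = int((n_sampled == 0).sum())
    if n_missing:
        warnings.warn(f"{n_missing} cells were never sampled; membership is missing", stacklevel=2)
    return MembershipResult(
        consensus_label=pd.Series(consensus, index=index),
        membership=pd.Series(member, index=index),
        noise=pd.Series(1.0 - member, index=index),
        n_sampled=pd.Series(n_sampled, index=index),
        score_kind=kind,
    )


# ---------------------------------------------------------------------------
# pipelines


def scallop_pipeline(
    ds: ExpressionDataset,
    params: ClusterParams,
    frac_cells: float = 0.95,
    n_trials: int = 30,
    seed: int = 0,
    graph: Optional[NeighborGraph] = None,
    score_kind: str = "freq",
    **preprocess_kw,
) -> MembershipResult:
    """Full membership run: bootstrap -> relabel -> resolve unmapped -> score.

    If ``graph`` is not given, the standard preprocessing chain is run first
    (normalize, HVG, PCA, SNN graph).
    """
    if graph is None:
        ds, _, graph = preprocess(ds, **preprocess_kw)
    run = run_bootstrap(graph, params, frac_cells=frac_cells, n_trials=n_trials, seed=seed)
    relabeled, registry = relabel_trials(run)
    run.relabeled = resolve_unmapped(run, relabeled, registry)
    return membership_scores(run, kind=score_kind, cell_ids=ds.cell_ids)


def multires_noise(
    ds: ExpressionDataset,
    res_grid: Optional[Sequence[float]] = None,
    frac_cells: float = 0.8,
    n_trials: int = 30,
    seed: int = 0,
    graph: Optional[NeighborGraph] = None,
    **preprocess_kw,
) -> pd.DataFrame:
    """Noise averaged over a resolution grid (default 0.1..1.5 step 0.1).

    Membership is computed per resolution and averaged per cell (missing
    values excluded); noise = 1 - mean membership.  Returns a DataFrame with
    columns membership, noise, n_resolutions.
    """
    if res_grid is None:
        res_grid = np.round(np.arange(0.1, 1.51, 0.1), 10)
    res_grid = list(res_grid)
    if len(res_grid) == 0:
        raise ValueError("resolution grid is empty")
    if graph is None:
        ds, _, graph = preprocess(ds, **preprocess_kw)
    mems = []
    for i, r in enumerate(res_grid):
        sub_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0] % 2**31)
        res = scallop_pipeline(
            ds,
            ClusterParams(resolution=float(r), seed=sub_seed),
            frac_cells=frac_cells,
            n_trials=n_trials,
            seed=sub_seed,
            graph=graph,
        )
        mems.append(res.membership)
    mat = pd.concat(mems, axis=1)
    mean_mem = mat.mean(axis=1, skipna=True)
    return pd.DataFrame(
        {
            "membership": mean_mem,
            "noise": 1.0 - mean_mem,
            "n_resolutions": mat.notna().sum(axis=1),
        }
    )


def aging_noise_contrast(
    ds: ExpressionDataset,
    res_grid: Optional[Sequence[float]] = None,
    frac_cells: float = 0.8,
    n_trials: int = 30,
    seed: int = 0,
    noisy_cutoff: float = 0.2,
    min_cells: int = 10,
    **preprocess_kw,
) -> pd.DataFrame:
    """Per-cell-type old-vs-young noise contrast.

    The dataset is split by age group; preprocessing (HVG, PCA, graph) is
    re-run on each split, multi-resolution noise computed, and per cell type
    the median noise in each group, the delta (old - young), and the noisy
    cell fractions (noise >= cutoff) are reported.
    """
    from .composition import noisy_fraction

    if "age_group" not in ds.cell_meta.columns:
        raise ValueError("cell_meta is missing 'age_group'")
    noise_by_group = {}
    for grp in ("young", "old"):
        idx = np.where(ds.cell_meta["age_group"].to_numpy() == grp)[0]
        if len(idx) == 0:
            raise ValueError(f"age group '{grp}' is empty")
        sub = ds.subset_cells(idx)
        nf = multires_noise(
            sub, res_grid=res_grid, frac_cells=frac_cells, n_trials=n_trials, seed=seed, **preprocess_kw
        )
        nf["cell_type"] = sub.cell_meta["cell_type"].to_numpy()
        noise_by_group[grp] = nf
    rows = []
    types = sorted(set(ds.cell_meta["cell_type"]))
    for ct in types:
        rec = {"cell_type": ct}
        ok = True
        for grp in ("young", "old"):
            nf = noise_by_group[grp]
            vals = nf.loc[nf["cell_type"] == ct, "noise"].dropna()
            if len(vals) < min_cells:
                ok = False
                break
            rec[f"median_noise_{grp}"] = float(vals.median())
            rec[f"noisy_fraction_{grp}"] = noisy_fraction(vals.to_numpy(), cutoff=noisy_cutoff)
        if not ok:
            continue
        rec["delta"] = rec["median_noise_old"] - rec["median_noise_young"]
        rows.append(rec)
    return pd.DataFrame(rows)
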