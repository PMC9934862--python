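import numpy as np
import pandas as pd
import pytest

import cellnoise as cn


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured simulation: 3 groups, clear signatures."""
    spec = cn.SimSpec(
        n_cells=300,
        n_genes=250,
        proportions=(0.5, 0.3, 0.2),
        de_prob=0.2,
        seed=11,
        n_ercc=20,
    )
    ds, truth = cn.simulate_counts(spec)
    ds = cn.normalize_log1p(ds)
    return ds, truth


@pytest.fixture(scope="session")
def two_blob_dataset():
    """Two far-separated Gaussian blobs in gene space with metadata."""
    rng = np.random.default_rng(7)
    n_per, p = 60, 40
    a = rng.normal(0.0, 0.3, size=(n_per, p)) + np.r_[np.full(p // 2, 5.0), np.zeros(p - p // 2)]
    b = rng.normal(0.0, 0.3, size=(n_per, p)) + np.r_[np.zeros(p // 2), np.full(p - p // 2, 5.0)]
    counts = np.abs(np.vstack([a, b]))
    cell_ids = [f"c{i}" for i in range(2 * n_per)]
    meta = pd.DataFrame(
        {
            "cell_type": ["A"] * n_per + ["B"] * n_per,
            "individual": ["m1"] * (2 * n_per),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    ds = cn.ExpressionDataset(
        counts=counts,
        cell_ids=np.array(cell_ids, dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(p)], dtype=object),
        cell_meta=meta,
    )
    return cn.normalize_log1p(ds)


def make_dataset(counts, cell_types=None, individuals=None, gene_ids=None, normalize=True):
    """Helper: build a labelled ExpressionDataset from a raw count array."""
    counts = np.asarray(counts, dtype=float)
    n, p = counts.shape
    cell_ids = np.array([f"c{i}" for i in range(n)], dtype=object)
    meta = pd.DataFrame(
        {
            "cell_type": cell_types if cell_types is not None else ["T"] * n,
            "individual": individuals if individuals is not None else ["m1"] * n,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    ds = cn.ExpressionDataset(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=np.array(gene_ids if gene_ids is not None else [f"g{j}" for j in range(p)], dtype=object),
        cell_meta=meta,
    )
    return cn.normalize_log1p(ds) if normalize else ds
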