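"""Bootstrap membership-scoring tests: overlap algebra, Hungarian mapping,
membership formulas, and pipeline behaviour on synthetic blobs."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import cellnoise as cn
from cellnoise.scallop import (
    NOT_SAMPLED,
    UNMAPPED,
    BootstrapRun,
    ClusterParams,
    cluster_graph,
    hungarian_map,
    membership_scores,
    overlap_matrix,
    overlap_score,
    relabel_trials,
    resolve_unmapped,
    run_bootstrap,
)


def block_graph(*cliques):
    """Disjoint unit-weight cliques as a NeighborGraph."""
    n = sum(cliques)
    adj = np.zeros((n, n))
    start = 0
    for size in cliques:
        adj[start : start + size, start : start + size] = 1.0
        start += size
    np.fill_diagonal(adj, 0.0)
    return cn.NeighborGraph(adjacency=sp.csr_matrix(adj), k_neighbors=max(cliques) - 1)


class TestOverlapScore:
    def test_identical_clusters(self):
        assert overlap_score(10, 10, 10, scaled=False) == 2.0
        assert overlap_score(10, 10, 10) == 1.0

    def test_disjoint_and_half(self):
        assert overlap_score(4, 4, 0) == 0.0
        assert overlap_score(4, 4, 2) == 0.5

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = rng.integers(1, 50, size=2)
            i = rng.integers(0, min(a, b) + 1)
            s = overlap_score(int(a), int(b), int(i))
            assert 0.0 <= s <= 1.0
            assert s == overlap_score(int(b), int(a), int(i))

    def test_monotone_in_intersection(self):
        scores = [overlap_score(8, 6, i) for i in range(7)]
        assert all(x < y for x, y in zip(scores, scores[1:]))

    def test_equals_one_iff_identical(self):
        assert overlap_score(5, 5, 5) == 1.0
        assert overlap_score(5, 6, 5) < 1.0

    def test_intersection_out_of_range(self):
        with pytest.raises(ValueError):
            overlap_score(3, 4, 5)


def brute_force_assignment(mat):
    """Best injective mapping of columns (trial) to rows (reference)."""
    n_r, n_t = mat.shape
    best, best_map = -1.0, None
    cols = range(n_t)
    for chosen in itertools.permutations(range(n_r), min(n_r, n_t)):
        # chosen[i] is the row assigned to the i-th selected column subset
        for subset in itertools.combinations(cols, min(n_r, n_t)):
            total = sum(mat[r, c] for r, c in zip(chosen, subset))
            if total > best + 1e-15:
                best = total
                m = {c: UNMAPPED for c in cols}
                for r, c in zip(chosen, subset):
                    m[c] = r
                best_map = m
    return best, best_map


class TestHungarianMap:
    def test_identity_and_swap(self):
        assert hungarian_map(np.array([[0.9, 0.1], [0.2, 0.8]])) == {0: 0, 1: 1}
        assert hungarian_map(np.array([[0.1, 0.9], [0.8, 0.2]])) == {0: 1, 1: 0}

    def test_surplus_trial_cluster_unmapped(self):
        mat = np.array([[0.9, 0.1, 0.01], [0.1, 0.8, 0.02]])
        assert hungarian_map(mat) == {0: 0, 1: 1, 2: UNMAPPED}

    def test_fewer_trial_clusters(self):
        mat = np.array([[0.9], [0.2], [0.1]])
        assert hungarian_map(mat) == {0: 0}

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_total(self, seed):
        rng = np.random.default_rng(seed)
        n_r = rng.integers(1, 6)
        n_t = rng.integers(1, 6)
        mat = rng.random((n_r, n_t))
        mapping = hungarian_map(mat)
        total = sum(mat[r, c] for c, r in mapping.items() if r != UNMAPPED)
        best, _ = brute_force_assignment(mat)
        assert total == pytest.approx(best, abs=1e-12)


class TestClusterGraph:
    def test_two_triangles_modularity(self):
        g = block_graph(3, 3)
        sol = cluster_graph(g, ClusterParams(resolution=1.0, seed=0))
        assert sol.n_clusters == 2
        assert sorted(np.bincount(sol.labels)) == [3, 3]
        # Q = sum_c (e_c - r K_c^2 / 4m): each clique e=3, K=6, m=6
        assert sol.modularity == pytest.approx(2 * (3 - 36 / 24))

    def test_low_resolution_single_cluster(self):
        g = block_graph(6)
        sol = cluster_graph(g, ClusterParams(resolution=1e-3, seed=0))
        assert sol.n_clusters == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        coords = np.vstack([rng.normal(size=(30, 2)), rng.normal(size=(30, 2)) + 8])
        emb = cn.Embedding(coords=coords, explained_variance=np.ones(2))
        g = cn.build_neighbor_graph(emb, k=5)
        s1 = cluster_graph(g, ClusterParams(resolution=1.0, seed=42))
        s2 = cluster_graph(g, ClusterParams(resolution=1.0, seed=42))
        np.testing.assert_array_equal(s1.labels, s2.labels)

    def test_labels_ordered_by_size(self):
        g = block_graph(5, 3)
        sol = cluster_graph(g, ClusterParams(resolution=1.0, seed=0))
        counts = np.bincount(sol.labels)
        assert list(counts) == sorted(counts, reverse=True)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def blob_graph(self):
        rng = np.random.default_rng(2)
        coords = np.vstack([rng.normal(size=(40, 3)), rng.normal(size=(40, 3)) + 10])
        emb = cn.Embedding(coords=coords, explained_variance=np.ones(3))
        return cn.build_neighbor_graph(emb, k=8)

    def test_draw_count(self, blob_graph):
        run = run_bootstrap(blob_graph, ClusterParams(1.0, 0), frac_cells=0.95, n_trials=3, seed=1)
        # 80 cells -> 76 draws; dedup means <= 76 sampled
        for t in range(3):
            sampled = (run.assignments[:, t] != NOT_SAMPLED).sum()
            assert sampled <= 76
            assert sampled > 40  # with replacement, expect ~0.61*80 unique at least

    def test_frac_one_draws_all_indices(self, blob_graph):
        run = run_bootstrap(blob_graph, ClusterParams(1.0, 0), frac_cells=1.0, n_trials=2, seed=3)
        assert run.assignments.shape == (80, 2)

    def test_seed_reproducibility(self, blob_graph):
        r1 = run_bootstrap(blob_graph, ClusterParams(1.0, 0), n_trials=4, seed=9)
        r2 = run_bootstrap(blob_graph, ClusterParams(1.0, 0), n_trials=4, seed=9)
        np.testing.assert_array_equal(r1.assignments, r2.assignments)

    def test_invalid_params(self, blob_graph):
        with pytest.raises(ValueError):
            run_bootstrap(blob_graph, ClusterParams(1.0, 0), n_trials=0, seed=0)
        with pytest.raises(ValueError):
            run_bootstrap(blob_graph, ClusterParams(1.0, 0), frac_cells=0.0, seed=0)


def make_run(reference_labels, assignments):
    """BootstrapRun stub with given reference labels and assignment matrix."""
    ref_labels = np.asarray(reference_labels)
    n_clusters = int(ref_labels.max()) + 1
    ref = cn.scallop.ClusteringSolution(
        labels=ref_labels,
        n_clusters=n_clusters,
        cluster_edge_weight=np.zeros(n_clusters),
        cluster_degree=np.zeros(n_clusters),
        modularity=0.0,
        resolution=1.0,
    )
    assignments = np.asarray(assignments)
    return BootstrapRun(
        reference=ref,
        assignments=assignments,
        frac_cells=1.0,
        n_trials=assignments.shape[1],
        seed=0,
    )


class TestRelabeling:
    def test_swapped_labels_recovered(self):
        ref = np.array([0, 0, 0, 1, 1, 1])
        trial = np.array([1, 1, 1, 0, 0, 0])  # same partition, swapped names
        run = make_run(ref, trial[:, None])
        out, registry = relabel_trials(run)
        np.testing.assert_array_equal(out[:, 0], ref)
        assert registry == []

    def test_split_cluster_flags_unmapped(self):
        ref = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        # trial splits reference cluster 1 into clusters 1 and 2
        trial = np.array([0, 0, 0, 0, 1, 1, 2, 2])
        run = make_run(ref, trial[:, None])
        out, registry = relabel_trials(run)
        assert len(registry) == 1
        assert UNMAPPED in out[:, 0]

    def test_recurring_split_gets_shared_new_label(self):
        ref = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        trial = np.array([0, 0, 0, 0, 1, 1, 2, 2])
        run = make_run(ref, np.column_stack([trial, trial]))
        out, registry = relabel_trials(run)
        out = resolve_unmapped(run, out, registry)
        # both trials' surplus clusters (identical cell sets) share label 2
        np.testing.assert_array_equal(out[:, 0], out[:, 1])
        assert set(out[6:, 0]) == {2}

    def test_below_floor_clusters_stay_distinct(self):
        ref = np.zeros(40, dtype=int)
        t1 = np.zeros(40, dtype=int)
        t1[:2] = 1  # surplus cluster {0,1}
        t2 = np.zeros(40, dtype=int)
        t2[20:22] = 1  # surplus cluster {20,21}; overlap with {0,1} is 0
        run = make_run(ref, np.column_stack([t1, t2]))
        out, registry = relabel_trials(run)
        out = resolve_unmapped(run, out, registry)
        assert out[0, 0] != out[20, 1] or out[0, 0] == NOT_SAMPLED

    def test_no_unmapped_is_identity(self):
        ref = np.array([0, 0, 1, 1])
        run = make_run(ref, ref[:, None])
        out, registry = relabel_trials(run)
        assert registry == []
        np.testing.assert_array_equal(resolve_unmapped(run, out, registry), out)


class TestMembershipScores:
    def test_worked_example(self):
        # 10 sampled trials: 7 x label 0, 3 x label 2
        row = [0] * 7 + [2] * 3
        run = make_run(np.array([0]), np.array([row]))
        res = membership_scores(run, relabeled=np.array([row]))
        assert res.membership.iloc[0] == pytest.approx(0.7)
        assert res.consensus_label.iloc[0] == 0
        assert res.noise.iloc[0] == pytest.approx(0.3)

    def test_unanimous(self):
        row = [1] * 30
        run = make_run(np.array([0, 1]), np.array([row, row]))
        res = membership_scores(run, relabeled=np.array([row, row]))
        assert (res.membership == 1.0).all()
        assert (res.noise == 0.0).all()

    def test_tie_breaks_to_smallest_label(self):
        row = [0] * 5 + [1] * 5
        run = make_run(np.array([0, 1]), np.array([row]))
        res = membership_scores(run, relabeled=np.array([row]))
        assert res.membership.iloc[0] == pytest.approx(0.5)
        assert res.consensus_label.iloc[0] == 0

    def test_never_sampled_missing_with_warning(self):
        rows = np.array([[0, 0], [NOT_SAMPLED, NOT_SAMPLED]])
        run = make_run(np.array([0, 0]), rows)
        with pytest.warns(UserWarning, match="never sampled"):
            res = membership_scores(run, relabeled=rows)
        assert np.isnan(res.membership.iloc[1])
        assert res.n_sampled.iloc[1] == 0

    def test_noise_identity(self):
        rng = np.random.default_rng(5)
        rows = rng.integers(0, 3, size=(20, 15))
        run = make_run(np.arange(3).repeat(7)[:20], rows)
        res = membership_scores(run, relabeled=rows)
        np.testing.assert_array_equal(res.noise.to_numpy(), 1.0 - res.membership.to_numpy())
        # consensus is always a label the cell actually received
        for c in range(20):
            assert res.consensus_label.iloc[c] in set(rows[c])

    def test_label_permutation_invariance(self):
        # permuting cluster ids inside any trial column before relabeling
        # leaves membership unchanged: the harmonization pass undoes it
        rng = np.random.default_rng(6)
        ref = np.repeat([0, 1, 2], 10)
        trials = []
        for _ in range(8):
            col = ref.copy()
            flip = rng.random(30) < 0.15
            col[flip] = rng.integers(0, 3, size=flip.sum())
            trials.append(col)
        rows = np.column_stack(trials)

        def score(assign):
            run = make_run(ref, assign)
            out, registry = relabel_trials(run)
            out = resolve_unmapped(run, out, registry)
            return membership_scores(run, relabeled=out).membership.to_numpy()

        base = score(rows)
        permuted = rows.copy()
        for t in range(rows.shape[1]):
            perm = rng.permutation(3)
            permuted[:, t] = perm[rows[:, t]]
        np.testing.assert_allclose(score(permuted), base)

    def test_entropy_and_kl_kinds(self):
        row = [0] * 7 + [2] * 3
        run = make_run(np.array([0]), np.array([row]))
        ent = membership_scores(run, relabeled=np.array([row]), kind="entropy")
        assert 0.0 < ent.membership.iloc[0] < 1.0
        kl = membership_scores(run, relabeled=np.array([row]), kind="kl")
        assert 0.0 < kl.membership.iloc[0] <= 1.0
        unan = make_run(np.array([0]), np.array([[0, 0, 0]]))
        for kind in ("entropy", "kl"):
            r = membership_scores(unan, relabeled=np.array([[0, 0, 0]]), kind=kind)
            assert r.membership.iloc[0] == pytest.approx(1.0, abs=1e-6)


class TestPipeline:
    @pytest.fixture(scope="class")
    def blobs(self):
        rng = np.random.default_rng(12)
        n_per, p = 60, 30
        a = rng.normal(0, 0.5, size=(n_per, p)) + np.r_[np.full(15, 8.0), np.zeros(15)]
        b = rng.normal(0, 0.5, size=(n_per, p)) + np.r_[np.zeros(15), np.full(15, 8.0)]
        counts = np.abs(np.vstack([a, b]))
        ds = cn.ExpressionDataset(
            counts=counts,
            cell_ids=np.array([f"c{i}" for i in range(2 * n_per)], dtype=object),
            gene_ids=np.array([f"g{j}" for j in range(p)], dtype=object),
        )
        return cn.normalize_log1p(ds)

    def test_separated_blobs_high_membership(self, blobs):
        res = cn.scallop_pipeline(
            blobs, ClusterParams(resolution=1.0, seed=0), n_trials=30, seed=1,
            n_top=30, n_comps=10, k=30,
        )
        assert (res.membership == 1.0).mean() >= 0.95

    def test_homogeneous_blob_lower_membership(self, blobs):
        rng = np.random.default_rng(13)
        counts = np.abs(rng.normal(5, 0.5, size=(120, 30)))
        ds = cn.ExpressionDataset(
            counts=counts,
            cell_ids=np.array([f"c{i}" for i in range(120)], dtype=object),
            gene_ids=np.array([f"g{j}" for j in range(30)], dtype=object),
        )
        ds = cn.normalize_log1p(ds)
        res = cn.scallop_pipeline(
            ds, ClusterParams(resolution=2.0, seed=0), n_trials=30, seed=1,
            n_top=30, n_comps=10, k=30,
        )
        two_blob = cn.scallop_pipeline(
            blobs, ClusterParams(resolution=1.0, seed=0), n_trials=30, seed=1,
            n_top=30, n_comps=10, k=30,
        )
        assert res.membership.mean() < two_blob.membership.mean()

    def test_pipeline_deterministic(self, blobs):
        kw = dict(n_trials=10, seed=4, n_top=30, n_comps=10, k=30)
        r1 = cn.scallop_pipeline(blobs, ClusterParams(1.0, 0), **kw)
        r2 = cn.scallop_pipeline(blobs, ClusterParams(1.0, 0), **kw)
        pd.testing.assert_series_equal(r1.membership, r2.membership)


class TestMultires:
    def test_single_value_grid_equals_pipeline(self, two_blob_dataset):
        ds = two_blob_dataset
        out = cn.multires_noise(ds, res_grid=[1.0], frac_cells=0.95, n_trials=10, seed=7,
                                n_top=40, n_comps=10, k=10)
        sub_seed = int(np.random.SeedSequence(entropy=7, spawn_key=(0,)).generate_state(1)[0] % 2**31)
        direct = cn.scallop_pipeline(
            ds, ClusterParams(1.0, sub_seed), frac_cells=0.95, n_trials=10, seed=sub_seed,
            n_top=40, n_comps=10, k=10,
        )
        np.testing.assert_allclose(out["membership"].to_numpy(), direct.membership.to_numpy())

    def test_default_grid_has_15_resolutions(self):
        grid = np.round(np.arange(0.1, 1.51, 0.1), 10)
        assert len(grid) == 15

    def test_empty_grid_errors(self, two_blob_dataset):
        with pytest.raises(ValueError):
            cn.multires_noise(two_blob_dataset, res_grid=[])


class TestAgingContrast:
    def test_identical_populations_null_delta(self):
        rng = np.random.default_rng(20)
        n, p = 80, 30
        base = np.abs(rng.normal(5, 1, size=(2 * n, p)))
        meta = pd.DataFrame(
            {
                "cell_type": ["T"] * (2 * n),
                "individual": ["m1"] * (2 * n),
                "age_group": ["young"] * n + ["old"] * n,
            },
            index=pd.Index([f"c{i}" for i in range(2 * n)], name="cell_id"),
        )
        ds = cn.ExpressionDataset(
            counts=base,
            cell_ids=np.array([f"c{i}" for i in range(2 * n)], dtype=object),
            gene_ids=np.array([f"g{j}" for j in range(p)], dtype=object),
            cell_meta=meta,
        )
        ds = cn.normalize_log1p(ds)
        tab = cn.aging_noise_contrast(
            ds, res_grid=[0.6, 1.0], n_trials=10, seed=3, n_top=30, n_comps=10, k=30
        )
        assert len(tab) == 1
        assert abs(tab["delta"].iloc[0]) < 0.2

    def test_missing_age_group_errors(self, two_blob_dataset):
        with pytest.raises(ValueError, match="age_group"):
            cn.aging_noise_contrast(two_blob_dataset)
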