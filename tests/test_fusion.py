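import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from icell.fusion import (
    InitSolution,
    SolverConfig,
    build_icell,
    build_icell_pair,
    fuse,
    fuse_pair,
    hard_cluster,
    init_svd,
    rse,
    update_g,
    update_s,
)
from icell.net_io import MultiplexNetworks
from icell.synthetic import simulate_multiplex


def block_k4_multiplex(layers: int = 3) -> MultiplexNetworks:
    """Three disjoint 4-cliques in every layer."""
    n = 12
    a = np.zeros((n, n))
    for b in range(3):
        for i in range(4 * b, 4 * b + 4):
            for j in range(4 * b, 4 * b + 4):
                if i != j:
                    a[i, j] = 1.0
    return MultiplexNetworks(
        gene_index=[f"g{i:02d}" for i in range(n)],
        matrices=[a.copy() for _ in range(layers)],
        layer_labels=[f"l{i}" for i in range(layers)],
    )


class TestInitSVD:
    def test_k2_single_layer_hand_value(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        mx = MultiplexNetworks(gene_index=["a", "b"], matrices=[a], layer_labels=["l"])
        col = init_svd(mx, 1).G_init.ravel()
        assert col == pytest.approx([2 ** -0.5, 2 ** -0.5])

    def test_non_negative(self):
        pm = simulate_multiplex(30, 3, 2, 0.4, 0.05, seed=0)
        g = init_svd(pm.multiplex, 5).G_init
        assert np.all(g >= 0)

    def test_rank_deficient_pads_with_warning(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        mx = MultiplexNetworks(
            gene_index=list("abcd"), matrices=[a], layer_labels=["l"]
        )
        with pytest.warns(RuntimeWarning, match="zero-padded"):
            g = init_svd(mx, 4).G_init
        assert np.all(g[:, 2:] == 0)


class TestUpdateS:
    def test_identity_g_recovers_adjacency(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, size=(5, 5)).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        s = update_s(a, np.eye(5))
        assert np.allclose(s, a, atol=1e-6)

    def test_zero_adjacency_gives_zero(self):
        assert np.allclose(update_s(np.zeros((4, 4)), np.eye(4)), 0.0)

    def test_one_hot_hand_example(self):
        g = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        s = update_s(a, g)
        assert s == pytest.approx(np.array([[0.5, 0.0], [0.0, 0.5]]), abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            update_s(np.zeros((3, 3)), np.zeros((4, 2)))


class TestUpdateG:
    def test_preserves_non_negativity(self):
        pm = simulate_multiplex(20, 2, 2, 0.5, 0.1, seed=1)
        rng = np.random.default_rng(1)
        g = rng.uniform(size=(20, 2))
        s_list = [update_s(a, g) for a in pm.multiplex.matrices]
        g2 = update_g(pm.multiplex, s_list, g)
        assert np.all(g2 >= 0)

    def test_exact_factorization_is_near_fixed_point(self):
        # A_i = G S_i G^T exactly, with strictly positive G
        rng = np.random.default_rng(2)
        g = rng.uniform(0.5, 1.0, size=(8, 2))
        s = np.array([[1.0, 0.2], [0.2, 0.8]])
        a = g @ s @ g.T
        np.fill_diagonal(a, 0.0)
        # zeroing the diagonal breaks exactness slightly; rebuild closure
        a = (a + a.T) / 2
        mx_like = MultiplexNetworks(
            gene_index=[f"g{i}" for i in range(8)], matrices=[a], layer_labels=["l"]
        )
        s_opt = update_s(a, g)
        before = rse(mx_like, g, [s_opt])
        g2 = update_g(mx_like, [s_opt], g)
        after = rse(mx_like, g2, [update_s(a, g2)])
        assert after <= before + 1e-10

    def test_monotone_descent_50_iterations(self):
        pm = simulate_multiplex(60, 4, 2, 0.3, 0.05, seed=3)
        result = fuse(pm.multiplex, SolverConfig(k=4, max_iter=50))
        trace = np.array(result.rse_trace)
        assert np.all(np.diff(trace) <= 1e-9)


class TestRSE:
    def test_exact_factorization_zero(self):
        mx = block_k4_multiplex(1)
        res = fuse(
            mx,
            SolverConfig(k=12, max_iter=1),
            init=InitSolution(G_init=np.eye(12), method="custom"),
        )
        assert res.final_rse < 1e-12

    def test_zero_factors_give_one(self):
        mx = block_k4_multiplex(2)
        g = np.zeros((12, 3))
        assert rse(mx, g, [np.zeros((3, 3))] * 2) == pytest.approx(1.0)

    def test_matches_elementwise_evaluation(self):
        rng = np.random.default_rng(4)
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        mx = MultiplexNetworks(
            gene_index=list("abc"), matrices=[a], layer_labels=["l"]
        )
        g = rng.uniform(size=(3, 2))
        s = rng.uniform(size=(2, 2))
        s = (s + s.T) / 2
        recon = g @ s @ g.T
        expected = sum(
            (a[i, j] - recon[i, j]) ** 2 for i in range(3) for j in range(3)
        ) / np.sum(a * a)
        assert rse(mx, g, [s]) == pytest.approx(expected)

    def test_all_zero_layers_rejected(self):
        mx = MultiplexNetworks(
            gene_index=list("ab"), matrices=[np.zeros((2, 2))], layer_labels=["l"]
        )
        with pytest.raises(ValueError):
            rse(mx, np.ones((2, 1)), [np.ones((1, 1))])


class TestFuse:
    def test_block_k4_converges_to_analytic_optimum(self):
        # best rank-3 symmetric factorization of three K4 blocks (zero
        # diagonals) is (3/4)J per block, with RSE exactly 1/4
        mx = block_k4_multiplex(3)
        res = fuse(mx, SolverConfig(k=3, max_iter=200))
        assert res.final_rse == pytest.approx(0.25, abs=1e-3)

    def test_planted_recovery_single_seed(self):
        pm = simulate_multiplex(150, 3, 3, 0.3, 0.02, seed=0)
        res = fuse(pm.multiplex, SolverConfig(k=3, max_iter=150))
        clustering = hard_cluster(res.G, pm.multiplex.gene_index)
        truth = [pm.truth_clusters[g] for g in pm.multiplex.gene_index]
        ari = adjusted_rand_score(truth, clustering.labels(pm.multiplex.gene_index))
        assert ari >= 0.9

    def test_deterministic_given_seed(self):
        pm = simulate_multiplex(40, 2, 2, 0.4, 0.05, seed=5)
        cfg = SolverConfig(k=2, max_iter=30, init="random", seed=11)
        r1 = fuse(pm.multiplex, cfg)
        r2 = fuse(pm.multiplex, cfg)
        assert np.array_equal(r1.G, r2.G)

    def test_s_symmetric_and_g_nonnegative(self):
        pm = simulate_multiplex(40, 3, 2, 0.4, 0.05, seed=6)
        res = fuse(pm.multiplex, SolverConfig(k=3, max_iter=40))
        assert np.all(res.G >= 0)
        for s in res.S:
            assert np.allclose(s, s.T)

    def test_flipped_orientation_not_monotone(self):
        # the update with the positive/negative parts of A G S swapped
        # (the printed orientation) loses the descent guarantee
        pm = simulate_multiplex(60, 4, 2, 0.3, 0.05, seed=0)
        res = fuse(
            pm.multiplex,
            SolverConfig(k=4, max_iter=50, update_orientation="flipped"),
        )
        trace = np.array(res.rse_trace)
        assert np.any(np.diff(trace) > 1e-9)


class TestBuildICell:
    def _factor_for_w(self, w: np.ndarray) -> np.ndarray:
        """G whose G G^T has the requested off-diagonal entries (the
        diagonal is irrelevant: build_icell zeroes it)."""
        shifted = w + np.eye(w.shape[0]) * (np.abs(w).sum() + 1.0)
        vals, vecs = np.linalg.eigh(shifted)
        assert np.all(vals > 0)
        return vecs * np.sqrt(vals)

    def test_three_node_hand_example(self):
        w = np.array([[0.0, 0.9, 0.5], [0.9, 0.0, 0.1], [0.5, 0.1, 0.0]])
        g = self._factor_for_w(w)
        icell = build_icell(g, ["a", "b", "c"], threshold_fraction=0.34)
        assert icell.network.edges == {("a", "b"), ("a", "c")}

    def test_full_fraction_keeps_all_positive_pairs(self):
        rng = np.random.default_rng(7)
        g = rng.uniform(0.1, 1.0, size=(6, 2))
        icell = build_icell(g, [f"g{i}" for i in range(6)], threshold_fraction=1.0)
        assert icell.network.n_edges == 15

    def test_one_hot_indicators_keep_within_cluster_edges(self):
        g = np.zeros((6, 2))
        g[:3, 0] = 1.0
        g[3:, 1] = 1.0
        icell = build_icell(g, [f"g{i}" for i in range(6)], threshold_fraction=0.5)
        for u, v in icell.network.edges:
            assert (u in {"g0", "g1", "g2"}) == (v in {"g0", "g1", "g2"})

    def test_symmetric_and_bounded_edge_count(self):
        pm = simulate_multiplex(60, 3, 2, 0.3, 0.05, seed=8)
        res = fuse(pm.multiplex, SolverConfig(k=3, max_iter=40))
        q = 0.05
        icell = build_icell(res.G, pm.multiplex.gene_index, threshold_fraction=q)
        n = 60
        assert icell.network.n_edges <= n * int(np.ceil(q * (n - 1)))


class TestFusePair:
    def test_mismatched_indexes_rejected(self):
        a = simulate_multiplex(10, 2, 1, 0.5, 0.1, seed=0).multiplex
        b = simulate_multiplex(12, 2, 1, 0.5, 0.1, seed=0).multiplex
        with pytest.raises(ValueError):
            fuse_pair(a, b, SolverConfig(k=2, max_iter=5))

    def test_identical_conditions_identical_icells(self):
        mx = simulate_multiplex(30, 3, 2, 0.4, 0.05, seed=9).multiplex
        r1, r2 = fuse_pair(mx, mx, SolverConfig(k=3, max_iter=30))
        assert np.array_equal(r1.G, r2.G)
        i1, i2 = build_icell_pair(r1.G, r2.G, mx.gene_index, 0.1)
        assert i1.network.edges == i2.network.edges


class TestHardCluster:
    def test_one_hot_rows_exact_labels(self):
        g = np.zeros((4, 2))
        g[0, 0] = g[1, 0] = 1.0
        g[2, 1] = g[3, 1] = 1.0
        c = hard_cluster(g, ["a", "b", "c", "d"])
        assert c.assignment == {"a": 1, "b": 1, "c": 2, "d": 2}

    def test_tie_goes_to_lowest_column(self):
        g = np.array([[0.5, 0.5]])
        c = hard_cluster(g, ["a"])
        assert c.assignment["a"] == 1

    def test_zero_row_warns_and_goes_to_cluster_one(self):
        g = np.array([[0.0, 0.0], [0.0, 1.0]])
        with pytest.warns(RuntimeWarning):
            c = hard_cluster(g, ["a", "b"])
        assert c.assignment["a"] == 1

    def test_agrees_with_per_row_argmax_scan(self):
        rng = np.random.default_rng(10)
        g = rng.uniform(size=(20, 4))
        genes = [f"g{i}" for i in range(20)]
        c = hard_cluster(g, genes)
        for i, gene in enumerate(genes):
            best = max(range(4), key=lambda j: g[i, j])
            assert c.assignment[gene] == best + 1
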