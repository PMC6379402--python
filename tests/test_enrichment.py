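import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from icell.enrichment import (
    bh_adjust,
    cluster_enrichment,
    depletion_p,
    empirical_permutation_p,
    fold_enrichment,
    gene_set_stats,
    hypergeom_enrichment_p,
)
from icell.fusion import Clustering
from icell.synthetic import simulate_annotations, simulate_multiplex


def brute_force_tail(x, n, k, m, upper):
    """Oracle: exact combinatorial sum with integer arithmetic."""
    denom = math.comb(m, n)
    rng = range(x, min(n, k) + 1) if upper else range(0, x + 1)
    total = sum(
        math.comb(k, i) * math.comb(m - k, n - i)
        for i in rng
        if n - i <= m - k
    )
    return total / denom


def random_tuples(count, seed, m_max=60):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < count:
        m = int(rng.integers(2, m_max + 1))
        n = int(rng.integers(1, m + 1))
        k = int(rng.integers(0, m + 1))
        lo = max(0, n - (m - k))
        hi = min(n, k)
        if hi < lo:
            continue
        x = int(rng.integers(lo, hi + 1))
        out.append((x, n, k, m))
    return out


class TestHypergeometricTails:
    def test_x_zero_gives_one(self):
        assert hypergeom_enrichment_p(0, 4, 5, 10) == 1.0

    def test_hand_example_enrichment(self):
        assert hypergeom_enrichment_p(4, 4, 5, 10) == pytest.approx(5 / 210, abs=1e-15)

    def test_hand_example_depletion(self):
        assert depletion_p(0, 4, 5, 10) == pytest.approx(5 / 210, abs=1e-15)

    def test_depletion_full_support_is_one(self):
        assert depletion_p(min(4, 5), 4, 5, 10) == 1.0

    def test_matches_brute_force_on_random_tuples(self):
        for x, n, k, m in random_tuples(200, seed=0):
            assert hypergeom_enrichment_p(x, n, k, m) == pytest.approx(
                brute_force_tail(x, n, k, m, upper=True), abs=1e-12
            )
            assert depletion_p(x, n, k, m) == pytest.approx(
                brute_force_tail(x, n, k, m, upper=False), abs=1e-12
            )

    def test_complementarity(self):
        for x, n, k, m in random_tuples(100, seed=1):
            if x == 0:
                continue
            total = hypergeom_enrichment_p(x, n, k, m) + depletion_p(x - 1, n, k, m)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_scipy_at_large_background(self):
        # independent route through scipy's survival function
        x, n, k, m = 40, 500, 1000, 20000
        assert hypergeom_enrichment_p(x, n, k, m) == pytest.approx(
            float(stats.hypergeom.sf(x - 1, m, k, n)), rel=1e-9
        )

    def test_bounds_violation_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment_p(6, 5, 5, 10)


class TestFoldEnrichment:
    def test_equal_frequency_is_one(self):
        assert fold_enrichment(2, 4, 5, 10) == pytest.approx(1.0)

    def test_hand_example(self):
        assert fold_enrichment(4, 4, 5, 10) == pytest.approx(2.0)

    def test_x_zero_is_zero(self):
        assert fold_enrichment(0, 4, 5, 10) == 0.0

    def test_zero_k_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(0, 4, 0, 10)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50).tolist()
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected.tolist())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, pvals):
        adj = bh_adjust(pvals)
        for raw, a in zip(pvals, adj):
            assert a >= raw - 1e-15
            assert a <= 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        direct = np.array(bh_adjust(p.tolist()))
        permuted = np.array(bh_adjust(p[perm].tolist()))
        inverse = np.empty(20)
        inverse[perm] = permuted
        assert np.allclose(direct, inverse)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestClusterEnrichment:
    def test_annotations_equal_clusters_full_coverage(self):
        pm = simulate_multiplex(60, 3, 1, 1.0, 0.0, seed=0)
        clustering = Clustering(assignment=pm.truth_clusters, k=3)
        terms = simulate_annotations(pm.truth_clusters, 1, coverage=1.0, noise=0.0)
        _, percent = cluster_enrichment(clustering, terms)
        assert percent == pytest.approx(100.0)

    def test_noisy_annotations_enriched_in_home_cluster(self):
        pm = simulate_multiplex(150, 3, 1, 1.0, 0.0, seed=1)
        clustering = Clustering(assignment=pm.truth_clusters, k=3)
        terms = simulate_annotations(
            pm.truth_clusters, 2, coverage=0.8, noise=0.02, seed=2
        )
        results, _ = cluster_enrichment(clustering, terms, alpha=0.05)
        for r in results:
            home = int(r.term.split("_")[1][1:])
            if int(r.set_id) == home:
                assert r.p_adjusted <= 0.05

    def test_empty_annotations_rejected(self):
        clustering = Clustering(assignment={"a": 1}, k=1)
        with pytest.raises(ValueError):
            cluster_enrichment(clustering, {})

    def test_unenriched_gene_counts_in_denominator(self):
        # g5's only annotation is spread evenly, so it cannot be enriched
        assignment = {f"g{i}": 1 if i < 3 else 2 for i in range(6)}
        clustering = Clustering(assignment=assignment, k=2)
        terms = {
            "t_home": {"g0", "g1", "g2"},
            "t_flat": {"g2", "g5"},
        }
        _, percent = cluster_enrichment(clustering, terms, alpha=0.05)
        annotated = {"g0", "g1", "g2", "g5"}
        assert percent <= 100.0 * (len(annotated) - 1) / len(annotated)

    def test_percent_monotone_in_alpha(self):
        pm = simulate_multiplex(90, 3, 1, 1.0, 0.0, seed=3)
        clustering = Clustering(assignment=pm.truth_clusters, k=3)
        terms = simulate_annotations(
            pm.truth_clusters, 2, coverage=0.6, noise=0.05, seed=4
        )
        percents = [
            cluster_enrichment(clustering, terms, alpha=a)[1]
            for a in (0.001, 0.05, 0.5)
        ]
        assert percents == sorted(percents)
        assert all(0.0 <= p <= 100.0 for p in percents)


class TestGeneSetStats:
    def test_disjoint_markers_rejected(self):
        with pytest.raises(ValueError, match="K = 0"):
            gene_set_stats({"a"}, {"a", "b"}, {"z"})

    def test_set_equals_background(self):
        res = gene_set_stats({"a", "b"}, {"a", "b"}, {"a"})
        assert res.fold == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_set_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            gene_set_stats({"q"}, {"a", "b"}, {"a"})

    def test_planted_fold_and_p(self):
        background = {f"g{i}" for i in range(1000)}
        markers = {f"g{i}" for i in range(50)}
        gene_set = {f"g{i}" for i in range(30)} | {f"g{i}" for i in range(100, 170)}
        res = gene_set_stats(gene_set, background, markers)
        assert res.X == 30 and res.N == 100 and res.K == 50 and res.M == 1000
        assert res.fold == pytest.approx(6.0)
        assert res.p_raw == pytest.approx(
            brute_force_tail(30, 100, 50, 1000, upper=True), rel=1e-9
        )
        assert res.direction == "enriched"


class TestEmpiricalPermutationP:
    @pytest.mark.parametrize(
        "r, n, expected", [(0, 1000, 1 / 1001), (99, 99, 1.0), (9, 99, 0.1)]
    )
    def test_formula(self, r, n, expected):
        assert empirical_permutation_p(r, n) == pytest.approx(expected)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            empirical_permutation_p(5, 4)
        with pytest.raises(ValueError):
            empirical_permutation_p(0, 0)
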