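import numpy as np
import pytest

from icell.net_io import (
    EdgeListParseError,
    GeneNetwork,
    align_networks,
    edge_jaccard,
    filter_to_anchor_layer,
    make_tissue_specific,
    read_edge_list,
    read_expression_table,
    read_gene_list,
    read_gmt,
    union_network,
    write_edge_list,
    write_expression_table,
    write_gene_list,
    write_gmt,
)
from icell.synthetic import random_gnp_network

from .conftest import make_random_network


class TestReadEdgeList:
    def test_dedup_and_self_loop(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nb\ta\na\ta\n")
        net = read_edge_list(p)
        assert set(net.nodes) == {"a", "b"}
        assert net.edges == {("a", "b")}

    def test_triangle(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a b\nb c\na c\n")
        net = read_edge_list(p)
        assert net.n_nodes == 3 and net.n_edges == 3

    def test_comments_and_blank_lines(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("# header\n\na\tb\n")
        assert read_edge_list(p).n_edges == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nsolo\n")
        with pytest.raises(EdgeListParseError, match=":2"):
            read_edge_list(p)

    def test_empty_file_is_empty_network(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("")
        net = read_edge_list(p)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_round_trip_preserves_sets(self, tmp_path):
        net = random_gnp_network(50, 0.1, seed=7)
        p = tmp_path / "rt.tsv"
        write_edge_list(net, p)
        back = read_edge_list(p)
        assert set(back.nodes) == set(net.nodes)
        assert back.edges == net.edges


class TestMakeTissueSpecific:
    def test_triangle_two_expressed(self, triangle):
        sub = make_tissue_specific(triangle, {"a", "b"})
        assert sub.nodes == ["a", "b"] and sub.edges == {("a", "b")}

    def test_superset_is_identity(self, triangle):
        sub = make_tissue_specific(triangle, {"a", "b", "c", "z"})
        assert sub.nodes == triangle.nodes and sub.edges == triangle.edges

    def test_matches_brute_force_filter(self):
        net = make_random_network(100, 0.1, seed=3)
        rng = np.random.default_rng(0)
        kept = {g for g in net.nodes if rng.random() < 0.5}
        sub = make_tissue_specific(net, kept)
        expected = sum(1 for u, v in net.edges if u in kept and v in kept)
        assert sub.n_edges == expected

    def test_idempotent(self):
        net = make_random_network(40, 0.2, seed=5)
        kept = set(net.nodes[::2])
        once = make_tissue_specific(net, kept)
        twice = make_tissue_specific(once, kept)
        assert once.nodes == twice.nodes and once.edges == twice.edges

    def test_empty_intersection(self, triangle):
        sub = make_tissue_specific(triangle, {"x"})
        assert sub.n_nodes == 0 and sub.n_edges == 0


class TestAlignNetworks:
    def test_identical_nets_identical_matrices(self, triangle):
        mx = align_networks([triangle, triangle])
        assert np.array_equal(mx.matrices[0], mx.matrices[1])

    def test_union_pads_missing_nodes(self):
        n1 = GeneNetwork.from_edges([("a", "b")])
        n2 = GeneNetwork.from_edges([("b", "c")])
        mx = align_networks([n1, n2], node_policy="union")
        assert mx.gene_index == ["a", "b", "c"]
        assert mx.matrices[0][mx.gene_index.index("c")].sum() == 0

    def test_intersection_empty_raises(self):
        n1 = GeneNetwork.from_edges([("a", "b")])
        n2 = GeneNetwork.from_edges([("c", "d")])
        with pytest.raises(ValueError, match="empty"):
            align_networks([n1, n2], node_policy="intersection")

    def test_row_sums_match_degree_sequences(self):
        nets = [make_random_network(30, 0.15, seed=s) for s in range(3)]
        mx = align_networks(nets, node_policy="union")
        for net, a in zip(nets, mx.matrices):
            assert np.array_equal(a, a.T)
            assert np.all(np.diag(a) == 0)
            deg = net.degree()
            for i, g in enumerate(mx.gene_index):
                assert a[i].sum() == deg.get(g, 0)

    def test_anchor_layer_filter(self):
        n1 = GeneNetwork.from_edges([("a", "b")], layer_label="ppi")
        n2 = GeneNetwork.from_edges([("a", "c"), ("b", "c")], layer_label="coex")
        filtered = filter_to_anchor_layer([n1, n2], anchor=0)
        assert set(filtered[1].nodes) == {"a", "b"}
        assert filtered[1].n_edges == 0


class TestEdgeJaccard:
    @pytest.mark.parametrize(
        "e1, e2, expected",
        [
            ([("a", "b"), ("b", "c")], [("a", "b"), ("b", "c")], 1.0),
            ([("a", "b")], [("c", "d")], 0.0),
            ([("a", "b"), ("b", "c")], [("a", "b"), ("c", "d")], 1 / 3),
        ],
    )
    def test_values(self, e1, e2, expected):
        n1 = GeneNetwork.from_edges(e1)
        n2 = GeneNetwork.from_edges(e2)
        assert edge_jaccard(n1, n2) == pytest.approx(expected)

    def test_empty_union_returns_zero(self):
        n = GeneNetwork.from_edges([], nodes=["a"])
        assert edge_jaccard(n, n) == 0.0


class TestUnionNetwork:
    def test_single_network_is_itself(self, triangle):
        u = union_network([triangle])
        assert set(u.nodes) == set(triangle.nodes) and u.edges == triangle.edges

    def test_disjoint_pairs(self):
        u = union_network(
            [GeneNetwork.from_edges([("a", "b")]), GeneNetwork.from_edges([("c", "d")])]
        )
        assert u.n_nodes == 4 and u.n_edges == 2

    def test_overlapping_triangles(self):
        t1 = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        t2 = GeneNetwork.from_edges([("b", "c"), ("c", "d"), ("b", "d")])
        u = union_network([t1, t2])
        assert u.n_nodes == 4 and u.n_edges == 5


class TestTables:
    def test_expression_round_trip(self, tmp_path):
        from icell.net_io import ExpressionProfile

        profile = ExpressionProfile(
            calls={"control": {"g1", "g2"}, "case": {"g2", "g3"}}
        )
        p = tmp_path / "expr.tsv"
        write_expression_table(profile, ["g1", "g2", "g3"], p)
        back = read_expression_table(p)
        assert back.calls == profile.calls

    def test_expression_bad_cell(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tt1\ng1\t2\n")
        with pytest.raises(ValueError, match="not in"):
            read_expression_table(p)

    def test_gmt_round_trip_skips_empty(self, tmp_path):
        p = tmp_path / "a.gmt"
        skipped = write_gmt({"t1": {"g1", "g2"}, "t2": set()}, p)
        assert skipped == ["t2"]
        assert read_gmt(p) == {"t1": {"g1", "g2"}}

    def test_gene_list_round_trip(self, tmp_path):
        p = tmp_path / "genes.txt"
        write_gene_list(["g1", "g2"], p)
        assert read_gene_list(p) == ["g1", "g2"]
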