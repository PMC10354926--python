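import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_connected_graph
from oracle_utils import floyd_warshall
from pacsi.io import ExpressionMatrix, GeneIdMapping
from pacsi.network import (InteractionNetwork, build_coexpression_network,
                           induce_module, largest_connected_component,
                           load_network, multi_source_distance_field,
                           write_edge_list)
from pacsi.signatures import GeneSignature


class TestLoadNetwork:
    def test_edge_list_dedup_and_self_loops(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a\tb\nb\ta\na\ta\n")
        net = load_network(p)
        assert net.n_nodes == 2 and net.n_edges == 1

    def test_psimitab_rows(self, tmp_path):
        cols = ["-"] * 13
        rows = [
            "\t".join(["uniprotkb:P1", "uniprotkb:P2"] + cols),
            "\t".join(["uniprotkb:P2", "uniprotkb:P3"] + cols),
            "\t".join(["uniprotkb:P3", "uniprotkb:P4"] + cols),
        ]
        p = tmp_path / "m.mitab"
        p.write_text("\n".join(rows) + "\n")
        net = load_network(p, format="psimitab")
        assert net.n_edges == 3
        assert set(net.nodes) == {"P1", "P2", "P3", "P4"}

    def test_psimitab_short_row_names_line(self, tmp_path):
        p = tmp_path / "bad.mitab"
        p.write_text("uniprotkb:P1\tuniprotkb:P2\n")
        with pytest.raises(ValueError, match="line 1"):
            load_network(p, format="psimitab")

    def test_disconnected_two_triangles(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("a\tb\nb\tc\nc\ta\nx\ty\ny\tz\nz\tx\n")
        net = load_network(p)
        assert net.n_nodes == 6 and net.n_edges == 6
        assert not net.is_lcc

    def test_row_permutation_invariance(self, tmp_path):
        lines = ["a\tb", "b\tc", "c\td", "d\ta", "e\tf"]
        p1, p2 = tmp_path / "n1.tsv", tmp_path / "n2.tsv"
        p1.write_text("\n".join(lines) + "\n")
        p2.write_text("\n".join(reversed(lines)) + "\n")
        n1, n2 = load_network(p1), load_network(p2)
        assert n1.n_nodes == n2.n_nodes and n1.n_edges == n2.n_edges
        assert set(map(frozenset, n1.graph.edges)) == \
            set(map(frozenset, n2.graph.edges))

    def test_round_trip_via_edge_list(self, tmp_path, path5):
        out = tmp_path / "out.tsv"
        write_edge_list(path5, out)
        again = load_network(out)
        assert set(map(frozenset, again.graph.edges)) == \
            set(map(frozenset, path5.graph.edges))


class TestLargestConnectedComponent:
    def test_bigger_component_wins(self, tmp_path):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("x", "y")])
        lcc = largest_connected_component(InteractionNetwork(g))
        assert set(lcc.nodes) == {"a", "b", "c"} and lcc.is_lcc

    def test_idempotent_on_connected(self, path5):
        lcc = largest_connected_component(path5)
        assert set(lcc.nodes) == set(path5.nodes)
        assert lcc.n_edges == path5.n_edges

    def test_tie_keeps_lexicographically_smallest(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        lcc = largest_connected_component(InteractionNetwork(g))
        assert set(lcc.nodes) == {"a", "b"}


class TestCoexpressionNetwork:
    def _em(self, arr, genes):
        return ExpressionMatrix(pd.DataFrame(
            arr, index=genes,
            columns=[f"c{j}" for j in range(arr.shape[1])]))

    def test_perfect_correlation_gives_edge(self):
        x = np.linspace(1, 10, 10)
        m = self._em(np.vstack([x, 2 * x]), ["G1", "G2"])
        net = build_coexpression_network(m)
        assert net.graph.has_edge("G1", "G2")

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 1, size=20)
        m = self._em(np.vstack([x, x * 3, np.full(20, 7.0)]),
                     ["G1", "G2", "FLAT"])
        net = build_coexpression_network(m)
        assert "FLAT" not in set(net.nodes)

    def test_too_few_cells(self):
        m = self._em(np.ones((2, 2)) + np.eye(2), ["G1", "G2"])
        with pytest.raises(ValueError, match="at least 3 cells"):
            build_coexpression_network(m)

    def test_gene_universe_restricts_nodes(self):
        rng = np.random.default_rng(6)
        m = self._em(rng.normal(10, 2, size=(5, 30)),
                     [f"G{i}" for i in range(5)])
        net = build_coexpression_network(m, alpha=0.9,
                                         gene_universe=["G0", "G1", "G2"])
        assert set(net.nodes) <= {"G0", "G1", "G2"}


class TestInduceModule:
    def test_intersection(self, path5):
        sig = GeneSignature("cell1", ["a", "b", "q"])
        mod = induce_module(sig, path5)
        assert mod.nodes == frozenset({"a", "b"}) and mod.original_size == 3

    def test_full_containment(self, path5):
        mod = induce_module(GeneSignature("cell1", ["c", "d"]), path5)
        assert mod.size == 2

    def test_disjoint_gives_empty_module(self, path5):
        mod = induce_module(GeneSignature("cell1", ["q", "r"]), path5)
        assert mod.size == 0

    def test_mapping_translates_ids(self, path5):
        mapping = GeneIdMapping([("TP53", "a"), ("MYC", "b")])
        mod = induce_module(GeneSignature("cell1", ["TP53", "MYC", "EGFR"]),
                            path5, mapping)
        assert mod.nodes == frozenset({"a", "b"})

    def test_requires_lcc(self, path5):
        net = InteractionNetwork(path5.graph, is_lcc=False)
        with pytest.raises(ValueError, match="largest connected component"):
            induce_module(GeneSignature("cell1", ["a"]), net)


class TestDistanceField:
    def test_path_field(self, path5):
        mod = induce_module(GeneSignature("s", ["a", "b"]), path5)
        field = multi_source_distance_field(path5, mod)
        assert {n: field[n] for n in "abcde"} == \
            {"a": 0, "b": 0, "c": 1, "d": 2, "e": 3}

    def test_all_nodes_module_is_zero(self, path5):
        mod = induce_module(GeneSignature("s", list("abcde")), path5)
        field = multi_source_distance_field(path5, mod)
        assert field.distances.max() == 0

    def test_star_center(self):
        g = nx.star_graph(6)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = InteractionNetwork(g, is_lcc=True)
        mod = induce_module(GeneSignature("s", ["n0"]), net)
        field = multi_source_distance_field(net, mod)
        assert sorted(field.distances.tolist()) == [0] + [1] * 6

    def test_empty_module_raises(self, path5):
        mod = induce_module(GeneSignature("s", ["zz"]), path5)
        with pytest.raises(ValueError, match="no network support"):
            multi_source_distance_field(path5, mod)

    def test_matches_pointwise_minimum_of_single_source(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            net = random_connected_graph(rng)
            apsp = floyd_warshall(net.nodes, list(net.graph.edges))
            size = int(rng.integers(1, min(5, net.n_nodes) + 1))
            picks = list(rng.choice(net.nodes, size=size, replace=False))
            mod = induce_module(GeneSignature("s", picks), net)
            field = multi_source_distance_field(net, mod)
            for v in net.nodes:
                assert field[v] == min(apsp[s][v] for s in picks)

    def test_distances_bounded_and_adjacent_consistent(self, path5):
        mod = induce_module(GeneSignature("s", ["c"]), path5)
        field = multi_source_distance_field(path5, mod)
        assert field.distances.max() <= path5.n_nodes - 1
        for u, v in path5.graph.edges:
            assert abs(field[u] - field[v]) <= 1
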