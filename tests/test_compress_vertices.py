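"""Vertex-set compression: dl-sequences, subset selection, full runs."""

from itertools import combinations

import networkx as nx
import pytest

from gusm import (
    LabeledGraph,
    compress_edge,
    compress_vertices,
    concatenate,
    contract_subset_class,
    dl_less,
    dl_sequence,
    enumerate_connected_subsets,
    fig1_like,
    fig2_like,
    incompressible_star,
    permuted_copy,
    select_vertices,
)


def dl_displays(dl):
    return [(d, l.display) for d, l in dl]


class TestDLSequence:
    def test_a_a_b_path(self):
        g = LabeledGraph.build(
            {"x": "a", "y": "a", "z": "b"}, [("x", "y"), ("y", "z")]
        )
        assert dl_displays(dl_sequence(g, {"x", "y", "z"})) == [
            (2, "a"), (1, "b"), (1, "a")
        ]

    def test_single_edge(self):
        g = LabeledGraph.build({"u": "a", "v": "b"}, [("u", "v")])
        assert dl_displays(dl_sequence(g, {"u", "v"})) == [(1, "b"), (1, "a")]

    def test_distinct_paths_can_share_a_dl_sequence(self):
        abab = LabeledGraph.build(
            {"1": "a", "2": "b", "3": "a", "4": "b"},
            [("1", "2"), ("2", "3"), ("3", "4")],
        )
        aabb = LabeledGraph.build(
            {"1": "a", "2": "a", "3": "b", "4": "b"},
            [("1", "2"), ("2", "3"), ("3", "4")],
        )
        want = [(2, "b"), (2, "a"), (1, "b"), (1, "a")]
        assert dl_displays(dl_sequence(abab, {"1", "2", "3", "4"})) == want
        assert dl_displays(dl_sequence(aabb, {"1", "2", "3", "4"})) == want

    def test_degrees_count_only_induced_edges(self, triangle):
        # u has degree 2 in the triangle but 1 within the subset {u, v}
        assert [d for d, _ in dl_sequence(triangle, {"u", "v"})] == [1, 1]

    def test_disconnected_subset_rejected(self):
        g = LabeledGraph.build({"u": "a", "v": "a", "w": "a"}, [("u", "v")])
        with pytest.raises(ValueError):
            dl_sequence(g, {"u", "w"})


class TestDLLess:
    def test_last_element_decides(self, path3):
        a = dl_sequence(path3, {"v1", "v2", "v3"})
        g2 = LabeledGraph.build(
            {"v1": "x", "v2": "x", "v3": "y"}, [("v1", "v2"), ("v2", "v3")]
        )
        b = dl_sequence(g2, {"v1", "v2", "v3"})
        # ((2,x),(1,x),(1,x)) < ((2,x),(1,y),(1,x))
        assert dl_less(a, b)
        assert not dl_less(b, a)

    def test_irreflexive(self, path3):
        a = dl_sequence(path3, {"v1", "v2", "v3"})
        assert not dl_less(a, a)

    def test_length_mismatch_rejected(self, path3):
        a = dl_sequence(path3, {"v1", "v2"})
        b = dl_sequence(path3, {"v1", "v2", "v3"})
        with pytest.raises(ValueError):
            dl_less(a, b)

    def test_trichotomy_over_small_enumeration(self, random_graphs):
        g = random_graphs[4]
        subs = list(enumerate_connected_subsets(g, 3))[:15]
        dls = [dl_sequence(g, s) for s in subs]
        for a in dls:
            for b in dls:
                lt, gt = dl_less(a, b), dl_less(b, a)
                eq = [(d, l.ordinal) for d, l in a] == [
                    (d, l.ordinal) for d, l in b
                ]
                assert [lt, gt, eq].count(True) == 1


class TestEnumerateConnectedSubsets:
    def test_triangle_counts(self, triangle):
        assert len(enumerate_connected_subsets(triangle, 2)) == 3
        assert len(enumerate_connected_subsets(triangle, 3)) == 1

    def test_m_below_two_rejected(self, triangle):
        with pytest.raises(ValueError):
            enumerate_connected_subsets(triangle, 1)

    def test_matches_brute_force(self):
        from conftest import make_random_graphs

        for g in make_random_graphs(6, seed0=50, max_n=10, max_m=16):
            for m in (2, 3, 4):
                brute = {
                    frozenset(c)
                    for c in combinations(g.vertices(), m)
                    if nx.is_connected(nx.Graph(g.nx.subgraph(c)))
                }
                assert enumerate_connected_subsets(g, m) == brute


class TestSelectVertices:
    def test_fig2_has_no_eligible_pair(self):
        assert select_vertices(fig2_like(), 2) is None

    def test_fig2_selects_abb_paths_at_m3(self):
        cls, dl = select_vertices(fig2_like(), 3)
        assert dl_displays(dl) == [(2, "a"), (1, "b"), (1, "b")]
        assert cls.count == 2
        assert not set.intersection(*(set(m) for m in cls.members))

    def test_single_edge_graph_pair_class(self):
        g = LabeledGraph.build({"u": "a", "v": "b"}, [("u", "v")])
        cls, dl = select_vertices(g, 2)
        assert dl_displays(dl) == [(1, "b"), (1, "a")]
        assert cls.members == (frozenset({"u", "v"}),)


class TestContractSubsetClass:
    def test_fig1_aab_subsets_leave_no_self_loop(self):
        g = fig1_like()
        cls, dl = select_vertices(g, 3)
        _, out = contract_subset_class(g, cls)
        assert not out.has_self_loop()

    def test_fig2_contraction_gives_two_abb_vertices(self):
        g = fig2_like()
        cls, _ = select_vertices(g, 3)
        rule, out = contract_subset_class(g, cls)
        labels = sorted(out.vertex_labels().values())
        assert labels == ["abb", "abb", "c"]
        assert out.number_of_edges() == 4
        assert rule.new_label.display == "abb"

    def test_triangle_contracts_to_single_vertex(self, triangle):
        cls, _ = select_vertices(triangle, 3)
        _, out = contract_subset_class(triangle, cls)
        assert out.number_of_vertices() == 1
        assert out.number_of_edges() == 0


class TestCompressVertices:
    def test_m_below_two_rejected(self, triangle):
        with pytest.raises(ValueError):
            compress_vertices(triangle, 1)

    def test_equivalent_to_compress_edge_at_m2(self, random_graphs):
        for g in random_graphs:
            e = compress_edge(g)
            v = compress_vertices(g, 2)
            assert v.size == e.size
            edge_bodies = [
                tuple(l.ordinal for l in r.body) for r in e.rules
            ]
            pair_bodies = [
                tuple(l.ordinal for _, l in r.body) for r in v.rules
            ]
            assert edge_bodies == pair_bodies

    def test_fig2_first_rule(self):
        res = compress_vertices(fig2_like(), 3)
        assert res.rules[0].body_display()[0] == [2, "a"]
        assert res.rules[0].body_display() == [[2, "a"], [1, "b"], [1, "b"]]

    def test_star_fully_contracts_at_m4(self):
        res = compress_vertices(incompressible_star(3), M=4)
        assert res.n_rules == 1
        assert res.size == 1
        assert len(res.rules[0].body) == 4

    def test_star_stalls_at_m3(self):
        # the whole star has 4 vertices; with M = 3 nothing is eligible
        res = compress_vertices(incompressible_star(3), M=3)
        assert res.n_rules == 0
        assert res.size == 3

    def test_isomorphism_invariance(self, random_graphs):
        for i, g in enumerate(random_graphs[:6]):
            ref = compress_vertices(g, 3)
            for s in range(3):
                res = compress_vertices(permuted_copy(g, 31 * i + s), 3)
                assert res.rule_bodies() == ref.rule_bodies()
                assert res.size == ref.size

    def test_lockstep_self_similarity(self, random_graphs):
        for g in random_graphs[:8]:
            r = compress_vertices(g, 3)
            assert (
                compress_vertices(concatenate(g, g), 3).size
                == r.n_rules + 2 * r.residual_edges
            )

    def test_every_rule_removes_at_least_one_edge(self, random_graphs):
        for g in random_graphs[:8]:
            res = compress_vertices(g, 3)
            assert res.n_rules <= g.number_of_edges()
            assert res.size <= g.number_of_edges()
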