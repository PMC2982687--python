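"""Edge-contraction compression: classes, selection, contraction, full runs."""

import pytest

from gusm import (
    LabeledGraph,
    build_edge_classes,
    compress_edge,
    concatenate,
    contract_edge_class,
    compressible_matching,
    fig1_like,
    incompressible_star,
    permuted_copy,
    select_edge_class,
)
from gusm.compress_edge import EdgeClass, _classes_of
from gusm.grammar import Run


def class_by_displays(classes):
    return {tuple(l.display for l in c.pair): c for c in classes}


class TestBuildEdgeClasses:
    def test_fig1_eligible_classes(self):
        classes = class_by_displays(build_edge_classes(fig1_like()))
        # the 4-edge ('b','a') class overlaps and must be absent
        assert ("b", "a") not in classes
        assert len(classes[("a", "a")].members) == 2
        assert len(classes[("b", "b")].members) == 1
        assert len(classes[("c", "a")].members) == 1
        assert set(classes) == {("a", "a"), ("b", "b"), ("c", "a")}

    def test_star_has_no_eligible_class(self):
        assert build_edge_classes(incompressible_star(3)) == []

    def test_perfect_matching_is_one_class(self):
        classes = build_edge_classes(compressible_matching(5))
        assert len(classes) == 1
        assert classes[0].count == 5

    def test_parallel_copies_make_class_ineligible(self):
        g = LabeledGraph.build({"u": "a", "v": "b"})
        g.add_edge("u", "v")
        g.add_edge("u", "v")
        assert build_edge_classes(g) == []

    def test_self_loops_are_never_candidates(self):
        g = LabeledGraph.build({"u": "a", "v": "a"}, [("u", "v")])
        g.add_edge("u", "u")
        classes = build_edge_classes(g)
        assert len(classes) == 1
        assert classes[0].members == (("u", "v"),) or classes[0].members == (
            ("v", "u"),
        )


class TestSelectEdgeClass:
    def test_fig1_selects_the_disjoint_aa_class(self):
        chosen = select_edge_class(build_edge_classes(fig1_like()))
        assert tuple(l.display for l in chosen.pair) == ("a", "a")

    def test_bag_breaks_count_ties(self):
        # ('aa','b') with s = {a,a,b} beats ('b','b') with s = {b,b}
        run = Run(LabeledGraph.build({"x": "a", "y": "b"}))
        a, b = run.order.get("a"), run.order.get("b")
        aa = run.order.derive(run.order.union_bags(a, a))
        c1 = EdgeClass(pair=(aa, b), members=(("p", "q"),),
                       bag=run.order.union_bags(aa, b))
        c2 = EdgeClass(pair=(b, b), members=(("r", "s"),),
                       bag=run.order.union_bags(b, b))
        assert select_edge_class([c1, c2]) is c1

    def test_single_class_returned(self):
        classes = build_edge_classes(compressible_matching(2))
        assert select_edge_class(classes) is classes[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_edge_class([])


class TestContractEdgeClass:
    def test_single_edge_contracts_to_one_vertex(self):
        g = LabeledGraph.build({"u": "a", "v": "b"}, [("u", "v")])
        rule, out = contract_edge_class(g, ("b", "a"))
        assert out.number_of_vertices() == 1
        assert out.number_of_edges() == 0
        assert rule.new_label.display == "ab"

    def test_fig1_contraction_gives_5_vertices_6_edges(self):
        _, out = contract_edge_class(fig1_like(), ("a", "a"))
        assert out.number_of_vertices() == 5
        assert out.number_of_edges() == 6
        assert sorted(out.vertex_labels().values()) == [
            "aa", "aa", "b", "b", "c"
        ]

    def test_triangle_contraction_creates_parallel_edges(self, triangle):
        _, out = contract_edge_class(triangle, ("c", "a"))
        assert out.number_of_vertices() == 2
        assert out.number_of_edges() == 2
        (u, v), (x, y) = out.edges()
        assert {u, v} == {x, y} and u != v  # two parallel edges

    def test_absent_class_rejected(self, triangle):
        with pytest.raises(ValueError):
            contract_edge_class(triangle, ("a", "a"))


class TestCompressEdge:
    def test_all_distinct_labels_give_size_equal_edges(self, random_graphs):
        g = random_graphs[3]
        distinct = LabeledGraph.build(
            {v: f"L{i}" for i, v in enumerate(g.vertices())}, g.edges()
        )
        res = compress_edge(distinct)
        assert res.size == distinct.number_of_edges()

    def test_star_is_incompressible(self):
        res = compress_edge(incompressible_star(3))
        assert res.n_rules == 0
        assert res.size == 3

    def test_matching_compresses_to_one_rule(self):
        for k in (2, 5):
            res = compress_edge(compressible_matching(k))
            assert res.n_rules == 1
            assert res.size == 1

    def test_fig1_run(self):
        res = compress_edge(fig1_like())
        assert [r.body_display() for r in res.rules] == [
            ["a", "a"], ["b", "b"], ["aa", "c"]
        ]
        assert res.size == res.n_rules + res.residual_edges

    def test_input_not_modified(self):
        g = fig1_like()
        before = (g.vertex_labels(), g.edge_multiset())
        compress_edge(g)
        assert (g.vertex_labels(), g.edge_multiset()) == before

    def test_size_bounded_by_edge_count(self, random_graphs):
        for g in random_graphs:
            assert compress_edge(g).size <= g.number_of_edges()

    def test_isomorphism_invariance(self, random_graphs):
        for i, g in enumerate(random_graphs[:8]):
            ref = compress_edge(g)
            for s in range(5):
                res = compress_edge(permuted_copy(g, seed=97 * i + s))
                assert res.rule_bodies() == ref.rule_bodies()
                assert res.size == ref.size

    def test_concatenation_is_symmetric(self, random_graphs):
        g1, g2 = random_graphs[0], random_graphs[1]
        r12 = compress_edge(concatenate(g1, g2))
        r21 = compress_edge(concatenate(g2, g1))
        assert r12.rule_bodies() == r21.rule_bodies()
        assert r12.size == r21.size

    def test_lockstep_self_similarity(self, random_graphs):
        for g in random_graphs[:10]:
            r = compress_edge(g)
            assert (
                compress_edge(concatenate(g, g)).size
                == r.n_rules + 2 * r.residual_edges
            )
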