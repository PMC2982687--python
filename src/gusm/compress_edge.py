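"""Deterministic compression by iterated contraction of identical edges.

Each iteration partitions the edges by their (descending) endpoint-label
pair, keeps only the classes whose edges are pairwise vertex-disjoint, and
contracts the unique class selected by: largest class first, then smallest
label bag of the pair, then smallest label pair.  Because every choice is a
function of labels and structure alone, two isomorphic graphs are compressed
into identical rule sequences and sizes — the property that selection by
maximum-cardinality matching (GRAPHITOUR) lacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .graph import LabeledGraph
from .grammar import EDGE, CompressionResult, Rule, Run
from .labels import Label, LabelOrder


@dataclass(frozen=True)
class EdgeClass:
    """All edges whose endpoint labels equal ``pair`` (pair sorted with
    l1 >= l2), together with the bag s(l1) ⊎ s(l2) used for tie-breaking."""

    pair: tuple[Label, Label]
    members: tuple[tuple[str, str], ...]
    bag: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.members)


def _classes_of(run: Run) -> list[EdgeClass]:
    """Eligible edge classes of the working graph.

    Self-loops are never candidates (a contracted edge needs two distinct
    endpoints).  A class is eligible only if no two of its edges share a
    vertex; parallel copies of the same vertex pair therefore make their
    class ineligible.
    """
    groups: dict[tuple[int, int], list[tuple[str, str]]] = {}
    pairs: dict[tuple[int, int], tuple[Label, Label]] = {}
    for u, v, _ in run.graph.edges(keys=True):
        if u == v:
            continue
        lu, lv = run.label_of(u), run.label_of(v)
        if lu < lv:
            lu, lv = lv, lu
            u, v = v, u
        key = (lu.ordinal, lv.ordinal)
        groups.setdefault(key, []).append((u, v))
        pairs.setdefault(key, (lu, lv))
    out = []
    for key, members in groups.items():
        endpoints = [x for e in members for x in e]
        if len(set(endpoints)) != len(endpoints):
            continue  # two members share a vertex
        l1, l2 = pairs[key]
        out.append(
            EdgeClass(
                pair=(l1, l2),
                members=tuple(members),
                bag=run.order.union_bags(l1, l2),
            )
        )
    return out


def build_edge_classes(g: LabeledGraph) -> list[EdgeClass]:
    """Eligible edge classes of a graph (fresh label order per call)."""
    return _classes_of(Run(g))


def select_edge_class(classes: Sequence[EdgeClass]) -> EdgeClass:
    """Unique selection among eligible classes.

    Largest class wins; ties go to the smallest label bag of the endpoint
    pair, then to the smaller (descending-sorted) label pair itself.  The
    last tie-break always resolves because class keys are distinct pairs.
    """
    if not classes:
        raise ValueError("no eligible edge class to select from")
    return min(
        classes,
        key=lambda c: (-c.count, c.bag, tuple(l.ordinal for l in c.pair)),
    )


def _contract_class(run: Run, cls: EdgeClass) -> Rule:
    for u, v in cls.members:
        if not run.graph.has_edge(u, v):
            raise ValueError(f"member edge ({u!r}, {v!r}) absent from graph")
    l1, l2 = cls.pair
    new = run.new_label([l1, l2])
    rule = Rule(new_label=new, kind=EDGE, body=(l1, l2))
    run.contract_members(
        [frozenset(e) for e in cls.members], new, keep_internal_as_loops=True
    )
    run.rules.append(rule)
    return rule


def contract_edge_class(
    g: LabeledGraph, cls_pair: tuple[str, str]
) -> tuple[Rule, LabeledGraph]:
    """Contract the eligible class with endpoint-label displays ``cls_pair``.

    Convenience one-shot form: builds the label order for ``g``, finds the
    class, contracts it, and returns the rule plus the contracted graph.
    """
    run = Run(g)
    want = tuple(
        sorted((run.order.get(cls_pair[0]), run.order.get(cls_pair[1])),
               reverse=True)
    )
    for cls in _classes_of(run):
        if cls.pair == want:
            rule = _contract_class(run, cls)
            return rule, run.result("edge").residual
    raise ValueError(f"no eligible edge class with labels {cls_pair!r}")


def compress_edge(g: LabeledGraph) -> CompressionResult:
    """Run the full edge-contraction compressor on ``g``.

    Iterates until no edges remain or no eligible class exists (e.g. only
    self-loops or fully overlapping classes are left).  The input graph is
    not modified.
    """
    run = Run(g)
    while run.graph.number_of_edges() > 0:
        classes = _classes_of(run)
        if not classes:
            break
        _contract_class(run, select_edge_class(classes))
    return run.result("edge")
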