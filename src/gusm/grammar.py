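"""Contraction rules, compression results, and shared run machinery.

A compression run rewrites the input graph by repeatedly contracting a
selected set of identical pieces, recording one grammar rule per contraction.
The pair (ordered rule list R, residual graph G_c) is the compressed
representation and its size C = |R| + |E_c| stands in for the Kolmogorov
complexity of the graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import networkx as nx

from .graph import LabeledGraph
from .labels import Label, LabelOrder

# A dl-sequence: non-increasing (within-set degree, label) pairs.
DLSequence = Tuple[Tuple[int, Label], ...]

EDGE = "edge"
VERTEX_SET = "vertex_set"


@dataclass(frozen=True)
class Rule:
    """One contraction record: ``new_label <- body``.

    ``body`` is an ordered label pair ``(l1, l2)`` with ``l1 >= l2`` for an
    edge contraction, or a dl-sequence for a vertex-set contraction.
    """

    new_label: Label
    kind: str
    body: tuple

    def body_key(self) -> tuple:
        """Body reduced to ordinals — comparable across runs on isomorphic
        inputs, since original ordinals depend only on the label set."""
        if self.kind == EDGE:
            return tuple(l.ordinal for l in self.body)
        return tuple((d, l.ordinal) for d, l in self.body)

    def body_display(self) -> list:
        if self.kind == EDGE:
            return [l.display for l in self.body]
        return [[d, l.display] for d, l in self.body]

    def to_json(self) -> str:
        return json.dumps(
            {"new": self.new_label.display, "kind": self.kind,
             "body": self.body_display()},
            ensure_ascii=False,
        )


@dataclass
class CompressionResult:
    """Ordered rules, residual graph, and the compression size C."""

    rules: list[Rule]
    residual: LabeledGraph
    method: str = "edge"

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def residual_edges(self) -> int:
        return self.residual.number_of_edges()

    @property
    def size(self) -> int:
        """C(G) = |R| + |E_c| (residual edges counted with multiplicity)."""
        return len(self.rules) + self.residual.number_of_edges()

    def rule_bodies(self) -> list[tuple]:
        return [r.body_key() for r in self.rules]

    def rules_jsonl(self) -> str:
        return "\n".join(r.to_json() for r in self.rules) + ("\n" if self.rules else "")


class Run:
    """Mutable working state of one compression run.

    Holds the working multigraph (node attribute ``lab`` is a
    :class:`~gusm.labels.Label`), the label registry, and the rules emitted
    so far.  Fresh vertex ids are minted with a counter; ids never influence
    any algorithmic choice.
    """

    def __init__(self, g: LabeledGraph):
        self.order = LabelOrder(g.vertex_labels().values())
        self.graph = nx.MultiGraph()
        labels = g.vertex_labels()
        for vid in g.vertices():
            self.graph.add_node(vid, lab=self.order.get(labels[vid]))
        for u, v in g.edges():
            self.graph.add_edge(u, v)
        self.rules: list[Rule] = []
        self._fresh = 0

    def label_of(self, vid: str) -> Label:
        return self.graph.nodes[vid]["lab"]

    def fresh_id(self) -> str:
        self._fresh += 1
        return f"+{self._fresh}"

    def new_label(self, parts: Sequence[Label]) -> Label:
        return self.order.derive(self.order.union_bags(*parts))

    def contract_members(
        self,
        members: Iterable[frozenset[str] | tuple[str, ...]],
        new_label: Label,
        *,
        keep_internal_as_loops: bool = False,
    ) -> None:
        """Replace each member vertex set by one fresh vertex.

        All edges internal to a member disappear with it, except that in
        edge-contraction mode (``keep_internal_as_loops``) exactly one
        internal edge is consumed per member and any further internal edge
        survives as a self-loop on the new vertex.  Edges leaving a member
        are re-attached to its new vertex; an edge joining two different
        members becomes an edge between the two new vertices (members are
        pairwise disjoint, so the rewrite is well defined).
        """
        G = self.graph
        mapping: dict[str, str] = {}
        member_of: dict[str, int] = {}
        new_ids: list[str] = []
        for idx, mem in enumerate(members):
            nid = self.fresh_id()
            new_ids.append(nid)
            for v in mem:
                if v not in G:
                    raise ValueError(f"stale member vertex {v!r}")
                mapping[v] = nid
                member_of[v] = idx
        consumed: set[int] = set()
        kept: list[tuple[str, str]] = []
        for u, v, _ in G.edges(keys=True):
            iu, iv = member_of.get(u), member_of.get(v)
            if iu is None and iv is None:
                continue  # untouched edge, stays in place
            if iu is not None and iu == iv:
                # internal to one member
                if keep_internal_as_loops:
                    if iu not in consumed:
                        consumed.add(iu)  # the contracted edge itself
                    else:
                        kept.append((mapping[u], mapping[v]))  # self-loop
                continue
            kept.append((mapping.get(u, u), mapping.get(v, v)))
        G.remove_nodes_from(mapping)
        for nid in new_ids:
            G.add_node(nid, lab=new_label)
        for u, v in kept:
            G.add_edge(u, v)

    def result(self, method: str) -> CompressionResult:
        residual = LabeledGraph()
        for vid, data in self.graph.nodes(data=True):
            residual.add_vertex(vid, data["lab"].display)
        for u, v, _ in self.graph.edges(keys=True):
            residual.add_edge(u, v)
        return CompressionResult(list(self.rules), residual, method=method)
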