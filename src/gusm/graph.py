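"""Node-labeled undirected multigraphs: the object being compressed.

A :class:`LabeledGraph` is an undirected multigraph whose vertices carry
string labels.  Vertex ids are opaque strings used only for bookkeeping: every
algorithmic decision downstream depends on labels and structure alone, which
is what makes compression invariant under vertex renaming.  Parallel edges
and self-loops are representable because contraction can create both.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Iterator, Mapping, Tuple

import networkx as nx


class LabeledGraph:
    """Undirected multigraph with one string label per vertex."""

    def __init__(self) -> None:
        self._g = nx.MultiGraph()

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        vertices: Mapping[str, str] | Iterable[Tuple[str, str]],
        edges: Iterable[Tuple[str, str]] = (),
    ) -> "LabeledGraph":
        """Build a graph from ``{id: label}`` (or id/label pairs) and edges."""
        g = cls()
        items = vertices.items() if isinstance(vertices, Mapping) else vertices
        for vid, label in items:
            g.add_vertex(vid, label)
        for u, v in edges:
            g.add_edge(u, v)
        return g

    def add_vertex(self, vid: str, label: str) -> None:
        if vid in self._g:
            raise ValueError(f"duplicate vertex id {vid!r}")
        self._g.add_node(vid, label=str(label))

    def add_edge(self, u: str, v: str) -> None:
        for x in (u, v):
            if x not in self._g:
                raise KeyError(f"edge references undeclared vertex {x!r}")
        self._g.add_edge(u, v)

    def copy(self) -> "LabeledGraph":
        out = LabeledGraph()
        out._g = self._g.copy()
        return out

    # -- inspection -------------------------------------------------------

    @property
    def nx(self) -> nx.MultiGraph:
        """The underlying :class:`networkx.MultiGraph` (shared, not a copy)."""
        return self._g

    def vertices(self) -> list[str]:
        return list(self._g.nodes)

    def vertex_labels(self) -> dict[str, str]:
        return {v: d["label"] for v, d in self._g.nodes(data=True)}

    def label_of(self, vid: str) -> str:
        return self._g.nodes[vid]["label"]

    def edges(self) -> list[Tuple[str, str]]:
        return [(u, v) for u, v, _ in self._g.edges(keys=True)]

    def number_of_vertices(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def label_set(self) -> set[str]:
        return {d["label"] for _, d in self._g.nodes(data=True)}

    def has_self_loop(self) -> bool:
        return any(u == v for u, v in self.edges())

    def __contains__(self, vid: str) -> bool:
        return vid in self._g

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<LabeledGraph |V|={self.number_of_vertices()} "
            f"|E|={self.number_of_edges()}>"
        )

    # -- comparison -------------------------------------------------------

    def edge_multiset(self) -> Counter:
        """Multiset of edges as unordered id pairs (self-loops included)."""
        return Counter(tuple(sorted((u, v))) for u, v in self.edges())

    def equals(self, other: "LabeledGraph") -> bool:
        """Exact equality: same ids, same labels, same edge multiset."""
        return (
            self.vertex_labels() == other.vertex_labels()
            and self.edge_multiset() == other.edge_multiset()
        )


def degree_sequence(g: LabeledGraph) -> tuple[int, ...]:
    """Non-increasing sequence of vertex degrees.

    Parallel edges count with multiplicity and a self-loop contributes 2 to
    its vertex, so the sequence always sums to twice the edge count.
    """
    return tuple(sorted((d for _, d in g.nx.degree()), reverse=True))


def concatenate(g1: LabeledGraph, g2: LabeledGraph) -> LabeledGraph:
    """Disjoint union of two graphs.

    Vertices with identical labels stay distinct; ids are prefixed to keep
    the two copies apart even when the input id sets overlap.  The result has
    ``|V1|+|V2|`` vertices and ``|E1|+|E2|`` edges and the inputs are left
    untouched.
    """
    out = LabeledGraph()
    for prefix, g in (("a.", g1), ("b.", g2)):
        labels = g.vertex_labels()
        for vid in g.vertices():
            out.add_vertex(prefix + vid, labels[vid])
        for u, v in g.edges():
            out.add_edge(prefix + u, prefix + v)
    return out
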