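"""Compression by contraction of identical connected vertex subsets.

Where edge contraction stalls on graphs whose identical edges all overlap,
this compressor looks for identical connected vertex subsets of growing size
m = 2..M and contracts the whole subset — vertices plus every edge between
them, so no self-loop is left behind.  Subsets are canonicalized not by
subgraph isomorphism (NP-complete) but by their *dl-sequence*: the
non-increasing sequence of (within-subset degree, label) pairs, which admits
a total order.  With M = 2 the procedure reduces to edge contraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .compress_edge import _classes_of, select_edge_class
from .graph import LabeledGraph
from .grammar import VERTEX_SET, CompressionResult, DLSequence, Rule, Run
from .labels import Label, LabelOrder


@dataclass(frozen=True)
class SubsetClass:
    """Connected m-subsets sharing one dl-sequence, plus their label bag."""

    dl: DLSequence
    members: tuple[frozenset[str], ...]
    bag: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.members)


def _dl_of(G: nx.MultiGraph, subset: Iterable[str],
           label_of) -> DLSequence:
    sub = G.subgraph(set(subset))
    if sub.number_of_nodes() == 0 or not nx.is_connected(nx.Graph(sub)):
        raise ValueError("subset does not induce a connected subgraph")
    pairs = [(d, label_of(v)) for v, d in sub.degree()]
    pairs.sort(key=lambda p: (p[0], p[1].ordinal), reverse=True)
    return tuple(pairs)


def dl_sequence(g: LabeledGraph, subset: Iterable[str]) -> DLSequence:
    """dl-sequence of a connected vertex subset of ``g``.

    Degrees are computed within the subset's induced edge set (parallel
    edges with multiplicity, an induced self-loop adds 2), never against the
    whole graph; pairs are sorted non-increasing under
    ``(d1,l1) > (d2,l2) iff d1 > d2 or (d1 = d2 and l1 > l2)``.
    """
    run = Run(g)
    return _dl_of(run.graph, subset, run.label_of)


def dl_less(a: DLSequence, b: DLSequence) -> bool:
    """Strict total order between equal-length dl-sequences."""
    if len(a) != len(b):
        raise ValueError("dl-sequences of different lengths are not comparable")
    return _dl_key(a) < _dl_key(b)


def _dl_key(dl: DLSequence) -> tuple[tuple[int, int], ...]:
    return tuple((d, l.ordinal) for d, l in dl)


def _connected_subsets(G: nx.Graph, m: int) -> set[frozenset[str]]:
    if m < 2:
        raise ValueError("subset size must be at least 2")
    frontier: set[frozenset[str]] = {frozenset((v,)) for v in G}
    for _ in range(m - 1):
        grown: set[frozenset[str]] = set()
        for s in frontier:
            for v in s:
                for nb in G.adj[v]:
                    if nb not in s:
                        grown.add(s | {nb})
        frontier = grown
    return frontier


def enumerate_connected_subsets(g: LabeledGraph, m: int) -> set[frozenset[str]]:
    """Every size-m vertex subset inducing a connected subgraph, once each."""
    return _connected_subsets(g.nx, m)


def _select(run: Run, m: int) -> Optional[SubsetClass]:
    """SelectVertices(m) on the working graph; ``None`` when nothing is
    eligible.

    For m = 2 the candidate classes are exactly the edge classes of the edge
    compressor (every edge with the class's endpoint labels is a member, so
    parallel copies make a class ineligible) — this is what makes M = 2
    reproduce edge contraction rule for rule.  For m >= 3, connected
    m-subsets are grouped by dl-sequence; a class is eligible when its
    members are pairwise disjoint, and selection is by largest class, then
    smallest label bag, then smallest dl-sequence.
    """
    if m == 2:
        classes = _classes_of(run)
        if not classes:
            return None
        cls = select_edge_class(classes)
        dl: DLSequence = ((1, cls.pair[0]), (1, cls.pair[1]))
        return SubsetClass(
            dl=dl,
            members=tuple(frozenset(e) for e in cls.members),
            bag=cls.bag,
        )
    groups: dict[tuple, list[frozenset[str]]] = {}
    dls: dict[tuple, DLSequence] = {}
    for subset in _connected_subsets(run.graph, m):
        dl = _dl_of(run.graph, subset, run.label_of)
        key = _dl_key(dl)
        groups.setdefault(key, []).append(subset)
        dls.setdefault(key, dl)
    eligible = []
    for key, members in groups.items():
        total = sum(len(s) for s in members)
        if len(frozenset().union(*members)) != total:
            continue  # two members overlap
        dl = dls[key]
        bag = run.order.union_bags(*[l for _, l in dl])
        eligible.append(SubsetClass(dl=dl, members=tuple(members), bag=bag))
    if not eligible:
        return None
    return min(eligible, key=lambda c: (-c.count, c.bag, _dl_key(c.dl)))


def select_vertices(
    g: LabeledGraph, m: int
) -> Optional[tuple[SubsetClass, DLSequence]]:
    """The uniquely selected subset class of size ``m``, or ``None``."""
    if m < 2:
        raise ValueError("subset size must be at least 2")
    cls = _select(Run(g), m)
    return None if cls is None else (cls, cls.dl)


def _contract_class(run: Run, cls: SubsetClass) -> Rule:
    new = run.new_label([l for _, l in cls.dl])
    rule = Rule(new_label=new, kind=VERTEX_SET, body=cls.dl)
    run.contract_members(cls.members, new, keep_internal_as_loops=False)
    run.rules.append(rule)
    return rule


def contract_subset_class(
    g: LabeledGraph, cls: SubsetClass
) -> tuple[Rule, LabeledGraph]:
    """Contract one subset class of ``g``; returns the rule and the result.

    Every member's vertices and *all* edges between them are removed (no
    self-loop is left on the new vertex); edges leaving a member re-attach
    to its replacement vertex.
    """
    run = Run(g)
    rule = _contract_class(run, cls)
    return rule, run.result("vertices").residual


def compress_vertices(g: LabeledGraph, M: int = 3) -> CompressionResult:
    """Run the vertex-set compressor with maximum subset size ``M``.

    Each outer iteration retries subset sizes m = 2, 3, ..., M until one
    yields an eligible class, contracts that single class, and rescans from
    m = 2.  Stops when no size up to M yields a class or no edges remain.
    """
    if M < 2:
        raise ValueError(
            "M must be at least 2: a vertex by itself cannot be contracted"
        )
    run = Run(g)
    while run.graph.number_of_edges() > 0:
        chosen = None
        for m in range(2, M + 1):
            chosen = _select(run, m)
            if chosen is not None:
                break
        if chosen is None:
            break
        _contract_class(run, chosen)
    return run.result(f"vertices(M={M})")
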