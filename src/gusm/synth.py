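"""Seed-deterministic synthetic graphs for experiments and testing.

Provides random labeled graphs, isomorphic permuted copies, the two
compressibility extremes (a star whose identical edges all overlap, and a
perfect matching that contracts to nothing), and small fixed fixtures whose
edge-class structure reproduces the worked contraction examples: overlapping
versus disjoint classes, forced fallback from edge to three-vertex
contraction, and matching ambiguity for the GRAPHITOUR baseline.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .graph import LabeledGraph


def random_labeled_graph(
    n: int, m: int, alphabet: Sequence[str] = ("a", "b"), seed: int = 0
) -> LabeledGraph:
    """Simple graph with ``n`` vertices, ``m`` edges, labels drawn uniformly
    from ``alphabet`` under a seeded generator."""
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if m > n * (n - 1) // 2:
        raise ValueError(f"cannot place {m} edges on {n} vertices")
    rng = random.Random(seed)
    base = nx.gnm_random_graph(n, m, seed=rng.randrange(2**31))
    g = LabeledGraph()
    for v in range(n):
        g.add_vertex(f"v{v}", rng.choice(list(alphabet)))
    for u, v in base.edges():
        g.add_edge(f"v{u}", f"v{v}")
    return g


def permuted_copy(g: LabeledGraph, seed: int = 0) -> LabeledGraph:
    """Isomorphic copy: vertex ids permuted and insertion order shuffled.

    Compressing the copy must give the same rule bodies and size as the
    original — ids carry no information.
    """
    rng = random.Random(seed)
    ids = g.vertices()
    shuffled = list(ids)
    rng.shuffle(shuffled)
    mapping = dict(zip(ids, shuffled))
    labels = g.vertex_labels()
    order = list(ids)
    rng.shuffle(order)
    out = LabeledGraph()
    for v in order:
        out.add_vertex(mapping[v], labels[v])
    edges = [(mapping[u], mapping[v]) for u, v in g.edges()]
    rng.shuffle(edges)
    for u, v in edges:
        out.add_edge(u, v)
    return out


def incompressible_star(k: int = 3) -> LabeledGraph:
    """Star: center 'a', ``k`` leaves 'b'.  Every identical edge shares the
    center, so no edge class is eligible and C(G) = k; its self-distance
    under edge contraction is 1."""
    if k < 2:
        raise ValueError("star needs at least 2 leaves")
    g = LabeledGraph()
    g.add_vertex("c", "a")
    for i in range(k):
        g.add_vertex(f"l{i}", "b")
        g.add_edge("c", f"l{i}")
    return g


def compressible_matching(k: int = 2) -> LabeledGraph:
    """``k`` pairwise-disjoint a–b edges: one rule contracts everything,
    C(G) = 1 and the self-distance is 0."""
    if k < 2:
        raise ValueError("matching needs at least 2 edges")
    g = LabeledGraph()
    for i in range(k):
        g.add_vertex(f"a{i}", "a")
        g.add_vertex(f"b{i}", "b")
        g.add_edge(f"a{i}", f"b{i}")
    return g


def fig1_like() -> LabeledGraph:
    """7 vertices, 8 edges; classes 4x(a,b) overlapping, 2x(a,a) disjoint,
    1x(b,b), 1x(a,c); degree sequence (3,3,3,2,2,2,1).

    The overlapping (a,b) class is what a matching-based compressor would
    grab (ambiguously); the deterministic edge compressor must skip it and
    contract the two disjoint (a,a) edges instead, leaving 5 vertices and 6
    edges.
    """
    g = LabeledGraph.build(
        {
            "a1": "a", "a2": "a", "a3": "a", "a4": "a",
            "b1": "b", "b2": "b", "c1": "c",
        },
        [
            ("a1", "a2"), ("a3", "a4"),          # the 2 disjoint (a,a) edges
            ("a1", "b1"), ("a1", "b2"),          # (a,b) edges overlap on a1,
            ("a3", "b1"), ("a4", "b2"),          # b1 and b2
            ("b1", "b2"),                        # (b,b)
            ("a2", "c1"),                        # (a,c)
        ],
    )
    return g


def fig2_like() -> LabeledGraph:
    """7 vertices, 8 edges; 4x(a,b), 2x(a,c), 2x(b,c); every 2-subset class
    overlaps, forcing the vertex-set compressor up to m = 3, where the two
    overlapping {a,b,c} triangles lose to the two disjoint b–a–b paths
    ({a,b,b} with two (a,b) edges)."""
    g = LabeledGraph.build(
        {
            "a1": "a", "a2": "a",
            "b1": "b", "b2": "b", "b3": "b", "b4": "b",
            "c1": "c",
        },
        [
            ("a1", "b1"), ("a1", "b2"),
            ("a2", "b3"), ("a2", "b4"),
            ("a1", "c1"), ("a2", "c1"),
            ("b1", "c1"), ("b3", "c1"),
        ],
    )
    return g


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative recipe for a synthetic graph (same spec + seed →
    bit-identical serialization)."""

    kind: str
    seed: int = 0
    n: int = 10
    m: int = 12
    alphabet: tuple[str, ...] = ("a", "b")
    k: int = 3

    def build(self) -> LabeledGraph:
        if self.kind == "random":
            return random_labeled_graph(self.n, self.m, self.alphabet, self.seed)
        if self.kind == "star":
            return incompressible_star(self.k)
        if self.kind == "matching":
            return compressible_matching(self.k)
        if self.kind == "fig1_like":
            return fig1_like()
        if self.kind == "fig2_like":
            return fig2_like()
        raise ValueError(f"unknown generator kind {self.kind!r}")
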