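"""Comparison baselines: a GRAPHITOUR-style compressor and size distances.

GRAPHITOUR contracts the most frequent endpoint-label pair by solving a
maximum-cardinality matching over that class's edges.  Maximum matchings are
generally not unique, so isomorphic graphs presented with different vertex
orders can compress differently — the ambiguity the deterministic
compressors remove.  Here the chosen matching is the lexicographically first
maximum matching with respect to an explicit ``vertex_order``, which makes
the order dependence reproducible and controllable.
"""

from __future__ import annotations

from typing import Optional, Sequence

import networkx as nx

from .grammar import EDGE, CompressionResult, Rule, Run
from .graph import LabeledGraph
from .labels import Label


def _lex_first_max_matching(
    pairs: list[tuple[str, str]], target: int
) -> list[tuple[str, str]]:
    """First maximum matching in the given edge order (backtracking)."""

    def dfs(idx: int, used: frozenset[str], need: int):
        if need == 0:
            return []
        if len(pairs) - idx < need:
            return None
        u, v = pairs[idx]
        if u not in used and v not in used:
            rest = dfs(idx + 1, used | {u, v}, need - 1)
            if rest is not None:
                return [(u, v)] + rest
        return dfs(idx + 1, used, need)

    found = dfs(0, frozenset(), target)
    assert found is not None, "matching size was computed on the same edges"
    return found


def graphitour_compress(
    g: LabeledGraph, vertex_order: Optional[Sequence[str]] = None
) -> CompressionResult:
    """Matching-based iterative contraction of the most frequent edge class.

    ``vertex_order`` (default: input order) resolves ties among maximum
    matchings; different orders may yield different compressed graphs and
    sizes.  Iteration stops when the most frequent class has fewer than two
    edges — a rule must pay for itself.
    """
    run = Run(g)
    if vertex_order is None:
        vertex_order = g.vertices()
    missing = set(g.vertices()) - set(vertex_order)
    if missing:
        raise ValueError(f"vertex_order does not cover {sorted(missing)!r}")
    rank = {v: i for i, v in enumerate(vertex_order)}
    next_rank = len(rank)

    while run.graph.number_of_edges() > 0:
        groups: dict[tuple[int, int], list[tuple[str, str]]] = {}
        labels: dict[tuple[int, int], tuple[Label, Label]] = {}
        for u, v, _ in run.graph.edges(keys=True):
            if u == v:
                continue
            lu, lv = run.label_of(u), run.label_of(v)
            if lu < lv:
                lu, lv = lv, lu
            key = (lu.ordinal, lv.ordinal)
            groups.setdefault(key, []).append((u, v))
            labels.setdefault(key, (lu, lv))
        if not groups:
            break
        key = min(groups, key=lambda k: (-len(groups[k]), k))
        if len(groups[key]) < 2:
            break
        # distinct vertex pairs, ordered by the external vertex order
        pairs = sorted(
            {tuple(sorted(e, key=rank.get)) for e in groups[key]},
            key=lambda e: (rank[e[0]], rank[e[1]]),
        )
        simple = nx.Graph(pairs)
        target = len(nx.max_weight_matching(simple, maxcardinality=True))
        matched = _lex_first_max_matching(pairs, target)
        l1, l2 = labels[key]
        new = run.new_label([l1, l2])
        rule = Rule(new_label=new, kind=EDGE, body=(l1, l2))
        run.contract_members(
            [frozenset(e) for e in matched], new, keep_internal_as_loops=True
        )
        run.rules.append(rule)
        # new vertices rank after everything existing, in creation order
        for v in run.graph.nodes:
            if v not in rank:
                rank[v] = next_rank
                next_rank += 1
    return run.result("graphitour")


def size_distance(g1: LabeledGraph, g2: LabeledGraph, mode: str = "nodes") -> int:
    """Absolute difference of vertex counts (``nodes``) or edge counts
    (``edges``) — the naive network distances the compression distance is
    compared against."""
    if mode == "nodes":
        return abs(g1.number_of_vertices() - g2.number_of_vertices())
    if mode == "edges":
        return abs(g1.number_of_edges() - g2.number_of_edges())
    raise ValueError(f"mode must be 'nodes' or 'edges', got {mode!r}")
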