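"""Single-linkage (nearest neighbor) hierarchical clustering and Newick export.

The agglomeration is implemented directly rather than through a library call
so that tie-breaking is fully specified: among minimum-distance cluster
pairs, the pair whose clusters contain the smallest original name indices
merges first.  That makes dendrograms reproducible run to run and invariant
(up to leaf relabeling) under permutations of the input matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .similarity import DistanceMatrix


@dataclass(frozen=True)
class DendrogramNode:
    """A leaf (``name`` set) or an internal merge at ``height``."""

    height: float
    name: Optional[str] = None
    children: tuple["DendrogramNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [n for c in self.children for n in c.leaves()]


@dataclass
class Dendrogram:
    """Binary merge tree; internal heights are the linkage distances."""

    root: DendrogramNode
    names: list[str]

    def merges(self) -> list[tuple[int, tuple[str, ...], float]]:
        """Flat merge table: (step, member leaves, height), bottom-up."""
        internal: list[DendrogramNode] = []

        def walk(node: DendrogramNode) -> None:
            if node.is_leaf:
                return
            for c in node.children:
                walk(c)
            internal.append(node)

        walk(self.root)
        internal.sort(key=lambda n: n.height)
        return [
            (i + 1, tuple(sorted(n.leaves())), n.height)
            for i, n in enumerate(internal)
        ]


def single_linkage(m: DistanceMatrix) -> Dendrogram:
    """Agglomerative single linkage over a symmetric distance matrix.

    Repeatedly merges the two clusters whose minimum inter-cluster distance
    is smallest; ties break on the smaller (first, second) smallest-leaf
    index pair.  Heights are non-decreasing along the merge sequence.
    """
    n = len(m.names)
    if n < 2:
        raise ValueError("need at least two items to cluster")
    # cluster -> (node, member indices, representative = min index)
    clusters: dict[int, tuple[DendrogramNode, frozenset[int]]] = {
        i: (DendrogramNode(0.0, name=m.names[i]), frozenset([i]))
        for i in range(n)
    }
    d = m.values
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters, key=lambda k: min(clusters[k][1]))
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                dist = min(
                    d[i, j]
                    for i in clusters[a][1]
                    for j in clusters[b][1]
                )
                rep = (min(clusters[a][1]), min(clusters[b][1]))
                cand = (dist, rep[0], rep[1], a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        dist, _, _, a, b = best
        na, ma = clusters.pop(a)
        nb, mb = clusters.pop(b)
        node = DendrogramNode(height=dist, children=(na, nb))
        clusters[min(a, b)] = (node, ma | mb)
    (root, _), = clusters.values()
    return Dendrogram(root=root, names=list(m.names))


_NEWICK_UNSAFE = re.compile(r"[\s():;,\[\]']")


def _quote(name: str) -> str:
    if _NEWICK_UNSAFE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick(node: DendrogramNode, parent_height: float) -> str:
    length = parent_height - node.height
    if node.is_leaf:
        return f"{_quote(node.name)}:{length:.12g}"
    inner = ",".join(_newick(c, node.height) for c in node.children)
    return f"({inner}):{length:.12g}"


def to_newick(d: Dendrogram) -> str:
    """Newick string with branch lengths = parent − child merge heights."""
    root = d.root
    if root.is_leaf:
        return f"{_quote(root.name)}:0;"
    inner = ",".join(_newick(c, root.height) for c in root.children)
    return f"({inner});"
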