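"""GUSM: compression-based graph similarity, and pairwise distance matrices.

The universal similarity metric between two objects is defined through
Kolmogorov complexity, which is uncomputable; here K(G) is approximated by
the compression size C(G) = |R| + |E_c| and the conditional complexity
K(G1|G2) by C(G1 ∪ G2) − C(G2), where G1 ∪ G2 is the disjoint union.  The
resulting distance is

    GUSM(G1, G2) = (C(G1 ∪ G2) − min(C1, C2)) / max(C1, C2).

Identical fully compressible graphs score 0; a graph whose identical edges
all overlap (incompressible by edge contraction) scores 1 against itself —
the failure mode that motivates vertex-set contraction with M > 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence, Tuple

import numpy as np

from .compress_edge import compress_edge
from .grammar import CompressionResult
from .graph import LabeledGraph, concatenate

Compressor = Callable[[LabeledGraph], CompressionResult]


def compression_size(g: LabeledGraph, compressor: Compressor = compress_edge) -> int:
    """C(G) = |R| + |E_c| under the given compressor."""
    return compressor(g).size


def gusm(
    g1: LabeledGraph,
    g2: LabeledGraph,
    compressor: Compressor = compress_edge,
) -> float:
    """The compression-approximated universal similarity metric.

    Symmetric in its arguments; defined as 0 when both graphs compress to
    size 0 (identical empty objects).  No [0, 1] bound is asserted: the
    greedy compressor carries no subadditivity guarantee.
    """
    c1 = compression_size(g1, compressor)
    c2 = compression_size(g2, compressor)
    c12 = compression_size(concatenate(g1, g2), compressor)
    denom = max(c1, c2)
    if denom == 0:
        return 0.0
    return (c12 - min(c1, c2)) / denom


@dataclass
class DistanceMatrix:
    """Named symmetric matrix of pairwise distances."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match the number of names")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i, j = (self.names.index(k) for k in pair)
        return float(self.values[i, j])

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.names)]
        for name, row in zip(self.names, self.values):
            lines.append(name + "\t" + "\t".join(f"{x:.10g}" for x in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "DistanceMatrix":
        rows = [line.split("\t") for line in text.splitlines() if line.strip()]
        names = rows[0][1:]
        values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
        return cls(names=names, values=values)


def distance_matrix(
    graphs: Mapping[str, LabeledGraph] | Sequence[Tuple[str, LabeledGraph]],
    compressor: Compressor = compress_edge,
) -> DistanceMatrix:
    """All pairwise GUSM values over a named graph collection.

    Each C(g_i) is computed once and reused for every pair; only the
    concatenations are compressed per pair.  Deterministic: identical input
    collections give bit-identical matrices.
    """
    items = list(graphs.items()) if isinstance(graphs, Mapping) else list(graphs)
    names = [n for n, _ in items]
    if len(names) != len(set(names)):
        raise ValueError("duplicate graph names in collection")
    if len(items) < 2:
        raise ValueError("need at least two graphs for a distance matrix")
    sizes = [compression_size(g, compressor) for _, g in items]
    n = len(items)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c12 = compression_size(
                concatenate(items[i][1], items[j][1]), compressor
            )
            denom = max(sizes[i], sizes[j])
            d = 0.0 if denom == 0 else (c12 - min(sizes[i], sizes[j])) / denom
            values[i, j] = values[j, i] = d
    return DistanceMatrix(names=names, values=values)
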