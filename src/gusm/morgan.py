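"""Morgan indices: iterative structural relabeling of vertices.

Metabolic networks labeled with distinct compound names are incompressible
(every edge class has one member), so structure-aware labels are needed
before compression.  The Morgan procedure starts from 1 on every vertex and
repeatedly assigns each vertex the sum of its neighbors' current values;
after one iteration the value equals the degree.  The "original" variant
stops as soon as one more iteration would not increase the number of
distinct values, keeping the finest accepted labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import LabeledGraph


@dataclass(frozen=True)
class MorganLabeling:
    """Per-vertex Morgan values and the iteration count that produced them."""

    values: dict[str, int]
    iteration: int

    def distinct(self) -> int:
        return len(set(self.values.values()))


def _check_no_self_loops(g: LabeledGraph) -> None:
    if g.has_self_loop():
        raise ValueError("Morgan indices are defined for graphs without self-loops")


def _step(g: LabeledGraph, values: dict[str, int]) -> dict[str, int]:
    out = {}
    G = g.nx
    for v in G.nodes:
        # parallel edges contribute once per copy
        out[v] = sum(len(keys) * values[nb] for nb, keys in G.adj[v].items())
    return out


def morgan_iterate(g: LabeledGraph, k: int) -> MorganLabeling:
    """Morgan values after exactly ``k`` summation iterations (k >= 1)."""
    if k < 1:
        raise ValueError("number of Morgan iterations must be >= 1")
    _check_no_self_loops(g)
    values = {v: 1 for v in g.vertices()}
    for _ in range(k):
        values = _step(g, values)
    return MorganLabeling(values=values, iteration=k)


def morgan_original(g: LabeledGraph) -> MorganLabeling:
    """Iterate until the number of distinct values stops increasing.

    Returns the labeling of the last strictly refining iteration t: the
    smallest t >= 1 with distinct(m_{t+1}) <= distinct(m_t).
    """
    _check_no_self_loops(g)
    current = morgan_iterate(g, 1)
    while True:
        nxt = MorganLabeling(_step(g, current.values), current.iteration + 1)
        if nxt.distinct() <= current.distinct():
            return current
        current = nxt


def relabel(g: LabeledGraph, m: MorganLabeling) -> LabeledGraph:
    """Copy of ``g`` with each vertex label replaced by its Morgan value.

    The decimal labels order numerically in later compression runs.
    """
    missing = [v for v in g.vertices() if v not in m.values]
    if missing:
        raise ValueError(f"Morgan labeling does not cover vertices {missing!r}")
    out = LabeledGraph()
    for v in g.vertices():
        out.add_vertex(v, str(m.values[v]))
    for u, v in g.edges():
        out.add_edge(u, v)
    return out
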