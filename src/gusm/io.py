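"""Reading and writing labeled graphs (canonical TSV and GraphML).

TSV dialect: UTF-8 text, ``#`` comment lines, vertex lines
``V<TAB>id<TAB>label`` and edge lines ``E<TAB>id1<TAB>id2``.  Ids must be
declared before they are used by an edge.  The format round-trips exactly:
labels, parallel edges and self-loops survive a write/read cycle.
"""

from __future__ import annotations

import os
from typing import Union

import networkx as nx

from .graph import LabeledGraph

PathLike = Union[str, os.PathLike]


class GraphFormatError(ValueError):
    """Malformed graph file (bad line syntax)."""


class GraphReferenceError(ValueError):
    """Edge referencing a vertex id that was never declared."""


def _infer_format(path: PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext in (".graphml", ".xml"):
        return "graphml"
    return "tsv"


def loads_tsv(text: str) -> LabeledGraph:
    """Parse the canonical TSV dialect from a string."""
    g = LabeledGraph()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        tag = parts[0]
        if tag == "V":
            if len(parts) != 3:
                raise GraphFormatError(
                    f"line {lineno}: vertex line needs 'V<TAB>id<TAB>label'"
                )
            try:
                g.add_vertex(parts[1], parts[2])
            except ValueError as exc:
                raise GraphFormatError(f"line {lineno}: {exc}") from exc
        elif tag == "E":
            if len(parts) != 3:
                raise GraphFormatError(
                    f"line {lineno}: edge line needs 'E<TAB>id1<TAB>id2'"
                )
            try:
                g.add_edge(parts[1], parts[2])
            except KeyError as exc:
                raise GraphReferenceError(
                    f"line {lineno}: {exc.args[0]}"
                ) from exc
        else:
            raise GraphFormatError(
                f"line {lineno}: unknown record type {tag!r}"
            )
    return g


def dumps_tsv(g: LabeledGraph) -> str:
    lines = ["# labeled graph: V<TAB>id<TAB>label / E<TAB>id1<TAB>id2"]
    labels = g.vertex_labels()
    for vid in g.vertices():
        lines.append(f"V\t{vid}\t{labels[vid]}")
    for u, v in g.edges():
        lines.append(f"E\t{u}\t{v}")
    return "\n".join(lines) + "\n"


def read_graph(path: PathLike, fmt: str | None = None) -> LabeledGraph:
    """Read a labeled graph from ``path`` (format inferred from extension)."""
    fmt = _infer_format(path, fmt)
    if fmt == "tsv":
        with open(path, "r", encoding="utf-8") as fh:
            return loads_tsv(fh.read())
    if fmt == "graphml":
        raw = nx.read_graphml(path, force_multigraph=True)
        g = LabeledGraph()
        for vid, data in raw.nodes(data=True):
            if "label" not in data:
                raise GraphFormatError(
                    f"GraphML node {vid!r} has no 'label' attribute"
                )
            g.add_vertex(str(vid), str(data["label"]))
        for u, v, _ in raw.edges(keys=True):
            g.add_edge(str(u), str(v))
        return g
    raise ValueError(f"unknown graph format {fmt!r}")


def write_graph(g: LabeledGraph, path: PathLike, fmt: str | None = None) -> None:
    """Write a labeled graph to ``path`` as TSV or GraphML."""
    fmt = _infer_format(path, fmt)
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(dumps_tsv(g))
    elif fmt == "graphml":
        nx.write_graphml(g.nx, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
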