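# gusm — deterministic graph compression and compression-based network similarity

`gusm` compares node-labeled undirected networks (metabolic networks,
interaction networks, any graph whose vertices carry labels) by *graph
compression*. It implements two deterministic grammar-style compressors —
iterated contraction of identical edges, and of identical connected vertex
subsets — plus the compression distance built on them, Morgan-index
relabeling, single-linkage clustering of network collections, and a
matching-based baseline that demonstrates why determinism matters.

## The method

A compression run extracts an ordered list of contraction rules R from a
graph G and leaves a residual graph G_c; the compression size

    C(G) = |R| + |E_c|

approximates the Kolmogorov complexity K(G). The similarity of two graphs is
the universal similarity metric with C in place of K, using
K(G1|G2) ≈ C(G1 ∪ G2) − C(G2) on the disjoint union G1 ∪ G2:

    GUSM(G1, G2) = (C(G1 ∪ G2) − min(C1, C2)) / max(C1, C2)

Similar graphs share rules, so their union compresses almost as well as
either part and GUSM → 0; an identical pair scores |E_c| / C(G), which is 0
when the graph is fully compressible and 1 when nothing contracts.

The defining property of both compressors is that every contraction choice
is a function of labels and structure alone — class frequency, then label
bags under a total order, then label pairs / dl-sequences — so **isomorphic
graphs always compress into identical rule sequences and sizes**. Contrast
with contraction via maximum-cardinality matching (GRAPHITOUR), where the
matching, and hence the output, depends on the order vertices are read in.
Because edge contraction stalls when all identical edges overlap,
`compress_vertices(g, M)` escalates to connected subsets of up to M
vertices, canonicalized by their dl-sequence (the sorted sequence of
within-subset degree/label pairs); `compress_vertices(g, 2)` is exactly
`compress_edge(g)`.

## Worked example

```python
from gusm import compress_edge, compress_vertices, fig1_like, fig2_like

res = compress_edge(fig1_like())
for rule in res.rules:
    print(rule.new_label.display, "<-", rule.body_display())
print("C(G) =", res.size)
```

prints

```
aa <- ['a', 'a']
bb <- ['b', 'b']
aac <- ['aa', 'c']
C(G) = 7
```

The fixture's most frequent class (four a–b edges) is skipped because its
edges overlap; the first rule contracts the two *disjoint* (a,a) edges, and
after three rules four edges remain, so C(G) = 3 + 4 = 7. On the second
fixture, where every identical edge overlaps, the vertex-set compressor
escalates to three-vertex subsets:

```
abb <- [[2, 'a'], [1, 'b'], [1, 'b']]
aabbbbc <- [[4, 'c'], [2, 'abb'], [2, 'abb']]
C(G) = 2
```

The first rule contracts the two disjoint b–a–b paths (dl-sequence
`((2,'a'),(1,'b'),(1,'b'))`); the 8-edge graph compresses to just 2 rules.

Distances and clustering (`examples/similarity_and_clustering.py`):

```
	g1	g1_iso	g2	g3
g1	0	0.3	1.4	1
...
(((g1:0.3,g1_iso:0.3):0.7,g3:1):0,g2:1);
```

`g1_iso` is an isomorphic copy of `g1`: their distance is the self-distance
|E_c|/C = 0.3 and they merge first in the single-linkage tree. (Values above
1 can occur: the greedy compressor has no subadditivity guarantee.)

More narratives under `examples/`: `compress_basics.py`,
`morgan_relabeling.py` (why distinct-labeled networks need Morgan indices
before they compress at all), `determinism_vs_matching.py`.

## Command line

```
gusm synth --kind fig1_like --out g.tsv     # synthetic fixtures / random graphs
gusm compress --method vertices -M 3 g.tsv  # rules, residual edges, C(G)
gusm gusm a.tsv b.tsv                       # one distance
gusm matrix --relabel morgan:3 *.tsv        # pairwise GUSM matrix (TSV)
gusm cluster dist.tsv --out tree.nwk        # single-linkage Newick tree
```

Graphs are plain TSV (`V id label` / `E id1 id2` lines, tab-separated) or
GraphML with a `label` node attribute.

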