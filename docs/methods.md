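# Methods

## Problem and model

Comparing the global structure of two large node-labeled networks (e.g.
metabolic networks with compounds as vertices and reactions as edges) is hard
because subgraph isomorphism is intractable at that scale. The
compression-based approach sidesteps it: approximate the Kolmogorov
complexity K(G) of a graph by the size of a grammar-style compression,

    C(G) = |R| + |E_c|,

where R is the ordered list of contraction rules extracted from G and E_c the
multiset of edges left in the residual graph, and measure similarity by how
much better two graphs compress together than apart:

    GUSM(G1, G2) = (C(G1 ∪ G2) − min(C1, C2)) / max(C1, C2),

with G1 ∪ G2 the disjoint union (equal labels do **not** merge vertices).
This instantiates the universal similarity metric with C in place of K and
K(G1|G2) ≈ C(G1 ∪ G2) − C(G2). Two structurally similar graphs share rules,
so the union compresses almost as well as either part and GUSM approaches 0.

## The compressors

Both compressors operate on undirected multigraphs whose vertices carry
labels from a totally ordered set L; every contraction mints a fresh label
greater than all existing ones, and each label `l` carries a *bag* s(l): the
multiset of original labels it expands to (s(l) = {l} for originals, bags
merge on contraction). Bags are compared by sorting descending and taking
the first difference; a strict prefix counts as smaller (the element-wise
rule is silent on exhaustion; prefix-as-smaller preserves totality).

**Edge contraction.** Each iteration groups non-self-loop edges by the
descending pair of endpoint labels. A class is *eligible* only if no two of
its edges share a vertex — parallel copies of one vertex pair therefore
disqualify their class, and self-loops are never candidates (an "edge" to be
replaced by a vertex needs two distinct endpoints; loops still count in |E|
and |E_c|). Among eligible classes the selection is unique: largest class,
then smallest bag s(l1) ⊎ s(l2), then smallest label pair. All member edges
are replaced by fresh vertices carrying the new label; edges incident to the
removed endpoints re-attach to the new vertex. The loop stops when no edges
or no eligible classes remain. Every rule removes at least one edge, so
C(G) ≤ |E| and termination is guaranteed.

Because every choice is a function of labels and structure only — vertex ids
never enter any comparison — isomorphic graphs yield identical rule
sequences and sizes. This is the property that selection by
maximum-cardinality matching (the GRAPHITOUR baseline) lacks: maximum
matchings are not unique, so the baseline's output depends on vertex order.
The baseline here makes that dependence explicit and reproducible by taking
the lexicographically first maximum matching under a caller-supplied vertex
order, and stops once the most frequent class has fewer than two edges (a
rule must pay for itself).

**Vertex-set contraction.** Graphs whose identical edges all overlap (a
star with same-labeled leaves is the extreme) are incompressible by edge
contraction, driving GUSM(G, G) to 1 instead of 0. The vertex-set compressor
therefore escalates: each outer iteration tries subset sizes m = 2, 3, …, M
until something is eligible, contracts that one class, and rescans from
m = 2. Connected m-subsets are canonicalized by their *dl-sequence* — the
non-increasing sequence of (degree within the subset's induced edge set,
label) pairs under (d1,l1) > (d2,l2) iff d1 > d2 or (d1 = d2 and l1 > l2).
dl-sequences are cheap total-order keys; for m ≥ 4 non-isomorphic subsets
can collide (a-b-a-b and a-a-b-b both give ((2,b),(2,a),(1,b),(1,a))) and
are then deliberately contracted under one label — the method trades
exactness for never solving subgraph isomorphism. Contracting a subset
removes its vertices and **all** induced edges, so no self-loop survives the
rewrite; external edges re-attach, and an edge joining two different members
becomes an edge between the two new vertices.

Numerical/degenerate choices:

- Original labels that parse as integers (Morgan indices) order numerically,
  other labels lexicographically; ordinals are assigned once per run, so the
  order depends only on the label set, not on input order.
- The m = 2 stage of the vertex-set compressor uses the *edge classes* of
  the edge compressor (members are edge instances, so parallel copies make a
  class ineligible) rather than literal vertex subsets keyed by dl-sequence.
  On multigraph intermediates the two readings differ — a doubled vertex
  pair would form its own dl-class with degrees (2,2) — and only the
  edge-class reading keeps CompressVertices(2) exactly equivalent to
  CompressEdge, which is a defining property of the method. Rules from this
  stage are recorded with the dl body ((1,l1),(1,l2)).
- The bag of a vertex-set rule's new label is the multiset union of the
  subset's label bags, mirroring the edge rule.
- M defaults to 3 (the value used for the network experiments the method
  was designed for); subset enumeration grows connected sets breadth-first
  with set-deduplication and is intended for M ≤ 5.
- GUSM is defined as 0 when both graphs compress to size 0, and is *not*
  clamped to [0, 1]: the greedy compressor has no subadditivity guarantee,
  so values slightly above 1 can occur for dissimilar graphs.

## Morgan relabeling

Networks whose vertices all carry distinct labels (compound names) have
one-member edge classes only, hence C(G) = |E| — nothing compresses.
Structure-aware labels fix this: start with 1 on every vertex and repeatedly
assign each vertex the sum of its neighbors' values (parallel edges count
per copy). One iteration reproduces the degree map; the *original* variant
iterates while the number of distinct values still increases and returns the
last strictly refining labeling (iteration t with
distinct(m_{t+1}) ≤ distinct(m_t)). Morgan values are isomorphism-invariant
and component-local, so relabeling before or after disjoint union is
equivalent; isolated vertices get value 0. Inputs are expected self-loop
free (original networks are).

## Clustering

Distance matrices over graph collections are clustered by single linkage
(nearest neighbor), implemented directly so tie-breaking is fully specified:
among minimum-distance cluster pairs, the pair with the smallest (first,
second) smallest-leaf-index wins. Merge heights are non-decreasing, trees
are exported as Newick with branch lengths equal to height differences, and
scipy's linkage serves as an independent reference in the tests.

## Synthetic data

All experiments run on generated inputs:

- `random_labeled_graph(n, m, alphabet, seed)` — uniform simple graphs with
  uniform labels; the test families use n ≤ 30, m ≤ 60 and alphabets of up
  to 4 symbols, sizes at which identical-label edge classes are common
  enough to exercise every eligibility and tie-breaking path while keeping
  the full suite fast.
- `permuted_copy(g, seed)` — the isomorphism-invariance probe: ids renamed
  and insertion order shuffled.
- `incompressible_star(k)` / `compressible_matching(k)` — the two analytic
  extremes (self-distance 1 and 0 under edge contraction).
- `fig1_like()` / `fig2_like()` — 7-vertex, 8-edge fixtures reconstructed
  from stated class-count, degree-sequence and overlap constraints: the
  first makes the frequent class ambiguous for matching-based contraction
  while the deterministic compressor must pick the two disjoint (a,a)
  edges; the second has every pair class overlapping, forcing escalation to
  m = 3 where two disjoint b–a–b paths beat two overlapping a–b–c
  triangles. The embeddings are fixed constructions satisfying those
  constraints; tests assert the constrained behavior, not a particular
  drawing.

What the generators do not emulate: real metabolic networks (thousands of
vertices, scale-free degree structure, database-specific edge semantics) and
label distributions induced by real compound frequencies. Passing tests
establish the algorithmic identities and invariances, not biological
conclusions about any particular organism set.

## Known limitations

- Compression is lossy: the original graph cannot be reconstructed from
  (R, G_c).
- The greedy rule extraction is not optimal compression; C(G) is an upper
  bound proxy for K(G), and GUSM inherits its quirks (no triangle
  inequality guarantee, no [0,1] bound).
- Directed graphs and edge labels are out of scope.
- dl-sequence collisions for m ≥ 4 merge non-isomorphic subsets by design.
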