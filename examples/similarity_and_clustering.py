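"""GUSM distances over a small graph collection, clustered to a dendrogram.

Builds three related random graphs plus an isomorphic copy of the first,
computes all pairwise compression distances, and clusters them with single
linkage.  The isomorphic pair must sit at distance GUSM(g,g) and merge
first.
"""

import functools

from gusm import (
    compress_vertices,
    distance_matrix,
    permuted_copy,
    random_labeled_graph,
    single_linkage,
    to_newick,
)

g1 = random_labeled_graph(14, 18, "ab", seed=11)
graphs = [
    ("g1", g1),
    ("g1_iso", permuted_copy(g1, seed=5)),
    ("g2", random_labeled_graph(14, 18, "ab", seed=12)),
    ("g3", random_labeled_graph(14, 18, "abcd", seed=13)),
]

# vertex-set contraction (M=3) compresses overlapping-edge regions that
# plain edge contraction cannot touch
dm = distance_matrix(graphs, functools.partial(compress_vertices, M=3))
print(dm.to_tsv())
# Rows/columns are symmetric; the g1/g1_iso entry equals the self-distance
# |E_c|/C(G) because ids never influence compression.

tree = single_linkage(dm)
for step, members, height in tree.merges():
    print(f"merge {step}: {'+'.join(members)} at height {height:.4f}")
print(to_newick(tree))
# The isomorphic pair merges first, at the lowest height in the tree.
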