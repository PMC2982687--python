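"""Isomorphic graphs compress identically; matching-based contraction varies.

Runs the deterministic edge compressor on 30 permuted copies of one graph
(always the same rules and size) and the GRAPHITOUR-style baseline on 30
vertex orders of the ambiguity fixture (several distinct outcomes).
"""

import random

from gusm import (
    compress_edge,
    fig1_like,
    graphitour_compress,
    permuted_copy,
    random_labeled_graph,
)

g = random_labeled_graph(18, 30, "abc", seed=21)
ref = compress_edge(g)
outcomes = {
    (tuple(compress_edge(permuted_copy(g, s)).rule_bodies()),
     compress_edge(permuted_copy(g, s)).size)
    for s in range(30)
}
print(f"compress_edge on 30 isomorphic copies: {len(outcomes)} distinct "
      f"outcome(s); size always {ref.size}")

fix = fig1_like()
baseline_outcomes = set()
for s in range(30):
    order = fix.vertices()
    random.Random(s).shuffle(order)
    res = graphitour_compress(fix, order)
    residual = tuple(sorted(
        tuple(sorted((res.residual.label_of(u), res.residual.label_of(v))))
        for u, v in res.residual.edges()
    ))
    baseline_outcomes.add(residual)
print(f"graphitour baseline on 30 vertex orders of the ambiguous fixture: "
      f"{len(baseline_outcomes)} distinct residual graphs")
# The baseline's maximum matchings are not unique, so the compressed result
# depends on input order -- unusable as a graph invariant.
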