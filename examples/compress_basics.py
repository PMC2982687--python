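"""Compress two small fixture graphs and inspect the extracted grammar.

The first fixture has an ambiguous frequent class (four overlapping a-b
edges) that the deterministic edge compressor must skip; the second defeats
edge contraction entirely and needs three-vertex contraction.
"""

from gusm import compress_edge, compress_vertices, fig1_like, fig2_like

g = fig1_like()
res = compress_edge(g)
print(f"fig1-like: |V|={g.number_of_vertices()} |E|={g.number_of_edges()}")
for rule in res.rules:
    print(f"  rule: {rule.new_label.display} <- {rule.body_display()}")
print(f"  C(G) = |R| + |E_c| = {res.n_rules} + {res.residual_edges}"
      f" = {res.size}")
# The first rule contracts the two disjoint (a,a) edges, not the frequent
# but overlapping (a,b) class.

g2 = fig2_like()
res2 = compress_vertices(g2, M=3)
print(f"fig2-like: |V|={g2.number_of_vertices()} |E|={g2.number_of_edges()}")
for rule in res2.rules:
    print(f"  rule: {rule.new_label.display} <- {rule.body_display()}")
print(f"  C(G) = {res2.size}")
# Every identical edge overlaps, so the compressor escalates to m=3 and
# contracts the two disjoint b-a-b paths; the graph compresses to 2 rules.
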