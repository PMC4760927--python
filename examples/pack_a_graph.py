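"""Decompose a hand-built splicing graph into isoform paths.

Builds the classic skipped-exon diamond -- two branches of weight 10
and 30 between matched flanks -- balances it, runs the packing sweep,
and prints each item's trajectory.  The two trajectories are the two
isoform paths and the item sizes are their junction-level coverages.
"""

from isopack import SplicingGraph, prepare, run_packing

g = SplicingGraph()
for n in ("flank5", "exon", "skip", "flank3"):
    g.add_node(n)
g.add_edge("flank5", "exon", 30)   # inclusion route, 30x
g.add_edge("exon", "flank3", 30)
g.add_edge("flank5", "skip", 10)   # skipping route, 10x
g.add_edge("skip", "flank3", 10)

balanced = prepare(g)              # adds s/t and interior transcript ends
state, items = run_packing(balanced)

print(f"{len(items)} isoform path(s) from {g.n_edges()} junctions:")
for it in items:
    path = " -> ".join(str(v) for _, v in it.edges[:-1])
    print(f"  coverage {it.size:4.0f}x : s -> {path} -> t")
print(f"direction reversals used: {state.iteration_count} (bound {balanced.n_nodes()})")
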