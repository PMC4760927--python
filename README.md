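# isopack

De novo recovery of transcript isoforms — and their coverages — from
short RNA-seq reads, by decomposing weighted splicing graphs into
source-to-sink paths with a bin-packing sweep and exact 0–1 ILP
sub-solves.

## The problem

A eukaryotic gene usually produces several transcript isoforms through
alternative splicing (skipped exons, retained introns, mutually
exclusive exons), expressed at levels spanning orders of magnitude.
Given only short reads — no reference genome — the assembler must
recover every full-length isoform and say how abundant each one is.
`isopack` is for people who study transcriptomes where a reference is
missing, incomplete or rearranged, and for method developers who want a
compact, fully tested implementation of coverage-guided splicing-graph
decomposition to build on.

## The model

Each gene becomes a **splicing graph**: a weighted DAG whose nodes are
maximal unspliced sequence segments and whose edges are splice
junctions weighted by spanning-read counts. After adding a source *s*
and sink *t* and marking interior transcript ends wherever a node's
flow imbalance exceeds the adaptive threshold

&nbsp;&nbsp;&nbsp;&nbsp;*c* = α(γ−β)/*w*<sub>min</sub> + β  (α = 10, β = 1.4, γ = 1.5),

the graph is decomposed by tracking *items* — tokens whose sizes
approximate isoform coverages — through a series of bin-packing
problems. Every edge is a bin with capacity equal to its weight. Items
seeded on the largest set of pairwise incompatible edges (the widest
gap cut of the topologically ordered graph) are pushed node by node,
solving at each node

&nbsp;&nbsp;&nbsp;&nbsp;min Σ<sub>i</sub> (c<sub>i</sub> − Σ<sub>j</sub> w<sub>j</sub> x<sub>ij</sub>)²&nbsp;&nbsp; s.t.&nbsp; Σ<sub>i</sub> x<sub>ij</sub> = 1, Σ<sub>j</sub> x<sub>ij</sub> ≥ n<sub>i</sub>, x<sub>ij</sub> ∈ {0,1},

linearized into a 0–1 ILP with m·n·(n+3)/2 variables and solved
exactly. *Trap* nodes (more receiving edges than carrying edges)
replace the items and reverse the sweep; the number of reversals is
bounded by |V|. At termination the bins holding one item trace out one
s–t path per item — an edge-path cover that explains every observed
splicing event — and each path is spelled into a transcript sequence
with a least-squares coverage estimate. See `docs/methods.md` for the
full account.

## Worked example

`examples/assemble_simulated_gene.py` simulates one skipped-exon gene
(inclusion isoform at 50×, skipping isoform at 10×, error-free 100 bp
reads), assembles the reads, and compares with the truth:

```
simulated 421 reads from gene with isoform lengths [751, 447] at depths (50.0, 10.0)
  BP.comp1.1: 747 bp, coverage  50.1  (g1.iso1)
  BP.comp1.2: 443 bp, coverage  10.5  (g1.iso2)
```

Both isoforms come back as exact substrings of the truth (terminal
bases covered by a single read sit below the k-mer noise floor, hence
747 vs 751 bp) and the recovered coverages 50.1 and 10.5 estimate the
true depths 50 and 10. The other examples show the packing sweep on a
hand-built graph (`pack_a_graph.py`), one exact node solve against the
enumeration oracle (`solve_packing_instance.py`), and the full
evaluation loop (`score_an_assembly.py`).

The same pipeline is available from the shell:

```sh
isopack simulate --n-genes 2 --seed 11 --out sim/
isopack assemble --left sim/reads.fq -o asm/     # -k 25 --alpha 10 --beta 1.4 --gamma 1.5
isopack evaluate --assembled asm/transcripts.fa --reference sim/reference.fa
```

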