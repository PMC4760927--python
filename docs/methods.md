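# Methods

## Problem and model

`isopack` reconstructs full-length transcript isoforms, with per-isoform
coverage estimates, from short RNA-seq reads without a reference genome.
Each expressed gene is represented by a **splicing graph**: a weighted
directed acyclic graph whose nodes are maximal unspliced sequence
segments ("generalized exons", not necessarily annotated exons) and
whose edges are splice junctions weighted by the number of reads that
span them. Reconstructing the transcriptome amounts to decomposing each
splicing graph into a set of source-to-sink paths — an **edge-path
cover**, so that every observed splicing event is explained — together
with one coverage value per path.

The decomposition is modeled as tracking *items* through a sequence of
small bin-packing problems. Every edge is a bin whose capacity is its
junction weight; an item is a token whose size approximates one
isoform's coverage. Items are seeded on the widest set of pairwise
incompatible edges and pushed node by node across the graph; the bin an
item occupies at each cut, accumulated over all cuts, induces its path.

## Pipeline

### 1. Graph construction (`build`)

A deliberately minimal k-mer front end (the published construction this
package models delegates to a predecessor assembler whose internals are
not specified; paired-end bridging and mate-aware branch trimming are
out of scope):

1. Count all k-mers of the reads (default k = 25; reads shorter than k
   are skipped, so variable-length input is fine). k-mers with
   multiplicity below `min_kmer_count` (default 2) are discarded as
   singleton sequencing errors.
2. Collapse maximal unbranched k-mer chains into sequence nodes
   (consecutive k-mers overlap by k−1 bases); node coverage is the mean
   member k-mer count.
3. Weight each junction u→v by the number of reads containing its
   minimal identifying context: the last k bases of u followed by the
   first base of v beyond the (k−1)-overlap, a (k+1)-mer. A k-length
   window would equal v's first k-mer, which *every* edge entering v
   shares, and could not separate (for example) a skip junction from an
   inclusion junction at the same acceptor. Matching is exact — the
   graph has already been error-trimmed. Unsupported (weight-0) edges
   are removed.
4. Trim to a fixed point, interleaved with re-collapsing: junctions
   with fewer than `min_junction_reads` (default 2) spanning reads, and
   dead-end tips shorter than `tip_length_factor·k` (default 2.0) with
   coverage below the k-mer noise floor, are removed.
5. Split into weakly connected components, each treated as one
   expressed gene (homologous genes can in principle merge components;
   the synthetic data below avoids this by construction).

Unstranded libraries are assembled together with the reverse
complements of all reads; each resulting component then has a
reverse-complement twin, and the twin whose k-mers are better supported
by the reads as given (plurality vote) is emitted.

### 2. Canonical order and the seed cut (`graph`)

Nodes are linearly arranged by topological order (Kahn's algorithm;
deterministic: smallest node id first, pure sources leftmost, pure
sinks rightmost). Two edges are **compatible** if some directed path
contains both; the edges crossing the gap between two consecutive nodes
of the canonical order are pairwise incompatible, and the largest such
crossing set — leftmost gap on ties — is a *maximal* set of pairwise
incompatible edges once the graph is balanced (every edge on an s–t
path; the property-test suite verifies both halves by brute force).
Cycles, which can arise from repetitive sequence, are broken before
ordering by removing the minimum-weight edge of each cycle found by
depth-first search.

### 3. Balancing (`balance`)

A source s and sink t are attached: s feeds every node without
in-edges (weight = that node's total out-weight) and every node without
out-edges drains to t (weight = total in-weight); an isolated mono-exon
node receives both, weighted by its coverage.

Interior transcript ends are then marked. For a node u with in-weight
w_in and out-weight w_out, let w_min = min(w_in, w_out) and

    c = α (γ − β) / w_min + β,  α = 10, β = 1.4, γ = 1.5 (defaults).

If w_out / w_in ≥ c, an edge s→u with weight w_out − w_in is added (a
transcript starts at u); symmetrically u→t with weight w_in − w_out
when w_in / w_out ≥ c. The threshold adapts to coverage: deep nodes
(small sampling noise) are tested near β, shallow nodes near γ. The
pass is single-sweep over pre-pass weights, so it is order-independent
and idempotent. A node with a zero-weight side is always tied to the
corresponding sentinel.

### 4. The packing sweep (`packing`)

One item per edge of the seed cut, sized by that edge's weight. The
sweep starts at the left endpoint of the cut's gap and moves left. At
each node the edges of the two flanking cuts split into I_in (into the
node), I_out (out of the node) and I_m (spanning it); items in I_m
edges are untouched. Moving left, the items carried in I_out are packed
into the bins I_in by an exactly solved least-squares assignment
(below); mirrored when moving right. Each bin must receive at least as
many items as it held on its previous visit (at least one on a first
visit), so re-crossings refine earlier structure without contradicting
it.

A **trap** is an unprocessed node whose carrying side has fewer edges
than its bin side (moving left: |I_out| < |I_in|). The items in the
carrying edges are retired and replaced by one new item per bin-side
edge, sized by that edge's weight; the new items are packed back into
the carrying edges under the per-bin minimum counts, each new item
inherits the processed-side path segment of a retired item from its
assigned edge (round-robin within the edge, so every retired segment
survives), and the sweep reverses direction starting from the trap
node. On reaching a sentinel without a trap, the sweep jumps back to
the current iteration's start node and continues the other way, until
every node is processed. Processed nodes are never trapped again, which
bounds the number of direction reversals by |V|; the engine enforces
this bound and the terminal invariants (contiguous s–t trajectories,
full edge cover) as hard errors.

Two consequences of allowing several items per edge, which the
single-item-per-edge description glosses over, are handled explicitly:
the per-bin minimum counts are capped to the available item count
(largest first, floor one) because a trap that retires r items and
creates m < r shrinks the population; and a later sweep re-crossing a
processed node that was left short-handed by such a trap re-seeds one
item per receiving edge with the same replacement machinery, without
reversing direction (the node's structure is already explained, so this
is refinement, not a new iteration).

### 5. Exact node-local solves (`solver`)

Each node instance minimizes

    f = Σ_i (c_i − Σ_j w_j x_ij)²,   x_ij ∈ {0,1}

subject to: each item in exactly one bin, and bin i receiving at least
n_i items (n_i = 1 on first visits). The quadratic objective is
linearized by one product variable y_ijk per pair x_ij·x_ik (j ≤ k
within bin i) with the standard linking constraints y ≤ x_ij, y ≤ x_ik,
x_ij + x_ik − 1 ≤ y; diagonal products simplify via x² = x but are
retained as variables, so the variable count is exactly m·n·(n+3)/2.
The resulting 0–1 ILP is solved exactly with HiGHS via
`scipy.optimize.milp`; instances are tiny (usually under 27 variables),
and single-bin or single-item cases short-circuit without a solver
call. Ties among equal-objective optima are broken by the
lexicographically smallest flattened assignment matrix, so results are
reproducible across solver backends. An exhaustive-enumeration oracle
over the quadratic objective (`brute_force_pack`) provides an
independent route; the suite asserts agreement on hundreds of random
instances.

### 6. Transcripts and abundances (`assembly`)

Each surviving item's edges form one s–t path; interior node sequences
are spliced with the (k−1)-base junction overlap collapsed once —
the single coordinate convention of the code base. Sentinel edges
contribute no sequence. Junction-free components are emitted directly
as mono-exon transcripts. Transcripts shorter than
`min_transcript_length` (default 200, a community convention extrinsic
to the algorithm) are suppressed.

Reported coverage is **not** the raw item size. Raw sizes are
junction-spanning read counts, which underestimate per-base depth by a
factor (rl − k)/rl for read length rl and, at low depth, carry the full
sampling noise of a single junction. With the item-to-edge assignment
fixed, the packing model reads "edge weight ≈ sum of the sizes of the
items in the edge"; the reported abundances are the non-negative
least-squares solution of exactly that relation over all junction
edges, augmented with node k-mer coverages as additional, much less
noisy observations of the same sums (length-weighted; a node holding a
transcript end is damped by the analytic terminal coverage-ramp factor
1 − (R−1)/(2m), R = rl−k+1, m = k-mers in the node). The fit is the
same least-squares objective the packing minimizes — no read
re-assignment or EM — and is converted to per-base depth units with the
analytic factor rl(L−rl+1)/((rl−k)L). With no read-length information
the raw junction-count scale is reported unchanged.

### 7. Evaluation (`evaluate`)

A reference transcript is **full-length recovered** by an assembled
transcript when their best local alignment covers ≥ 95% of the
reference length at ≥ 95% identity with ≤ 0.5% indel columns (all three
thresholds are flags). Alignment uses biopython's `PairwiseAligner` in
local mode (match +1, mismatch −2, gap open −3, gap extend −1); both
orientations of the assembled sequence are tried. Sensitivity is the
number of full-length recovered references under a greedy one-to-one
matching (identity × coverage, each assembled transcript consumable
once; a reference is recovered by a single transcript, never a union);
the reference true-positive rate divides sensitivity by the number of
assembled transcripts, the assembled true-positive rate is the fraction
of assembled transcripts that full-length recover *some* reference, and
reliability is summarized by the distribution of best reference
coverage over 80–100% in 1% bins.

## Synthetic data (`sim`)

The generator emulates the controlled conditions of an in-silico
RNA-seq experiment at desk scale (thousands of reads, not tens of
millions). A gene is 3–4 random uniform-ACGT exons (150–350 bp by
default) with an isoform pair realizing one event — skipped exon,
retained intron, mutually exclusive exons — or a single isoform.
Expression is a per-isoform read depth, log-uniform over 5–200× by
default (mimicking the wide dynamic range of real transcript
abundance) or pinned explicitly. Reads (default 100 bp single-end,
strand-specific, error-free; paired-end, mixed-orientation and i.i.d.
substitution errors up to 5% are options) start uniformly along the
isoform — no positional or fragment-GC bias — with
round(depth·L/yield) fragments per isoform, so expected coverage is
analytic. Genes are rejection-sampled so that no two genes share a
k-mer on either strand, which makes "one component per gene" a sharp
integration assertion.

What passing on these data does *not* show: robustness to homologous
gene families (shared k-mers merge components), positional coverage
bias, indel sequencing errors, or genuine paired-end bridging of
coverage gaps — none of which the generator produces.

## Numerical and design choices

- All weights are kept as reals end to end; no integer rescaling.
- The ratio tests of the balancer use exact floating comparison; c is a
  smooth function of w_min and needs no tolerance.
- Objective ties in the exact solver: lexicographic on the flattened
  assignment matrix, applied identically in the ILP route and the
  enumeration oracle.
- Determinism throughout: node orders, edge orders, item ids and solver
  tie-breaks are all fixed, so identical inputs give byte-identical
  outputs.
- Problem sizes used by the test suite and the acceptance script —
  200 random packing instances (m ≤ 3, n ≤ 6), 200 random balanced
  graphs (≤ 15 nodes), ten 2-isoform genes at 10×/50× with 100 bp reads
  — were chosen to exercise every code path (including traps and
  re-seeding) while keeping a full run around a minute.

## Known limitations

- The sweep is node-local and greedy by design; there is no global
  optimality claim over whole-graph path decompositions, and no
  stochastic restarts.
- Graph construction is a simplification: no paired-end bridging over
  uncovered contigs, no quality-aware error correction, no scaffolding.
- At 10× depth the minor isoform of a two-isoform gene is constrained
  by very little data — its single discriminating junction is spanned
  by a Binomial count with ≈ 30% coefficient of variation — so
  individual recovered coverages at that depth scatter by ±15–30%
  around the truth even with the least-squares refit; the recovery
  experiment in the acceptance script reports the realized error
  distribution. Coverage estimation that re-assigns individual reads
  (EM) could tighten this but is deliberately out of scope.
- Mono-exon transcript abundance comes from mean node coverage alone.
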