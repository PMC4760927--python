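"""Build weighted splicing graphs from RNA-seq reads.

A minimal k-mer front end: count k-mers, drop the low-multiplicity ones
(singleton sequencing errors), collapse maximal unbranched k-mer chains
into sequence nodes, weight each junction by the number of reads that
span it, trim weak tips and junctions, and split the result into weakly
connected components -- each assumed to be one expressed gene.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .graph import SplicingGraph

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class BuildConfig:
    k: int = 25
    min_kmer_count: int = 2
    min_junction_reads: int = 2
    tip_length_factor: float = 2.0
    strand_mode: str = "stranded"  # or "unstranded"

    def __post_init__(self) -> None:
        if self.k < 15:
            raise ValueError("k must be at least 15")
        if self.min_kmer_count < 0 or self.min_junction_reads < 0:
            raise ValueError("thresholds must be non-negative")
        if self.strand_mode not in ("stranded", "unstranded"):
            raise ValueError("strand_mode must be 'stranded' or 'unstranded'")


@dataclass
class KmerGraph:
    """k-mer multiplicities; adjacency is implied by (k-1)-overlap."""

    k: int
    kmer_count: dict[str, int]

    def drop_low_count(self, min_count: int) -> "KmerGraph":
        return KmerGraph(
            self.k,
            {km: c for km, c in self.kmer_count.items() if c >= min_count},
        )

    def successors(self, km: str) -> list[str]:
        return [km[1:] + b for b in _BASES if km[1:] + b in self.kmer_count]

    def predecessors(self, km: str) -> list[str]:
        return [b + km[:-1] for b in _BASES if b + km[:-1] in self.kmer_count]


def count_kmers(reads: Iterable[str], config: BuildConfig) -> KmerGraph:
    """Count every k-window of every read long enough to hold one.

    k-mers containing non-ACGT symbols are dropped; reads shorter than k
    are skipped (with a logged count) -- read lengths may vary freely.
    """
    k = config.k
    counts: Counter[str] = Counter()
    skipped = 0
    total = 0
    for read in reads:
        total += 1
        seq = read.upper()
        if len(seq) < k:
            skipped += 1
            continue
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if all(b in _BASES for b in km):
                counts[km] += 1
    if total == 0:
        raise ValueError("no reads supplied")
    if not counts:
        raise ValueError(f"k={k} exceeds every read length")
    if skipped:
        log.info("count_kmers: skipped %d read(s) shorter than k=%d", skipped, k)
    return KmerGraph(k=k, kmer_count=dict(counts))


def collapse_linear_paths(kgraph: KmerGraph, config: BuildConfig) -> SplicingGraph:
    """Merge maximal unbranched k-mer chains into single sequence nodes.

    A chain continues through k-mer x -> y only when y is x's unique
    successor and x is y's unique predecessor.  Node sequence is the
    chain spelling (k-1 overlap between consecutive k-mers); node
    coverage is the mean member k-mer count.  Every remaining boundary
    becomes a junction edge (weights are provisional until
    :func:`weight_junctions`).
    """
    k = kgraph.k
    counts = kgraph.kmer_count
    in_chain: set[str] = set()
    unitigs: list[list[str]] = []

    def is_linear_link(x: str, y: str) -> bool:
        return kgraph.successors(x) == [y] and kgraph.predecessors(y) == [x]

    for km in sorted(counts):
        if km in in_chain:
            continue
        preds = kgraph.predecessors(km)
        if len(preds) == 1 and is_linear_link(preds[0], km):
            continue  # interior of a chain; reached from its start
        chain = [km]
        in_chain.add(km)
        cur = km
        while True:
            succs = kgraph.successors(cur)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if not is_linear_link(cur, nxt) or nxt in in_chain:
                break
            chain.append(nxt)
            in_chain.add(nxt)
            cur = nxt
        unitigs.append(chain)
    # isolated cycles (every k-mer 1-in-1-out) were never started above
    for km in sorted(counts):
        if km not in in_chain:
            chain = [km]
            in_chain.add(km)
            cur = km
            while True:
                succs = kgraph.successors(cur)
                if len(succs) != 1 or succs[0] in in_chain:
                    break
                chain.append(succs[0])
                in_chain.add(succs[0])
                cur = succs[0]
            unitigs.append(chain)

    unitigs.sort(key=lambda ch: ch[0])
    first_kmer = {ch[0]: i for i, ch in enumerate(unitigs)}
    graph = SplicingGraph()
    for i, ch in enumerate(unitigs):
        seq = ch[0] + "".join(km[-1] for km in ch[1:])
        cov = sum(counts[km] for km in ch) / len(ch)
        graph.add_node(i, seq=seq, cov=cov)
    for i, ch in enumerate(unitigs):
        last = ch[-1]
        for nxt in kgraph.successors(last):
            j = first_kmer.get(nxt)
            if j is None:
                continue  # interior k-mer: same chain, already collapsed
            if j == i and len(ch) > 1 and nxt == ch[0]:
                continue  # chain closing on itself (cycle) -- dropped here
            graph.add_edge(i, j, weight=0.0)
    return graph


def junction_window(graph: SplicingGraph, u, v, k: int) -> str:
    """Minimal read context that uniquely identifies junction u->v.

    The parent's last k bases followed by the child's first base beyond
    the (k-1)-overlap: length k+1.  (A k-length window would equal the
    child's first k-mer, which every edge entering the child shares.)
    """
    su, sv = graph.node_seq(u), graph.node_seq(v)
    return su[-k:] + sv[k - 1]


def weight_junctions(
    graph: SplicingGraph, reads: Iterable[str], config: BuildConfig
) -> SplicingGraph:
    """Weight each edge by the number of reads spanning its junction window.

    Exact string matching (consistent with the error-trimmed graph); in
    unstranded mode a read supports a junction on either strand.
    Zero-weight edges are removed with a logged count.
    """
    k = config.k
    window_counts: Counter[str] = Counter()
    w = k + 1
    for read in reads:
        seq = read.upper()
        for i in range(len(seq) - w + 1):
            window_counts[seq[i : i + w]] += 1
    g = graph.copy()
    dropped = 0
    for u, v in graph.edges:
        win = junction_window(graph, u, v, k)
        n = window_counts[win]
        if config.strand_mode == "unstranded":
            n += window_counts[revcomp(win)]
        if n > 0:
            g.set_edge_weight(u, v, float(n))
        else:
            g.remove_edge(u, v)
            dropped += 1
    if dropped:
        log.info("weight_junctions: removed %d unsupported junction(s)", dropped)
    return g


def _recollapse(graph: SplicingGraph, k: int) -> SplicingGraph:
    """Merge u->v chains left linear by trimming (k-1 sequence overlap)."""
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        for u, v in g.edges:
            if u == v:
                continue
            if g.out_degree(u) == 1 and g.in_degree(v) == 1:
                su, sv = g.node_seq(u), g.node_seq(v)
                if len(su) >= k - 1 and su[-(k - 1):] == sv[: k - 1]:
                    lu = len(su) - k + 1  # k-mers in u
                    lv = len(sv) - k + 1
                    cov = (g.node_cov(u) * lu + g.node_cov(v) * lv) / (lu + lv)
                    g.set_node_seq(u, su + sv[k - 1:])
                    g.set_node_cov(u, cov)
                    for _, w_ in g.out_edges(v):
                        g.add_edge(u, w_, g.edge_weight(v, w_))
                    g.remove_node(v)
                    changed = True
                    break
    return g


def trim_and_split(graph: SplicingGraph, config: BuildConfig) -> list[SplicingGraph]:
    """Trim weak structure, then split into per-gene components.

    Iterated to a fixed point, interleaved with linear-chain collapsing:
    (a) dead-end tips shorter than tip_length_factor*k with coverage
    below min_kmer_count are removed; (b) junctions with fewer than
    min_junction_reads spanning reads are removed; (c) weakly connected
    components are returned as separate graphs, each assumed to be one
    expressed gene.
    """
    import networkx as nx

    k = config.k
    g = graph.copy()
    max_tip = config.tip_length_factor * k
    while True:
        changed = False
        for u, v in list(g.edges):
            if g.edge_weight(u, v) < config.min_junction_reads:
                g.remove_edge(u, v)
                changed = True
        for n in list(g.nodes):
            is_tip = g.in_degree(n) == 0 or g.out_degree(n) == 0
            if (
                is_tip
                and (g.in_degree(n) + g.out_degree(n)) > 0  # still attached
                and len(g.node_seq(n)) < max_tip
                and g.node_cov(n) < config.min_kmer_count
            ):
                g.remove_node(n)
                changed = True
        for n in list(g.nodes):
            # fully detached low-coverage debris
            if (
                g.in_degree(n) == 0
                and g.out_degree(n) == 0
                and g.node_cov(n) < config.min_kmer_count
            ):
                g.remove_node(n)
                changed = True
        if not changed:
            break
        g = _recollapse(g, k)
    g = _recollapse(g, k)
    comps = list(nx.weakly_connected_components(g.nx()))
    out: list[SplicingGraph] = []
    for comp in comps:
        sub = SplicingGraph()
        relabel = {
            n: i
            for i, n in enumerate(sorted(comp, key=lambda n: g.node_seq(n)))
        }
        for n in comp:
            sub.add_node(relabel[n], seq=g.node_seq(n), cov=g.node_cov(n))
        for u, v in g.edges:
            if u in comp and v in comp:
                sub.add_edge(relabel[u], relabel[v], g.edge_weight(u, v))
        out.append(sub)
    out.sort(key=lambda sg: sg.node_seq(0) if 0 in sg else "")
    return out


def _component_key(graph: SplicingGraph) -> tuple[str, ...]:
    return tuple(sorted(graph.node_seq(n) for n in graph.nodes))


def _strand_vote(graph: SplicingGraph, read_kmers: set[str], k: int) -> int:
    """Number of forward-read k-mers supporting this component's strand."""
    score = 0
    for n in graph.nodes:
        seq = graph.node_seq(n)
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in read_kmers:
                score += 1
    return score


def build_graphs(
    reads: Sequence[str], config: BuildConfig | None = None
) -> list[SplicingGraph]:
    """Full front end: reads -> per-gene weighted splicing graphs.

    In unstranded mode the reads and their reverse complements are
    assembled together; each component then has a reverse-complement
    twin, and the twin whose k-mers are better supported by the reads as
    given (plurality vote) is kept.
    """
    config = config or BuildConfig()
    reads = [r.upper() for r in reads]
    work_reads = reads
    if config.strand_mode == "unstranded":
        work_reads = list(itertools.chain(reads, (revcomp(r) for r in reads)))
    kg = count_kmers(work_reads, config).drop_low_count(config.min_kmer_count)
    if not kg.kmer_count:
        raise ValueError("no k-mers survive the multiplicity filter")
    collapsed = collapse_linear_paths(kg, config)
    weighted = weight_junctions(collapsed, work_reads, config)
    comps = trim_and_split(weighted, config)
    if config.strand_mode != "unstranded":
        return comps
    # collapse reverse-complement twins, keeping the better-voted strand
    fwd_kmers = {
        r[i : i + config.k]
        for r in reads
        for i in range(len(r) - config.k + 1)
    }
    by_key: dict[tuple[str, ...], list[SplicingGraph]] = {}
    for comp in comps:
        seqs = _component_key(comp)
        rc_seqs = tuple(sorted(revcomp(s) for s in seqs))
        key = min(seqs, rc_seqs)
        by_key.setdefault(key, []).append(comp)
    kept: list[SplicingGraph] = []
    for key, twins in sorted(by_key.items()):
        if len(twins) == 1:
            kept.append(twins[0])
            continue
        scored = sorted(
            twins,
            key=lambda c: (-_strand_vote(c, fwd_kmers, config.k), _component_key(c)),
        )
        if _strand_vote(scored[0], fwd_kmers, config.k) == _strand_vote(
            scored[1], fwd_kmers, config.k
        ):
            log.info("build_graphs: strand ambiguous for one component; "
                     "keeping the lexicographically smaller twin")
        kept.append(scored[0])
    kept.sort(key=_component_key)
    return kept
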