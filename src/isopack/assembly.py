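"""From item trajectories to transcript sequences.

Each live item at the end of the packing sweep occupies one edge per
gap of the canonical graph; those edges form an s-t path whose interior
nodes spell the transcript.  Adjacent nodes created by the k-mer
construction overlap by k-1 bases at each junction, so the path
sequence is the concatenation of node sequences with each junction
overlap collapsed once.  The item's size is reported as the transcript
abundance (coverage) estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.optimize import nnls

from .graph import GraphError, NodeId, SplicingGraph
from .packing import Item


class AssemblyError(ValueError):
    """Inconsistent trajectory or node-overlap mismatch."""


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    node_path: tuple[NodeId, ...]  # sentinels excluded
    sequence: str
    abundance: float

    @property
    def length(self) -> int:
        return len(self.sequence)


def trajectory_to_path(graph: SplicingGraph, item: Item) -> list[NodeId]:
    """Interior node sequence (s and t stripped) induced by the item's bins."""
    edges = item.edges
    if not edges:
        raise AssemblyError(f"item {item.item_id} has an empty trajectory")
    for (a, b), (c, d) in zip(edges, edges[1:]):
        if b != c:
            raise AssemblyError(
                f"item {item.item_id} trajectory is not contiguous: "
                f"{(a, b)} then {(c, d)}"
            )
    nodes = [edges[0][0]] + [v for _, v in edges]
    return [n for n in nodes if n not in (graph.source_id, graph.sink_id)]


def path_to_sequence(graph: SplicingGraph, path: Sequence[NodeId], k: int) -> str:
    """Spell the path: node sequences joined with (k-1)-base junction overlaps.

    Edges from s and to t contribute no sequence.  A junction whose
    flanking node sequences do not actually share the k-1 overlap is an
    upstream construction error and is reported as such.
    """
    if not path:
        raise AssemblyError("empty node path")
    seq = graph.node_seq(path[0])
    ov = k - 1
    for prev, nxt in zip(path, path[1:]):
        s_next = graph.node_seq(nxt)
        if len(seq) < ov or len(s_next) < ov or seq[-ov:] != s_next[:ov]:
            raise AssemblyError(
                f"junction {prev}->{nxt}: flanking sequences do not share "
                f"the expected {ov}-base overlap"
            )
        seq += s_next[ov:]
    return seq


def _depth_factor(transcript_length: int, rl: float, k: int) -> float:
    """Convert junction-spanning read counts to per-base read depth.

    A junction window is covered by reads starting in rl - k of the
    L - rl + 1 admissible positions of a length-L transcript sequenced
    to depth d, so its expected count is d * (L/rl) * (rl-k)/(L-rl+1);
    this returns the inverse factor.
    """
    L = float(transcript_length)
    starts = max(L - rl + 1.0, 1.0)
    return rl * starts / (max(rl - k, 1.0) * L)


def _ramp_factor(m: int, R: float, is_first: bool, is_last: bool) -> float:
    """Mean relative k-mer coverage of a node under terminal read ramps.

    With uniform fragment starts, the j-th k-mer from a transcript end
    is covered by min(j+1, R) of the R = rl-k+1 interior read windows.
    Averaged over a node of m k-mers that contains the transcript start
    (or end) this gives 1 - (R-1)/(2m) when m >= R and (m+1)/(2R) when
    the node lies entirely inside the ramp.
    """
    def one_end(m_: int) -> float:
        if m_ >= R:
            return 1.0 - (R - 1.0) / (2.0 * m_)
        return (m_ + 1.0) / (2.0 * R)

    f = 1.0
    if is_first:
        f -= 1.0 - one_end(m)
    if is_last:
        f -= 1.0 - one_end(m)
    return max(f, 1.0 / (2.0 * R))


def estimate_abundances(
    graph: SplicingGraph,
    items: Sequence[Item],
    k: int,
    mean_read_length: float | None,
) -> dict[int, float]:
    """Least-squares coverage deconvolution over the final path decomposition.

    With the item-to-edge assignment fixed, the packing model reads
    "edge weight = sum of the sizes of the items in the edge"; solving
    that relation in the least-squares sense over every junction edge,
    adding node k-mer coverages as additional (length-weighted, hence
    much less noisy) observations of the same sums, gives the best
    model-consistent size per item.  Results are converted to per-base
    read depth when the mean read length is known; otherwise the raw
    junction-count scale is kept.
    """
    ordered = sorted(items, key=lambda it: it.item_id)
    idx = {it.item_id: j for j, it in enumerate(ordered)}
    paths = {it.item_id: trajectory_to_path(graph, it) for it in ordered}
    sent = (graph.source_id, graph.sink_id)
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    rl = mean_read_length
    # junction-count observations: one per non-sentinel edge
    for u, v in graph.edges:
        if u in sent or v in sent:
            continue
        row = np.zeros(len(ordered))
        for it in ordered:
            if (u, v) in it.edges:
                row[idx[it.item_id]] = 1.0
        rows.append(row)
        rhs.append(graph.edge_weight(u, v))
    # node-coverage observations, rescaled to the junction-count unit.
    # A node holding a transcript end sits under the terminal coverage
    # ramp (only part of the read length can cover it), so its expected
    # contribution from that transcript is damped by _ramp_factor.
    if rl is not None and rl > k + 1:
        q = (rl - k) / (rl - k + 1.0)
        R = rl - k + 1.0
        for n in graph.nodes:
            if n in sent or not graph.node_seq(n):
                continue
            m = max(len(graph.node_seq(n)) - k + 1, 1)
            weight = np.sqrt(m / rl)
            row = np.zeros(len(ordered))
            for it in ordered:
                path = paths[it.item_id]
                if n not in path:
                    continue
                f = _ramp_factor(m, R, is_first=(n == path[0]),
                                 is_last=(n == path[-1]))
                row[idx[it.item_id]] = weight * f
            rows.append(row)
            rhs.append(graph.node_cov(n) * q * weight)
    if not rows:
        return {it.item_id: it.size for it in ordered}
    sol, _ = nnls(np.vstack(rows), np.asarray(rhs))
    out: dict[int, float] = {}
    for it in ordered:
        a = float(sol[idx[it.item_id]])
        if rl is not None and rl > k + 1:
            L = sum(len(graph.node_seq(n)) for n in paths[it.item_id]) - (
                len(paths[it.item_id]) - 1
            ) * (k - 1)
            a *= _depth_factor(L, rl, k)
        out[it.item_id] = max(a, 1e-3)
    return out


def items_to_transcripts(
    graph: SplicingGraph,
    items: Iterable[Item],
    k: int,
    gene_id: str,
    min_length: int = 0,
    mean_read_length: float | None = None,
) -> list[Transcript]:
    """Convert all live items of one gene's graph into transcripts.

    Abundances come from :func:`estimate_abundances` (falling back to
    raw item sizes when no read-length information is supplied).
    Ordered by descending abundance (ties by item id); transcripts
    shorter than ``min_length`` are dropped.
    """
    abund = estimate_abundances(graph, items, k, mean_read_length)
    out: list[Transcript] = []
    ordered = sorted(items, key=lambda it: (-abund[it.item_id], it.item_id))
    n = 0
    for it in ordered:
        path = trajectory_to_path(graph, it)
        if not path:
            continue  # degenerate s->t only trajectory
        seq = path_to_sequence(graph, path, k)
        if len(seq) < min_length:
            continue
        n += 1
        out.append(
            Transcript(
                transcript_id=f"BP.{gene_id}.{n}",
                gene_id=gene_id,
                node_path=tuple(path),
                sequence=seq,
                abundance=abund[it.item_id],
            )
        )
    return out


def single_node_transcript(
    graph: SplicingGraph,
    node: NodeId,
    gene_id: str,
    min_length: int = 0,
    mean_read_length: float | None = None,
    k: int = 25,
) -> list[Transcript]:
    """A junction-free (mono-exon) component emitted directly."""
    seq = graph.node_seq(node)
    if len(seq) < min_length:
        return []
    cov = max(graph.node_cov(node), 0.0)
    rl = mean_read_length
    if rl is not None and rl > k:
        # mean k-mer count -> per-base depth: expected count is
        # d * (L/rl) * (rl-k+1)/(L-rl+1) for a length-L transcript
        L = float(len(seq))
        cov *= rl * max(L - rl + 1.0, 1.0) / ((rl - k + 1.0) * L)
    return [
        Transcript(
            transcript_id=f"BP.{gene_id}.1",
            gene_id=gene_id,
            node_path=(node,),
            sequence=seq,
            abundance=cov,
        )
    ]


def write_fasta(transcripts: Sequence[Transcript], fh: TextIO) -> None:
    """60-column FASTA; header ``>BP.<gene>.<n> len=<L> cov=<abundance>``."""
    if not transcripts:
        raise GraphError("no transcripts to write")
    ordered = sorted(
        transcripts, key=lambda t: (t.gene_id, -t.abundance, t.transcript_id)
    )
    for t in ordered:
        fh.write(f">{t.transcript_id} len={t.length} cov={t.abundance:g}\n")
        for i in range(0, len(t.sequence), 60):
            fh.write(t.sequence[i : i + 60] + "\n")


def write_path_report(transcripts: Sequence[Transcript], fh: TextIO) -> None:
    """TSV path report: gene, transcript, length, abundance, node path."""
    fh.write("gene_id\ttranscript_id\tlength\tabundance\tnode_path\n")
    for t in sorted(
        transcripts, key=lambda t: (t.gene_id, -t.abundance, t.transcript_id)
    ):
        path = ",".join(str(n) for n in t.node_path)
        fh.write(f"{t.gene_id}\t{t.transcript_id}\t{t.length}\t{t.abundance:g}\t{path}\n")
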