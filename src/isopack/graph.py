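"""Weighted splicing graphs and their canonical linear arrangement.

A splicing graph is a directed acyclic graph whose nodes are maximal
unspliced sequence segments ("generalized exons") and whose edges are
splice junctions weighted by read support.  Once the nodes are linearly
arranged by a topological order (the *canonical* splicing graph, every
edge pointing left-to-right), the edges crossing a gap between two
consecutive nodes are pairwise incompatible -- no directed path can use
two of them -- and the largest such crossing set is a maximal set of
pairwise incompatible edges.  That set seeds the packing iteration.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import networkx as nx

log = logging.getLogger(__name__)

NodeId = int | str
Edge = tuple[NodeId, NodeId]

#: Sentinel node identifiers added by the balancer.
SOURCE: str = "__source__"
SINK: str = "__sink__"


class GraphError(ValueError):
    """Structural error in a splicing graph or an operation on one."""


def _node_key(n: NodeId) -> tuple:
    # ints sort numerically among themselves, strings lexicographically;
    # all ints before all strings -> total deterministic order.
    if isinstance(n, bool):  # bool is an int subclass; refuse quietly
        n = int(n)
    if isinstance(n, int):
        return (0, n, "")
    return (1, 0, str(n))


class SplicingGraph:
    """Weighted DAG of sequence nodes and junction edges.

    Node payload: ``seq`` (nucleotide string, may be empty for abstract
    test graphs) and ``cov`` (mean k-mer coverage of the node).  Edge
    payload: ``weight`` (reads spanning the junction, >= 0).
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()
        self.source_id: NodeId | None = None
        self.sink_id: NodeId | None = None

    # -- construction -------------------------------------------------
    def add_node(self, n: NodeId, seq: str = "", cov: float = 0.0) -> None:
        self._g.add_node(n, seq=seq, cov=float(cov))

    def add_edge(self, u: NodeId, v: NodeId, weight: float) -> None:
        if weight < 0:
            raise GraphError(f"negative weight on edge {u}->{v}")
        for n in (u, v):
            if n not in self._g:
                self._g.add_node(n, seq="", cov=0.0)
        self._g.add_edge(u, v, weight=float(weight))

    def remove_edge(self, u: NodeId, v: NodeId) -> None:
        self._g.remove_edge(u, v)

    def remove_node(self, n: NodeId) -> None:
        self._g.remove_node(n)

    def copy(self) -> "SplicingGraph":
        g = SplicingGraph()
        g._g = self._g.copy()
        g.source_id = self.source_id
        g.sink_id = self.sink_id
        return g

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> list[NodeId]:
        return sorted(self._g.nodes, key=_node_key)

    @property
    def edges(self) -> list[Edge]:
        return sorted(self._g.edges, key=lambda e: (_node_key(e[0]), _node_key(e[1])))

    def __contains__(self, n: NodeId) -> bool:
        return n in self._g

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        return self._g.has_edge(u, v)

    def node_seq(self, n: NodeId) -> str:
        return self._g.nodes[n]["seq"]

    def set_node_seq(self, n: NodeId, seq: str) -> None:
        self._g.nodes[n]["seq"] = seq

    def node_cov(self, n: NodeId) -> float:
        return self._g.nodes[n]["cov"]

    def set_node_cov(self, n: NodeId, cov: float) -> None:
        self._g.nodes[n]["cov"] = float(cov)

    def edge_weight(self, u: NodeId, v: NodeId) -> float:
        return self._g.edges[u, v]["weight"]

    def set_edge_weight(self, u: NodeId, v: NodeId, w: float) -> None:
        self._g.edges[u, v]["weight"] = float(w)

    def in_edges(self, n: NodeId) -> list[Edge]:
        return sorted(((u, v) for u, v in self._g.in_edges(n)),
                      key=lambda e: (_node_key(e[0]), _node_key(e[1])))

    def out_edges(self, n: NodeId) -> list[Edge]:
        return sorted(((u, v) for u, v in self._g.out_edges(n)),
                      key=lambda e: (_node_key(e[0]), _node_key(e[1])))

    def in_degree(self, n: NodeId) -> int:
        return self._g.in_degree(n)

    def out_degree(self, n: NodeId) -> int:
        return self._g.out_degree(n)

    def in_weight(self, n: NodeId) -> float:
        return sum(self.edge_weight(u, v) for u, v in self._g.in_edges(n))

    def out_weight(self, n: NodeId) -> float:
        return sum(self.edge_weight(u, v) for u, v in self._g.out_edges(n))

    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self._g)

    def nx(self) -> nx.DiGraph:
        """The underlying networkx view (treat as read-only)."""
        return self._g


@dataclass(frozen=True)
class CanonicalOrder:
    """Linear arrangement of the nodes: 0-based contiguous ranks."""

    position: dict[NodeId, int]
    nodes: tuple[NodeId, ...]  # rank -> node

    def __post_init__(self) -> None:
        assert len(self.nodes) == len(self.position)

    def rank(self, n: NodeId) -> int:
        return self.position[n]

    def node_at(self, r: int) -> NodeId:
        return self.nodes[r]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class EdgeCut:
    """Edges crossing the gap between ranks ``gap_index`` and ``gap_index + 1``."""

    gap_index: int
    crossing_edges: frozenset[Edge]

    def __len__(self) -> int:
        return len(self.crossing_edges)


def break_cycles(graph: SplicingGraph) -> SplicingGraph:
    """Remove cycles by deleting the minimum-weight edge of each detected cycle.

    k-mer graphs of repetitive sequence can contain cycles; the packing
    model requires a DAG.  Dropping the weakest edge of each cycle found
    by depth-first search sacrifices the least read support.  Acyclic
    input is returned unchanged (same object content, new copy).
    """
    if graph.n_nodes() < 1:
        raise GraphError("empty graph")
    g = graph.copy()
    removed = 0
    while True:
        try:
            cycle = nx.find_cycle(g._g, orientation="original")
        except nx.NetworkXNoCycle:
            break
        # minimum-weight edge of the cycle; ties -> smallest (u, v)
        worst = min(
            ((u, v) for u, v, _ in cycle),
            key=lambda e: (g.edge_weight(*e), _node_key(e[0]), _node_key(e[1])),
        )
        g.remove_edge(*worst)
        removed += 1
    if removed:
        log.info("break_cycles: removed %d back-edge(s)", removed)
    return g


def topological_order(graph: SplicingGraph) -> CanonicalOrder:
    """Canonical linear arrangement by Kahn's algorithm.

    Deterministic: among simultaneously available nodes the smallest id
    is placed first, pure sources (only out-edges) gravitate leftmost and
    pure sinks (only in-edges) rightmost; the source/sink sentinels, when
    present, are forced first and last.
    """
    g = graph._g
    s, t = graph.source_id, graph.sink_id

    def prio(n: NodeId) -> tuple:
        if n == s:
            band = 0
        elif n == t:
            band = 3
        elif g.out_degree(n) == 0:
            band = 2  # pure sink: rightmost among peers
        else:
            band = 1
        return (band, _node_key(n))

    indeg = {n: g.in_degree(n) for n in g.nodes}
    heap = [(prio(n), n) for n, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    order: list[NodeId] = []
    while heap:
        _, n = heapq.heappop(heap)
        order.append(n)
        for _, v in g.out_edges(n):
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(heap, (prio(v), v))
    if len(order) != g.number_of_nodes():
        stuck = [n for n, d in indeg.items() if d > 0]
        cyc = nx.find_cycle(g.subgraph(stuck), orientation="original")
        raise GraphError(
            "graph is not acyclic; one cycle: "
            + " -> ".join(str(u) for u, v, _ in cyc)
        )
    return CanonicalOrder(
        position={n: i for i, n in enumerate(order)}, nodes=tuple(order)
    )


def are_compatible(graph: SplicingGraph, e1: Edge, e2: Edge) -> bool:
    """True iff the two edges can lie on one common directed path."""
    for e in (e1, e2):
        if not graph.has_edge(*e):
            raise GraphError(f"edge {e} not in graph")
    if e1 == e2:
        return True
    (a, b), (c, d) = e1, e2
    return nx.has_path(graph._g, b, c) or nx.has_path(graph._g, d, a)


def crossing_edges(graph: SplicingGraph, order: CanonicalOrder, p: int) -> EdgeCut:
    """The edges crossing the gap between consecutive ranks p and p+1."""
    if not 0 <= p < len(order) - 1:
        raise GraphError(f"gap index {p} out of range for {len(order)} nodes")
    pos = order.position
    crossing = frozenset(
        (u, v) for u, v in graph.edges if pos[u] <= p < pos[v]
    )
    return EdgeCut(gap_index=p, crossing_edges=crossing)


def max_incompatible_set(graph: SplicingGraph, order: CanonicalOrder) -> EdgeCut:
    """Largest crossing-edge set over all gaps (ties -> leftmost gap).

    In a canonical splicing graph this is a maximal set of pairwise
    incompatible edges: none can lie on a path with another, and no
    further edge of the graph can be added without breaking that.
    """
    if graph.n_edges() == 0:
        raise GraphError("nothing to pack: graph has no edges")
    best: EdgeCut | None = None
    for p in range(len(order) - 1):
        cut = crossing_edges(graph, order, p)
        if best is None or len(cut) > len(best):
            best = cut
    assert best is not None
    return best


# -- text formats ------------------------------------------------------

def write_graphs(graphs: Iterable[tuple[str, SplicingGraph]], fh: TextIO) -> None:
    """Write records in the plain graph text format.

    One record per graph: ``>graph <id>`` header, ``N <id> <sequence>``
    node lines (a lone ``.`` stands for an empty sequence), ``E <u> <v>
    <weight>`` edge lines.
    """
    for gid, g in graphs:
        fh.write(f">graph {gid}\n")
        for n in g.nodes:
            seq = g.node_seq(n) or "."
            fh.write(f"N {n} {seq} {g.node_cov(n):g}\n")
        for u, v in g.edges:
            fh.write(f"E {u} {v} {g.edge_weight(u, v):g}\n")


def _parse_node_id(tok: str) -> NodeId:
    try:
        return int(tok)
    except ValueError:
        return tok


def read_graphs(fh: TextIO) -> Iterator[tuple[str, SplicingGraph]]:
    """Parse records written by :func:`write_graphs`."""
    gid: str | None = None
    g: SplicingGraph | None = None
    for line in fh:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">graph"):
            if gid is not None:
                yield gid, g
            gid = line.split(None, 1)[1].strip()
            g = SplicingGraph()
        elif line.startswith("N "):
            if g is None:
                raise GraphError("node line before a graph header")
            parts = line.split()
            seq = "" if parts[2] == "." else parts[2]
            cov = float(parts[3]) if len(parts) > 3 else 0.0
            g.add_node(_parse_node_id(parts[1]), seq=seq, cov=cov)
        elif line.startswith("E "):
            if g is None:
                raise GraphError("edge line before a graph header")
            _, u, v, w = line.split()
            g.add_edge(_parse_node_id(u), _parse_node_id(v), float(w))
        else:
            raise GraphError(f"unrecognized graph line: {line!r}")
    if gid is not None:
        yield gid, g


def to_gfa(graph: SplicingGraph, fh: TextIO, name: str = "g") -> None:
    """GFA 1.0 export for visualization; junction weight in an RC:i tag."""
    fh.write("H\tVN:Z:1.0\n")
    for n in graph.nodes:
        seq = graph.node_seq(n) or "*"
        fh.write(f"S\t{name}.{n}\t{seq}\n")
    for u, v in graph.edges:
        w = int(round(graph.edge_weight(u, v)))
        fh.write(f"L\t{name}.{u}\t+\t{name}.{v}\t+\t0M\tRC:i:{w}\n")
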