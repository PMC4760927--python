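"""Source/sink augmentation and balancing of splicing graphs.

Before packing, every splicing graph is embedded between a source ``s``
and a sink ``t``: s feeds every node that has only out-going edges and
every node with only in-coming edges drains to t, with sentinel edge
weights mirroring the flow on the far side of the node.

Balancing then marks transcript ends *interior* to the graph.  A node u
whose in-weight and out-weight differ markedly is presumed to start (or
end) a transcript mid-graph, so an extra s->u (or u->t) edge carries the
surplus.  "Markedly" is the adaptive ratio threshold

    c = alpha * (gamma - beta) / w_min + beta,   w_min = min(w_in, w_out)

which tightens towards beta as coverage grows (sampling noise shrinks)
and loosens up to gamma at low coverage.  Defaults alpha=10, beta=1.4,
gamma=1.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .graph import SINK, SOURCE, GraphError, NodeId, SplicingGraph, topological_order

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BalanceParams:
    alpha: float = 10.0
    beta: float = 1.4
    gamma: float = 1.5

    def __post_init__(self) -> None:
        if not (self.gamma >= self.beta >= 1.0):
            raise ValueError("require gamma >= beta >= 1")
        if self.alpha < 0:
            raise ValueError("require alpha >= 0")


@dataclass(frozen=True)
class NodeBalance:
    """In/out flow of one interior node and its adaptive threshold."""

    node: NodeId
    w_in: float
    w_out: float
    w_min: float
    c: float  # +inf when w_min == 0


def add_source_sink(graph: SplicingGraph) -> SplicingGraph:
    """Attach the s/t sentinels.

    s->u for every u without in-edges, weighted by u's total out-weight;
    v->t for every v without out-edges, weighted by v's total in-weight.
    An isolated node (a mono-exon gene) gets both, weighted by its
    coverage.
    """
    if graph.n_nodes() < 1:
        raise GraphError("empty graph")
    if graph.source_id is not None or SOURCE in graph or SINK in graph:
        raise GraphError("already augmented with source/sink")
    g = graph.copy()
    g.add_node(SOURCE, seq="")
    g.add_node(SINK, seq="")
    g.source_id = SOURCE
    g.sink_id = SINK
    for n in graph.nodes:
        indeg, outdeg = graph.in_degree(n), graph.out_degree(n)
        if indeg == 0 and outdeg == 0:
            w = max(graph.node_cov(n), 1.0)
            g.add_edge(SOURCE, n, w)
            g.add_edge(n, SINK, w)
            continue
        if indeg == 0:
            g.add_edge(SOURCE, n, graph.out_weight(n))
        if outdeg == 0:
            g.add_edge(n, SINK, graph.in_weight(n))
    return g


def node_balance(
    graph: SplicingGraph, u: NodeId, params: BalanceParams | None = None
) -> NodeBalance:
    """Flow balance of interior node u under the c-threshold rule."""
    params = params or BalanceParams()
    if u in (graph.source_id, graph.sink_id):
        raise GraphError("balance is undefined for the s/t sentinels")
    w_in = graph.in_weight(u)
    w_out = graph.out_weight(u)
    w_min = min(w_in, w_out)
    if w_min > 0:
        c = params.alpha * (params.gamma - params.beta) / w_min + params.beta
    else:
        c = math.inf
    return NodeBalance(node=u, w_in=w_in, w_out=w_out, w_min=w_min, c=c)


def balance_graph(
    graph: SplicingGraph, params: BalanceParams | None = None
) -> SplicingGraph:
    """Add interior transcript-end edges where the ratio test fires.

    Single pass in canonical order using the pre-pass weights: for each
    interior node u, if w_out/w_in >= c an edge s->u with weight
    w_out - w_in is added (u starts a transcript); if w_in/w_out >= c an
    edge u->t with weight w_in - w_out is added (u ends one).  A node
    with a zero-weight side is always augmented with the nonzero side's
    weight.
    """
    params = params or BalanceParams()
    if graph.source_id is None or graph.sink_id is None:
        raise GraphError("augment with add_source_sink before balancing")
    s, t = graph.source_id, graph.sink_id
    order = topological_order(graph)
    g = graph.copy()
    for u in order.nodes:
        if u in (s, t):
            continue
        bal = node_balance(graph, u, params)
        if bal.w_min == 0:
            # degenerate: one side carries no flow at all
            if bal.w_out > 0 and not graph.has_edge(s, u):
                log.info("balance: node %s has zero in-flow; tying to source", u)
                g.add_edge(s, u, bal.w_out)
            elif bal.w_in > 0 and not graph.has_edge(u, t):
                log.info("balance: node %s has zero out-flow; tying to sink", u)
                g.add_edge(u, t, bal.w_in)
            continue
        if bal.w_out / bal.w_in >= bal.c:
            g.add_edge(s, u, bal.w_out - bal.w_in)
        elif bal.w_in / bal.w_out >= bal.c:
            g.add_edge(u, t, bal.w_in - bal.w_out)
    return g


def prepare(graph: SplicingGraph, params: BalanceParams | None = None) -> SplicingGraph:
    """Convenience: add_source_sink then balance_graph."""
    return balance_graph(add_source_sink(graph), params)
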