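"""The forth-and-back packing sweep over a balanced splicing graph.

Every edge is a bin whose capacity is its junction weight.  One item is
seeded in each edge of the largest set of pairwise incompatible edges
(the widest gap cut of the canonical graph); the item sizes are those
edge weights and approximate the coverages of the underlying isoforms.
The sweep then pushes items node by node towards the source: at each
node the items carried on its out-edges are packed optimally into its
in-edges (least-squares against capacities, each bin keeping at least
the count it held before).  A *trap* node -- where the carrying side has
fewer items than the receiving side has bins -- retires the carried
items, replaces them with one new item per receiving edge (sized by that
edge's weight), re-packs the new items into the carrying edges under
per-bin minimum counts, and reverses the sweep direction.  On reaching a
sentinel the sweep jumps back to the start of the current iteration and
continues the other way, until every node is processed.  The number of
direction reversals is bounded by |V|: a processed node is never trapped
again.  At termination each live item's bin sequence induces one s-t
path, and together the paths cover every edge of the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .graph import (
    CanonicalOrder,
    _node_key,
    Edge,
    EdgeCut,
    GraphError,
    NodeId,
    SplicingGraph,
    max_incompatible_set,
    topological_order,
)
from .solver import (
    Assignment,
    PackingFormulationError,
    formulate_eq1,
    formulate_eq2,
    solve_exact,
)

log = logging.getLogger(__name__)

LEFT = "left"
RIGHT = "right"


class PackingRuntimeError(RuntimeError):
    """Violation of a packing-sweep invariant (implementation bug)."""


@dataclass
class Item:
    """A tracked packing item; its size approximates one isoform's coverage.

    ``edges`` is the contiguous path segment currently assigned to the
    item, ordered upstream (towards s) to downstream (towards t).
    """

    item_id: int
    size: float
    origin: tuple[int, Edge]  # (iteration index, edge where created)
    edges: list[Edge] = field(default_factory=list)

    def trajectory(self, order: CanonicalOrder) -> dict[int, Edge]:
        """gap index -> edge holding the item at that cut."""
        out: dict[int, Edge] = {}
        for u, v in self.edges:
            for g in range(order.rank(u), order.rank(v)):
                out[g] = (u, v)
        return out

    def edge_at_gap(self, order: CanonicalOrder, g: int) -> Edge | None:
        for u, v in self.edges:
            if order.rank(u) <= g < order.rank(v):
                return (u, v)
        return None


@dataclass(frozen=True)
class EdgePartition:
    """Edges of the two cuts around one node: into it, out of it, spanning it."""

    node: NodeId
    i_in: tuple[Edge, ...]
    i_out: tuple[Edge, ...]
    i_m: tuple[Edge, ...]


@dataclass
class TraceRecord:
    node: NodeId
    direction: str
    n_in: int
    n_out: int
    n_m: int
    n_items: int
    trap: bool
    objective: float | None


@dataclass
class PackingState:
    graph: SplicingGraph
    order: CanonicalOrder
    items: dict[int, Item]
    cursor: int                   # rank of the next node to process
    direction: str
    start_rank: int               # rank of the current iteration's start node
    processed: set[NodeId] = field(default_factory=set)
    iteration_count: int = 1
    occupancy: dict[Edge, int] = field(default_factory=dict)
    next_item_id: int = 0
    trace: list[TraceRecord] = field(default_factory=list)

    def new_item(self, size: float, edge: Edge) -> Item:
        it = Item(
            item_id=self.next_item_id,
            size=size,
            origin=(self.iteration_count, edge),
            edges=[edge],
        )
        self.next_item_id += 1
        self.items[it.item_id] = it
        return it

    def live_items(self) -> list[Item]:
        return [self.items[i] for i in sorted(self.items)]


def init_items(graph: SplicingGraph, cut: EdgeCut) -> PackingState:
    """Seed one item per edge of the maximal incompatible cut."""
    if not cut.crossing_edges:
        raise GraphError("cannot initialize packing from an empty cut")
    order = topological_order(graph)
    state = PackingState(
        graph=graph,
        order=order,
        items={},
        cursor=cut.gap_index,       # n_L = left endpoint of the cut's gap
        direction=LEFT,
        start_rank=cut.gap_index,
    )
    for e in sorted(cut.crossing_edges, key=lambda e: (_node_key(e[0]), _node_key(e[1]))):
        it = state.new_item(size=graph.edge_weight(*e), edge=e)
        state.occupancy[e] = 1
    return state


def partition_at(state: PackingState, node: NodeId) -> EdgePartition:
    """Split the edges of the two cuts flanking ``node`` into in/out/spanning."""
    order = state.order
    r = order.rank(node)
    if node in (state.graph.source_id, state.graph.sink_id):
        raise GraphError("sentinels are never partitioned")
    i_in = tuple(state.graph.in_edges(node))
    i_out = tuple(state.graph.out_edges(node))
    pos = order.position
    i_m = tuple(
        (u, v)
        for u, v in state.graph.edges
        if pos[u] < r < pos[v]
    )
    return EdgePartition(node=node, i_in=i_in, i_out=i_out, i_m=i_m)


def _carrying_and_bins(
    state: PackingState, part: EdgePartition, direction: str
) -> tuple[tuple[Edge, ...], tuple[Edge, ...], int]:
    """(carrying edges, bin edges, item-side gap index) for the direction."""
    r = state.order.rank(part.node)
    if direction == LEFT:
        return part.i_out, part.i_in, r
    return part.i_in, part.i_out, r - 1


def _items_on(state: PackingState, edges: tuple[Edge, ...], gap: int) -> list[Item]:
    es = set(edges)
    return [
        it
        for it in state.live_items()
        if it.edge_at_gap(state.order, gap) in es
    ]


def is_trap(state: PackingState, part: EdgePartition, direction: str) -> bool:
    """True iff the carrying side has fewer edges than the bin side.

    Moving left this is the cardinality test |I_out| < |I_in| (mirrored
    when moving right).  A node that has already been processed is never
    trapped again: on re-crossings the minimum-count bookkeeping
    guarantees enough items are available, and the node's structure has
    already been explained.
    """
    if part.node in state.processed:
        return False
    carrying, bins, _ = _carrying_and_bins(state, part, direction)
    return len(carrying) < len(bins)


def _feasible_mins(raw: list[int], n_items: int) -> list[int]:
    """Cap per-bin minimum counts so they sum to at most the item count.

    The "at least as many as last time" rule can become infeasible after
    a trap shrinks the item population; the largest minima are reduced
    first (never below one).
    """
    mins = [max(1, m) for m in raw]
    while sum(mins) > n_items:
        i = max(range(len(mins)), key=lambda j: (mins[j], -j))
        if mins[i] <= 1:
            break  # cannot reduce further; caller will raise
        mins[i] -= 1
    return mins


def _min_counts(
    state: PackingState, bins: tuple[Edge, ...], n_items: int
) -> list[int]:
    return _feasible_mins(
        [state.occupancy.get(e, 1) for e in bins], n_items
    )


def step_node(state: PackingState, node: NodeId) -> PackingState:
    """Pack the carried items into this node's receiving edges (no trap)."""
    part = partition_at(state, node)
    carrying, bins, gap = _carrying_and_bins(state, part, state.direction)
    movers = _items_on(state, carrying, gap)
    if len(movers) < len(bins):
        raise PackingRuntimeError(
            f"step_node called on trap node {node} "
            f"({len(movers)} items, {len(bins)} bins)"
        )
    mins = _min_counts(state, bins, len(movers))
    if sum(mins) > len(movers):
        raise PackingRuntimeError(
            f"occupancy bookkeeping violated at node {node}: minimum counts "
            f"{mins} exceed {len(movers)} items"
        )
    caps = [state.graph.edge_weight(*e) for e in bins]
    sizes = [it.size for it in movers]
    if all(c == 1 for c in mins):
        inst = formulate_eq1(caps, sizes)
    else:
        inst = formulate_eq2(caps, sizes, mins)
    sol = solve_exact(inst)
    _apply_assignment(state, movers, bins, sol, gap)
    state.processed.add(node)
    state.trace.append(
        TraceRecord(
            node=node,
            direction=state.direction,
            n_in=len(part.i_in),
            n_out=len(part.i_out),
            n_m=len(part.i_m),
            n_items=len(movers),
            trap=False,
            objective=sol.objective,
        )
    )
    return state


def _apply_assignment(
    state: PackingState,
    movers: list[Item],
    bins: tuple[Edge, ...],
    sol: Assignment,
    gap: int,
) -> None:
    counts = [0] * len(bins)
    for j, it in enumerate(movers):
        i = sol.bin_of(j)
        counts[i] += 1
        b = bins[i]
        cur = it.edge_at_gap(state.order, gap)
        idx = it.edges.index(cur)
        if state.direction == LEFT:
            it.edges = [b] + it.edges[idx:]       # drop any stale upstream
        else:
            it.edges = it.edges[: idx + 1] + [b]  # drop any stale downstream
    for i, b in enumerate(bins):
        state.occupancy[b] = counts[i]


def handle_trap(state: PackingState, node: NodeId) -> PackingState:
    """Replace the carried items at a trap node and reverse the sweep.

    The retired items' processed-side trajectory segments are inherited
    by the new items packed into their edges (round-robin within each
    edge), so every already-explained splicing event stays covered.
    """
    part = partition_at(state, node)
    carrying, bins, _ = _carrying_and_bins(state, part, state.direction)
    if len(carrying) >= len(bins):
        raise PackingRuntimeError(f"handle_trap called on non-trap node {node}")
    if node in state.processed:
        raise PackingRuntimeError(
            f"node {node} trapped again after being processed "
            "(violates the no-retrap guarantee)"
        )
    _replace_items(state, node, part, trap=True)
    # reverse: next iteration starts from the trap node, opposite direction
    r = state.order.rank(node)
    state.direction = RIGHT if state.direction == LEFT else LEFT
    state.iteration_count += 1
    state.start_rank = r
    state.cursor = r + 1 if state.direction == RIGHT else r - 1
    return state


def replenish_items(state: PackingState, node: NodeId) -> PackingState:
    """Re-seed items at a processed node left short-handed by a trap.

    A trap that retires more items than it creates shrinks the live
    population; a later sweep re-crossing an already-processed node can
    then find fewer items than receiving edges.  The same replacement
    machinery restores one item per receiving edge, but the sweep keeps
    its direction -- the node's structure was already explained, so this
    is refinement, not a new iteration.
    """
    part = partition_at(state, node)
    _replace_items(state, node, part, trap=False)
    return state


def _replace_items(
    state: PackingState, node: NodeId, part: EdgePartition, trap: bool
) -> None:
    carrying, bins, gap = _carrying_and_bins(state, part, state.direction)
    retired = _items_on(state, carrying, gap)
    # new items: one per bin-side edge, sized by its weight
    new_items = [
        state.new_item(size=state.graph.edge_weight(*b), edge=b) for b in bins
    ]
    # re-pack the new items into the carrying edges under minimum counts
    mins = _min_counts(state, carrying, len(new_items))
    if sum(mins) > len(new_items):
        raise PackingFormulationError(
            f"trap replacement infeasible at node {node}: minimum counts "
            f"{mins} exceed {len(new_items)} new items "
            "(occupancy bookkeeping bug)"
        )
    caps = [state.graph.edge_weight(*e) for e in carrying]
    inst = formulate_eq2(caps, [it.size for it in new_items], mins)
    sol = solve_exact(inst)
    # hand off trajectories: new item -> retired partner within its edge
    by_edge: dict[Edge, list[Item]] = {}
    for it in retired:
        e = it.edge_at_gap(state.order, gap)
        by_edge.setdefault(e, []).append(it)
    for partners in by_edge.values():
        partners.sort(key=lambda it: it.item_id)
    taken: dict[Edge, int] = {e: 0 for e in by_edge}
    counts = [0] * len(carrying)
    for j, it in enumerate(new_items):
        i = sol.bin_of(j)
        counts[i] += 1
        ce = carrying[i]
        partners = by_edge.get(ce, [])
        if not partners:
            raise PackingRuntimeError(
                f"carrying edge {ce} held no retired item at trap node {node}"
            )
        partner = partners[taken[ce] % len(partners)]
        taken[ce] += 1
        idx = partner.edges.index(ce)
        if state.direction == LEFT:
            it.edges = it.edges + partner.edges[idx:]
        else:
            it.edges = partner.edges[: idx + 1] + it.edges
    for it in retired:
        del state.items[it.item_id]
    for i, e in enumerate(carrying):
        state.occupancy[e] = counts[i]
    for b in bins:
        state.occupancy[b] = 1
    state.processed.add(node)
    state.trace.append(
        TraceRecord(
            node=node,
            direction=state.direction,
            n_in=len(part.i_in),
            n_out=len(part.i_out),
            n_m=len(part.i_m),
            n_items=len(retired),
            trap=trap,
            objective=sol.objective,
        )
    )


def run(graph: SplicingGraph) -> tuple[PackingState, list[Item]]:
    """Execute the full sweep; return the final state and the live items.

    The graph must be balanced (source/sink present, every node on an
    s-t path).  Raises if the iteration bound |V| is exceeded or a
    terminal invariant (path contiguity, edge cover) fails.
    """
    if graph.source_id is None or graph.sink_id is None:
        raise GraphError("packing requires a balanced graph with s and t")
    order = topological_order(graph)
    cut = max_incompatible_set(graph, order)
    state = init_items(graph, cut)
    n_total = graph.n_nodes()
    interior = set(graph.nodes) - {graph.source_id, graph.sink_id}
    max_iterations = n_total
    while True:
        if state.iteration_count > max_iterations:
            raise PackingRuntimeError(
                f"packing exceeded the {max_iterations}-iteration bound"
            )
        node = order.node_at(state.cursor)
        if node in (graph.source_id, graph.sink_id):
            if state.processed >= interior:
                break
            # jump back to the current iteration's start node, reverse
            state.direction = RIGHT if state.direction == LEFT else LEFT
            state.iteration_count += 1
            state.cursor = (
                state.start_rank + 1
                if state.direction == RIGHT
                else state.start_rank - 1
            )
            continue
        part = partition_at(state, node)
        if is_trap(state, part, state.direction):
            handle_trap(state, node)
        else:
            carrying, bins, gap = _carrying_and_bins(state, part, state.direction)
            if len(_items_on(state, carrying, gap)) < len(bins):
                replenish_items(state, node)
            else:
                step_node(state, node)
            state.cursor += 1 if state.direction == RIGHT else -1
    items = state.live_items()
    _validate_final(state, items)
    return state, items


def _validate_final(state: PackingState, items: list[Item]) -> None:
    g, order = state.graph, state.order
    covered: set[Edge] = set()
    for it in items:
        edges = it.edges
        if edges[0][0] != g.source_id or edges[-1][1] != g.sink_id:
            raise PackingRuntimeError(
                f"item {it.item_id} trajectory does not run s->t: {edges}"
            )
        for (a, b), (c, d) in zip(edges, edges[1:]):
            if b != c:
                raise PackingRuntimeError(
                    f"item {it.item_id} trajectory not contiguous at {b}!={c}"
                )
        covered.update(edges)
    missing = set(g.edges) - covered
    if missing:
        raise PackingRuntimeError(
            f"edge-path cover violated; uncovered edges: {sorted(missing)}"
        )
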