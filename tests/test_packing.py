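"""The packing sweep: initialization, partitions, traps, full runs."""

import numpy as np
import pytest

from isopack import (
    init_items,
    max_incompatible_set,
    prepare,
    run_packing,
    topological_order,
)
from isopack.graph import GraphError
from isopack.packing import (
    LEFT,
    RIGHT,
    PackingRuntimeError,
    is_trap,
    partition_at,
    step_node,
)

from conftest import make_random_balanced_dag


def _prepared_state(graph):
    order = topological_order(graph)
    cut = max_incompatible_set(graph, order)
    return init_items(graph, cut), cut


def direction_runs(state):
    """Collapse the node-visit trace into (direction, [(node, trap)]) runs."""
    runs = []
    for rec in state.trace:
        if not runs or runs[-1][0] != rec.direction:
            runs.append((rec.direction, []))
        runs[-1][1].append((rec.node, rec.trap))
    return runs


class TestInitItems:
    def test_items_mirror_cut_weights(self, diamond_graph):
        bal = prepare(diamond_graph)
        state, cut = _prepared_state(bal)
        assert len(state.items) == len(cut)
        assert sorted(it.size for it in state.items.values()) == [10, 30]

    def test_single_edge_cut_single_item(self, chain_graph):
        bal = prepare(chain_graph)
        state, cut = _prepared_state(bal)
        assert len(state.items) == 1

    def test_item_count_equals_cut_cardinality_on_random_graphs(self):
        rng = np.random.default_rng(41)
        for _ in range(15):
            bal = make_random_balanced_dag(rng, 8)
            if bal is None:
                continue
            state, cut = _prepared_state(bal)
            assert len(state.items) == len(cut)

    def test_empty_cut_rejected(self, diamond_graph):
        from isopack.graph import EdgeCut

        bal = prepare(diamond_graph)
        with pytest.raises(GraphError):
            init_items(bal, EdgeCut(gap_index=0, crossing_edges=frozenset()))


class TestPartition:
    def test_chain_node_one_in_one_out(self, chain_graph):
        bal = prepare(chain_graph)
        state, _ = _prepared_state(bal)
        part = partition_at(state, 2)
        assert len(part.i_in) == 1 and len(part.i_out) == 1
        assert part.i_m == ()

    def test_diamond_partition_sets(self, diamond_graph):
        bal = prepare(diamond_graph)
        state, _ = _prepared_state(bal)
        part = partition_at(state, "b")  # order: s, a, b, c, d, t
        assert part.i_in == (("a", "b"),)
        assert part.i_out == (("b", "d"),)
        assert set(part.i_m) == {("a", "c")}

    def test_partition_sets_disjoint_and_cover_cut_union(self):
        rng = np.random.default_rng(43)
        for _ in range(15):
            bal = make_random_balanced_dag(rng, 8)
            if bal is None:
                continue
            state, _ = _prepared_state(bal)
            order = state.order
            for node in order.nodes[1:-1]:
                part = partition_at(state, node)
                sets = [set(part.i_in), set(part.i_out), set(part.i_m)]
                assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
                from isopack import crossing_edges

                r = order.rank(node)
                union = (
                    crossing_edges(bal, order, r - 1).crossing_edges
                    | crossing_edges(bal, order, r).crossing_edges
                )
                assert sets[0] | sets[1] | sets[2] == union

    def test_sentinels_not_partitioned(self, chain_graph):
        bal = prepare(chain_graph)
        state, _ = _prepared_state(bal)
        with pytest.raises(GraphError):
            partition_at(state, bal.source_id)


class TestTrapDetection:
    def test_chain_nodes_never_trap(self, chain_graph):
        bal = prepare(chain_graph)
        state, _ = _prepared_state(bal)
        for node in (1, 2, 3):
            part = partition_at(state, node)
            assert not is_trap(state, part, LEFT)
            assert not is_trap(state, part, RIGHT)

    def test_fewer_carrying_edges_than_bins_is_a_trap(self, sweep_fixture_graph):
        state, _ = _prepared_state(sweep_fixture_graph)
        part = partition_at(state, 2)  # out: {2->3}; in: {1->2, s->2}
        assert is_trap(state, part, LEFT)
        assert not is_trap(state, part, RIGHT)

    def test_processed_nodes_are_exempt(self, sweep_fixture_graph):
        state, _ = _prepared_state(sweep_fixture_graph)
        part = partition_at(state, 2)
        state.processed.add(2)
        assert not is_trap(state, part, LEFT)


class TestStepNode:
    def test_forced_assignment_into_single_upstream_bin(self, diamond_graph):
        bal = prepare(diamond_graph)
        state, _ = _prepared_state(bal)
        # start node is "a": both items pack into the single s->a bin
        step_node(state, "a")
        assert state.trace[-1].objective == 0.0
        for it in state.items.values():
            assert it.edges[0] == (bal.source_id, "a")

    def test_least_squares_objective_of_mismatched_bins(self):
        from isopack import SplicingGraph
        from isopack.graph import SINK, SOURCE

        g = SplicingGraph()
        g.add_node(SOURCE), g.add_node(SINK)
        g.source_id, g.sink_id = SOURCE, SINK
        # two branches (10, 30) feeding bins of capacities 12 and 29
        for u, v, w in [
            (SOURCE, "a", 12), (SOURCE, "b", 29), ("a", "m", 12), ("b", "m", 29),
            ("m", "x", 10), ("m", "y", 30), ("x", SINK, 10), ("y", SINK, 30),
        ]:
            g.add_edge(u, v, w)
        from isopack import crossing_edges

        order = topological_order(g)
        cut = crossing_edges(g, order, order.rank("m"))
        assert set(cut.crossing_edges) == {("m", "x"), ("m", "y")}
        state = init_items(g, cut)
        step_node(state, "m")
        assert state.trace[-1].objective == pytest.approx(5.0)  # (12-10)^2 + (29-30)^2

    def test_every_bin_occupied_after_step(self, diamond_graph):
        bal = prepare(diamond_graph)
        state, _ = _prepared_state(bal)
        step_node(state, "a")
        for e in bal.in_edges("a"):
            assert state.occupancy[e] >= 1


class TestRun:
    def test_chain_yields_single_full_trajectory(self, chain_graph):
        bal = prepare(chain_graph)
        state, items = run_packing(bal)
        assert len(items) == 1
        assert set(items[0].edges) == set(bal.edges)

    def test_diamond_trajectories_follow_branch_weights(self, diamond_graph):
        bal = prepare(diamond_graph)
        state, items = run_packing(bal)
        assert len(items) == 2
        by_size = {it.size: it for it in items}
        assert ("a", "b") in by_size[10].edges
        assert ("a", "c") in by_size[30].edges

    def test_sweep_direction_sequence_with_two_traps(self, sweep_fixture_graph):
        state, items = run_packing(sweep_fixture_graph)
        runs = direction_runs(state)
        assert [d for d, _ in runs] == [LEFT, RIGHT, LEFT, RIGHT]
        assert runs[0][1][-1] == (2, True)   # first iteration traps at node 2
        assert runs[1][1][-1] == (6, True)   # second traps at node 6
        assert runs[2][1][-1][0] == 1        # third reaches the source side
        assert state.iteration_count <= sweep_fixture_graph.n_nodes()

    def test_unbalanced_graph_rejected(self, chain_graph):
        with pytest.raises(GraphError):
            run_packing(chain_graph)

    def test_random_graphs_terminate_and_cover_all_edges(self):
        rng = np.random.default_rng(47)
        checked = 0
        for _ in range(40):
            bal = make_random_balanced_dag(rng, int(rng.integers(3, 13)))
            if bal is None:
                continue
            checked += 1
            state, items = run_packing(bal)  # run() validates cover + paths
            assert state.iteration_count <= bal.n_nodes()
            covered = set()
            for it in items:
                covered.update(it.edges)
            assert covered == set(bal.edges)
        assert checked >= 20

    def test_item_count_constant_without_traps(self, diamond_graph):
        bal = prepare(diamond_graph)
        state, items = run_packing(bal)
        assert not any(rec.trap for rec in state.trace)
        assert len(items) == 2

    def test_live_items_sit_in_one_bin_per_processed_cut(self, sweep_fixture_graph):
        state, items = run_packing(sweep_fixture_graph)
        order = state.order
        for g in range(len(order) - 1):
            for it in items:
                edges_at_gap = [
                    e for e in it.edges
                    if order.rank(e[0]) <= g < order.rank(e[1])
                ]
                assert len(edges_at_gap) == 1
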