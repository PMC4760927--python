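"""Shared fixtures: toy splicing graphs and random-graph generators."""

from __future__ import annotations

import numpy as np
import pytest

from isopack import SplicingGraph, prepare
from isopack.graph import SINK, SOURCE


@pytest.fixture
def chain_graph() -> SplicingGraph:
    """1 -> 2 -> 3, uniform weight 7."""
    g = SplicingGraph()
    for n in (1, 2, 3):
        g.add_node(n, seq="", cov=7.0)
    g.add_edge(1, 2, 7)
    g.add_edge(2, 3, 7)
    return g


@pytest.fixture
def diamond_graph() -> SplicingGraph:
    """a -> {b, c} -> d with branch weights 10/30 and matched flanks."""
    g = SplicingGraph()
    for n in ("a", "b", "c", "d"):
        g.add_node(n)
    g.add_edge("a", "b", 10)
    g.add_edge("a", "c", 30)
    g.add_edge("b", "d", 10)
    g.add_edge("c", "d", 30)
    return g


@pytest.fixture
def sweep_fixture_graph() -> SplicingGraph:
    """Pre-balanced 7-node graph whose sweep starts at node 4 and traps
    at node 2 (moving left) and node 6 (moving right) before finishing."""
    g = SplicingGraph()
    for n in range(1, 8):
        g.add_node(n)
    g.add_node(SOURCE)
    g.add_node(SINK)
    g.source_id, g.sink_id = SOURCE, SINK
    edges = [
        (SOURCE, 1, 30), (SOURCE, 2, 20), (1, 2, 15), (1, 3, 64),
        (2, 3, 36), (3, 4, 40), (3, 5, 20), (3, 7, 40), (4, 5, 10),
        (4, 7, 30), (5, 6, 30), (6, 7, 25), (6, SINK, 35), (7, SINK, 95),
    ]
    for u, v, w in edges:
        g.add_edge(u, v, w)
    return g


def make_random_dag(rng: np.random.Generator, n_nodes: int,
                    edge_prob: float = 0.4, max_weight: int = 50) -> SplicingGraph:
    """Random DAG on nodes 1..n with integer weights; edges go low -> high."""
    g = SplicingGraph()
    for n in range(1, n_nodes + 1):
        g.add_node(n)
    for u in range(1, n_nodes + 1):
        for v in range(u + 1, n_nodes + 1):
            if rng.random() < edge_prob:
                g.add_edge(u, v, int(rng.integers(1, max_weight + 1)))
    # drop isolated nodes so every node can sit on an s-t path
    for n in list(g.nodes):
        if g.in_degree(n) == 0 and g.out_degree(n) == 0:
            g.remove_node(n)
    return g


def make_random_balanced_dag(rng: np.random.Generator, n_nodes: int) -> SplicingGraph | None:
    """Random DAG run through source/sink augmentation and balancing.

    Returns None when the draw has no edges (caller should redraw).
    """
    g = make_random_dag(rng, n_nodes)
    if g.n_nodes() == 0 or g.n_edges() == 0:
        return None
    return prepare(g)
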