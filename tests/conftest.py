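"""Shared fixtures: small hand-checked flow graphs and random generators."""

from __future__ import annotations

import numpy as np
import pytest

from safeflow import FlowGraph


@pytest.fixture
def g1() -> FlowGraph:
    """Diamond funnel: two vertex-disjoint s-t paths, unique decomposition."""
    return FlowGraph("g1", 4, [(0, 1, 1), (1, 3, 1), (0, 2, 2), (2, 3, 2)])


@pytest.fixture
def g2() -> FlowGraph:
    """Fork after a heavy first edge: 0->1 (5) splits into 3 and 2."""
    return FlowGraph(
        "g2", 5, [(0, 1, 5), (1, 2, 3), (1, 3, 2), (2, 4, 3), (3, 4, 2)]
    )


@pytest.fixture
def g3() -> FlowGraph:
    """Double diamond through a central merge/fork vertex (not a funnel)."""
    return FlowGraph(
        "g3",
        7,
        [
            (0, 1, 1),
            (0, 2, 2),
            (1, 3, 1),
            (2, 3, 2),
            (3, 4, 1),
            (3, 5, 2),
            (4, 6, 1),
            (5, 6, 2),
        ],
    )


@pytest.fixture
def chain() -> FlowGraph:
    return FlowGraph("chain", 4, [(0, 1, 7), (1, 2, 7), (2, 3, 7)])


def random_guard_graph(
    rng: np.random.Generator,
    max_flow: int = 6,
    max_edges: int = 10,
    max_n: int = 7,
) -> FlowGraph:
    """Random integer flow graph inside the brute-force oracle's guard.

    Built by superimposing 1-3 random s-t paths (increasing vertex
    sequences) with small integer weights, so flow conservation holds by
    construction.  Rejection-sampled to the guard bounds.
    """
    while True:
        n = int(rng.integers(4, max_n + 1))
        n_paths = int(rng.integers(2, 5))
        flow: dict[tuple[int, int], int] = {}
        total = 0
        for _ in range(n_paths):
            inner = [v for v in range(1, n - 1) if rng.random() < 0.5]
            verts = [0, *inner, n - 1]
            w = int(rng.integers(1, 3))
            total += w
            for u, v in zip(verts, verts[1:]):
                flow[(u, v)] = flow.get((u, v), 0) + w
        if total > max_flow or len(flow) > max_edges:
            continue
        used = sorted({u for u, _ in flow} | {v for _, v in flow})
        relabel = {v: i for i, v in enumerate(used)}
        edges = [(relabel[u], relabel[v], w) for (u, v), w in sorted(flow.items())]
        return FlowGraph(f"rand-{rng.integers(1 << 30)}", len(used), edges)


def all_paths_up_to(g: FlowGraph, max_len: int) -> list[tuple[int, ...]]:
    """Every directed edge-id path of ``g`` with 1..max_len edges."""
    out: list[tuple[int, ...]] = []

    def walk(path: list[int]) -> None:
        out.append(tuple(path))
        if len(path) == max_len:
            return
        for e in g.out_edges(g.head(path[-1])):
            path.append(e)
            walk(path)
            path.pop()

    for e in range(g.m):
        walk([e])
    return out


def all_paths(g: FlowGraph) -> list[tuple[int, ...]]:
    return all_paths_up_to(g, g.n)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
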