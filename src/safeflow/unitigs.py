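"""Unitigs, extended unitigs, and funnel detection.

A *unitig* is a path whose internal vertices all have indegree 1 and
outdegree 1 — the classic assembly-graph notion of an unambiguous stretch.
An *extended unitig* additionally grows left through vertices of indegree
exactly 1 and right through vertices of outdegree exactly 1; the extension
uses degrees only, never weights, yet every extended unitig is safe: each
extension step has zero excess-flow leakage, so the excess stays equal to
the (positive) seed-edge flow.

A *funnel* is a DAG in which no merge vertex (indegree >= 2) reaches a fork
vertex (outdegree >= 2) — equivalently every source-to-sink path owns a
private edge.  Funnels have a unique flow decomposition, so every
decomposition algorithm is trivially perfect on them; datasets are filtered
for funnels before comparing algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx

from .graph import FlowGraph
from .safepaths import deduplicate_subpaths

__all__ = ["UnitigSet", "unitigs", "extended_unitigs", "is_funnel"]


@dataclass
class UnitigSet:
    paths: list[tuple[int, ...]]
    kind: Literal["unitig", "extended"]

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)


def _linear(g: FlowGraph, v: int) -> bool:
    return g.indegree(v) == 1 and g.outdegree(v) == 1


def unitigs(g: FlowGraph) -> UnitigSet:
    """All maximal unitigs; every edge belongs to exactly one."""
    out: list[tuple[int, ...]] = []
    for e in range(g.m):
        # e starts a maximal unitig iff its tail cannot absorb it leftward
        if _linear(g, g.tail(e)):
            continue
        chain = [e]
        while _linear(g, g.head(chain[-1])):
            chain.append(g.out_edges(g.head(chain[-1]))[0])
        out.append(tuple(chain))
    return UnitigSet(paths=out, kind="unitig")


def _extend(g: FlowGraph, seed: tuple[int, ...]) -> tuple[int, ...]:
    chain = list(seed)
    while g.indegree(g.tail(chain[0])) == 1:
        chain.insert(0, g.in_edges(g.tail(chain[0]))[0])
    while g.outdegree(g.head(chain[-1])) == 1:
        chain.append(g.out_edges(g.head(chain[-1]))[0])
    return tuple(chain)


def extended_unitigs(g: FlowGraph) -> UnitigSet:
    """Extend every unitig (and every single edge) through unit-degree
    vertices, then drop results contained in others."""
    seeds: list[tuple[int, ...]] = list(unitigs(g).paths)
    seeds.extend((e,) for e in range(g.m))
    extended = [_extend(g, s) for s in seeds]
    return UnitigSet(paths=deduplicate_subpaths(extended), kind="extended")


def is_funnel(g: FlowGraph) -> bool:
    """True iff no merge vertex (indegree >= 2) reaches a fork vertex
    (outdegree >= 2), the same vertex included; O(n + m)."""
    merges = [v for v in range(g.n) if g.indegree(v) >= 2]
    forks = {v for v in range(g.n) if g.outdegree(v) >= 2}
    if not merges or not forks:
        return True
    nxg = nx.DiGraph(g.to_networkx())
    reachable: set[int] = set()
    for v in merges:
        if v not in reachable:
            reachable.add(v)
            reachable |= nx.descendants(nxg, v)
    return not (reachable & forks)
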