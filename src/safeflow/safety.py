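"""Excess flow and w-safety.

A path ``P`` is *w-safe* (w > 0) when, in every flow decomposition of the
graph, the paths that contain ``P`` as a subpath carry total weight at least
``w``; ``P`` is *safe* when it is w-safe for some positive ``w``.

The *excess flow* ``f_P`` characterizes this locally: it is the weight of the
first edge minus the flow leaking out of the path at its internal vertices
(*diverging* form), equivalently the weight of the last edge minus the flow
entering at internal vertices (*converging* form).  ``P`` is w-safe exactly
when ``f_P >= w``, so safety can be verified in time linear in ``|P|`` after
an O(m) preprocessing of the per-vertex flow sums.

For testing, :func:`brute_force_safety_oracle` checks the definition directly
by enumerating *all* integer flow decompositions of a (tiny) graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .graph import FlowGraph, in_out_flow

__all__ = [
    "SafetyIndex",
    "excess_flow",
    "is_w_safe",
    "extend_delta",
    "enumerate_all_decompositions",
    "brute_force_safety_oracle",
    "oracle_max_safe_weight",
    "OracleGuardError",
]

#: Default guards for the exponential all-decompositions oracle.
ORACLE_MAX_FLOW = 8
ORACLE_MAX_EDGES = 12


class OracleGuardError(ValueError):
    """The brute-force oracle refused an instance above its size guard."""


@dataclass
class SafetyIndex:
    """O(m)-preprocessed per-vertex flow sums for O(|P|) safety queries."""

    graph: FlowGraph
    fin: Sequence[float]
    fout: Sequence[float]

    @classmethod
    def build(cls, g: FlowGraph) -> "SafetyIndex":
        fin, fout = in_out_flow(g)
        return cls(graph=g, fin=fin, fout=fout)


def _check_path(g: FlowGraph, path: Sequence[int]) -> None:
    if not path:
        raise ValueError("excess flow is undefined for an empty path")
    for a, b in zip(path, path[1:]):
        if g.head(a) != g.tail(b):
            raise ValueError(f"edges {a} and {b} are not consecutive")


def excess_flow(g: FlowGraph, path: Sequence[int]) -> float:
    """Excess flow ``f_P`` of a contiguous edge-id path (may be negative).

    Both the diverging and the converging formulation are evaluated and, in
    integer mode, asserted equal — they coincide by conservation of flow.
    A single-edge path has no internal vertices, so ``f_P = f(e)``.
    """
    _check_path(g, path)
    fin, fout = in_out_flow(g)
    diverging = g.weight(path[0])
    converging = g.weight(path[-1])
    for prev, nxt in zip(path, path[1:]):
        u = g.head(prev)  # internal vertex between consecutive path edges
        diverging -= fout[u] - g.weight(nxt)
        converging -= fin[u] - g.weight(prev)
    if g.is_integer():
        assert diverging == converging, "conservation of flow violated"
    return diverging


def extend_delta(index: SafetyIndex, edge: int, side: Literal["start", "end"]) -> float:
    """Excess-flow reduction from extending a path by ``edge``.

    Prepending edge (u, v) reduces the excess by ``fin(v) - f(u, v)``;
    appending it reduces the excess by ``fout(u) - f(u, v)``.  Both are
    nonnegative by conservation, so extension never raises the excess.
    """
    g = index.graph
    u, v, w = g.edges[edge]
    if side == "start":
        return index.fin[v] - w
    if side == "end":
        return index.fout[u] - w
    raise ValueError(f"side must be 'start' or 'end', got {side!r}")


def is_w_safe(index: SafetyIndex, path: Sequence[int], w: float) -> bool:
    """True iff ``path`` is w-safe, i.e. its excess flow is at least ``w``."""
    if w <= 0:
        raise ValueError("w-safety is defined only for w > 0")
    return excess_flow(index.graph, path) >= w


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate every integer flow decomposition
# ---------------------------------------------------------------------------


def _all_st_paths(g: FlowGraph) -> list[tuple[int, ...]]:
    """All s-t paths as edge-id tuples, lexicographic by edge-id sequence."""
    s, t = g.source, g.sink
    out: list[tuple[int, ...]] = []

    def walk(v: int, acc: list[int]) -> None:
        if v == t:
            out.append(tuple(acc))
            return
        for e in sorted(g.out_edges(v)):
            acc.append(e)
            walk(g.head(e), acc)
            acc.pop()

    walk(s, [])
    return out


def _guard(g: FlowGraph, max_flow: int, max_edges: int) -> None:
    if not g.is_integer():
        raise OracleGuardError("oracle requires integer weights")
    if g.m > max_edges:
        raise OracleGuardError(f"m={g.m} exceeds oracle guard {max_edges}")
    _, fout = in_out_flow(g)
    total = fout[g.source]
    if total > max_flow:
        raise OracleGuardError(f"total flow {total} exceeds oracle guard {max_flow}")


def enumerate_all_decompositions(
    g: FlowGraph,
    max_flow: int = ORACLE_MAX_FLOW,
    max_edges: int = ORACLE_MAX_EDGES,
) -> list[tuple[tuple[tuple[int, ...], int], ...]]:
    """Every decomposition of ``g`` into integer-weighted s-t paths.

    A decomposition is a set of *distinct* paths with positive integer
    weights (repeating a path only merges its weight); each is enumerated
    exactly once by peeling paths in strictly increasing lexicographic
    order.  Exponential — guarded by ``max_flow``/``max_edges``.
    """
    _guard(g, max_flow, max_edges)
    paths = _all_st_paths(g)
    residual = [w for _, _, w in g.edges]
    results: list[tuple[tuple[tuple[int, ...], int], ...]] = []

    def rec(start_idx: int, acc: list[tuple[tuple[int, ...], int]]):
        if all(r == 0 for r in residual):
            results.append(tuple(acc))
            return
        for i in range(start_idx, len(paths)):
            cap = min(residual[e] for e in paths[i])
            for w in range(1, cap + 1):
                for e in paths[i]:
                    residual[e] -= w
                acc.append((paths[i], w))
                rec(i + 1, acc)
                acc.pop()
                for e in paths[i]:
                    residual[e] += w

    rec(0, [])
    return results


def _contains_subpath(host: tuple[int, ...], query: Sequence[int]) -> bool:
    q = tuple(query)
    k = len(q)
    return any(host[i : i + k] == q for i in range(len(host) - k + 1))


def oracle_max_safe_weight(
    g: FlowGraph,
    path: Sequence[int],
    decompositions: Sequence | None = None,
    **guards,
) -> int:
    """Largest w such that ``path`` is w-safe, straight from the definition.

    Over all integer decompositions, the minimum total weight of paths
    containing ``path`` as a contiguous subpath (0 if some decomposition
    avoids it entirely).
    """
    _check_path(g, path)
    if decompositions is None:
        decompositions = enumerate_all_decompositions(g, **guards)
    best = None
    for dec in decompositions:
        covered = sum(w for p, w in dec if _contains_subpath(p, path))
        best = covered if best is None else min(best, covered)
    if best is None:
        raise ValueError("graph admits no decomposition (zero flow?)")
    return best


def brute_force_safety_oracle(
    g: FlowGraph,
    path: Sequence[int],
    w: float,
    decompositions: Sequence | None = None,
    **guards,
) -> bool:
    """Definition-level w-safety test by exhaustive decomposition enumeration."""
    if w <= 0:
        raise ValueError("w-safety is defined only for w > 0")
    return oracle_max_safe_weight(g, path, decompositions, **guards) >= w
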