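"""Flow decompositions: simple peeling and the greedy-width heuristic.

*Simple peeling* repeatedly takes a globally minimum-residual edge and
extends it to the source and sink through positive-residual edges; because
the chosen edge is a residual minimum, every iteration zeroes at least one
edge, so at most ``m`` paths are produced.  This decomposition seeds the
safe-path enumeration.

*Greedy-width* repeatedly removes a widest (maximum-bottleneck) s-t path —
the popular transcript-assembly heuristic the safe paths are evaluated
against.

All tie-breaking is by smallest edge-id, so both algorithms are
deterministic without a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import FlowGraph, WeightedPath, topological_order

__all__ = [
    "Decomposition",
    "simple_flow_decomposition",
    "greedy_width_decomposition",
    "widest_path",
    "verify_decomposition",
]


@dataclass
class Decomposition:
    """A multiset of weighted s-t paths whose per-edge sums equal the flow."""

    paths: list[WeightedPath]
    provenance: str = "unknown"
    diagnostics: list[str] = field(default_factory=list)

    def total_size(self) -> int:
        """``||P||`` — summed number of edges over all paths."""
        return sum(len(p) for p in self.paths)

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)


def _extend_to_st(g: FlowGraph, residual: list, seed_edge: int) -> list[int]:
    """Extend an edge to an s-t path along positive-residual edges."""
    path = [seed_edge]
    while True:  # toward the source
        u = g.tail(path[0])
        cands = [e for e in sorted(g.in_edges(u)) if residual[e] > 0]
        if not cands:
            break
        path.insert(0, cands[0])
    while True:  # toward the sink
        v = g.head(path[-1])
        cands = [e for e in sorted(g.out_edges(v)) if residual[e] > 0]
        if not cands:
            break
        path.append(cands[0])
    return path


def simple_flow_decomposition(g: FlowGraph) -> Decomposition:
    """Peel the minimum-residual edge, extended to s and t, until zero flow."""
    s, t = g.source, g.sink
    residual = [w for _, _, w in g.edges]
    paths: list[WeightedPath] = []
    while True:
        live = [e for e in range(g.m) if residual[e] > 0]
        if not live:
            break
        seed = min(live, key=lambda e: (residual[e], e))
        path = _extend_to_st(g, residual, seed)
        if g.tail(path[0]) != s or g.head(path[-1]) != t:
            raise RuntimeError(
                f"residual extension stranded off s/t in {g.name!r}; "
                "flow conservation violated"
            )
        w = min(residual[e] for e in path)
        for e in path:
            residual[e] -= w
        paths.append(WeightedPath(tuple(path), w))
    return Decomposition(paths=paths, provenance="simple")


def widest_path(g: FlowGraph, residual: list) -> WeightedPath:
    """Maximum-bottleneck s-t path over positive residual weights.

    Dynamic program over a topological order; ties between equal-width
    predecessors are broken by the smallest incoming edge-id.
    """
    s, t = g.source, g.sink
    width: dict[int, float] = {s: float("inf")}
    back: dict[int, int] = {}
    for v in topological_order(g):
        if v == s:
            continue
        best_w, best_e = 0, None
        for e in sorted(g.in_edges(v)):
            u = g.tail(e)
            if residual[e] <= 0 or u not in width:
                continue
            cand = min(width[u], residual[e])
            if cand > best_w:
                best_w, best_e = cand, e
        if best_e is not None:
            width[v] = best_w
            back[v] = best_e
    if t not in width:
        raise ValueError("no s-t path with positive residual flow")
    edges: list[int] = []
    v = t
    while v != s:
        e = back[v]
        edges.append(e)
        v = g.tail(e)
    edges.reverse()
    return WeightedPath(tuple(edges), width[t])


def greedy_width_decomposition(g: FlowGraph) -> Decomposition:
    """Repeatedly remove the widest s-t path at its bottleneck weight."""
    residual = [w for _, _, w in g.edges]
    paths: list[WeightedPath] = []
    while any(r > 0 for r in residual):
        p = widest_path(g, residual)
        for e in p.edge_ids:
            residual[e] -= p.weight
            if residual[e] < 0:
                raise RuntimeError("negative residual: conservation violated")
        paths.append(p)
    return Decomposition(paths=paths, provenance="greedy-width")


def verify_decomposition(g: FlowGraph, d: Decomposition) -> bool:
    """True iff every path is a valid s-t path and per-edge sums match f(e)."""
    d.diagnostics.clear()
    try:
        s, t = g.source, g.sink
    except ValueError as exc:
        d.diagnostics.append(str(exc))
        return False
    ok = True
    covered = [0] * g.m
    for i, p in enumerate(d.paths):
        if p.weight <= 0:
            d.diagnostics.append(f"path {i} has nonpositive weight {p.weight}")
            ok = False
        try:
            verts = g.path_vertices(p.edge_ids)
        except ValueError as exc:
            d.diagnostics.append(f"path {i}: {exc}")
            ok = False
            continue
        if verts[0] != s or verts[-1] != t:
            d.diagnostics.append(f"path {i} is not source-to-sink")
            ok = False
        for e in p.edge_ids:
            covered[e] += p.weight
    for e in range(g.m):
        want = g.weight(e)
        if covered[e] != want:
            if not (isinstance(want, float) and abs(covered[e] - want) <= 1e-9 * max(want, 1)):
                d.diagnostics.append(
                    f"edge {e} covered with weight {covered[e]}, flow is {want}"
                )
                ok = False
    return ok
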