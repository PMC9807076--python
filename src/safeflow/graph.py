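"""Flow-graph data model and plain-text I/O.

A *flow graph* is a weighted DAG with a unique source ``s`` (indegree 0), a
unique sink ``t`` (outdegree 0), strictly positive edge weights, and
conservation of flow ``fin(v) == fout(v)`` at every internal vertex.  Splice
graphs built by superimposing weighted transcript paths satisfy these
invariants by construction.

Edges are stored in file order and addressed by their 0-based ordinal
(*edge-id*); paths are sequences of edge-ids so that parallel edges are
unambiguous.  Weights are kept as Python ``int`` whenever every input weight
is integral, which makes all excess-flow arithmetic exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "FlowGraph",
    "WeightedPath",
    "ValidationReport",
    "GraphFormatError",
    "read_graphs",
    "write_graphs",
    "read_truth",
    "write_truth",
    "read_node_lengths",
    "write_node_lengths",
    "augment_single_source_sink",
    "validate_flow_graph",
    "topological_order",
    "in_out_flow",
]


class GraphFormatError(ValueError):
    """Raised for malformed graph/truth/length files (carries a line number)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _coerce_weight(text: str):
    """Parse a weight, preferring exact ints over floats."""
    try:
        return int(text)
    except ValueError:
        value = float(text)
        return int(value) if value.is_integer() else value


@dataclass
class FlowGraph:
    """A weighted DAG with parallel-edge support.

    Parameters
    ----------
    name
        Instance label (the ``#`` header of the file record).
    n
        Vertex count; vertices are labeled ``0 .. n-1``.
    edges
        Ordered list of ``(tail, head, weight)``; the position in this list is
        the edge-id.
    node_lengths
        Optional per-vertex base counts (e.g. exon lengths), ``None`` if the
        instance carries no base information.
    """

    name: str
    n: int
    edges: list[tuple[int, int, float]]
    node_lengths: dict[int, int] | None = None

    # -- derived, cached lazily -------------------------------------------
    _fin: list | None = field(default=None, repr=False, compare=False)
    _fout: list | None = field(default=None, repr=False, compare=False)

    @property
    def m(self) -> int:
        return len(self.edges)

    def tail(self, e: int) -> int:
        return self.edges[e][0]

    def head(self, e: int) -> int:
        return self.edges[e][1]

    def weight(self, e: int):
        return self.edges[e][2]

    def in_edges(self, v: int) -> list[int]:
        self._build_adjacency()
        return self._in_adj[v]

    def out_edges(self, v: int) -> list[int]:
        self._build_adjacency()
        return self._out_adj[v]

    def indegree(self, v: int) -> int:
        return len(self.in_edges(v))

    def outdegree(self, v: int) -> int:
        return len(self.out_edges(v))

    def _build_adjacency(self) -> None:
        if getattr(self, "_in_adj", None) is None:
            self._in_adj = [[] for _ in range(self.n)]
            self._out_adj = [[] for _ in range(self.n)]
            for e, (u, v, _) in enumerate(self.edges):
                self._out_adj[u].append(e)
                self._in_adj[v].append(e)

    def invalidate_caches(self) -> None:
        self._in_adj = None
        self._fin = None
        self._fout = None

    @property
    def source(self) -> int:
        fin, fout = in_out_flow(self)
        sources = [v for v in range(self.n) if self.indegree(v) == 0]
        if len(sources) != 1:
            raise ValueError(f"graph {self.name!r} has {len(sources)} sources")
        return sources[0]

    @property
    def sink(self) -> int:
        sinks = [v for v in range(self.n) if self.outdegree(v) == 0]
        if len(sinks) != 1:
            raise ValueError(f"graph {self.name!r} has {len(sinks)} sinks")
        return sinks[0]

    def is_integer(self) -> bool:
        return all(isinstance(w, int) for _, _, w in self.edges)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(name=self.name)
        g.add_nodes_from(range(self.n))
        for e, (u, v, w) in enumerate(self.edges):
            g.add_edge(u, v, key=e, weight=w)
        return g

    # -- path helpers ------------------------------------------------------
    def path_vertices(self, edge_ids: Sequence[int]) -> list[int]:
        """Vertex sequence spelled by a contiguous edge-id path."""
        if not edge_ids:
            raise ValueError("empty edge sequence has no vertex spelling")
        verts = [self.tail(edge_ids[0])]
        for e in edge_ids:
            if self.tail(e) != verts[-1]:
                raise ValueError(
                    f"edges {edge_ids} are not contiguous at edge {e}"
                )
            verts.append(self.head(e))
        return verts

    def vertex_path_to_edges(self, vertices: Sequence[int]) -> list[int]:
        """Translate a vertex path to edge-ids (smallest id among parallels)."""
        edge_ids = []
        for u, v in zip(vertices, vertices[1:]):
            cands = [e for e in self.out_edges(u) if self.head(e) == v]
            if not cands:
                raise ValueError(f"no edge {u}->{v} in graph {self.name!r}")
            edge_ids.append(min(cands))
        return edge_ids


@dataclass(frozen=True)
class WeightedPath:
    """A contiguous directed path (edge-id sequence) with a flow weight."""

    edge_ids: tuple[int, ...]
    weight: float

    def __post_init__(self):
        if not self.edge_ids:
            raise ValueError("a weighted path needs at least one edge")
        object.__setattr__(self, "edge_ids", tuple(self.edge_ids))

    def __len__(self) -> int:
        return len(self.edge_ids)


# ---------------------------------------------------------------------------
# File I/O.  Record format (one or more records per file):
#   # <name>
#   <n>
#   <u> <v> <w>          (m lines)
# Truth files:   "# <name>" then one "<w> <v0> <v1> ... <vk>" line per path.
# Length files:  "# <name>" then "<v> <length>" lines.
# ---------------------------------------------------------------------------


def _records(lines: Iterable[str]):
    """Split numbered lines into (#-header, body-lines) records."""
    header: tuple[int, str] | None = None
    body: list[tuple[int, str]] = []
    for no, raw in enumerate(lines, start=1):
        text = raw.strip()
        if not text:
            continue
        if text.startswith("#"):
            if header is not None:
                yield header, body
            header = (no, text[1:].strip())
            body = []
        else:
            if header is None:
                raise GraphFormatError("content before first '#' header", no)
            body.append((no, text))
    if header is not None:
        yield header, body


def read_graphs(path) -> list[FlowGraph]:
    """Read all flow-graph records of a plain-text multigraph file."""
    graphs: list[FlowGraph] = []
    with open(path) as fh:
        for (hline, name), body in _records(fh):
            if not body:
                raise GraphFormatError(f"record {name!r} has no vertex count", hline)
            nline, ntext = body[0]
            try:
                n = int(ntext)
            except ValueError:
                raise GraphFormatError(f"bad vertex count {ntext!r}", nline) from None
            edges = []
            for lno, text in body[1:]:
                parts = text.split()
                if len(parts) != 3:
                    raise GraphFormatError(f"expected 'u v w', got {text!r}", lno)
                try:
                    u, v = int(parts[0]), int(parts[1])
                    w = _coerce_weight(parts[2])
                except ValueError:
                    raise GraphFormatError(f"non-numeric edge line {text!r}", lno) from None
                if not (0 <= u < n and 0 <= v < n):
                    raise GraphFormatError(
                        f"vertex out of range in {text!r} (n={n})", lno
                    )
                if w <= 0:
                    raise GraphFormatError(f"nonpositive weight in {text!r}", lno)
                edges.append((u, v, w))
            graphs.append(FlowGraph(name=name, n=n, edges=edges))
    return graphs


def _fmt_weight(w) -> str:
    return repr(w) if isinstance(w, int) else format(w, "g")


def write_graphs(graphs: Sequence[FlowGraph], path) -> None:
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(f"# {g.name}\n{g.n}\n")
            for u, v, w in g.edges:
                fh.write(f"{u} {v} {_fmt_weight(w)}\n")


def read_truth(path) -> dict[str, list[tuple[float, list[int]]]]:
    """Read ground-truth transcripts: per graph name, (weight, vertex path)."""
    out: dict[str, list[tuple[float, list[int]]]] = {}
    with open(path) as fh:
        for (_, name), body in _records(fh):
            paths = []
            for lno, text in body:
                parts = text.split()
                if len(parts) < 2:
                    raise GraphFormatError(f"expected 'w v0 v1 ...', got {text!r}", lno)
                w = _coerce_weight(parts[0])
                verts = [int(p) for p in parts[1:]]
                paths.append((w, verts))
            out[name] = paths
    return out


def write_truth(records: dict[str, Sequence[tuple[float, Sequence[int]]]], path) -> None:
    with open(path, "w") as fh:
        for name, paths in records.items():
            fh.write(f"# {name}\n")
            for w, verts in paths:
                fh.write(f"{_fmt_weight(w)} " + " ".join(map(str, verts)) + "\n")


def read_node_lengths(path) -> dict[str, dict[int, int]]:
    out: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for (_, name), body in _records(fh):
            lens = {}
            for lno, text in body:
                parts = text.split()
                if len(parts) != 2:
                    raise GraphFormatError(f"expected 'v length', got {text!r}", lno)
                lens[int(parts[0])] = int(parts[1])
            out[name] = lens
    return out


def write_node_lengths(records: dict[str, dict[int, int]], path) -> None:
    with open(path, "w") as fh:
        for name, lens in records.items():
            fh.write(f"# {name}\n")
            for v in sorted(lens):
                fh.write(f"{v} {lens[v]}\n")


# ---------------------------------------------------------------------------
# Validation and elementary queries
# ---------------------------------------------------------------------------


def augment_single_source_sink(g: FlowGraph) -> FlowGraph:
    """Add a global source/sink to a graph with several of either.

    The new source feeds each original source with its outflow; each original
    sink feeds the new sink with its inflow — the construction used when
    superimposing transcripts that start/end at different exons.  Vertices are
    shifted by one so the global source is 0 and the global sink is n+1.
    """
    fin, fout = in_out_flow(g)
    sources = [v for v in range(g.n) if g.indegree(v) == 0]
    sinks = [v for v in range(g.n) if g.outdegree(v) == 0]
    n = g.n + 2
    s, t = 0, n - 1
    edges: list[tuple[int, int, float]] = []
    edges.extend((s, v + 1, fout[v]) for v in sources)
    edges.extend((u + 1, v + 1, w) for u, v, w in g.edges)
    edges.extend((v + 1, t, fin[v]) for v in sinks)
    lengths = None
    if g.node_lengths is not None:
        lengths = {v + 1: L for v, L in g.node_lengths.items()}
        lengths[s] = lengths[t] = 1
    return FlowGraph(name=g.name, n=n, edges=edges, node_lengths=lengths)


@dataclass
class ValidationReport:
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def in_out_flow(g: FlowGraph):
    """Per-vertex (fin, fout) flow sums, single pass over the edge list."""
    if g._fin is None:
        fin = [0] * g.n
        fout = [0] * g.n
        for u, v, w in g.edges:
            fout[u] += w
            fin[v] += w
        g._fin, g._fout = fin, fout
    return g._fin, g._fout


def topological_order(g: FlowGraph) -> list[int]:
    """Topological vertex order, ties broken by ascending label."""
    nxg = g.to_networkx()
    try:
        return list(nx.lexicographical_topological_sort(nx.DiGraph(nxg)))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(nx.DiGraph(nxg))
        raise ValueError(f"graph {g.name!r} is cyclic, e.g. back edge {cycle[-1][:2]}")


def validate_flow_graph(g: FlowGraph, tol: float = 1e-9) -> ValidationReport:
    """Check the flow-graph invariants, reporting every violation found.

    Conservation residuals are compared against ``tol * max(fin(v), 1)``;
    with integer weights any nonzero residual is reported.
    """
    violations: list[str] = []
    for e, (u, v, w) in enumerate(g.edges):
        if w <= 0:
            violations.append(f"edge {e} ({u}->{v}) has nonpositive weight {w}")
    if not nx.is_directed_acyclic_graph(nx.DiGraph(g.to_networkx())):
        violations.append("graph contains a directed cycle")
        return ValidationReport(violations)

    sources = [v for v in range(g.n) if g.indegree(v) == 0]
    sinks = [v for v in range(g.n) if g.outdegree(v) == 0]
    if len(sources) != 1:
        violations.append(f"expected one source, found {sources}")
    if len(sinks) != 1:
        violations.append(f"expected one sink, found {sinks}")

    fin, fout = in_out_flow(g)
    internal = set(range(g.n)) - set(sources) - set(sinks)
    for v in sorted(internal):
        resid = abs(fin[v] - fout[v])
        if resid > tol * max(fin[v], 1):
            violations.append(
                f"conservation violated at vertex {v}: fin={fin[v]} fout={fout[v]}"
            )
    return ValidationReport(violations)
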