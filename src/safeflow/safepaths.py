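"""Safe-and-complete enumeration of maximal safe paths.

Given any flow decomposition, every safe path occurs as a subpath of some
decomposition path (it is w-safe for w > 0, so paths of positive total
weight contain it in *every* decomposition).  A two-pointer scan over each
decomposition path therefore finds all maximal safe paths: the right pointer
advances while the window's excess flow stays positive (updated in O(1) per
move), the window is emitted when the right pointer stalls, and the left
pointer then advances.  Windows that are maximal only within their host but
not in the graph appear as substrings of longer windows on other hosts and
are removed by Aho-Corasick substring deduplication, leaving exactly the
maximal safe paths of the graph.

The result is kept as a *concise representation*: per host, the minimal
subpath spanning each run of overlapping windows, plus the window offsets —
its total size is proportional to the decomposition size instead of the
(potentially much larger) expanded output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._aho import AhoCorasick
from .decompose import (
    Decomposition,
    simple_flow_decomposition,
    verify_decomposition,
)
from .graph import FlowGraph, WeightedPath
from .safety import SafetyIndex, extend_delta

__all__ = [
    "PathWindow",
    "ConciseEntry",
    "ConciseRepresentation",
    "maximal_safe_paths_on_path",
    "enumerate_maximal_safe_paths",
    "maximal_safe_paths",
    "deduplicate_subpaths",
    "expand_concise",
]


@dataclass(frozen=True)
class PathWindow:
    """A subpath of a host decomposition path: inclusive edge-index bounds."""

    host_path: int
    left: int
    right: int
    excess: float


@dataclass
class ConciseEntry:
    host_path: int
    edge_ids: tuple[int, ...]
    #: (left, right) inclusive offsets of maximal safe paths within edge_ids
    windows: list[tuple[int, int]]
    excesses: list[float] = field(default_factory=list)


@dataclass
class ConciseRepresentation:
    entries: list[ConciseEntry]

    def total_size(self) -> int:
        """``|P_c|`` — summed edge count of the stored host subpaths."""
        return sum(len(e.edge_ids) for e in self.entries)

    def n_paths(self) -> int:
        return sum(len(e.windows) for e in self.entries)


def maximal_safe_paths_on_path(
    index: SafetyIndex, host: WeightedPath | Sequence[int]
) -> list[PathWindow]:
    """Two-pointer scan: all windows of ``host`` with positive excess that
    cannot be extended along the host without the excess dropping to <= 0.

    Excess is maintained incrementally (one delta per pointer move), so the
    scan costs O(|host|) arithmetic operations in total.
    """
    edges = tuple(host.edge_ids) if isinstance(host, WeightedPath) else tuple(host)
    g = index.graph
    g.path_vertices(edges)  # raises if not a contiguous path
    L = len(edges)
    out: list[PathWindow] = []
    left = right = 0
    excess = g.weight(edges[0])
    last_reported_right = -1
    while left < L:
        while right + 1 < L:
            delta = extend_delta(index, edges[right + 1], "end")
            if excess - delta > 0:
                right += 1
                excess -= delta
            else:
                break
        if right > last_reported_right:
            out.append(PathWindow(-1, left, right, excess))
            last_reported_right = right
        if right == L - 1:
            break  # any window with a larger left bound is nested
        if left == right:
            left += 1
            right = left
            excess = g.weight(edges[left])
        else:
            excess += extend_delta(index, edges[left], "start")
            left += 1
    return out


def deduplicate_subpaths(paths: Sequence[Sequence[int]]) -> list[tuple[int, ...]]:
    """Drop exact duplicates and any sequence contained in another.

    Containment means occurrence as a *contiguous substring* anywhere in a
    longer sequence (not just as a prefix/suffix); matching is multi-pattern
    via an Aho-Corasick automaton over the edge-id alphabet.  The first
    occurrence of each surviving sequence is kept, in input order.
    """
    unique: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    for p in paths:
        t = tuple(p)
        if t not in seen:
            seen.add(t)
            unique.append(t)
    if not unique:
        return []
    automaton = AhoCorasick(unique)
    contained = [False] * len(unique)
    index_of = {p: i for i, p in enumerate(unique)}
    for tid, text in enumerate(unique):
        for _, pid in automaton.iter_matches(text):
            if pid != tid:
                contained[pid] = True
    del index_of
    return [p for i, p in enumerate(unique) if not contained[i]]


def enumerate_maximal_safe_paths(
    g: FlowGraph, d: Decomposition | None = None
) -> ConciseRepresentation:
    """All maximal safe paths of ``g``, as a deduplicated concise representation.

    ``d`` defaults to the simple peeling decomposition; any valid flow
    decomposition yields the same expanded path set.
    """
    if d is None:
        d = simple_flow_decomposition(g)
    elif not verify_decomposition(g, d):
        raise ValueError(f"invalid decomposition: {d.diagnostics}")
    index = SafetyIndex.build(g)

    windows: list[PathWindow] = []
    for hi, host in enumerate(d.paths):
        for w in maximal_safe_paths_on_path(index, host):
            windows.append(PathWindow(hi, w.left, w.right, w.excess))

    # Substring dedup across hosts: a host-maximal window that is not
    # globally maximal is a substring of a longer safe window elsewhere.
    expanded = [d.paths[w.host_path].edge_ids[w.left : w.right + 1] for w in windows]
    kept_seqs = set(deduplicate_subpaths(expanded))
    kept: list[PathWindow] = []
    emitted: set[tuple[int, ...]] = set()
    for w, seq in zip(windows, expanded):
        if seq in kept_seqs and seq not in emitted:
            emitted.add(seq)
            kept.append(w)

    # Group surviving windows per host; merge runs of edge-sharing windows
    # into one minimal-length host subpath each.
    by_host: dict[int, list[PathWindow]] = {}
    for w in kept:
        by_host.setdefault(w.host_path, []).append(w)
    entries: list[ConciseEntry] = []
    for hi in sorted(by_host):
        ws = sorted(by_host[hi], key=lambda w: (w.left, w.right))
        run: list[PathWindow] = []
        for w in ws:
            if run and w.left <= run[-1].right:  # shares >= 1 edge
                run.append(w)
            else:
                if run:
                    entries.append(_make_entry(d, hi, run))
                run = [w]
        if run:
            entries.append(_make_entry(d, hi, run))
    return ConciseRepresentation(entries=entries)


def _make_entry(d: Decomposition, host: int, run: list[PathWindow]) -> ConciseEntry:
    lo = min(w.left for w in run)
    hi = max(w.right for w in run)
    return ConciseEntry(
        host_path=host,
        edge_ids=tuple(d.paths[host].edge_ids[lo : hi + 1]),
        windows=[(w.left - lo, w.right - lo) for w in run],
        excesses=[w.excess for w in run],
    )


def expand_concise(c: ConciseRepresentation) -> list[tuple[int, ...]]:
    """Materialize every window as an explicit edge-id path."""
    out: list[tuple[int, ...]] = []
    for entry in c.entries:
        for l, r in entry.windows:
            out.append(entry.edge_ids[l : r + 1])
    return out


def maximal_safe_paths(
    g: FlowGraph, d: Decomposition | None = None
) -> list[tuple[int, ...]]:
    """Convenience wrapper: the expanded set of maximal safe paths."""
    return expand_concise(enumerate_maximal_safe_paths(g, d))
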