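"""Evaluation metrics for reported paths against ground-truth transcripts.

*Weighted precision*: a reported path is correct when it is a contiguous
subpath of some ground-truth transcript; the metric is the total length of
correct paths over the total length of reported paths, so longer correct
paths score higher than many short ones.

*Maximum relative coverage*: for each transcript, the longest single segment
of any reported path lying inside the transcript, relative to transcript
length, averaged over transcripts.  Segments are not merged — partial
transcripts are credited only for their best contiguous stretch.

*F-score*: harmonic mean of the two.

Lengths count vertices (exons/pseudoexons) in node units, or the summed
per-vertex base counts in base units; the artificial global source and sink
are stripped before any comparison and never contribute length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .graph import FlowGraph

__all__ = [
    "GroundTruth",
    "is_subpath",
    "weighted_precision",
    "max_relative_coverage",
    "f_score",
    "evaluate_instance",
    "aggregate_metrics",
]


@dataclass
class GroundTruth:
    """Weighted source-to-sink transcripts of one splice graph."""

    transcripts: list[tuple[float, tuple[int, ...]]]  # (abundance, vertex path)

    @property
    def k(self) -> int:
        """Graph complexity: the number of ground-truth transcripts."""
        return len(self.transcripts)

    def vertex_paths(self) -> list[tuple[int, ...]]:
        return [verts for _, verts in self.transcripts]


def is_subpath(query: Sequence[int], target: Sequence[int]) -> bool:
    """True iff ``query`` occurs as a contiguous run inside ``target``."""
    q, t = tuple(query), tuple(target)
    k = len(q)
    if k == 0 or k > len(t):
        return False
    return any(t[i : i + k] == q for i in range(len(t) - k + 1))


def _length_fn(unit: str, node_lengths: dict[int, int] | None) -> Callable:
    if unit == "node":
        return lambda verts: len(verts)
    if unit == "base":
        if node_lengths is None:
            raise ValueError("base units require node lengths")
        return lambda verts: sum(node_lengths[v] for v in verts)
    raise ValueError(f"unit must be 'node' or 'base', got {unit!r}")


def weighted_precision(
    reported: Sequence[Sequence[int]],
    truth: Sequence[Sequence[int]],
    unit: str = "node",
    node_lengths: dict[int, int] | None = None,
) -> float:
    """Length of correctly reported paths over total reported length.

    Vacuously 1.0 when nothing is reported.
    """
    length = _length_fn(unit, node_lengths)
    total = correct = 0
    for r in reported:
        ell = length(r)
        total += ell
        if any(is_subpath(r, t) for t in truth):
            correct += ell
    return 1.0 if total == 0 else correct / total


def _longest_segment(r: tuple[int, ...], t: tuple[int, ...], length) -> float:
    """Best length over all common contiguous stretches of ``r`` inside ``t``.

    Classic longest-common-substring dynamic program, scored by the length
    function (node count or base count).
    """
    best = 0
    prev = [0] * (len(t) + 1)  # run length (in vertices) ending at (i, j)
    for i, rv in enumerate(r, start=1):
        cur = [0] * (len(t) + 1)
        for j, tv in enumerate(t, start=1):
            if rv == tv:
                run = prev[j - 1] + 1
                cur[j] = run
                score = length(r[i - run : i])
                if score > best:
                    best = score
        prev = cur
    return best


def max_relative_coverage(
    reported: Sequence[Sequence[int]],
    truth: Sequence[Sequence[int]],
    unit: str = "node",
    node_lengths: dict[int, int] | None = None,
) -> float:
    """Average over transcripts of longest reported segment / transcript length."""
    length = _length_fn(unit, node_lengths)
    if not truth:
        raise ValueError("ground truth has no transcripts")
    vals = []
    for t in truth:
        t = tuple(t)
        denom = length(t)
        best = 0
        for r in reported:
            best = max(best, _longest_segment(tuple(r), t, length))
            if best == denom:
                break
        vals.append(best / denom)
    return sum(vals) / len(vals)


def f_score(precision: float, coverage: float) -> float:
    """Harmonic mean; 0 when both inputs are 0."""
    if precision + coverage == 0:
        return 0.0
    return 2 * precision * coverage / (precision + coverage)


def _strip(verts: Sequence[int], artificial: set[int]) -> tuple[int, ...]:
    return tuple(v for v in verts if v not in artificial)


def evaluate_instance(
    g: FlowGraph,
    truth: GroundTruth,
    reported: Sequence[Sequence[int]],
    unit: str = "node",
    reported_as: str = "edges",
    algorithm: str = "",
) -> dict:
    """Per-graph metric record for one algorithm's reported paths.

    ``reported`` holds edge-id sequences (``reported_as='edges'``) or vertex
    sequences (``'vertices'``).  The graph's source and sink are treated as
    artificial and stripped before comparison.  Splice-graph instances are
    simple graphs; parallel edges are rejected because vertex sequences
    would be ambiguous.
    """
    if len({(u, v) for u, v, _ in g.edges}) != g.m:
        raise ValueError("metrics require a simple graph (no parallel edges)")
    artificial = {g.source, g.sink}
    if reported_as == "edges":
        rep_verts = [g.path_vertices(r) for r in reported]
    else:
        rep_verts = [list(r) for r in reported]
        known = set(range(g.n))
        for r in rep_verts:
            if not set(r) <= known:
                raise ValueError(f"unknown vertex in reported path {r}")
    rep = [p for p in (_strip(r, artificial) for r in rep_verts) if p]
    tru = [p for p in (_strip(t, artificial) for t in truth.vertex_paths()) if p]
    if len(tru) != truth.k:
        raise ValueError("a transcript has no non-artificial vertices")
    kwargs = dict(unit=unit, node_lengths=g.node_lengths)
    p = weighted_precision(rep, tru, **kwargs)
    c = max_relative_coverage(rep, tru, **kwargs)
    return {
        "name": g.name,
        "algorithm": algorithm,
        "k": truth.k,
        "unit": unit,
        "precision": p,
        "coverage": c,
        "fscore": f_score(p, c),
    }


def aggregate_metrics(
    records: Sequence[dict], simple_max_k: int = 10
) -> pd.DataFrame:
    """Stratified summary: mean metrics per algorithm for all graphs,
    simple graphs (2 <= k <= simple_max_k), and complex graphs (k > that)."""
    df = pd.DataFrame(records)
    strata = {
        "k>=2": df["k"] >= 2,
        f"2<=k<={simple_max_k}": (df["k"] >= 2) & (df["k"] <= simple_max_k),
        f"k>{simple_max_k}": df["k"] > simple_max_k,
    }
    rows = []
    for label, mask in strata.items():
        sub = df[mask]
        if sub.empty:
            continue
        for algo, grp in sub.groupby("algorithm", sort=False):
            cov = grp["coverage"].mean()
            prec = grp["precision"].mean()
            rows.append(
                {
                    "stratum": label,
                    "algorithm": algo,
                    "graphs": len(grp),
                    "coverage": cov,
                    "precision": prec,
                    "fscore": f_score(prec, cov),
                }
            )
    return pd.DataFrame(rows)
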