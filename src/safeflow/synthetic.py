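"""Synthetic splice-graph instances and structured graph families.

`simulate_splice_instance` emulates the error-free transcript-superposition
protocol: an ordered exon backbone, ``k`` distinct transcripts drawn as
increasing exon subsequences, lognormal expression levels, and a flow graph
obtained by superimposing the weighted transcripts between a global source
and sink.  Because the flow *is* the superposition, the ground truth is a
flow decomposition of the instance and conservation holds by construction.

The expression model is lognormal with log-space location -4 and scale 2
(sigma^2 = 4), the read-simulator default this protocol descends from;
abundances are integerized as ``round(scale * X) + 1`` so all downstream
arithmetic is exact.

`worst_case_graph` / `best_case_graph` build the four-block ladder families
on which the enumeration's concise representation is, respectively, as large
as the whole decomposition and asymptotically smaller than it.
`random_funnel` grows a fork-phase out-tree joined onto a merge-phase
in-tree, guaranteeing funnel structure by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .graph import FlowGraph
from .metrics import GroundTruth

__all__ = [
    "SimulationConfig",
    "simulate_splice_instance",
    "simulate_dataset",
    "worst_case_graph",
    "best_case_graph",
    "random_funnel",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the transcript-superposition simulator.

    Defaults model error-free splice graphs of moderately complex genes:
    10-50 exons, per-exon skip probability 0.3, lognormal(-4, sigma=2)
    expression scaled by 1000 and integerized, exon lengths 30-1000 bases.
    """

    k: int = 5
    exon_range: tuple[int, int] = (10, 50)
    skip_prob: float = 0.3
    log_mean: float = -4.0
    log_sd: float = 2.0
    scale: float = 1000.0
    integerize: bool = True
    length_range: tuple[int, int] = (30, 1000)
    seed: int = 0
    name: str | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.log_sd <= 0:
            raise ValueError("lognormal scale (sigma) must be positive")
        if not 0 <= self.skip_prob < 1:
            raise ValueError("skip probability must be in [0, 1)")


def simulate_splice_instance(
    cfg: SimulationConfig,
) -> tuple[FlowGraph, GroundTruth, dict[int, int]]:
    """One error-free splice-graph instance.

    Draw order (fixed for reproducibility): exon count, transcript
    subsequences, abundances, exon lengths.
    """
    rng = np.random.default_rng(cfg.seed)
    n_exons = int(rng.integers(cfg.exon_range[0], cfg.exon_range[1] + 1))
    if cfg.k > 2**n_exons - 1:
        raise ValueError(
            f"k={cfg.k} exceeds the {2**n_exons - 1} distinct exon subsequences"
        )

    transcripts: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    attempts = 0
    while len(transcripts) < cfg.k:
        attempts += 1
        if attempts > 1000 * cfg.k:
            raise ValueError(
                f"could not draw {cfg.k} distinct transcripts from "
                f"{n_exons} exons at skip probability {cfg.skip_prob}"
            )
        keep = rng.random(n_exons) >= cfg.skip_prob
        tr = tuple(int(i) for i in np.flatnonzero(keep))
        if tr and tr not in seen:
            seen.add(tr)
            transcripts.append(tr)

    abundances = []
    for _ in range(cfg.k):
        x = cfg.scale * rng.lognormal(mean=cfg.log_mean, sigma=cfg.log_sd)
        abundances.append(int(round(x)) + 1 if cfg.integerize else x)

    # Compact relabeling: source 0, used exons 1..E in backbone order, sink E+1
    used = sorted({e for tr in transcripts for e in tr})
    label = {e: i + 1 for i, e in enumerate(used)}
    s, t = 0, len(used) + 1

    flow: dict[tuple[int, int], float] = {}
    truth_paths: list[tuple[float, tuple[int, ...]]] = []
    for tr, w in zip(transcripts, abundances):
        verts = (s, *(label[e] for e in tr), t)
        truth_paths.append((w, verts))
        for u, v in zip(verts, verts[1:]):
            flow[(u, v)] = flow.get((u, v), 0) + w

    edges = [(u, v, w) for (u, v), w in sorted(flow.items())]
    lengths = {
        v: int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        for v in range(1, t)
    }
    lengths[s] = lengths[t] = 1
    name = cfg.name or f"sim-k{cfg.k}-s{cfg.seed}"
    g = FlowGraph(name=name, n=t + 1, edges=edges, node_lengths=lengths)
    return g, GroundTruth(transcripts=truth_paths), lengths


def simulate_dataset(
    n_graphs: int,
    seed: int,
    k_range: tuple[int, int] = (2, 35),
    exclude_funnels: bool = True,
    base_config: SimulationConfig | None = None,
) -> list[tuple[FlowGraph, GroundTruth]]:
    """A dataset of instances with complexity drawn uniformly from k_range.

    With ``exclude_funnels`` (the default), funnel instances — on which every
    algorithm is trivially perfect — are redrawn, mirroring the filtering
    used before comparing algorithms.
    """
    from .unitigs import is_funnel  # local import to avoid a cycle

    base = base_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    out: list[tuple[FlowGraph, GroundTruth]] = []
    while len(out) < n_graphs:
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        child_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(base, k=k, seed=child_seed, name=f"sim{len(out):04d}-k{k}")
        g, truth, _ = simulate_splice_instance(cfg)
        if exclude_funnels and is_funnel(g):
            continue
        out.append((g, truth))
    return out


def _cd_layout(k: int, cd_edges):
    if k < 2:
        raise ValueError("ladder size k must be >= 2")
    if cd_edges is None:
        cd_edges = [(i, j) for i in range(k) for j in range(k)]
    cd_edges = sorted(set(map(tuple, cd_edges)))
    if not cd_edges:
        raise ValueError("cd_edges must be nonempty")
    for i, j in cd_edges:
        if not (0 <= i < k and 0 <= j < k):
            raise ValueError(f"C x D edge ({i},{j}) outside 0..{k - 1}")
    return cd_edges


def worst_case_graph(k: int, cd_edges=None) -> FlowGraph:
    """Ladder family where the concise representation is as large as ||P||.

    Chain A feeds a bipartite C x D block feeding chain B; every C x D edge
    carries unit flow and chain weights follow by conservation.  Every full
    s-t path then has excess exactly 1, so each C x D edge induces its own
    maximal safe path spanning the whole graph.
    """
    cd_edges = _cd_layout(k, cd_edges)
    c_used = sorted({i for i, _ in cd_edges})
    d_used = sorted({j for _, j in cd_edges})
    deg_c = {i: sum(1 for x, _ in cd_edges if x == i) for i in c_used}
    deg_d = {j: sum(1 for _, y in cd_edges if y == j) for j in d_used}
    F = len(cd_edges)

    a = {i: i for i in range(k)}  # a_1..a_k  -> 0..k-1
    c = {i: k + idx for idx, i in enumerate(c_used)}
    d = {j: k + len(c_used) + idx for idx, j in enumerate(d_used)}
    b0 = k + len(c_used) + len(d_used)
    b = {j: b0 + j for j in range(k)}  # b_1..b_k
    n = b0 + k

    edges: list[tuple[int, int, float]] = []
    edges += [(a[i], a[i + 1], F) for i in range(k - 1)]
    edges += [(a[k - 1], c[i], deg_c[i]) for i in c_used]
    edges += [(c[i], d[j], 1) for i, j in cd_edges]
    edges += [(d[j], b[0], deg_d[j]) for j in d_used]
    edges += [(b[j], b[j + 1], F) for j in range(k - 1)]
    return FlowGraph(name=f"worst-k{k}", n=n, edges=edges)


def best_case_graph(k: int) -> FlowGraph:
    """Ladder family where the concise representation is O(m + n).

    Same four blocks with the full C x D connection at weight 2, but the
    edges (a_{k-1}, a_k) and (b_1, b_2) are split into two parallel edges of
    equal flow k^2.  The parallel split caps every safe path at one of: an
    O(1)-size path around each C x D edge, or one of four chain-long paths
    through a parallel edge — so the deduplicated safe output is linear in
    n + m while the decomposition size ||P|| grows superlinearly.
    """
    if k < 3:
        raise ValueError("best-case family needs k >= 3")
    F = 2 * k * k
    a = {i: i for i in range(k)}
    c = {i: k + i for i in range(k)}
    d = {j: 2 * k + j for j in range(k)}
    b = {j: 3 * k + j for j in range(k)}
    edges: list[tuple[int, int, float]] = []
    edges += [(a[i], a[i + 1], F) for i in range(k - 2)]
    edges += [(a[k - 2], a[k - 1], F // 2), (a[k - 2], a[k - 1], F // 2)]
    edges += [(a[k - 1], c[i], 2 * k) for i in range(k)]
    edges += [(c[i], d[j], 2) for i in range(k) for j in range(k)]
    edges += [(d[j], b[0], 2 * k) for j in range(k)]
    edges += [(b[0], b[1], F // 2), (b[0], b[1], F // 2)]
    edges += [(b[j], b[j + 1], F) for j in range(1, k - 1)]
    return FlowGraph(name=f"best-k{k}", n=4 * k, edges=edges)


def random_funnel(n: int, seed: int) -> FlowGraph:
    """A random funnel flow graph on ``n`` vertices.

    A fork-phase out-tree rooted at the source is joined onto a merge-phase
    in-tree rooted at the sink; fork-tree vertices keep indegree <= 1 and
    merge-tree vertices keep outdegree <= 1, so no merge vertex can reach a
    fork vertex.  Join-edge weights are random positive integers and tree
    weights follow by conservation, so the result is a valid flow graph.
    """
    if n < 2:
        raise ValueError("a flow graph needs at least source and sink")
    rng = np.random.default_rng(seed)
    internal = n - 2
    a = int(rng.integers(0, internal + 1))  # fork-phase internal vertices
    b = internal - a  # merge-phase internal vertices
    s, t = 0, n - 1
    fork = list(range(1, a + 1))
    merge = list(range(a + 1, a + b + 1))

    parent = {x: int(rng.integers(0, x)) for x in fork}
    child = {}
    for y in merge:
        c = int(rng.integers(y + 1, a + b + 2))  # later merge vertex or sink
        child[y] = c if c <= a + b else t

    fork_children: dict[int, list[int]] = {v: [] for v in [s, *fork]}
    for x, p in parent.items():
        fork_children[p].append(x)
    leaves = [v for v in [s, *fork] if not fork_children[v]]
    merged_into = set(child.values())
    heads = [y for y in merge if y not in merged_into] or [t] * (not merge)
    if not heads:  # every merge vertex is chain-fed; route connectors to first
        heads = [merge[0]]

    # Cover both sides: cycle the shorter list under the longer one.
    L, H = len(leaves), len(heads)
    conn_w: dict[tuple[int, int], int] = {}
    for i in range(max(L, H)):
        conn_w[(leaves[i % L], heads[i % H])] = int(rng.integers(1, 6))

    fin = [0] * n
    fout = [0] * n
    for (u, v), w in conn_w.items():
        fin[v] += w
        fout[u] += w
    merge_edges: list[tuple[int, int, float]] = []
    for y in merge:  # topo order: in-flow is complete when y is reached
        w = fin[y]
        merge_edges.append((y, child[y], w))
        fin[child[y]] += w
        fout[y] += w
    fork_edges: list[tuple[int, int, float]] = []
    for x in reversed(fork):  # reverse topo order: out-flow is complete
        w = fout[x]
        fork_edges.append((parent[x], x, w))
        fout[parent[x]] += w
        fin[x] += w
    conn_edges = [(u, v, w) for (u, v), w in sorted(conn_w.items())]
    edges = sorted(fork_edges) + conn_edges + sorted(merge_edges)
    return FlowGraph(name=f"funnel-n{n}-s{seed}", n=n, edges=edges)
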