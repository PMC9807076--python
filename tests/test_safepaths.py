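"""Two-pointer enumeration, concise representation, and dedup."""

import pytest

import safeflow as sf

from conftest import all_paths, random_guard_graph


def _vertex_set(g, edge_seqs):
    return {tuple(g.path_vertices(p)) for p in edge_seqs}


def _oracle_maximal_safe_set(g):
    """Maximal elements of the oracle-safe paths under the subpath order."""
    decs = sf.enumerate_all_decompositions(g)
    safe = [p for p in all_paths(g) if sf.oracle_max_safe_weight(g, p, decs) >= 1]
    return set(sf.deduplicate_subpaths(safe))


def test_scan_on_chain_host_reports_whole_host(chain):
    index = sf.SafetyIndex.build(chain)
    (w,) = sf.maximal_safe_paths_on_path(index, (0, 1, 2))
    assert (w.left, w.right, w.excess) == (0, 2, 7)


def test_scan_on_full_host_single_window(g2):
    index = sf.SafetyIndex.build(g2)
    (w,) = sf.maximal_safe_paths_on_path(index, (0, 1, 3))  # 0->1->2->4
    assert (w.left, w.right, w.excess) == (0, 2, 3)


def test_scan_matches_brute_force_over_host_subpaths(g3):
    """Every reported window is safe and host-inextensible; every safe
    subpath of the host is contained in a reported window."""
    index = sf.SafetyIndex.build(g3)
    host = (1, 3, 5, 7)  # 0->2->3->5->6
    windows = sf.maximal_safe_paths_on_path(index, host)
    covered = set()
    for w in windows:
        sub = host[w.left : w.right + 1]
        assert sf.excess_flow(g3, sub) == w.excess > 0
        if w.left > 0:
            assert sf.excess_flow(g3, host[w.left - 1 : w.right + 1]) <= 0
        if w.right < len(host) - 1:
            assert sf.excess_flow(g3, host[w.left : w.right + 2]) <= 0
        covered |= {(l, r) for l in range(w.left, w.right + 1)
                    for r in range(l, w.right + 1)}
    for l in range(len(host)):
        for r in range(l, len(host)):
            if sf.excess_flow(g3, host[l : r + 1]) > 0:
                assert (l, r) in covered


def test_scan_rejects_non_path(g3):
    index = sf.SafetyIndex.build(g3)
    with pytest.raises(ValueError):
        sf.maximal_safe_paths_on_path(index, (0, 3))


@pytest.mark.parametrize(
    "paths, kept",
    [
        ([(1, 2), (1, 2)], [(1, 2)]),
        ([(2,), (1, 2, 3)], [(1, 2, 3)]),
        ([(1, 2), (2, 3)], [(1, 2), (2, 3)]),
        ([(2, 3), (1, 2, 3, 4), (3,)], [(1, 2, 3, 4)]),  # interior containment
        ([], []),
    ],
)
def test_deduplicate_subpaths(paths, kept):
    assert sf.deduplicate_subpaths(paths) == kept


def test_expand_concise_materializes_windows():
    entry = sf.ConciseRepresentation(
        entries=[
            sf.safepaths.ConciseEntry(
                host_path=0, edge_ids=(5, 6, 7, 8), windows=[(0, 2), (1, 3)]
            )
        ]
    )
    assert sf.expand_concise(entry) == [(5, 6, 7), (6, 7, 8)]
    assert sf.expand_concise(sf.ConciseRepresentation(entries=[])) == []


def test_funnel_expansion_is_both_st_paths(g1):
    assert _vertex_set(g1, sf.maximal_safe_paths(g1)) == {(0, 1, 3), (0, 2, 3)}


def test_chain_expansion_is_single_path(chain):
    assert _vertex_set(chain, sf.maximal_safe_paths(chain)) == {(0, 1, 2, 3)}


def test_expanded_set_matches_oracle_on_g3(g3):
    assert set(sf.maximal_safe_paths(g3)) == _oracle_maximal_safe_set(g3)


def test_expanded_set_matches_oracle_on_random_graphs(rng):
    for _ in range(20):
        g = random_guard_graph(rng)
        assert set(sf.maximal_safe_paths(g)) == _oracle_maximal_safe_set(g)


def test_soundness_and_global_maximality(rng):
    """Expanded paths are safe and unextendable by any incident graph edge."""
    for _ in range(15):
        g = random_guard_graph(rng)
        for p in sf.maximal_safe_paths(g):
            assert sf.excess_flow(g, p) > 0
            for e in g.out_edges(g.head(p[-1])):
                assert sf.excess_flow(g, list(p) + [e]) <= 0
            for e in g.in_edges(g.tail(p[0])):
                assert sf.excess_flow(g, [e] + list(p)) <= 0


def test_decomposition_independence(rng):
    """Simple peeling and greedy-width seed identical expanded sets."""
    for _ in range(15):
        g = random_guard_graph(rng)
        via_simple = set(sf.maximal_safe_paths(g, sf.simple_flow_decomposition(g)))
        via_greedy = set(sf.maximal_safe_paths(g, sf.greedy_width_decomposition(g)))
        assert via_simple == via_greedy


def test_enumeration_rejects_invalid_decomposition(g1):
    bad = sf.Decomposition([sf.WeightedPath((0, 1), 2), sf.WeightedPath((2, 3), 2)])
    with pytest.raises(ValueError, match="invalid decomposition"):
        sf.enumerate_maximal_safe_paths(g1, bad)


def test_concise_windows_have_positive_excess_and_no_nesting(rng):
    for _ in range(10):
        g = random_guard_graph(rng)
        rep = sf.enumerate_maximal_safe_paths(g)
        for entry in rep.entries:
            for (l, r), x in zip(entry.windows, entry.excesses):
                assert x > 0
                assert sf.excess_flow(g, entry.edge_ids[l : r + 1]) == x
            spans = sorted(entry.windows)
            for (l1, r1), (l2, r2) in zip(spans, spans[1:]):
                assert not (l1 <= l2 and r2 <= r1) and not (l2 <= l1 and r1 <= r2)
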