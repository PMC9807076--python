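"""Flow-graph model, file I/O and validation."""

import pytest

import safeflow as sf
from safeflow.graph import GraphFormatError

G1_TEXT = """# g1
4
0 1 1
1 3 1
0 2 2
2 3 2
"""


def test_read_single_record(tmp_path):
    path = tmp_path / "one.graph"
    path.write_text(G1_TEXT)
    (g,) = sf.read_graphs(path)
    assert (g.name, g.n, g.m) == ("g1", 4, 4)
    assert g.edges == [(0, 1, 1), (1, 3, 1), (0, 2, 2), (2, 3, 2)]
    assert g.is_integer()


def test_read_two_records_in_file_order(tmp_path):
    path = tmp_path / "two.graph"
    path.write_text(G1_TEXT + "# g2\n2\n0 1 3.5\n")
    g1, g2 = sf.read_graphs(path)
    assert [g1.name, g2.name] == ["g1", "g2"]
    assert g2.edges == [(0, 1, 3.5)]
    assert not g2.is_integer()


@pytest.mark.parametrize(
    "body, fragment",
    [
        ("4\n0 5 1\n", "out of range"),
        ("4\n0 1 0\n", "nonpositive"),
        ("4\n0 1 -2\n", "nonpositive"),
        ("4\n0 1\n", "expected"),
        ("4\n0 1 x\n", "non-numeric"),
    ],
)
def test_read_rejects_malformed_lines_with_line_number(tmp_path, body, fragment):
    path = tmp_path / "bad.graph"
    path.write_text("# bad\n" + body)
    with pytest.raises(GraphFormatError, match=fragment) as exc:
        sf.read_graphs(path)
    assert "line 3" in str(exc.value)


def test_write_read_round_trip(tmp_path, g1):
    parallel = sf.FlowGraph("par", 2, [(0, 1, 2), (0, 1, 3)])
    floats = sf.FlowGraph("fl", 2, [(0, 1, 1.25)])
    path = tmp_path / "rt.graph"
    sf.write_graphs([g1, parallel, floats], path)
    back = sf.read_graphs(path)
    assert [(g.name, g.n, g.edges) for g in back] == [
        ("g1", 4, g1.edges),
        ("par", 2, parallel.edges),
        ("fl", 2, floats.edges),
    ]


def test_write_empty_sequence_gives_empty_file(tmp_path):
    path = tmp_path / "empty.graph"
    sf.write_graphs([], path)
    assert path.read_text() == ""
    assert sf.read_graphs(path) == []


def test_truth_and_length_round_trip(tmp_path):
    truth = {"g1": [(3, [0, 1, 3]), (2.5, [0, 2, 3])]}
    lens = {"g1": {1: 10, 2: 250}}
    tp, lp = tmp_path / "t.truth", tmp_path / "l.lengths"
    sf.write_truth(truth, tp)
    sf.write_node_lengths(lens, lp)
    assert sf.read_truth(tp) == {"g1": [(3, [0, 1, 3]), (2.5, [0, 2, 3])]}
    assert sf.read_node_lengths(lp) == lens


def test_validate_accepts_conserved_diamond(g1):
    assert sf.validate_flow_graph(g1).ok


def test_validate_flags_conservation_violation(g1):
    g1.edges[1] = (1, 3, 2)  # fin(1)=1 but fout(1)=2
    g1.invalidate_caches()
    report = sf.validate_flow_graph(g1)
    assert not report.ok
    assert any("vertex 1" in v for v in report.violations)


def test_validate_flags_cycle(g1):
    g1.edges.append((3, 0, 1))
    g1.invalidate_caches()
    report = sf.validate_flow_graph(g1)
    assert any("cycle" in v for v in report.violations)


def test_validate_flags_multiple_sources():
    g = sf.FlowGraph("two-src", 4, [(0, 2, 1), (1, 2, 1), (2, 3, 2)])
    report = sf.validate_flow_graph(g)
    assert any("source" in v for v in report.violations)


def test_augment_merges_sources_and_sinks():
    g = sf.FlowGraph("two-src", 4, [(0, 2, 1), (1, 2, 1), (2, 3, 2)])
    aug = sf.augment_single_source_sink(g)
    assert sf.validate_flow_graph(aug).ok
    fin, fout = sf.in_out_flow(aug)
    assert fout[aug.source] == fin[aug.sink] == 2


def test_topological_order_ties_by_label(g1, chain):
    assert sf.topological_order(g1) == [0, 1, 2, 3]
    assert sf.topological_order(chain) == [0, 1, 2, 3]


def test_topological_order_rejects_cycle(g1):
    g1.edges.append((3, 0, 1))
    g1.invalidate_caches()
    with pytest.raises(ValueError, match="cyclic"):
        sf.topological_order(g1)


def test_in_out_flow_sums(g1):
    fin, fout = sf.in_out_flow(g1)
    assert (fin[3], fout[0], fin[1], fout[1]) == (3, 3, 1, 1)
    total = sum(w for _, _, w in g1.edges)
    assert sum(fin) == sum(fout) == total
    assert fin[0] == fout[3] == 0  # fin(s) = fout(t) = 0


def test_in_out_flow_parallel_edges_and_isolated_vertex():
    g = sf.FlowGraph("par", 3, [(0, 1, 2), (0, 1, 3)])
    fin, fout = sf.in_out_flow(g)
    assert fout[0] == 5 and fin[1] == 5
    assert (fin[2], fout[2]) == (0, 0)


def test_path_vertices_and_edge_translation(g2):
    assert g2.path_vertices([0, 1, 3]) == [0, 1, 2, 4]
    assert g2.vertex_path_to_edges([0, 1, 2, 4]) == [0, 1, 3]
    with pytest.raises(ValueError, match="not contiguous"):
        g2.path_vertices([0, 3])
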