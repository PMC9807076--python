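"""Weighted precision, maximum relative coverage, and F-score."""

import pytest

import safeflow as sf
from safeflow.metrics import GroundTruth


def test_is_subpath():
    assert sf.is_subpath((1, 2), (0, 1, 2, 3))
    assert not sf.is_subpath((1, 3), (0, 1, 2, 3))  # not contiguous
    assert sf.is_subpath((0, 1, 2, 3), (0, 1, 2, 3))


def test_weighted_precision_worked_example():
    truth = [(1, 2, 3)]
    reported = [(1, 2), (1, 3)]  # only (1,2) is a subpath; both 2 nodes
    assert sf.weighted_precision(reported, truth) == 0.5


def test_weighted_precision_all_correct_is_one():
    truth = [(1, 2, 3, 4)]
    assert sf.weighted_precision([(2, 3), (1, 2, 3, 4)], truth) == 1.0


def test_weighted_precision_base_units():
    truth = [(1, 2, 3)]
    lengths = {1: 10, 2: 10, 3: 1}
    got = sf.weighted_precision(
        [(1, 2), (1, 3)], truth, unit="base", node_lengths=lengths
    )
    assert got == pytest.approx(20 / 31)  # (10+10) / (10+10+10+1)


def test_weighted_precision_vacuous_when_nothing_reported():
    assert sf.weighted_precision([], [(1, 2, 3)]) == 1.0


def test_coverage_worked_example():
    truth = [(1, 2, 3, 4)]
    assert sf.max_relative_coverage([(2, 3)], truth) == 0.5


def test_coverage_full_report_is_one():
    truth = [(1, 2, 3), (2, 4)]
    assert sf.max_relative_coverage([(1, 2, 3), (2, 4)], truth) == 1.0


def test_coverage_segments_are_not_merged():
    truth = [(1, 2, 3, 4)]
    # two disjoint 2-node segments; the maximum single segment is 2/4
    assert sf.max_relative_coverage([(1, 2), (3, 4)], truth) == 0.5


def test_coverage_uses_longest_common_stretch_not_whole_path():
    truth = [(1, 2, 3, 4, 5)]
    # reported path leaves the transcript after 3: segment (1,2,3) counts
    assert sf.max_relative_coverage([(1, 2, 3, 9)], truth) == pytest.approx(3 / 5)


def test_coverage_averages_over_transcripts():
    truth = [(1, 2), (3, 4, 5, 6)]
    got = sf.max_relative_coverage([(1, 2), (3, 4)], truth)
    assert got == pytest.approx((1.0 + 0.5) / 2)


def test_f_score():
    assert sf.f_score(1, 1) == 1
    assert sf.f_score(0.5, 1) == pytest.approx(2 / 3)
    assert sf.f_score(0, 0.7) == 0
    assert sf.f_score(0, 0) == 0


def test_coverage_monotone_under_additional_reports():
    truth = [(1, 2, 3, 4, 5)]
    reported = [(2, 3)]
    base = sf.max_relative_coverage(reported, truth)
    more = sf.max_relative_coverage(reported + [(3, 4, 5)], truth)
    assert more >= base


def _instance():
    g = sf.FlowGraph(
        "toy", 5, [(0, 1, 2), (1, 2, 2), (2, 3, 2), (3, 4, 2)]
    )
    truth = GroundTruth([(2, (0, 1, 2, 3, 4))])
    return g, truth


def test_evaluate_reported_equals_truth_scores_one():
    g, truth = _instance()
    rec = sf.evaluate_instance(g, truth, [(0, 1, 2, 3)], reported_as="edges")
    assert (rec["precision"], rec["coverage"], rec["fscore"]) == (1.0, 1.0, 1.0)
    assert rec["k"] == 1


def test_evaluate_empty_report_degenerate_rule():
    g, truth = _instance()
    rec = sf.evaluate_instance(g, truth, [])
    assert (rec["precision"], rec["coverage"], rec["fscore"]) == (1.0, 0.0, 0.0)


def test_evaluate_strips_artificial_endpoints():
    g, truth = _instance()
    # reported path covering only source+first exon reduces to one vertex
    rec = sf.evaluate_instance(g, truth, [(0,)], reported_as="edges")
    assert rec["precision"] == 1.0
    assert rec["coverage"] == pytest.approx(1 / 3)


def test_evaluate_rejects_parallel_edges():
    g = sf.FlowGraph("par", 2, [(0, 1, 1), (0, 1, 1)])
    with pytest.raises(ValueError, match="parallel"):
        sf.evaluate_instance(g, GroundTruth([(2, (0, 1))]), [])


def test_evaluate_rejects_unknown_vertices():
    g, truth = _instance()
    with pytest.raises(ValueError, match="unknown vertex"):
        sf.evaluate_instance(g, truth, [(1, 9)], reported_as="vertices")


def test_aggregate_fscore_is_harmonic_mean_of_columns():
    records = [
        {"algorithm": "A", "k": k, "unit": "node", "name": str(k),
         "precision": p, "coverage": c, "fscore": sf.f_score(p, c)}
        for k, p, c in [(2, 1.0, 0.5), (5, 0.8, 0.7), (12, 0.6, 0.9)]
    ]
    table = sf.aggregate_metrics(records)
    for _, row in table.iterrows():
        assert row["fscore"] == pytest.approx(
            sf.f_score(row["precision"], row["coverage"])
        )
    strata = set(table["stratum"])
    assert strata == {"k>=2", "2<=k<=10", "k>10"}
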