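import numpy as np
import pytest

from protlm.evalstats import (
    AlignmentHit,
    HSSPCurve,
    dataset_hssp_summary,
    hssp_threshold,
    ordered_fraction,
    parse_hit_table,
    read_iupred,
    read_ss2,
    select_best_hit,
    ss_content,
    write_hit_table,
)


# ---------------------------------------------------------------------------
# HSSP curve
# ---------------------------------------------------------------------------


def test_threshold_power_law_region():
    # 290.15 * 40^-0.562 ≈ 36.5% — short alignments demand high identity
    assert hssp_threshold(40) == pytest.approx(290.15 * 40**-0.562)
    assert hssp_threshold(10) > hssp_threshold(40) > hssp_threshold(79)


def test_threshold_plateau_for_long_alignments():
    assert hssp_threshold(200) == pytest.approx(24.8)
    assert hssp_threshold(80) == pytest.approx(24.8)
    assert hssp_threshold(10_000) == pytest.approx(24.8)


def test_threshold_monotone_nonincreasing_and_continuous():
    lengths = np.arange(1, 500)
    vals = np.array([hssp_threshold(int(L)) for L in lengths])
    assert np.all(np.diff(vals) <= 0)
    # continuity at the plateau junction within half a point
    junction = np.abs(vals[:-1] - 24.8) < 2.0
    assert np.all(np.abs(np.diff(vals))[junction] < 0.5)


def test_threshold_rejects_nonpositive_length():
    with pytest.raises(ValueError):
        hssp_threshold(0)


def test_alternative_curve_parameterization_is_pluggable():
    curve = HSSPCurve(amplitude=480.0, exponent=-0.32, plateau=19.5)
    assert curve.threshold(1_000_000) == pytest.approx(19.5)
    assert curve.threshold(10) == pytest.approx(480.0 * 10**-0.32)


# ---------------------------------------------------------------------------
# best-hit selection
# ---------------------------------------------------------------------------


def hit(q="q", t="t", ident=50.0, L=100, prob=99.0, qs=1):
    return AlignmentHit(q, t, identity=ident, aln_length=L, probability=prob, qstart=qs)


def test_longest_above_curve_alignment_wins():
    hits = [hit(ident=50.0, L=100), hit(ident=90.0, L=12)]
    # both above the curve (50 > 24.8 at L=100; 90 > 71.8 at L=12)
    v = select_best_hit(hits)
    assert v.above_curve and v.hit.aln_length == 100
    # identity breaks length ties
    v = select_best_hit([hit(ident=40.0, L=100), hit(ident=60.0, L=100)])
    assert v.hit.identity == 60.0


def test_no_hit_and_below_curve_verdicts():
    v = select_best_hit([])
    assert v.hit is None and not v.above_curve
    below = hit(ident=10.0, L=100)
    v = select_best_hit([below])
    assert v.hit == below and not v.above_curve
    assert v.threshold_at_length == pytest.approx(24.8)


def test_below_curve_selection_maximizes_identity_minus_threshold():
    h1 = hit(ident=20.0, L=100)  # 4.8 below the 24.8 plateau
    h2 = hit(ident=30.0, L=20)  # threshold ~54.3, 24.3 below
    v = select_best_hit([h1, h2])
    assert v.hit == h1


def test_selection_is_permutation_invariant():
    rng = np.random.default_rng(0)
    hits = [
        hit(ident=float(rng.uniform(5, 95)), L=int(rng.integers(10, 300)))
        for _ in range(12)
    ]
    base = select_best_hit(hits)
    for _ in range(5):
        perm = [hits[i] for i in rng.permutation(len(hits))]
        assert select_best_hit(perm) == base


def test_hit_validation():
    with pytest.raises(ValueError):
        hit(ident=120.0)
    with pytest.raises(ValueError):
        AlignmentHit("q", "t", identity=50.0, aln_length=0, probability=90.0)


# ---------------------------------------------------------------------------
# dataset summary
# ---------------------------------------------------------------------------


def test_summary_fraction_counts_missing_hits_as_below():
    verdicts = [select_best_hit([hit(ident=90.0, L=100)]) for _ in range(9)]
    verdicts.append(select_best_hit([]))
    frac, mean, sd = dataset_hssp_summary(verdicts)
    assert frac == pytest.approx(0.9)
    assert mean == pytest.approx(90.0) and sd == pytest.approx(0.0)


def test_summary_matches_manual_recount_on_synthetic_verdicts():
    rng = np.random.default_rng(1)
    verdicts = []
    expected_above = 0
    idents = []
    for _ in range(20):
        ident = float(rng.uniform(5, 95))
        L = int(rng.integers(10, 300))
        v = select_best_hit([hit(ident=ident, L=L)])
        verdicts.append(v)
        idents.append(ident)
        if ident > hssp_threshold(L):
            expected_above += 1
    frac, mean, sd = dataset_hssp_summary(verdicts)
    assert frac == pytest.approx(expected_above / 20)
    assert mean == pytest.approx(float(np.mean(idents)))
    assert sd == pytest.approx(float(np.std(idents)))


def test_summary_with_no_hits_reports_moments_unavailable():
    frac, mean, sd = dataset_hssp_summary([select_best_hit([])] * 3)
    assert frac == 0.0 and mean is None and sd is None


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------


def test_hit_table_round_trip(tmp_path):
    hits = [
        AlignmentHit("q1", "t1", identity=32.9, aln_length=120, probability=99.5, qstart=3, qend=122),
        AlignmentHit("q1", "t2", identity=88.0, aln_length=15, probability=70.0),
        AlignmentHit("q2", "t3", identity=12.5, aln_length=44, probability=50.0),
    ]
    path = tmp_path / "hits.tsv"
    write_hit_table(hits, path)
    assert parse_hit_table(path) == hits


def test_hit_table_errors_name_line_numbers(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("query\ttarget\tprob\tidentity\taln_length\tqstart\tqend\nq\tt\t99\tnot_a_number\t10\t1\t10\n")
    with pytest.raises(ValueError, match="line 2"):
        parse_hit_table(path)
    path.write_text("wrong\theader\n")
    with pytest.raises(ValueError, match="line 1"):
        parse_hit_table(path)


def test_iupred_reader_and_ordered_fraction(tmp_path):
    path = tmp_path / "scores.txt"
    path.write_text("# IUPred-style output\n1 M 0.60\n2 K 0.60\n3 V 0.20\n4 L 0.20\n")
    scores = read_iupred(path)
    np.testing.assert_allclose(scores, [0.6, 0.6, 0.2, 0.2])
    assert ordered_fraction(scores, 0.5) == pytest.approx(50.0)
    assert ordered_fraction([0.1] * 7, 0.5) == pytest.approx(100.0)
    assert ordered_fraction([0.1, 0.9], 0.0) == 0.0  # nothing is below zero
    with pytest.raises(ValueError):
        ordered_fraction([1.5])
    with pytest.raises(ValueError):
        ordered_fraction([])


def test_ss2_reader_and_content(tmp_path):
    path = tmp_path / "pred.ss2"
    path.write_text(
        "# normalized ss2\n"
        "1 M H 0.05 0.90 0.05\n"
        "2 K E 0.05 0.05 0.90\n"
        "3 V C 0.40 0.30 0.30\n"
        "4 L C 0.95 0.03 0.02\n"
    )
    records = read_ss2(path)
    assert records == [("H", 9), ("E", 9), ("C", 4), ("C", 9)]
    h, e, c = ss_content(records, min_conf=5)
    assert (h, e, c) == (pytest.approx(100 / 3), pytest.approx(100 / 3), pytest.approx(100 / 3))
    assert sum(ss_content(records, min_conf=5)) == pytest.approx(100.0)
    all_h = [("H", 9)] * 10
    assert ss_content(all_h) == (100.0, 0.0, 0.0)
    # min_conf 0 counts every residue
    h0, e0, c0 = ss_content(records, min_conf=0)
    assert (h0, e0, c0) == (25.0, 25.0, 50.0)


def test_ss_content_unreachable_confidence_is_none_not_zero():
    assert ss_content([("H", 3), ("C", 2)], min_conf=5) is None
    with pytest.raises(ValueError):
        ss_content([], min_conf=5)
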