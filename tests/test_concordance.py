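"""Recognition/consistency rates, table building, Cohen's kappa."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faceasym import concordance as cc
from faceasym.types import AxisId, InvalidInputError, RegionId, SeverityGrade

M, O, S = SeverityGrade.mild, SeverityGrade.moderate, SeverityGrade.severe


def test_recognition_rate_counts_moderate_or_severe():
    r = cc.recognition_rate([M, O, S, M])
    assert (r.numerator, r.denominator) == (2, 4)
    assert cc.recognition_rate([M, M]).numerator == 0
    grades = [O] * 21 + [M] * 3
    assert str(cc.recognition_rate(grades)) == "21/24"
    with pytest.raises(InvalidInputError):
        cc.recognition_rate([])


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((21, 24), (24, 24), 87.5),
        ((19, 24), (23, 24), 82.6),
        ((23, 24), (24, 24), 95.8),
        ((22, 23), (23, 23), 95.7),
        ((3, 23), (23, 23), 13.0),
        ((5, 24), (5, 24), 100.0),
    ],
)
def test_consistency_rate_closed_forms(a, b, expected):
    ra = cc.RecognitionRate(*a)
    rb = cc.RecognitionRate(*b)
    assert cc.consistency_percent(ra, rb) == expected
    assert cc.consistency_percent(rb, ra) == expected  # symmetric


def test_consistency_rate_undefined_for_two_zero_rates():
    z = cc.RecognitionRate(0, 24)
    assert cc.consistency_rate(z, z) is None


def test_consistency_rate_brute_force_over_small_rationals():
    # oracle: plain float min/max ratio for every numerator pair up to 24
    for a in range(25):
        for b in range(25):
            ra, rb = cc.RecognitionRate(a, 24), cc.RecognitionRate(b, 24)
            got = cc.consistency_rate(ra, rb)
            if a == 0 and b == 0:
                assert got is None
                continue
            expected = 100.0 * min(a, b) / max(a, b)
            assert float(got) == pytest.approx(expected, abs=1e-12)
            assert 0 <= got <= 100
            assert (got == 100) == (a == b)


@given(a=st.integers(0, 24), b=st.integers(1, 24))
@settings(max_examples=80, derandomize=True)
def test_consistency_rate_is_symmetric_and_bounded(a, b):
    ra, rb = cc.RecognitionRate(a, 24), cc.RecognitionRate(b, 24)
    c1, c2 = cc.consistency_rate(ra, rb), cc.consistency_rate(rb, ra)
    assert c1 == c2
    assert c1 is None or Fraction(0) <= c1 <= 100
    assert (c1 == 100) == (a == b)


def test_half_up_rounding_convention():
    assert cc.round_half_up(Fraction(100 * 22, 23), 1) == 95.7
    assert cc.round_half_up(Fraction(100 * 3, 23), 1) == 13.0
    assert cc.round_half_up(87.25, 1) == 87.3
    assert cc.round_half_up(Fraction(100 * 21, 22), 1) == 95.5


def test_overall_table_from_counts_third_criterion_row():
    table = cc.overall_table_from_counts(
        [21, 23, 21, 22, 24], [24] * 5, 24
    )
    cells = table["consistency_percent"].tolist()
    assert cells[:5] == [87.5, 95.8, 87.5, 91.7, 100.0]
    assert cells[5] == 92.5  # average row


def test_overall_table_from_counts_second_criterion_row():
    table = cc.overall_table_from_counts(
        [17, 21, 16, 18, 24], [24] * 5, 24
    )
    assert table["consistency_percent"].tolist()[5] == 80.0


def test_identical_matrices_give_all_100(grade_matrices):
    a, _ = grade_matrices
    table = cc.build_overall_table(a, a)
    assert all(c == 100.0 for c in table["consistency_percent"])
    dim = cc.build_dimension_table(a, a)
    assert all(c == 100.0 for c in dim["consistency_percent"])


@pytest.fixture()
def grade_matrices():
    rng = np.random.default_rng(0)
    def build(bias):
        cells = {}
        for s in range(8):
            cells[f"s{s}"] = {
                (r, a): SeverityGrade(int(rng.integers(0, 3) if rng.random() > bias else 2))
                for r in RegionId
                for a in AxisId
            }
        return cc.GradeMatrix(cells)
    return build(0.3), build(0.6)


def test_dimension_table_has_15_consistent_rows(grade_matrices):
    a, b = grade_matrices
    table = cc.build_dimension_table(a, b)
    assert len(table) == 15
    for _, row in table.iterrows():
        na, da = row["mirror_rate"].split("/")
        nb, db = row["template_rate"].split("/")
        ra = cc.RecognitionRate(int(na), int(da))
        rb = cc.RecognitionRate(int(nb), int(db))
        assert row["consistency_percent"] == cc.consistency_percent(ra, rb)


def test_grade_matrix_requires_complete_cells():
    with pytest.raises(InvalidInputError, match="incomplete"):
        cc.GradeMatrix({"s0": {(RegionId.labial, AxisId.X): M}})


def test_grade_matrix_region_aggregate_follows_rule(grade_matrices):
    a, _ = grade_matrices
    for s in a.subjects:
        for r in RegionId:
            axis = [a.axis_grade(s, r, ax) for ax in AxisId]
            expected = M if all(g == M for g in axis) else max(axis)
            assert a.region_grade(s, r) == expected


def test_subject_mismatch_rejected(grade_matrices):
    a, _ = grade_matrices
    other = cc.GradeMatrix(
        {"different": {(r, ax): M for r in RegionId for ax in AxisId}}
    )
    with pytest.raises(InvalidInputError):
        cc.build_overall_table(a, other)


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

def test_kappa_identity_is_one():
    labels = [M, O, S, M, O]
    assert cc.cohen_kappa(labels, labels) == 1.0
    assert cc.cohen_kappa([M] * 5, [M] * 5) == 1.0  # constant raters agreeing


def test_kappa_perfect_balanced_disagreement_is_minus_one():
    a = [M] * 5 + [S] * 5
    b = [S] * 5 + [M] * 5
    assert cc.cohen_kappa(a, b) == pytest.approx(-1.0)


def test_kappa_two_by_two_oracle():
    # contingency table a=20, b=5, c=10, d=15: p_o=0.7, p_e=0.5 -> 0.4
    r1 = [M] * 25 + [O] * 25
    r2 = [M] * 20 + [O] * 5 + [M] * 10 + [O] * 15
    assert cc.cohen_kappa(r1, r2) == pytest.approx(0.4)


def test_kappa_invariant_under_parallel_permutation(rng):
    a = list(rng.integers(0, 3, 40))
    b = list(rng.integers(0, 3, 40))
    perm = rng.permutation(40)
    ka = cc.cohen_kappa([SeverityGrade(x) for x in a], [SeverityGrade(x) for x in b])
    kp = cc.cohen_kappa(
        [SeverityGrade(a[i]) for i in perm], [SeverityGrade(b[i]) for i in perm]
    )
    assert kp == pytest.approx(ka, abs=1e-12)
    assert -1.0 <= ka <= 1.0


def test_kappa_rejects_mismatched_lengths():
    with pytest.raises(InvalidInputError):
        cc.cohen_kappa([M, O], [M])
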