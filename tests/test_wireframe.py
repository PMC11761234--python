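"""Angular template: triplet angles, AAI, grading, wireframe edges."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faceasym import wireframe as wf
from faceasym.grading import aggregate_region
from faceasym.synthetic import apply_asymmetry, AsymmetrySpec
from faceasym.types import (
    AxisId,
    DegenerateGeometryError,
    InvalidInputError,
    LandmarkSet,
    RegionId,
    SeverityGrade,
)

from conftest import random_rigid


def _triplet_landmarks(a, b, c):
    return LandmarkSet(
        {
            "Sal_L": a, "Ch_L": b, "Stb": c,
            "Sal_R": [-a[0], a[1], a[2]],
            "Ch_R": [-b[0], b[1], b[2]],
        }
    )


def test_orthogonal_arms_measure_90_degrees():
    lm = _triplet_landmarks([1, 0, 0], [0, 0, 0], [0, 1, 0])
    assert wf.compute_angle(lm, ("Sal", "Ch", "Stb"), "left") == pytest.approx(90.0)


def test_collinear_arms_measure_zero():
    lm = _triplet_landmarks([1, 0, 0], [0, 0, 0], [2, 0, 0])
    assert wf.compute_angle(lm, ("Sal", "Ch", "Stb"), "left") == pytest.approx(0.0)


def test_zero_length_arm_is_degenerate():
    lm = _triplet_landmarks([0, 0, 0], [0, 0, 0], [0, 1, 0])
    with pytest.raises(DegenerateGeometryError):
        wf.compute_angle(lm, ("Sal", "Ch", "Stb"), "left")


def test_angle_rigid_invariance(base_case, rng):
    for _ in range(10):
        T = random_rigid(rng)
        moved = base_case.landmarks.transformed(T)
        for par in wf.TEMPLATE_PARAMETERS:
            for side in ("left", "right"):
                a0 = wf.compute_angle(base_case.landmarks, par.triplet, side)
                a1 = wf.compute_angle(moved, par.triplet, side)
                assert a1 == pytest.approx(a0, abs=1e-9)


@pytest.mark.parametrize(
    "left,right,expected",
    [(100.0, 100.0, 0.0), (100.0, 103.0, 3.0), (120.0, 117.0, 2.5)],
)
def test_aai_closed_form(left, right, expected):
    assert wf.compute_aai(left, right) == pytest.approx(expected)


def test_aai_requires_positive_left_denominator():
    with pytest.raises(InvalidInputError):
        wf.compute_aai(0.0, 10.0)


def test_aai_formula_is_not_symmetric_in_its_arguments():
    assert wf.compute_aai(100.0, 110.0) != wf.compute_aai(110.0, 100.0)


@pytest.mark.parametrize(
    "aai,grade",
    [
        (0.0, SeverityGrade.mild),
        (0.99, SeverityGrade.mild),
        (1.0, SeverityGrade.moderate),
        (2.99, SeverityGrade.moderate),
        (3.0, SeverityGrade.severe),
        (12.0, SeverityGrade.severe),
    ],
)
def test_aai_half_open_grade_bands(aai, grade):
    assert wf.classify_aai(aai) == grade


def test_negative_aai_rejected():
    with pytest.raises(InvalidInputError):
        wf.classify_aai(-0.1)


@given(delta=st.floats(0, 50), left=st.floats(60, 170))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_grade_never_decreases_with_increasing_difference(delta, left):
    g1 = wf.classify_aai(wf.compute_aai(left, left + delta))
    g2 = wf.classify_aai(wf.compute_aai(left, left + delta * 1.5))
    assert g2 >= g1


def test_template_is_symmetric_null_on_base_face(base_case):
    results = wf.evaluate_template(base_case.landmarks)
    assert len(results) == 15
    assert all(r.aai_percent == 0.0 for r in results)
    assert all(r.grade == SeverityGrade.mild for r in results)


def test_template_covers_each_region_axis_cell_once(base_case):
    results = wf.evaluate_template(base_case.landmarks)
    cells = {(r.parameter.region, r.parameter.axis) for r in results}
    assert cells == {(r, a) for r in RegionId for a in AxisId}


def test_displaced_gonion_affects_exactly_the_triplets_containing_it(base_case):
    # independent enumeration of the registry rows whose triplet holds Go
    expected = {
        (p.region, p.axis) for p in wf.TEMPLATE_PARAMETERS if "Go" in p.triplet
    }
    assert expected == {
        (RegionId.mandibular_angle, AxisId.X),
        (RegionId.mandibular_angle, AxisId.Y),
        (RegionId.mandibular_angle, AxisId.Z),
        (RegionId.labial, AxisId.Y),
        (RegionId.chin, AxisId.Z),
        (RegionId.articular, AxisId.X),
        (RegionId.articular, AxisId.Y),
        (RegionId.articular, AxisId.Z),
    }
    entries = {k: v.copy() for k, v in base_case.landmarks.items()}
    entries["Go_R"] = entries["Go_R"] + np.array([-3.0, 0.0, 0.0])
    moved = LandmarkSet(entries)
    changed = {
        (r.parameter.region, r.parameter.axis)
        for r in wf.evaluate_template(moved)
        if r.aai_percent > 1e-12
    }
    assert changed == expected


def test_missing_landmark_error_names_it(base_case):
    entries = {
        k: v for k, v in base_case.landmarks.items() if not k.startswith("He")
    }
    lm = LandmarkSet(entries)
    with pytest.raises(InvalidInputError, match="He_L"):
        wf.evaluate_template(lm)


def test_template_rigid_invariance(base_case, rng):
    ref = wf.evaluate_template(base_case.landmarks)
    for _ in range(5):
        T = random_rigid(rng)
        moved = wf.evaluate_template(base_case.landmarks.transformed(T))
        for r0, r1 in zip(ref, moved):
            assert r1.aai_percent == pytest.approx(r0.aai_percent, abs=1e-9)


@pytest.mark.parametrize(
    "grades,expected",
    [
        ((SeverityGrade.mild,) * 3, SeverityGrade.mild),
        ((SeverityGrade.mild, SeverityGrade.moderate, SeverityGrade.mild), SeverityGrade.moderate),
        ((SeverityGrade.severe, SeverityGrade.mild, SeverityGrade.moderate), SeverityGrade.severe),
    ],
)
def test_region_aggregation_rule(grades, expected):
    assert aggregate_region(grades) == expected


def test_region_aggregation_needs_three_grades():
    with pytest.raises(InvalidInputError):
        aggregate_region([SeverityGrade.mild])


def test_wireframe_edges_deduplicated_and_mirror_symmetric(base_case):
    edges = wf.build_wireframe(base_case.landmarks)
    # independent oracle: enumerate arms of all triplets on both sides
    expected = set()
    for par in wf.TEMPLATE_PARAMETERS:
        a, b, c = par.triplet
        for side in ("left", "right"):
            from faceasym.types import resolve_landmark

            na, nb, nc = (resolve_landmark(s, side) for s in (a, b, c))
            expected.add(tuple(sorted((na, nb))))
            expected.add(tuple(sorted((nb, nc))))
    assert set(edges) == expected
    assert len(edges) == len(set(edges))
    # left and right edge lengths agree on a symmetric face
    lm = base_case.landmarks
    def flip(name):
        if name.endswith("_L"):
            return name[:-1] + "R"
        if name.endswith("_R"):
            return name[:-1] + "L"
        return name
    for a, b in edges:
        d = np.linalg.norm(lm[a] - lm[b])
        d_m = np.linalg.norm(lm[flip(a)] - lm[flip(b)])
        assert d == pytest.approx(d_m, abs=1e-9)


def test_wireframe_of_empty_landmark_set_is_empty():
    assert wf.build_wireframe(LandmarkSet({})) == []


def test_duplicate_parameter_rows_share_one_measurement(base_case):
    case = apply_asymmetry(
        base_case,
        AsymmetrySpec(RegionId.mandibular_angle, AxisId.Y, 2.0, "landmark_shift"),
    )
    results = {
        (r.parameter.region, r.parameter.axis): r
        for r in wf.evaluate_template(case.landmarks)
    }
    shared_a = results[(RegionId.mandibular_angle, AxisId.Y)]
    shared_b = results[(RegionId.articular, AxisId.Y)]
    assert shared_a.parameter.triplet == shared_b.parameter.triplet == ("Tr", "Zg", "Go")
    assert shared_a.aai_percent == shared_b.aai_percent
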