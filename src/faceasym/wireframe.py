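"""Spatial-angle wireframe template analysis.

The template connects named soft-tissue landmarks into a wireframe and
quantifies left/right asymmetry per facial region and axis through 15
landmark-triplet angles. For each angular parameter the full 3D angle at
the middle (vertex) landmark is measured on the left and on the right side,
and asymmetry is expressed as the angle asymmetry index

    AAI = |R - L| / L x 100%

with L the anatomical-left angle. AAI is graded mild / moderate / severe
with half-open cuts at 1% and 3%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grading import CRITERIA, aggregate_region
from .types import (
    AxisId,
    DegenerateGeometryError,
    GradingCriterion,
    InvalidInputError,
    LandmarkSet,
    RegionId,
    SeverityGrade,
    is_bilateral,
    resolve_landmark,
)


@dataclass(frozen=True)
class AngularParameter:
    """One (region, axis) angular parameter: ordered landmark triplet (A, B, C).

    B is the vertex; the measured quantity is the 3D angle between segments
    B->A and B->C, evaluated with bilateral landmark names resolved per side.
    """

    region: RegionId
    axis: AxisId
    triplet: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(set(self.triplet)) != 3:
            raise InvalidInputError(f"triplet members must be distinct: {self.triplet}")

    @property
    def label(self) -> str:
        a, b, c = self.triplet
        return f"∠{a}-{b}-{c}"


#: The 15-row angular-parameter registry (5 regions x 3 axes). Two triplets
#: serve two rows each (Tr-Zg-Go for mandibular-angle Y and articular Y;
#: Me-Go-Mt for mandibular-angle X and chin Z).
TEMPLATE_PARAMETERS: tuple[AngularParameter, ...] = (
    AngularParameter(RegionId.labial, AxisId.X, ("Sal", "Ch", "Stb")),
    AngularParameter(RegionId.labial, AxisId.Y, ("Sal", "Go", "Ch")),
    AngularParameter(RegionId.labial, AxisId.Z, ("Sal", "Ch", "As")),
    AngularParameter(RegionId.mandibular_angle, AxisId.X, ("Me", "Go", "Mt")),
    AngularParameter(RegionId.mandibular_angle, AxisId.Y, ("Tr", "Zg", "Go")),
    AngularParameter(RegionId.mandibular_angle, AxisId.Z, ("Zg", "Tr", "Go")),
    AngularParameter(RegionId.cheek, AxisId.X, ("Ex", "Zg", "Sal")),
    AngularParameter(RegionId.cheek, AxisId.Y, ("Zg", "Tr", "He")),
    AngularParameter(RegionId.cheek, AxisId.Z, ("Tr", "Zg", "Ex")),
    AngularParameter(RegionId.chin, AxisId.X, ("Gn", "Mt", "Me")),
    AngularParameter(RegionId.chin, AxisId.Y, ("Li", "Mt", "Gn")),
    AngularParameter(RegionId.chin, AxisId.Z, ("Me", "Go", "Mt")),
    AngularParameter(RegionId.articular, AxisId.X, ("Ex", "Tr", "Go")),
    AngularParameter(RegionId.articular, AxisId.Y, ("Tr", "Zg", "Go")),
    AngularParameter(RegionId.articular, AxisId.Z, ("Tr", "Go", "Zg")),
)


@dataclass(frozen=True)
class AngleMeasurement:
    parameter: AngularParameter
    left_deg: float
    right_deg: float


@dataclass(frozen=True)
class AAIResult:
    parameter: AngularParameter
    left_deg: float
    right_deg: float
    aai_percent: float
    grade: SeverityGrade


def compute_angle(landmarks: LandmarkSet, triplet, side: str) -> float:
    """3D angle in degrees at the triplet's vertex landmark, for one side.

    Bilateral names are resolved with the side suffix; midline names
    resolve as-is. The angle is arccos of the normalized dot product of
    (A - B) and (C - B), clamped to [-1, 1].
    """
    a, b, c = (landmarks.get(stem, side) for stem in triplet)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu <= 1e-12 or nv <= 1e-12:
        raise DegenerateGeometryError(
            f"zero-length arm in triplet {tuple(triplet)} on side {side!r}"
        )
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def compute_aai(left_deg: float, right_deg: float) -> float:
    """Angle asymmetry index |R - L| / L x 100, in percent.

    The denominator is the anatomical-left angle.
    """
    if not (left_deg > 0):
        raise InvalidInputError(f"left angle must be > 0 deg, got {left_deg}")
    return abs(right_deg - left_deg) / left_deg * 100.0


def classify_aai(
    aai_percent: float, criterion: GradingCriterion | None = None
) -> SeverityGrade:
    """Grade an AAI value; default criterion cuts at 1% and 3% (half-open)."""
    crit = CRITERIA["aai"] if criterion is None else criterion
    return crit.classify(aai_percent)


def measure_parameter(
    landmarks: LandmarkSet, parameter: AngularParameter
) -> AngleMeasurement:
    return AngleMeasurement(
        parameter,
        left_deg=compute_angle(landmarks, parameter.triplet, "left"),
        right_deg=compute_angle(landmarks, parameter.triplet, "right"),
    )


def evaluate_template(
    landmarks: LandmarkSet,
    criterion: GradingCriterion | None = None,
    aai_denominator: str = "left",
) -> list[AAIResult]:
    """Measure all 15 angular parameters and grade their AAI values.

    ``aai_denominator`` is ``"left"`` (the printed formula) or ``"min"``
    (symmetric variant using the smaller of the two angles).
    """
    if aai_denominator not in ("left", "min"):
        raise InvalidInputError("aai_denominator must be 'left' or 'min'")
    results = []
    cache: dict[tuple[str, str, str], AngleMeasurement] = {}
    for par in TEMPLATE_PARAMETERS:
        if par.triplet not in cache:
            cache[par.triplet] = measure_parameter(landmarks, par)
        m = cache[par.triplet]
        if aai_denominator == "left":
            aai = compute_aai(m.left_deg, m.right_deg)
        else:
            lo, hi = sorted((m.left_deg, m.right_deg))
            aai = compute_aai(lo, hi)
        results.append(
            AAIResult(par, m.left_deg, m.right_deg, aai, classify_aai(aai, criterion))
        )
    return results


def region_grades(results: list[AAIResult]) -> dict[RegionId, SeverityGrade]:
    """Aggregate the 15 per-axis grades into 5 region grades.

    A region is mild only if its X, Y and Z parameters are all mild;
    otherwise it takes the worst axis grade.
    """
    by_region: dict[RegionId, dict[AxisId, SeverityGrade]] = {}
    for r in results:
        by_region.setdefault(r.parameter.region, {})[r.parameter.axis] = r.grade
    out = {}
    for region, axes in by_region.items():
        if set(axes) != {AxisId.X, AxisId.Y, AxisId.Z}:
            raise InvalidInputError(f"region {region.value} missing axis grades")
        out[region] = aggregate_region([axes[AxisId.X], axes[AxisId.Y], axes[AxisId.Z]])
    return out


def build_wireframe(landmarks: LandmarkSet) -> list[tuple[str, str]]:
    """Edge list of the wireframe: the two arms of every triplet, both sides.

    Edges are deduplicated and each is a sorted (name, name) pair of
    concrete (side-resolved) landmark identifiers. Only edges whose both
    endpoints are present in ``landmarks`` are emitted.
    """
    edges: set[tuple[str, str]] = set()
    for par in TEMPLATE_PARAMETERS:
        a, b, c = par.triplet
        for side in ("left", "right"):
            names = [resolve_landmark(s, side) for s in (a, b, c)]
            if not all(n in landmarks for n in names):
                continue
            na, nb, nc = names
            edges.add(tuple(sorted((na, nb))))
            edges.add(tuple(sorted((nb, nc))))
    return sorted(edges)


def wireframe_obj_lines(landmarks: LandmarkSet) -> str:
    """OBJ text with the wireframe as line elements, for overlay display."""
    edges = build_wireframe(landmarks)
    names = sorted({n for e in edges for n in e})
    index = {n: i + 1 for i, n in enumerate(names)}
    out = []
    for n in names:
        x, y, z = landmarks[n]
        out.append(f"v {x:.6f} {y:.6f} {z:.6f}")
    for a, b in edges:
        out.append(f"l {index[a]} {index[b]}")
    return "\n".join(out) + "\n"


def template_landmark_stems() -> set[str]:
    """All landmark stems referenced by the 15 angular parameters."""
    return {s for par in TEMPLATE_PARAMETERS for s in par.triplet}


def affected_parameters(stem: str) -> list[AngularParameter]:
    """Parameters whose triplet contains the given landmark stem."""
    return [p for p in TEMPLATE_PARAMETERS if stem in p.triplet]


def results_table(results: list[AAIResult]):
    """Per-parameter report rows as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "region": [r.parameter.region.value for r in results],
            "axis": [r.parameter.axis.value for r in results],
            "parameter": [r.parameter.label for r in results],
            "left_deg": [r.left_deg for r in results],
            "right_deg": [r.right_deg for r in results],
            "aai_percent": [r.aai_percent for r in results],
            "grade": [r.grade.name for r in results],
        }
    )
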