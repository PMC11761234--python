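"""End-to-end workflows tying the modules together.

Two analyses per subject:

* wireframe: pose-independent (triplet angles are rigid-invariant) —
  evaluate the 15 angular parameters and grade their AAI values;
* mirroring: pose-normalize, optionally crop, reflect across X = 0,
  trimmed-ICP align the reflection onto the original, measure per-vertex
  point-to-surface deviations, summarize per region, grade under one of
  the three deviation criteria.

Cohort helpers turn lists of analyzed subjects into GradeMatrix objects
for the concordance layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import concordance, regions, wireframe
from .grading import get_criterion
from .mirror import (
    DeviationField,
    ICPParams,
    ICPResult,
    RegionDeviationSummary,
    best_fit_align,
    compute_deviation,
    mirror_mesh,
)
from .pose import RigidTransform, crop_extent, frankfort_pose
from .types import (
    AxisId,
    FaceMesh,
    GradingCriterion,
    InvalidInputError,
    LandmarkSet,
    RegionId,
    SeverityGrade,
)


@dataclass
class WireframeReport:
    results: list[wireframe.AAIResult]
    region_grades: dict[RegionId, SeverityGrade]

    def axis_grades(self) -> dict[tuple[RegionId, AxisId], SeverityGrade]:
        return {
            (r.parameter.region, r.parameter.axis): r.grade for r in self.results
        }


def run_wireframe(
    landmarks: LandmarkSet, aai_denominator: str = "left"
) -> WireframeReport:
    results = wireframe.evaluate_template(landmarks, aai_denominator=aai_denominator)
    return WireframeReport(results, wireframe.region_grades(results))


@dataclass(repr=False)
class MirrorReport:
    criterion: GradingCriterion
    icp: ICPResult
    deviations: DeviationField
    summaries: dict[RegionId, RegionDeviationSummary]
    axis_grades: dict[tuple[RegionId, AxisId], SeverityGrade]
    region_grades: dict[RegionId, SeverityGrade]
    normalized_mesh: FaceMesh
    normalized_landmarks: LandmarkSet
    pose: RigidTransform


def run_mirror(
    mesh: FaceMesh,
    landmarks: LandmarkSet,
    criterion: str | int = 3,
    icp_params: ICPParams | None = None,
    roi_config: regions.RoiConfig | None = None,
    crop_bounds=None,
    normalize: bool = True,
    two_way: bool = False,
) -> MirrorReport:
    """Full mirroring-and-overlapping analysis of one subject.

    ``criterion`` is 1 (RMSE 0.5/1), 2 (MFM 3/6) or 3 (MFM 1/2), or a
    criterion name. Set ``normalize=False`` when mesh and landmarks are
    already in the standard frame. ``two_way=True`` additionally samples
    deviations mirrored->original (vertex i of the mirrored mesh is the
    reflection of original vertex i, so region masks apply to both
    directions) and summarizes over both; the default is the one-way
    original->mirrored sampling.
    """
    crit = get_criterion(criterion)
    if crit.statistic not in ("RMSE", "MFM"):
        raise InvalidInputError(
            f"criterion {crit.name!r} grades {crit.statistic}, not a deviation summary"
        )
    if normalize:
        pose = frankfort_pose(landmarks)
        mesh_n = pose.apply_mesh(mesh, frame_tag="normalized")
        lm_n = landmarks.transformed(pose)
    else:
        pose = RigidTransform.identity()
        mesh_n = mesh
        lm_n = landmarks
    if crop_bounds is not None:
        mesh_n = crop_extent(mesh_n, crop_bounds)
    mirrored = mirror_mesh(mesh_n)
    icp = best_fit_align(mirrored, mesh_n, icp_params)
    aligned = icp.transform.apply_mesh(mirrored)
    dev = compute_deviation(mesh_n, aligned)
    reverse = compute_deviation(aligned, mesh_n) if two_way else None
    masks = regions.region_masks(mesh_n, lm_n, roi_config)
    summaries = {}
    axis_grades = {}
    region_grades = {}
    from .grading import aggregate_region
    from .mirror import summarize_region

    for region, mask in masks.items():
        s = summarize_region(dev, mask.vertex_indices, region)
        if reverse is not None:
            r = summarize_region(reverse, mask.vertex_indices, region)
            n = s.n_vertices + r.n_vertices
            s = type(s)(
                region=region,
                n_vertices=n,
                rmse=float(
                    np.sqrt(
                        (s.rmse**2 * s.n_vertices + r.rmse**2 * r.n_vertices) / n
                    )
                ),
                mfm=max(s.mfm, r.mfm),
                rmse_axis=tuple(
                    float(
                        np.sqrt(
                            (a**2 * s.n_vertices + b**2 * r.n_vertices) / n
                        )
                    )
                    for a, b in zip(s.rmse_axis, r.rmse_axis)
                ),
                mfm_axis=tuple(
                    max(a, b) for a, b in zip(s.mfm_axis, r.mfm_axis)
                ),
            )
        summaries[region] = s
        for axis in AxisId:
            stat = (
                s.rmse_axis[axis.index]
                if crit.statistic == "RMSE"
                else s.mfm_axis[axis.index]
            )
            axis_grades[(region, axis)] = crit.classify(stat)
        region_grades[region] = aggregate_region(
            [axis_grades[(region, a)] for a in AxisId]
        )
    return MirrorReport(
        crit, icp, dev, summaries, axis_grades, region_grades, mesh_n, lm_n, pose
    )


def wireframe_grade_matrix(cases) -> concordance.GradeMatrix:
    """GradeMatrix of the wireframe analysis over a cohort of cases.

    ``cases`` is an iterable of objects with ``landmarks`` and ``case_id``.
    """
    grades = {}
    for case in cases:
        rep = run_wireframe(case.landmarks)
        grades[case.case_id] = rep.axis_grades()
    return concordance.GradeMatrix(grades, method_tag="wireframe")


def mirror_grade_matrix(
    cases,
    criterion: str | int = 3,
    icp_params: ICPParams | None = None,
    roi_config: regions.RoiConfig | None = None,
) -> concordance.GradeMatrix:
    """GradeMatrix of the mirroring analysis over a cohort of cases."""
    crit = get_criterion(criterion)
    grades = {}
    for case in cases:
        rep = run_mirror(
            case.mesh, case.landmarks, criterion, icp_params, roi_config
        )
        grades[case.case_id] = rep.axis_grades
    return concordance.GradeMatrix(grades, method_tag=f"mirroring({crit.name})")


def mirror_summary_table(report: MirrorReport):
    """Per-region RMSE/MFM rows of one mirror analysis as a DataFrame."""
    import pandas as pd

    rows = []
    for region, s in report.summaries.items():
        rows.append(
            {
                "region": region.value,
                "n_vertices": s.n_vertices,
                "rmse_mm": s.rmse,
                "mfm_mm": s.mfm,
                "rmse_x": s.rmse_axis[0],
                "rmse_y": s.rmse_axis[1],
                "rmse_z": s.rmse_axis[2],
                "mfm_x": s.mfm_axis[0],
                "mfm_y": s.mfm_axis[1],
                "mfm_z": s.mfm_axis[2],
                "grade": report.region_grades[region].name,
            }
        )
    return pd.DataFrame(rows)
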