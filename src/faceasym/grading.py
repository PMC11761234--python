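"""Severity criteria for grading regional asymmetry.

Three criteria grade the mirroring-and-overlap deviation summaries and one
grades the wireframe template's angle asymmetry index (AAI):

* ``rmse_criterion`` (criterion 1): region RMSE, cuts 0.5 / 1.0 mm
* ``mfm_wide``       (criterion 2): region MFM,  cuts 3 / 6 mm
* ``mfm_narrow``     (criterion 3): region MFM,  cuts 1 / 2 mm
* ``aai``                         : AAI,         cuts 1 / 3 percent

All bands are half-open: [0, lower) mild, [lower, upper) moderate,
[upper, inf) severe.
"""

from __future__ import annotations

from .types import GradingCriterion, InvalidInputError, SeverityGrade

CRITERIA: dict[str, GradingCriterion] = {
    "rmse_criterion": GradingCriterion("rmse_criterion", "RMSE", 0.5, 1.0, "mm"),
    "mfm_wide": GradingCriterion("mfm_wide", "MFM", 3.0, 6.0, "mm"),
    "mfm_narrow": GradingCriterion("mfm_narrow", "MFM", 1.0, 2.0, "mm"),
    "aai": GradingCriterion("aai", "AAI", 1.0, 3.0, "percent"),
}

#: Conventional numbering of the mirroring criteria.
CRITERION_BY_NUMBER = {1: "rmse_criterion", 2: "mfm_wide", 3: "mfm_narrow"}


def get_criterion(key: str | int) -> GradingCriterion:
    """Look up a criterion by name or by its conventional number (1/2/3)."""
    if isinstance(key, int):
        try:
            key = CRITERION_BY_NUMBER[key]
        except KeyError:
            raise InvalidInputError(f"criterion number must be 1..3, got {key}") from None
    try:
        return CRITERIA[key]
    except KeyError:
        raise InvalidInputError(
            f"unknown criterion {key!r}; choose from {sorted(CRITERIA)}"
        ) from None


def aggregate_region(grades) -> SeverityGrade:
    """Region-level grade from its three per-axis grades.

    Mild only when all three axes are mild; otherwise the worst (maximum)
    of the three grades.
    """
    grades = list(grades)
    if len(grades) != 3:
        raise InvalidInputError(f"need exactly 3 axis grades, got {len(grades)}")
    return SeverityGrade(max(int(g) for g in grades))
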