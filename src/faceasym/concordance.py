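"""Recognition rates, consistency rates and repeatability statistics.

The two asymmetry-grading methods (mirroring-and-overlap, wireframe
template) are compared through per-region recognition rates — the fraction
of subjects graded moderate-or-severe — and the consistency rate

    consistency = min(rate_a, rate_b) / max(rate_a, rate_b) x 100%

which realizes both directions of the published ratio formula (the smaller
recognition rate is always the numerator). Rates are kept as exact
rationals; table output is rounded half-up to one decimal only at the end,
so no double-rounding drift enters the printed percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grading import aggregate_region
from .types import AxisId, InvalidInputError, RegionId, SeverityGrade

#: Threshold above which inter-method consistency is called good (percent).
GOOD_CONSISTENCY_PERCENT = 85.0

REGION_ORDER = (
    RegionId.labial,
    RegionId.mandibular_angle,
    RegionId.cheek,
    RegionId.chin,
    RegionId.articular,
)


@dataclass(frozen=True)
class RecognitionRate:
    """Moderate-or-severe count over total subjects, kept exact."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise InvalidInputError("recognition rate needs a positive denominator")
        if not (0 <= self.numerator <= self.denominator):
            raise InvalidInputError(
                f"recognition count {self.numerator}/{self.denominator} out of range"
            )

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def percent(self) -> float:
        return 100.0 * self.numerator / self.denominator

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.numerator}/{self.denominator}"


def round_half_up(value, ndigits: int = 1) -> float:
    """Decimal half-up rounding (22/23 -> 95.7, 3/23 -> 13.0)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


def recognition_rate(grades: Iterable[SeverityGrade]) -> RecognitionRate:
    """Fraction of grades that are moderate or severe."""
    grades = list(grades)
    if not grades:
        raise InvalidInputError("cannot compute a recognition rate of no grades")
    num = sum(1 for g in grades if SeverityGrade(g) >= SeverityGrade.moderate)
    return RecognitionRate(num, len(grades))


def consistency_rate(rate_a: RecognitionRate, rate_b: RecognitionRate) -> Fraction | None:
    """min/max ratio of two recognition rates, in percent (exact Fraction).

    Returns None (flagged missing) when both rates are zero, where the
    ratio is undefined.
    """
    fa, fb = rate_a.fraction, rate_b.fraction
    if fa == 0 and fb == 0:
        return None
    lo, hi = sorted((fa, fb))
    return Fraction(100) * lo / hi


def consistency_percent(rate_a: RecognitionRate, rate_b: RecognitionRate) -> float | None:
    """Consistency rate rounded half-up to one decimal, or None if undefined."""
    c = consistency_rate(rate_a, rate_b)
    return None if c is None else round_half_up(c, 1)


# ---------------------------------------------------------------------------
# Grade matrices
# ---------------------------------------------------------------------------

class GradeMatrix:
    """Per-subject severity grades at (region, axis) and region level.

    ``axis_grades[subject][(region, axis)]`` holds the 15 per-axis grades;
    region aggregates are derived with the all-mild/worst-axis rule and
    must therefore always be consistent with their axis cells.
    """

    def __init__(
        self,
        axis_grades: Mapping[str, Mapping[tuple[RegionId, AxisId], SeverityGrade]],
        method_tag: str = "",
    ) -> None:
        subjects = list(axis_grades)
        if not subjects:
            raise InvalidInputError("grade matrix needs at least one subject")
        cells = {}
        expected = {(r, a) for r in RegionId for a in AxisId}
        for s in subjects:
            got = dict(axis_grades[s])
            if set(got) != expected:
                raise InvalidInputError(
                    f"subject {s!r}: grade matrix incomplete (needs all 5x3 cells)"
                )
            cells[s] = {k: SeverityGrade(v) for k, v in got.items()}
        self.subjects = subjects
        self.cells = cells
        self.method_tag = method_tag

    def axis_grade(self, subject, region, axis) -> SeverityGrade:
        return self.cells[subject][(region, axis)]

    def region_grade(self, subject, region) -> SeverityGrade:
        return aggregate_region(
            [self.cells[subject][(region, a)] for a in AxisId]
        )

    def region_recognition(self, region: RegionId) -> RecognitionRate:
        return recognition_rate(
            self.region_grade(s, region) for s in self.subjects
        )

    def axis_recognition(self, region: RegionId, axis: AxisId) -> RecognitionRate:
        return recognition_rate(
            self.axis_grade(s, region, axis) for s in self.subjects
        )


def _check_same_subjects(a: GradeMatrix, b: GradeMatrix) -> None:
    if sorted(a.subjects) != sorted(b.subjects):
        raise InvalidInputError("grade matrices cover different subjects")


def build_overall_table(
    mirror_grades: GradeMatrix, template_grades: GradeMatrix
) -> pd.DataFrame:
    """Per-region recognition and consistency rates, plus the average row.

    Per-region cells are exact min/max ratios rounded half-up to one
    decimal; the average row is the mean of those rounded cells (the
    convention the published tables follow), itself rounded to one decimal.
    """
    _check_same_subjects(mirror_grades, template_grades)
    rows = []
    for region in REGION_ORDER:
        rm = mirror_grades.region_recognition(region)
        rt = template_grades.region_recognition(region)
        c = consistency_rate(rm, rt)
        rows.append(
            {
                "region": region.value,
                "mirror_rate": str(rm),
                "template_rate": str(rt),
                "consistency_percent": None if c is None else round_half_up(c, 1),
            }
        )
    defined = [r["consistency_percent"] for r in rows if r["consistency_percent"] is not None]
    mean = (
        round_half_up(sum(defined) / len(defined), 1) if defined else None
    )
    rows.append(
        {
            "region": "average",
            "mirror_rate": "",
            "template_rate": "",
            "consistency_percent": mean,
        }
    )
    return pd.DataFrame(rows)


def build_dimension_table(
    mirror_grades: GradeMatrix, template_grades: GradeMatrix
) -> pd.DataFrame:
    """Per-(region, axis) recognition and consistency rates: 15 rows."""
    _check_same_subjects(mirror_grades, template_grades)
    rows = []
    for region in REGION_ORDER:
        for axis in AxisId:
            rm = mirror_grades.axis_recognition(region, axis)
            rt = template_grades.axis_recognition(region, axis)
            c = consistency_rate(rm, rt)
            rows.append(
                {
                    "region": region.value,
                    "axis": axis.value,
                    "mirror_rate": str(rm),
                    "template_rate": str(rt),
                    "consistency_percent": None if c is None else round_half_up(c, 1),
                }
            )
    return pd.DataFrame(rows)


def overall_table_from_counts(
    mirror_counts: Sequence[int],
    template_counts: Sequence[int],
    n_subjects: int,
) -> pd.DataFrame:
    """Counts-replay variant of :func:`build_overall_table`.

    ``mirror_counts`` / ``template_counts`` are the five per-region
    moderate-or-severe counts in the canonical region order.
    """
    if len(mirror_counts) != 5 or len(template_counts) != 5:
        raise InvalidInputError("need exactly five per-region counts per method")
    rows = []
    for region, nm, nt in zip(REGION_ORDER, mirror_counts, template_counts):
        rm = RecognitionRate(int(nm), n_subjects)
        rt = RecognitionRate(int(nt), n_subjects)
        c = consistency_rate(rm, rt)
        rows.append(
            {
                "region": region.value,
                "mirror_rate": str(rm),
                "template_rate": str(rt),
                "consistency_percent": None if c is None else round_half_up(c, 1),
            }
        )
    defined = [r["consistency_percent"] for r in rows if r["consistency_percent"] is not None]
    mean = round_half_up(sum(defined) / len(defined), 1) if defined else None
    rows.append(
        {
            "region": "average",
            "mirror_rate": "",
            "template_rate": "",
            "consistency_percent": mean,
        }
    )
    return pd.DataFrame(rows)


def dimension_table_from_counts(
    mirror_counts: Mapping[tuple[str, str], int],
    template_counts: Mapping[tuple[str, str], int],
    n_subjects: int,
) -> pd.DataFrame:
    """Counts-replay variant of :func:`build_dimension_table`.

    Keys are (region value, axis value) pairs for all 15 cells.
    """
    rows = []
    for region in REGION_ORDER:
        for axis in AxisId:
            key = (region.value, axis.value)
            try:
                nm = mirror_counts[key]
                nt = template_counts[key]
            except KeyError:
                raise InvalidInputError(f"missing counts for cell {key}") from None
            rm = RecognitionRate(int(nm), n_subjects)
            rt = RecognitionRate(int(nt), n_subjects)
            c = consistency_rate(rm, rt)
            rows.append(
                {
                    "region": region.value,
                    "axis": axis.value,
                    "mirror_rate": str(rm),
                    "template_rate": str(rt),
                    "consistency_percent": None if c is None else round_half_up(c, 1),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeatability
# ---------------------------------------------------------------------------

def cohen_kappa(
    labels_a: Sequence[SeverityGrade], labels_b: Sequence[SeverityGrade]
) -> float:
    """Unweighted Cohen's kappa between two grade sequences.

    Identical sequences return 1.0 (covers the degenerate p_e = 1 case of
    two constant, agreeing raters, where the usual formula is 0/0).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise InvalidInputError(f"label lengths differ: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise InvalidInputError("kappa needs at least 2 paired labels")
    if a == b:
        return 1.0
    from sklearn.metrics import cohen_kappa_score

    levels = sorted({*a, *b})
    return float(
        cohen_kappa_score(
            [int(SeverityGrade(x)) for x in a],
            [int(SeverityGrade(x)) for x in b],
            labels=[int(SeverityGrade(x)) for x in levels],
        )
    )


def kappa_table(
    first: GradeMatrix, repeat: GradeMatrix
) -> pd.DataFrame:
    """Per-(region, axis) kappa between two repeated grade matrices."""
    _check_same_subjects(first, repeat)
    subjects = first.subjects
    rows = []
    for region in REGION_ORDER:
        for axis in AxisId:
            ka = cohen_kappa(
                [first.axis_grade(s, region, axis) for s in subjects],
                [repeat.axis_grade(s, region, axis) for s in subjects],
            )
            rows.append(
                {"region": region.value, "axis": axis.value, "kappa": ka}
            )
    return pd.DataFrame(rows)
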