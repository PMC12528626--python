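"""Image-quality severity rubric, rater consensus, and exam-level grading.

The rubric converts the obscured-prostate proportion (scored in 10%
increments on low b-value DWI) into four categories: optimal (0%), mild
(10%), moderate (20%), severe (>= 30%).  Multi-rater assessments are
combined by the ordinal median; when an examination has several DWI series,
the best (least severe) series-level grade becomes the examination-level
grade, because the radiologist reads whichever series shows the gland best.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from .cohort import CohortTable, ExamRecord, IQCategory, SeriesRecord

__all__ = [
    "RatingConsensus",
    "grade_from_proportion",
    "consensus_rating",
    "exam_level_iq",
    "reconcile_series",
    "reconcile_exam",
    "binarize_iq",
    "grade_cohort",
]

AdjudicationPolicy = Literal["worse", "better", "error"]


@dataclass(frozen=True)
class RatingConsensus:
    """Outcome of combining several ordinal ratings of one item."""

    category: IQCategory
    adjudication_needed: bool
    n_raters: int


def grade_from_proportion(obscured_pct: int) -> IQCategory:
    """Map an obscured-prostate percentage to its severity category.

    0 -> optimal, 10 -> mild, 20 -> moderate, >= 30 -> severe.
    """
    if obscured_pct % 10 != 0 or not (0 <= obscured_pct <= 100):
        raise ValueError(
            f"obscured_pct must be on the 10%-increment grid in [0, 100], got {obscured_pct}"
        )
    if obscured_pct == 0:
        return IQCategory.OPTIMAL
    if obscured_pct == 10:
        return IQCategory.MILD
    if obscured_pct == 20:
        return IQCategory.MODERATE
    return IQCategory.SEVERE


def consensus_rating(
    ratings: Sequence[IQCategory], adjudication: AdjudicationPolicy = "worse"
) -> RatingConsensus:
    """Ordinal median of the raters' categories.

    With an even rater count the median can fall between two categories;
    such items are flagged ``adjudication_needed`` and resolved by policy:
    ``worse`` (default) takes the more severe of the two middle ratings,
    ``better`` the less severe, ``error`` raises so a human adjudicates.
    """
    if len(ratings) == 0:
        raise ValueError("consensus_rating requires at least one rating")
    s = sorted(ratings)
    n = len(s)
    if n % 2 == 1:
        return RatingConsensus(s[n // 2], False, n)
    lo, hi = s[n // 2 - 1], s[n // 2]
    if lo == hi:
        return RatingConsensus(lo, False, n)
    if adjudication == "error":
        raise ValueError(f"median falls between {lo} and {hi}; adjudication required")
    cat = hi if adjudication == "worse" else lo
    return RatingConsensus(cat, True, n)


def exam_level_iq(series_categories: Sequence[IQCategory]) -> IQCategory:
    """Examination-level IQ = the best (least severe) series-level grade."""
    if len(series_categories) == 0:
        raise ValueError("exam_level_iq requires at least one series category")
    return min(series_categories)


def reconcile_series(
    series: SeriesRecord, adjudication: AdjudicationPolicy = "worse"
) -> tuple[IQCategory, str]:
    """Resolve one series to a single category with its source tag.

    Radiologist information (per-rater categories, or a scored obscured
    proportion) overrides the model's category: the study treated
    radiologist review as ground truth wherever it existed.
    """
    if series.rater_categories:
        cat = consensus_rating(list(series.rater_categories.values()), adjudication).category
        return cat, "radiologist"
    if series.obscured_pct is not None:
        return grade_from_proportion(series.obscured_pct), "radiologist"
    if series.model_category is not None:
        return series.model_category, "model"
    raise ValueError(f"series {series.series_id}: no IQ source present")


def reconcile_exam(
    series: Sequence[SeriesRecord], adjudication: AdjudicationPolicy = "worse"
) -> tuple[IQCategory, str]:
    """Reconcile every series, then take the best as the exam-level grade.

    The source tag of the exam is 'radiologist' if any series achieving the
    best category was radiologist-graded, else 'model'.
    """
    if len(series) == 0:
        raise ValueError("reconcile_exam requires at least one series")
    graded = [reconcile_series(s, adjudication) for s in series]
    best = min(cat for cat, _ in graded)
    sources = {src for cat, src in graded if cat == best}
    return best, ("radiologist" if "radiologist" in sources else "model")


def binarize_iq(category: IQCategory) -> str:
    """Binarize IQ: severe-moderate -> 'poor', mild-optimal -> 'acceptable'."""
    return "poor" if category >= IQCategory.MODERATE else "acceptable"


def grade_cohort(
    cohort: CohortTable, adjudication: AdjudicationPolicy = "worse"
) -> CohortTable:
    """Fill ``exam_iq``/``iq_source`` for exams lacking a stored grade.

    Stored grades are kept untouched.  Exams with neither a stored grade nor
    any linked series stay ungraded.
    """
    by_exam: dict[str, list[SeriesRecord]] = {}
    for s in cohort.series:
        by_exam.setdefault(s.exam_id, []).append(s)
    graded: list[ExamRecord] = []
    for ex in cohort.exams:
        if ex.exam_iq is not None or ex.exam_id not in by_exam:
            graded.append(ex)
            continue
        cat, src = reconcile_exam(by_exam[ex.exam_id], adjudication)
        graded.append(replace(ex, exam_iq=cat, iq_source=src))
    return cohort.with_exams(graded)
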