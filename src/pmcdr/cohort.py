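"""Cohort domain types and delimited-text I/O.

The analysis operates on two tables: a series-level table (one row per DWI
series, carrying the obscured-prostate proportion and/or categorical
image-quality ratings) and an examination-level table (one row per prostate
MRI examination, carrying the confounders and diagnostic outcomes).  Both are
plain delimited text (comma by default, tab accepted), UTF-8, with a header
row.  Missing values are empty fields in files and ``None`` in memory —
never a sentinel number.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IQCategory",
    "SeriesRecord",
    "ExamRecord",
    "CohortTable",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "read_series",
    "read_exams",
    "write_series",
    "write_exams",
]


class IQCategory(enum.IntEnum):
    """Four-point DWI image-quality scale, ordered by artifact severity.

    The ordinal code counts severity: ``OPTIMAL`` (0% of the prostate
    obscured by gas-induced susceptibility artifact) < ``MILD`` (10%) <
    ``MODERATE`` (20%) < ``SEVERE`` (>= 30%).
    """

    OPTIMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    def __str__(self) -> str:  # category names in files are lowercase
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "IQCategory":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown IQ category {name!r}") from None


FACILITIES = ("I", "II", "III")
BIOPSY_STATUSES = ("naive", "prev_benign", "unknown")
ZONES = ("PZ", "TZ", "none")


class CohortValidationError(ValueError):
    """Raised when one or more rows violate the cohort invariants.

    Carries the full list of row-numbered messages so no offending row is
    silently dropped.
    """

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class SeriesRecord:
    """One DWI series of an examination.

    At least one of ``obscured_pct`` (radiologist-scored obscured prostate
    proportion, 10% increments), ``rater_categories`` (per-rater categorical
    assessments) or ``model_category`` (deep-learning model output) must be
    present.
    """

    exam_id: str
    series_id: str
    obscured_pct: int | None = None
    rater_categories: Mapping[str, IQCategory] = field(default_factory=dict)
    model_category: IQCategory | None = None

    def validate(self) -> list[str]:
        errs = []
        if self.obscured_pct is not None:
            p = self.obscured_pct
            if p % 10 != 0 or not (0 <= p <= 100):
                errs.append(
                    f"obscured_pct must be a multiple of 10 in [0, 100], got {p}"
                )
        if (
            self.obscured_pct is None
            and not self.rater_categories
            and self.model_category is None
        ):
            errs.append(
                "series carries no IQ information (no obscured_pct, "
                "rater_categories or model_category)"
            )
        return errs


@dataclass(frozen=True)
class ExamRecord:
    """One prostate MRI examination with confounders and outcomes.

    ``confirmed`` means any pathological diagnosis within the one-year
    post-MRI window; ``cspca`` means clinically significant prostate cancer
    (Grade group >= 2), which implies ``confirmed``.  ``exam_iq`` is the
    examination-level IQ (best series); ``iq_source`` records whether that
    grade came from radiologists or the model.
    """

    exam_id: str
    patient_id: str
    age: float
    psa: float | None
    facility: str
    biopsy_status: str
    pirads: int
    confirmed: bool
    cspca: bool
    dominant_zone: str = "none"
    exam_iq: IQCategory | None = None
    iq_source: str | None = None  # "radiologist" | "model"

    def validate(self) -> list[str]:
        errs = []
        if not self.age > 0:
            errs.append(f"age must be positive, got {self.age}")
        if self.psa is not None and self.psa < 0:
            errs.append(f"psa must be non-negative, got {self.psa}")
        if self.facility not in FACILITIES:
            errs.append(f"facility must be one of {FACILITIES}, got {self.facility!r}")
        if self.biopsy_status not in BIOPSY_STATUSES:
            errs.append(
                f"biopsy_status must be one of {BIOPSY_STATUSES}, "
                f"got {self.biopsy_status!r}"
            )
        if self.pirads not in (1, 2, 3, 4, 5):
            errs.append(f"pirads must be an integer 1-5, got {self.pirads}")
        if self.cspca and not self.confirmed:
            errs.append("cspca implies confirmed (Grade group >= 2 is a diagnosis)")
        if self.dominant_zone not in ZONES:
            errs.append(
                f"dominant_zone must be one of {ZONES}, got {self.dominant_zone!r}"
            )
        if self.iq_source is not None and self.iq_source not in ("radiologist", "model"):
            errs.append(f"iq_source must be 'radiologist' or 'model', got {self.iq_source!r}")
        return errs


@dataclass
class CohortTable:
    """Validated container for one cohort: exams plus optional linked series."""

    exams: list[ExamRecord]
    series: list[SeriesRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        errs = []
        seen: set[str] = set()
        for i, ex in enumerate(self.exams):
            if ex.exam_id in seen:
                errs.append(f"exam row {i}: duplicate exam_id {ex.exam_id!r}")
            seen.add(ex.exam_id)
            errs.extend(f"exam row {i} ({ex.exam_id}): {m}" for m in ex.validate())
        for i, sr in enumerate(self.series):
            if sr.exam_id not in seen:
                errs.append(
                    f"series row {i}: exam_id {sr.exam_id!r} has no matching exam"
                )
            errs.extend(f"series row {i} ({sr.series_id}): {m}" for m in sr.validate())
        if errs:
            raise CohortValidationError(errs)

    def __len__(self) -> int:
        return len(self.exams)

    def series_for(self, exam_id: str) -> list[SeriesRecord]:
        return [s for s in self.series if s.exam_id == exam_id]

    def exams_frame(self) -> pd.DataFrame:
        """Examination table as a DataFrame (missing values as NA/None)."""
        return pd.DataFrame([_exam_to_row(e) for e in self.exams], columns=EXAM_COLUMNS)

    def series_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [_series_to_row(s) for s in self.series], columns=SERIES_COLUMNS
        )

    def with_exams(self, exams: Iterable[ExamRecord]) -> "CohortTable":
        return CohortTable(list(exams), list(self.series), self.provenance)


EXAM_COLUMNS = [
    "exam_id",
    "patient_id",
    "age",
    "psa",
    "facility",
    "biopsy_status",
    "pirads",
    "confirmed",
    "cspca",
    "dominant_zone",
    "exam_iq",
    "iq_source",
]
SERIES_COLUMNS = ["exam_id", "series_id", "obscured_pct", "rater_categories", "model_category"]


def _exam_to_row(e: ExamRecord) -> dict:
    return {
        "exam_id": e.exam_id,
        "patient_id": e.patient_id,
        "age": e.age,
        "psa": e.psa,
        "facility": e.facility,
        "biopsy_status": e.biopsy_status,
        "pirads": e.pirads,
        "confirmed": int(e.confirmed),
        "cspca": int(e.cspca),
        "dominant_zone": e.dominant_zone,
        "exam_iq": str(e.exam_iq) if e.exam_iq is not None else None,
        "iq_source": e.iq_source,
    }


def _series_to_row(s: SeriesRecord) -> dict:
    raters = ";".join(f"{r}={c}" for r, c in s.rater_categories.items())
    return {
        "exam_id": s.exam_id,
        "series_id": s.series_id,
        "obscured_pct": s.obscured_pct,
        "rater_categories": raters or None,
        "model_category": str(s.model_category) if s.model_category is not None else None,
    }


def _parse_raters(cell: str) -> dict[str, IQCategory]:
    out: dict[str, IQCategory] = {}
    for part in cell.split(";"):
        part = part.strip()
        if not part:
            continue
        rater, _, cat = part.partition("=")
        if not _ or not cat:
            raise ValueError(f"malformed rater entry {part!r} (expected rater=category)")
        out[rater.strip()] = IQCategory.from_name(cat)
    return out


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or v is pd.NA or v == ""


def _read_table(path, delimiter: str | None, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(
            [f"{path}: missing required column(s) {missing}; found {list(df.columns)}"]
        )
    return df


def read_exams(path, delimiter: str | None = None) -> list[ExamRecord]:
    """Read the examination-level table; collect row-numbered errors."""
    required = [c for c in EXAM_COLUMNS if c not in ("exam_iq", "iq_source")]
    df = _read_table(path, delimiter, required)
    errs: list[str] = []
    out: list[ExamRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # 1-based + header
        try:
            out.append(
                ExamRecord(
                    exam_id=row["exam_id"],
                    patient_id=row["patient_id"],
                    age=float(row["age"]),
                    psa=None if _is_missing(row["psa"]) else float(row["psa"]),
                    facility=row["facility"],
                    biopsy_status=row["biopsy_status"],
                    pirads=int(row["pirads"]),
                    confirmed=_parse_bool(row["confirmed"]),
                    cspca=_parse_bool(row["cspca"]),
                    dominant_zone=row["dominant_zone"] or "none",
                    exam_iq=None
                    if _is_missing(row.get("exam_iq"))
                    else IQCategory.from_name(row["exam_iq"]),
                    iq_source=None
                    if _is_missing(row.get("iq_source"))
                    else row["iq_source"],
                )
            )
        except (ValueError, KeyError) as exc:
            errs.append(f"{path} line {i}: {exc}")
    if errs:
        raise CohortValidationError(errs)
    return out


def read_series(path, delimiter: str | None = None) -> list[SeriesRecord]:
    df = _read_table(path, delimiter, SERIES_COLUMNS)
    errs: list[str] = []
    out: list[SeriesRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            rec = SeriesRecord(
                exam_id=row["exam_id"],
                series_id=row["series_id"],
                obscured_pct=None
                if _is_missing(row["obscured_pct"])
                else _parse_pct(row["obscured_pct"]),
                rater_categories=_parse_raters(row["rater_categories"] or ""),
                model_category=None
                if _is_missing(row["model_category"])
                else IQCategory.from_name(row["model_category"]),
            )
            errs.extend(f"{path} line {i}: {m}" for m in rec.validate())
            out.append(rec)
        except ValueError as exc:
            errs.append(f"{path} line {i}: {exc}")
    if errs:
        raise CohortValidationError(errs)
    return out


def _parse_pct(cell: str) -> int:
    v = float(cell)
    if v != int(v):
        raise ValueError(f"obscured_pct must be an integer percentage, got {cell!r}")
    return int(v)


def _parse_bool(cell: str) -> bool:
    c = str(cell).strip().lower()
    if c in ("1", "true", "yes"):
        return True
    if c in ("0", "false", "no"):
        return False
    raise ValueError(f"expected boolean 0/1, got {cell!r}")


def load_cohort(series_path=None, exams_path=None, delimiter: str | None = None) -> CohortTable:
    """Load and validate a cohort from its delimited-text tables.

    Stored ``exam_iq`` values are kept as read; the loader never overwrites
    a stored grade (both raw and pre-graded inputs are supported).
    """
    if exams_path is None:
        raise ValueError("exams_path is required")
    exams = read_exams(exams_path, delimiter)
    series = read_series(series_path, delimiter) if series_path is not None else []
    return CohortTable(exams, series, provenance=f"loaded from {exams_path}")


def write_exams(exams: Iterable[ExamRecord], path, delimiter: str = ",") -> None:
    df = pd.DataFrame([_exam_to_row(e) for e in exams], columns=EXAM_COLUMNS)
    df.to_csv(path, sep=delimiter, index=False)


def write_series(series: Iterable[SeriesRecord], path, delimiter: str = ",") -> None:
    df = pd.DataFrame([_series_to_row(s) for s in series], columns=SERIES_COLUMNS)
    # obscured_pct as integer text, not "10.0"
    df["obscured_pct"] = df["obscured_pct"].map(
        lambda v: "" if v is None or pd.isna(v) else str(int(v))
    )
    df.to_csv(path, sep=delimiter, index=False)


def write_cohort(cohort: CohortTable, exams_path, series_path=None, delimiter: str = ",") -> None:
    """Write a cohort back to delimited text that :func:`load_cohort` accepts.

    Column order is stable; missing PSA (and every other absent value) is an
    empty cell, never a number.
    """
    write_exams(cohort.exams, exams_path, delimiter)
    if series_path is not None:
        write_series(cohort.series, series_path, delimiter)
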