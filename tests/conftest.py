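import pandas as pd
import pytest

from pmcdr import CohortTable, ExamRecord, IQCategory, SeriesRecord


def make_exam(i, **kw):
    base = dict(
        exam_id=f"E{i:04d}",
        patient_id=f"P{i:04d}",
        age=65.0,
        psa=6.0,
        facility="I",
        biopsy_status="naive",
        pirads=2,
        confirmed=False,
        cspca=False,
        dominant_zone="none",
        exam_iq=None,
        iq_source=None,
    )
    base.update(kw)
    return ExamRecord(**base)


@pytest.fixture
def tiny_cohort():
    exams = [
        make_exam(0, pirads=4, confirmed=True, cspca=True, dominant_zone="PZ"),
        make_exam(1, psa=None, facility="II"),
    ]
    series = [
        SeriesRecord("E0000", "E0000_s0", obscured_pct=30),
        SeriesRecord("E0001", "E0001_s0", model_category=IQCategory.OPTIMAL),
    ]
    return CohortTable(exams, series)


def exam_frame(exams):
    """Covariate frame in the shape the matcher expects."""
    rows = []
    for e in exams:
        rows.append(
            {
                "exam_id": e.exam_id,
                "age": e.age,
                "psa": e.psa,
                "facility": e.facility,
                "biopsy_status": e.biopsy_status,
                "exam_iq": str(e.exam_iq) if e.exam_iq else None,
                "iq_source": e.iq_source,
            }
        )
    return pd.DataFrame(rows)
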