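"""Diagnostic-yield metrics, ratios, factorization, subgroups, associations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pmcdr import (
    DiagnosticMetrics,
    IQCategory,
    compare_groups,
    compute_metrics,
    factor_association,
    zone_subgroup,
)
from pmcdr.metrics import ratio_ci_katz

from conftest import make_exam


def test_cohort_level_worked_counts():
    """3065 detected of 12,947 exams -> CDR 0.24; 5790 abnormal -> AIR 0.45."""
    m = DiagnosticMetrics(
        n_exams=12947, n_pirads3plus=5790, n_confirmed_pirads3plus=4000, n_cspca_detected=3065
    )
    assert round(m.cdr.value, 2) == 0.24
    assert round(m.air.value, 2) == 0.45


def test_all_pirads12_group_has_absent_ppv_not_zero():
    exams = [make_exam(i, pirads=1) for i in range(10)]
    m = compute_metrics(exams)
    assert m.air.value == 0.0 and m.cdr.value == 0.0
    assert m.ppv is None and m.confirmation_rate is None


def test_compute_metrics_counts_from_exam_records():
    exams = [
        make_exam(0, pirads=4, confirmed=True, cspca=True, dominant_zone="PZ"),
        make_exam(1, pirads=3, confirmed=True, cspca=False),
        make_exam(2, pirads=3, confirmed=False, cspca=False),
        make_exam(3, pirads=1, confirmed=True, cspca=True, dominant_zone="TZ"),  # missed cancer
        make_exam(4, pirads=2),
    ]
    m = compute_metrics(exams)
    assert (m.n_exams, m.n_pirads3plus, m.n_confirmed_pirads3plus, m.n_cspca_detected) == (5, 3, 2, 1)
    assert m.cdr.value == pytest.approx(0.2)
    assert m.ppv.value == pytest.approx(0.5)
    assert m.confirmation_rate.value == pytest.approx(2 / 3)


def test_cdr_never_exceeds_air_and_rates_in_unit_interval():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        exams = [
            make_exam(
                i,
                pirads=int(rng.integers(1, 6)),
                cspca=bool(cs := rng.random() < 0.3),
                confirmed=bool(cs or rng.random() < 0.5),
            )
            for i in range(n)
        ]
        m = compute_metrics(exams)
        assert m.cdr.value <= m.air.value
        for p in (m.ppv, m.confirmation_rate):
            if p is not None:
                assert 0.0 <= p.value <= 1.0


def test_identical_groups_give_unit_ratios_and_p_of_one():
    m = DiagnosticMetrics(100, 40, 30, 20)
    r = compare_groups(m, m)
    for ratio in (r.cdr_ratio, r.air_ratio, r.ppv_ratio, r.confirmation_ratio):
        assert ratio.value == pytest.approx(1.0)
    assert r.chi2_p == pytest.approx(1.0)


def test_chi_squared_matches_hand_computed_pearson_value():
    """2x2 table 30/120 vs 45/130: chi2 = 250/91 by expected-count arithmetic."""
    t = DiagnosticMetrics(120, 60, 50, 30)
    c = DiagnosticMetrics(130, 60, 50, 45)
    r = compare_groups(t, c)
    assert r.chi2_stat == pytest.approx(250 / 91)
    assert r.chi2_p == pytest.approx(1 - stats.chi2.cdf(250 / 91, 1))


counts = st.integers(0, 50)


@given(
    n1=st.integers(1, 200), n2=st.integers(1, 200),
    a1=counts, c1=counts, d1=counts,
    a2=counts, c2=counts, d2=counts,
)
@settings(max_examples=200, deadline=None)
def test_factorization_identity_exact_on_counts(n1, n2, a1, c1, d1, a2, c2, d2):
    """cdr_ratio == air_ratio * ppv_ratio * confirmation_ratio whenever all
    components are defined."""
    def mk(n, abn, conf, det):
        abn = min(abn, n)
        conf = min(conf, abn)
        det = min(det, conf)
        return DiagnosticMetrics(n, abn, conf, det)

    t, c = mk(n1, a1, c1, d1), mk(n2, a2, c2, d2)
    r = compare_groups(t, c)
    if all(x is not None for x in (r.cdr_ratio, r.air_ratio, r.ppv_ratio, r.confirmation_ratio)):
        prod = r.air_ratio.value * r.ppv_ratio.value * r.confirmation_ratio.value
        assert r.cdr_ratio.value == pytest.approx(prod, rel=1e-12)


def test_zero_control_component_gives_absent_ratio_with_warning():
    t = DiagnosticMetrics(50, 20, 15, 10)
    c = DiagnosticMetrics(50, 20, 15, 0)
    with pytest.warns(UserWarning, match="cdr_ratio"):
        r = compare_groups(t, c)
    assert r.cdr_ratio is None
    assert r.air_ratio is not None


def test_katz_ci_contains_point_estimate_and_matches_closed_form():
    rr, lo, hi = ratio_ci_katz(30, 120, 45, 130)
    assert lo < rr < hi
    se = np.sqrt(1 / 30 - 1 / 120 + 1 / 45 - 1 / 130)
    assert lo == pytest.approx(rr * np.exp(-1.959963984540054 * se))
    assert hi == pytest.approx(rr * np.exp(1.959963984540054 * se))


def test_zone_subgroup_excludes_only_proven_cspca_in_the_other_zone():
    exams = [
        make_exam(0, pirads=4, confirmed=True, cspca=True, dominant_zone="TZ"),
        make_exam(1, pirads=4, confirmed=True, cspca=True, dominant_zone="PZ"),
        make_exam(2),  # benign
    ]
    pz = zone_subgroup(exams, "PZ")
    assert [e.exam_id for e in pz] == ["E0001", "E0002"]
    tz = zone_subgroup(exams, "TZ")
    assert [e.exam_id for e in tz] == ["E0000", "E0002"]


def test_zone_subgroup_warns_on_cspca_without_zone():
    exams = [make_exam(0, pirads=4, confirmed=True, cspca=True, dominant_zone="none")]
    with pytest.warns(UserWarning, match="retained"):
        kept = zone_subgroup(exams, "PZ")
    assert len(kept) == 1


def test_zone_subgroup_rejects_unknown_zone():
    with pytest.raises(ValueError):
        zone_subgroup([], "CZ")


def _graded_exams(rng, n=300, dependent=False):
    exams = []
    for i in range(n):
        iq = IQCategory(int(rng.integers(0, 4)))
        fac = "II" if (dependent and iq >= IQCategory.MODERATE and rng.random() < 0.6) else \
            ["I", "II", "III"][int(rng.integers(3))]
        exams.append(make_exam(i, exam_iq=iq, facility=fac, age=float(rng.integers(50, 85))))
    return exams


def test_factor_association_chi2_matches_independent_expected_count_oracle():
    rng = np.random.default_rng(7)
    exams = _graded_exams(rng, dependent=True)
    res = factor_association(exams, "facility")
    assert res.test == "chi2"
    obs = res.table.to_numpy().astype(float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    stat = ((obs - exp) ** 2 / exp).sum()
    assert res.statistic == pytest.approx(stat)
    assert res.p_value < 0.05  # the planted facility-IQ dependence is detected


def test_factor_association_identical_distribution_gives_p_of_one():
    exams = [
        make_exam(12 * i + 3 * j + k, exam_iq=IQCategory(j), facility=["I", "II", "III"][k])
        for i in range(5)
        for j in range(4)
        for k in range(3)
    ]
    res = factor_association(exams, "facility")
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_factor_association_constant_continuous_factor_flagged():
    rng = np.random.default_rng(9)
    exams = [make_exam(i, exam_iq=IQCategory(int(rng.integers(0, 4))), age=60.0) for i in range(40)]
    res = factor_association(exams, "age")
    assert res.statistic is None and "undefined" in res.test
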