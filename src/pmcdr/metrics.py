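"""Diagnostic-yield metrics for prostate MRI and their group comparison.

With PI-RADS >= 3 as the abnormal threshold, each group of examinations is
summarized by four proportions:

    CDR  = #(csPCa and PI-RADS>=3) / #exams          (cancer detection rate)
    AIR  = #(PI-RADS>=3) / #exams                    (abnormal interpretation rate)
    PPV  = #(csPCa and PI-RADS>=3) / #(confirmed and PI-RADS>=3)
    confirmation rate = #(confirmed and PI-RADS>=3) / #(PI-RADS>=3)

so that CDR = AIR x PPV x confirmation rate holds exactly on the counts,
and the same factorization carries over to target/control ratios.  This
decomposition attributes a CDR change to reading behaviour (AIR), biopsy
yield (PPV), or biopsy uptake (confirmation rate).

Proportions carry Wilson 95% CIs; ratios carry Katz log-method 95% CIs;
the CDR difference is tested with Pearson's chi-squared (no continuity
correction) on the detected/not 2x2 table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import ExamRecord
from .grading import binarize_iq

__all__ = [
    "Proportion",
    "DiagnosticMetrics",
    "MetricRatios",
    "compute_metrics",
    "compare_groups",
    "zone_subgroup",
    "factor_association",
    "ratio_ci_katz",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class Proportion:
    """A proportion with its Wilson 95% confidence interval."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = proportion_confint(self.numerator, self.denominator, alpha=0.05, method="wilson")
        return float(lo), float(hi)

    def __format__(self, spec: str) -> str:
        lo, hi = self.ci
        return f"{self.value:{spec or '.2f'}} ({lo:{spec or '.2f'}}–{hi:{spec or '.2f'}})"


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The four counts and derived proportions for one exam group.

    Components with a zero denominator are absent (``None``), never 0.
    """

    n_exams: int
    n_pirads3plus: int
    n_confirmed_pirads3plus: int
    n_cspca_detected: int

    @classmethod
    def from_exams(cls, exams: Iterable[ExamRecord] | pd.DataFrame) -> "DiagnosticMetrics":
        if isinstance(exams, pd.DataFrame):
            df = exams
            abn = df["pirads"].astype(int) >= 3
            conf = df["confirmed"].astype(bool)
            cs = df["cspca"].astype(bool)
            return cls(
                n_exams=len(df),
                n_pirads3plus=int(abn.sum()),
                n_confirmed_pirads3plus=int((abn & conf).sum()),
                n_cspca_detected=int((abn & cs).sum()),
            )
        ex = list(exams)
        return cls(
            n_exams=len(ex),
            n_pirads3plus=sum(e.pirads >= 3 for e in ex),
            n_confirmed_pirads3plus=sum(e.pirads >= 3 and e.confirmed for e in ex),
            n_cspca_detected=sum(e.pirads >= 3 and e.cspca for e in ex),
        )

    def _prop(self, num: int, den: int) -> Proportion | None:
        return None if den == 0 else Proportion(num, den)

    @property
    def cdr(self) -> Proportion | None:
        return self._prop(self.n_cspca_detected, self.n_exams)

    @property
    def air(self) -> Proportion | None:
        return self._prop(self.n_pirads3plus, self.n_exams)

    @property
    def ppv(self) -> Proportion | None:
        return self._prop(self.n_cspca_detected, self.n_confirmed_pirads3plus)

    @property
    def confirmation_rate(self) -> Proportion | None:
        return self._prop(self.n_confirmed_pirads3plus, self.n_pirads3plus)


def compute_metrics(exams: Iterable[ExamRecord] | pd.DataFrame) -> DiagnosticMetrics:
    """Count-based metrics for a group of examinations."""
    m = DiagnosticMetrics.from_exams(exams)
    if m.n_exams == 0:
        raise ValueError("compute_metrics requires a non-empty exam group")
    return m


def ratio_ci_katz(a: int, n1: int, b: int, n2: int) -> tuple[float, float, float]:
    """Risk ratio (a/n1)/(b/n2) with Katz log-method 95% CI."""
    if b == 0 or n1 == 0 or n2 == 0:
        raise ValueError("ratio undefined: zero denominator")
    rr = (a / n1) / (b / n2)
    if a == 0:
        return rr, 0.0, np.inf
    se = np.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    return rr, float(rr * np.exp(-Z95 * se)), float(rr * np.exp(Z95 * se))


@dataclass(frozen=True)
class Ratio:
    value: float
    ci: tuple[float, float]


@dataclass(frozen=True)
class MetricRatios:
    """Target/control ratios of the four metrics, with the chi-squared
    comparison of the detected/not 2x2 table."""

    cdr_ratio: Ratio | None
    air_ratio: Ratio | None
    ppv_ratio: Ratio | None
    confirmation_ratio: Ratio | None
    chi2_stat: float | None
    chi2_p: float | None


def _safe_ratio(a: int, n1: int, b: int, n2: int, name: str) -> Ratio | None:
    try:
        rr, lo, hi = ratio_ci_katz(a, n1, b, n2)
    except ValueError:
        warnings.warn(f"{name}: control component is zero; ratio undefined")
        return None
    return Ratio(rr, (lo, hi))


def compare_groups(target: DiagnosticMetrics, control: DiagnosticMetrics) -> MetricRatios:
    """Target-over-control metric ratios with Katz 95% CIs.

    The factorization cdr_ratio = air_ratio x ppv_ratio x
    confirmation_ratio holds exactly on unrounded counts whenever all
    components are defined.
    """
    cdr = _safe_ratio(
        target.n_cspca_detected, target.n_exams, control.n_cspca_detected, control.n_exams, "cdr_ratio"
    )
    air = _safe_ratio(
        target.n_pirads3plus, target.n_exams, control.n_pirads3plus, control.n_exams, "air_ratio"
    )
    ppv = _safe_ratio(
        target.n_cspca_detected,
        target.n_confirmed_pirads3plus,
        control.n_cspca_detected,
        control.n_confirmed_pirads3plus,
        "ppv_ratio",
    ) if target.n_confirmed_pirads3plus and control.n_confirmed_pirads3plus else None
    conf = _safe_ratio(
        target.n_confirmed_pirads3plus,
        target.n_pirads3plus,
        control.n_confirmed_pirads3plus,
        control.n_pirads3plus,
        "confirmation_ratio",
    ) if target.n_pirads3plus and control.n_pirads3plus else None

    table = np.array(
        [
            [target.n_cspca_detected, target.n_exams - target.n_cspca_detected],
            [control.n_cspca_detected, control.n_exams - control.n_cspca_detected],
        ]
    )
    if table.sum(axis=0).min() == 0:
        stat, p = (0.0, 1.0) if np.all(table[0] * control.n_exams == table[1] * target.n_exams) else (None, None)
    else:
        res = stats.chi2_contingency(table, correction=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return MetricRatios(cdr, air, ppv, conf, stat, p)


def zone_subgroup(exams: Sequence[ExamRecord], zone: str) -> list[ExamRecord]:
    """Subgroup focused on one tumour zone.

    For ``zone='PZ'`` excludes exams with pathologically proven csPCa whose
    dominant lesion is in the transition zone (and symmetrically for
    ``'TZ'``); benign and unconfirmed exams are always retained.  A csPCa
    exam without a dominant zone is retained with a warning.
    """
    if zone not in ("PZ", "TZ"):
        raise ValueError(f"zone must be 'PZ' or 'TZ', got {zone!r}")
    other = "TZ" if zone == "PZ" else "PZ"
    kept = []
    for e in exams:
        if e.cspca and e.dominant_zone == other:
            continue
        if e.cspca and e.dominant_zone == "none":
            warnings.warn(f"exam {e.exam_id}: csPCa with no dominant zone; retained")
        kept.append(e)
    return kept


@dataclass(frozen=True)
class AssociationResult:
    factor: str
    test: str
    statistic: float | None
    p_value: float | None
    table: pd.DataFrame | None


def factor_association(exams: Sequence[ExamRecord], factor: str) -> AssociationResult:
    """Association between a patient factor and binarized IQ.

    IQ is binarized to poor (severe-moderate) vs acceptable (mild-optimal).
    Categorical factors are tested with the chi-squared test on the
    cross-tabulation; ``age`` with Welch's t-test; ``psa`` with the
    Wilcoxon rank-sum test (skewed).
    """
    graded = [e for e in exams if e.exam_iq is not None]
    if not graded:
        raise ValueError("no graded exams")
    labels = [binarize_iq(e.exam_iq) for e in graded]
    groups = {"poor", "acceptable"}
    present = set(labels)
    if factor in ("age", "psa"):
        vals = {
            g: [getattr(e, factor) for e, l in zip(graded, labels) if l == g and getattr(e, factor) is not None]
            for g in groups
        }
        if present != groups or any(len(v) < 2 for v in vals.values()):
            return AssociationResult(factor, "undefined", None, None, None)
        if len(set(vals["poor"]) | set(vals["acceptable"])) == 1:
            return AssociationResult(factor, "undefined (constant factor)", None, None, None)
        if factor == "age":
            r = stats.ttest_ind(vals["poor"], vals["acceptable"], equal_var=False)
            return AssociationResult(factor, "welch_t", float(r.statistic), float(r.pvalue), None)
        r = stats.mannwhitneyu(vals["poor"], vals["acceptable"])
        return AssociationResult(factor, "rank_sum", float(r.statistic), float(r.pvalue), None)

    df = pd.DataFrame({"iq": labels, "factor": [getattr(e, factor) for e in graded]})
    tab = pd.crosstab(df["iq"], df["factor"])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError(f"degenerate contingency table for {factor}: shape {tab.shape}")
    res = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return AssociationResult(factor, "chi2", float(res.statistic), float(res.pvalue), tab)
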