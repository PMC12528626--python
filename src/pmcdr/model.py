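"""Model/Results interface for the matched CDR comparison.

:class:`ArtifactImpactModel` is built from a cohort (or plain DataFrames)
and, on :meth:`~ArtifactImpactModel.fit`, runs the full analysis for each
artifact-severity group: exam-level grading (if needed), repeated coarsened
exact matching against the optimal-IQ pool, covariate-balance diagnostics,
and the CDR / AIR / PPV / confirmation-rate comparison with its ratio
factorization.  The returned :class:`ArtifactImpactResults` carries the
per-severity estimates, confidence intervals and diagnostics, and renders a
text summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .balance import balance_table
from .cohort import CohortTable, ExamRecord, IQCategory, read_exams, read_series
from .grading import grade_cohort
from .matching import MatchedCohort, match_all_categories
from .metrics import (
    DiagnosticMetrics,
    MetricRatios,
    compare_groups,
    compute_metrics,
    zone_subgroup,
)

__all__ = ["ArtifactImpactModel", "ArtifactImpactResults", "SeverityComparison"]

SEVERITIES = (IQCategory.MILD, IQCategory.MODERATE, IQCategory.SEVERE)


@dataclass(frozen=True)
class SeverityComparison:
    """One severity stratum: target vs matched-control metrics."""

    category: IQCategory
    matched: MatchedCohort
    target_metrics: DiagnosticMetrics | None
    control_metrics: DiagnosticMetrics | None
    ratios: MetricRatios | None
    balance_adjusted: pd.DataFrame | None
    balance_unadjusted: pd.DataFrame | None

    @property
    def empty(self) -> bool:
        return self.target_metrics is None


class ArtifactImpactModel:
    """Matched case-control comparison of diagnostic yield by DWI artifact
    severity.

    Parameters
    ----------
    cohort
        A validated cohort.  Exams lacking ``exam_iq`` are graded from
        their linked series (best-series rule) at fit time.
    max_rounds, retries_per_round
        Matching configuration (see :mod:`pmcdr.matching`).
    zone
        Optional tumour-zone restriction ('PZ' or 'TZ'): the comparison is
        run on the subgroup that excludes proven csPCa dominant in the
        other zone.
    """

    def __init__(
        self,
        cohort: CohortTable,
        *,
        max_rounds: int = 20,
        retries_per_round: int = 10,
        zone: str | None = None,
        adjudication: str = "worse",
    ):
        self.cohort = cohort
        self.max_rounds = max_rounds
        self.retries_per_round = retries_per_round
        self.zone = zone
        self.adjudication = adjudication

    @classmethod
    def from_dataframes(
        cls, exams: pd.DataFrame, series: pd.DataFrame | None = None, **kwargs
    ) -> "ArtifactImpactModel":
        """Build from raw exam/series DataFrames with the documented schema."""
        import io

        buf = io.StringIO()
        exams.to_csv(buf, index=False)
        buf.seek(0)
        ex = read_exams(buf)
        sr: list = []
        if series is not None:
            buf2 = io.StringIO()
            series.to_csv(buf2, index=False)
            buf2.seek(0)
            sr = read_series(buf2)
        return cls(CohortTable(ex, sr), **kwargs)

    @classmethod
    def from_files(cls, exams_path, series_path=None, **kwargs) -> "ArtifactImpactModel":
        ex = read_exams(exams_path)
        sr = read_series(series_path) if series_path else []
        return cls(CohortTable(ex, sr), **kwargs)

    def fit(self, seed: int = 0) -> "ArtifactImpactResults":
        cohort = grade_cohort(self.cohort, self.adjudication)
        matched = match_all_categories(
            cohort,
            seed=seed,
            max_rounds=self.max_rounds,
            retries_per_round=self.retries_per_round,
        )
        by_id: Mapping[str, ExamRecord] = {e.exam_id: e for e in cohort.exams}
        df = cohort.exams_frame().set_index("exam_id", drop=False)
        pool_ids = [e.exam_id for e in cohort.exams if e.exam_iq == IQCategory.OPTIMAL]

        comparisons: dict[IQCategory, SeverityComparison] = {}
        for cat in SEVERITIES:
            mc = matched[cat]
            if len(mc.target_ids) == 0 or mc.rounds_completed == 0:
                comparisons[cat] = SeverityComparison(cat, mc, None, None, None, None, None)
                continue
            t_exams = self._restrict([by_id[i] for i in mc.target_ids])
            c_exams = self._restrict([by_id[i] for i in mc.control_ids])
            tm = compute_metrics(t_exams) if t_exams else None
            cm = compute_metrics(c_exams) if c_exams else None
            ratios = compare_groups(tm, cm) if tm and cm else None
            t_df = df.loc[mc.target_ids]
            comparisons[cat] = SeverityComparison(
                cat,
                mc,
                tm,
                cm,
                ratios,
                balance_adjusted=balance_table(t_df, df.loc[mc.control_ids]),
                balance_unadjusted=balance_table(t_df, df.loc[pool_ids]),
            )

        overall = compute_metrics(self._restrict(cohort.exams)) if len(cohort.exams) else None
        return ArtifactImpactResults(
            model=self,
            cohort=cohort,
            comparisons=comparisons,
            overall_metrics=overall,
            seed=seed,
        )

    def _restrict(self, exams: Sequence[ExamRecord]) -> list[ExamRecord]:
        if self.zone is None:
            return list(exams)
        return zone_subgroup(exams, self.zone)


@dataclass
class ArtifactImpactResults:
    """Fitted results: per-severity matched comparisons plus cohort-level
    metrics."""

    model: ArtifactImpactModel
    cohort: CohortTable
    comparisons: dict[IQCategory, SeverityComparison]
    overall_metrics: DiagnosticMetrics | None
    seed: int

    def summary(self) -> str:
        """Text summary in the style of a regression results table."""
        lines = []
        zone = self.model.zone
        title = "Matched CDR comparison by DWI artifact severity"
        if zone:
            title += f" ({zone} tumour subgroup)"
        lines.append(title)
        lines.append("=" * len(title))
        if self.overall_metrics:
            om = self.overall_metrics
            lines.append(
                f"Cohort: {om.n_exams} exams | CDR {om.cdr.value:.2f} | AIR {om.air.value:.2f}"
            )
        hdr = (
            f"{'severity':<10}{'n_t':>6}{'n_c':>7}{'ratio':>6}  "
            f"{'CDR_t':>6}{'CDR_c':>7}  {'CDR ratio (95% CI)':>22}{'p':>8}"
        )
        lines.append("-" * len(hdr))
        lines.append(hdr)
        lines.append("-" * len(hdr))
        for cat in SEVERITIES:
            comp = self.comparisons.get(cat)
            name = str(cat)
            if comp is None or comp.empty:
                lines.append(f"{name:<10}{'—':>6}  (no matched stratum)")
                continue
            tm, cm, r = comp.target_metrics, comp.control_metrics, comp.ratios
            cr = r.cdr_ratio if r else None
            cr_txt = (
                f"{cr.value:.2f} ({cr.ci[0]:.2f}–{cr.ci[1]:.2f})" if cr else "—"
            )
            p_txt = f"{r.chi2_p:.2f}" if r and r.chi2_p is not None else "—"
            lines.append(
                f"{name:<10}{tm.n_exams:>6}{cm.n_exams:>7}{comp.matched.ratio:>6}  "
                f"{tm.cdr.value if tm.cdr else float('nan'):>6.2f}"
                f"{cm.cdr.value if cm.cdr else float('nan'):>7.2f}  "
                f"{cr_txt:>22}{p_txt:>8}"
            )
        lines.append("-" * len(hdr))
        bal = self.max_abs_smd()
        if bal is not None:
            lines.append(f"Max |SMD| after matching: {bal:.3f} (balance threshold 0.10)")
        return "\n".join(lines)

    def max_abs_smd(self) -> float | None:
        vals = []
        for comp in self.comparisons.values():
            if comp.balance_adjusted is not None:
                vals.extend(
                    abs(v) for v in comp.balance_adjusted["smd_raw"] if v is not None and np.isfinite(v)
                )
        return max(vals) if vals else None

    def to_dict(self) -> dict:
        """JSON-serializable report mirroring the per-severity panels."""
        out: dict = {"seed": self.seed, "zone": self.model.zone}
        if self.overall_metrics:
            om = self.overall_metrics
            out["overall"] = _metrics_dict(om)
        out["strata"] = {}
        for cat, comp in self.comparisons.items():
            entry: dict = {"n_targets": len(comp.matched.target_ids)}
            if comp.empty:
                entry["note"] = "empty stratum"
            else:
                entry.update(
                    {
                        "rounds": comp.matched.rounds_completed,
                        "n_controls": len(comp.matched.control_ids),
                        "target": _metrics_dict(comp.target_metrics),
                        "control": _metrics_dict(comp.control_metrics),
                        "ratios": _ratios_dict(comp.ratios),
                        "max_abs_smd_adjusted": max(
                            (abs(v) for v in comp.balance_adjusted["smd_raw"] if v is not None),
                            default=None,
                        ),
                    }
                )
            out["strata"][str(cat)] = entry
        return out


def _metrics_dict(m: DiagnosticMetrics) -> dict:
    d = {
        "n_exams": m.n_exams,
        "n_pirads3plus": m.n_pirads3plus,
        "n_confirmed_pirads3plus": m.n_confirmed_pirads3plus,
        "n_cspca_detected": m.n_cspca_detected,
    }
    for name in ("cdr", "air", "ppv", "confirmation_rate"):
        p = getattr(m, name)
        d[name] = None if p is None else {"value": p.value, "ci": list(p.ci)}
    return d


def _ratios_dict(r: MetricRatios | None) -> dict | None:
    if r is None:
        return None
    d = {}
    for name in ("cdr_ratio", "air_ratio", "ppv_ratio", "confirmation_ratio"):
        x = getattr(r, name)
        d[name] = None if x is None else {"value": x.value, "ci": list(x.ci)}
    d["chi2_stat"] = r.chi2_stat
    d["chi2_p"] = r.chi2_p
    return d
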