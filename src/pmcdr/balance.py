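"""Covariate balance diagnostics: standardized mean differences (SMD).

|SMD| < 0.10 is taken as good balance.  Continuous variables use the usual
pooled-SD standardization; multi-category variables use the Mahalanobis-type
multivariate standardized difference (one non-negative number per factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BalanceRow",
    "smd_continuous",
    "smd_continuous_from_samples",
    "smd_categorical",
    "balance_table",
    "BALANCE_THRESHOLD",
]

BALANCE_THRESHOLD = 0.10


@dataclass(frozen=True)
class BalanceRow:
    variable: str
    summary_target: str
    summary_control: str
    smd: float | None
    p_value: float | None = None

    @property
    def balanced(self) -> bool | None:
        return None if self.smd is None else abs(self.smd) < BALANCE_THRESHOLD


def smd_continuous(mean_t: float, sd_t: float, mean_c: float, sd_c: float) -> float:
    """(mean_t - mean_c) / sqrt((sd_t^2 + sd_c^2) / 2)."""
    if sd_t < 0 or sd_c < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = np.sqrt((sd_t**2 + sd_c**2) / 2.0)
    if denom == 0:
        if mean_t == mean_c:
            return 0.0
        raise ValueError("SMD undefined: both SDs zero with unequal means")
    return (mean_t - mean_c) / denom


def smd_continuous_from_samples(x_t: Sequence[float], x_c: Sequence[float]) -> float:
    a = np.asarray(x_t, dtype=float)
    b = np.asarray(x_c, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    return smd_continuous(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1))


def smd_categorical(props_t: Sequence[float], props_c: Sequence[float]) -> float:
    """Multivariate standardized difference for a k-category variable.

    sqrt(d' S^-1 d) over the first k-1 categories, with d the proportion
    differences and S the average of the two multinomial covariance
    matrices.  For k = 2 this reduces to |binary-proportion SMD|.  A
    singular S falls back to the maximum pairwise binary SMD, with a
    warning.
    """
    p = np.asarray(props_t, dtype=float)
    q = np.asarray(props_c, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("proportion vectors must be 1-d and of equal length")
    for v, name in ((p, "props_t"), (q, "props_c")):
        if np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{name} must be a probability vector summing to 1")
    if np.allclose(p, q):
        return 0.0
    d = (p - q)[:-1]
    S = (_multinomial_cov(p) + _multinomial_cov(q)) / 2.0
    try:
        sol = np.linalg.solve(S, d)
        val = float(np.sqrt(d @ sol))
        if not np.isfinite(val):
            raise np.linalg.LinAlgError
        return val
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; falling back to max pairwise binary SMD")
        vals = []
        for i in range(len(p)):
            s2 = (p[i] * (1 - p[i]) + q[i] * (1 - q[i])) / 2.0
            if s2 > 0:
                vals.append(abs(p[i] - q[i]) / np.sqrt(s2))
        return float(max(vals)) if vals else 0.0


def _multinomial_cov(p: np.ndarray) -> np.ndarray:
    r = p[:-1]
    return np.diag(r) - np.outer(r, r)


def _cat_props(series: pd.Series, levels: Sequence[str]) -> np.ndarray:
    counts = series.value_counts()
    total = len(series)
    return np.asarray([counts.get(lv, 0) / total for lv in levels])


def balance_table(
    targets: pd.DataFrame, controls: pd.DataFrame, with_p_values: bool = False
) -> pd.DataFrame:
    """Balance rows for age, PSA (non-missing), PSA missingness, facility
    and biopsy status between a target group and a comparison group.

    The comparison group may be the full control pool (unadjusted) or the
    matched controls (adjusted).  PSA's SMD is computed on non-missing
    values; the missingness proportion gets its own binary SMD row.
    Optional p-values reproduce descriptive companions: t-test for age,
    rank-sum for PSA, chi-squared for categorical factors.
    """
    if len(targets) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    rows: list[BalanceRow] = []

    at, ac = targets["age"].astype(float), controls["age"].astype(float)
    rows.append(
        BalanceRow(
            "age",
            f"{at.mean():.1f} ± {at.std(ddof=1):.1f}",
            f"{ac.mean():.1f} ± {ac.std(ddof=1):.1f}",
            smd_continuous_from_samples(at, ac),
            stats.ttest_ind(at, ac, equal_var=False).pvalue if with_p_values else None,
        )
    )

    pt = pd.to_numeric(targets["psa"], errors="coerce")
    pc = pd.to_numeric(controls["psa"], errors="coerce")
    pt_obs, pc_obs = pt.dropna(), pc.dropna()
    if len(pt_obs) > 1 and len(pc_obs) > 1:
        smd_psa = smd_continuous_from_samples(pt_obs, pc_obs)
        p_psa = (
            stats.mannwhitneyu(pt_obs, pc_obs).pvalue if with_p_values else None
        )
    else:
        smd_psa, p_psa = None, None
    rows.append(
        BalanceRow(
            "psa",
            _median_iqr(pt_obs),
            _median_iqr(pc_obs),
            smd_psa,
            p_psa,
        )
    )
    miss_t, miss_c = pt.isna().mean(), pc.isna().mean()
    rows.append(
        BalanceRow(
            "psa_missing",
            f"{miss_t:.1%}",
            f"{miss_c:.1%}",
            smd_categorical([miss_t, 1 - miss_t], [miss_c, 1 - miss_c])
            if (0 < miss_t < 1 or 0 < miss_c < 1)
            else 0.0,
        )
    )

    for var, levels in (("facility", ("I", "II", "III")), ("biopsy_status", ("naive", "prev_benign", "unknown"))):
        p = _cat_props(targets[var], levels)
        q = _cat_props(controls[var], levels)
        pv = None
        if with_p_values:
            tab = np.vstack(
                [
                    (p * len(targets)).round().astype(int),
                    (q * len(controls)).round().astype(int),
                ]
            )
            keep = tab.sum(axis=0) > 0
            if keep.sum() >= 2:
                pv = stats.chi2_contingency(tab[:, keep], correction=False).pvalue
        rows.append(
            BalanceRow(
                var,
                " / ".join(f"{lv} {x:.1%}" for lv, x in zip(levels, p)),
                " / ".join(f"{lv} {x:.1%}" for lv, x in zip(levels, q)),
                smd_categorical(p, q),
                pv,
            )
        )

    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "target": [r.summary_target for r in rows],
            "control": [r.summary_control for r in rows],
            "smd": [None if r.smd is None else round(r.smd, 2) for r in rows],
            "smd_raw": [r.smd for r in rows],
            "balanced": [r.balanced for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )


def _median_iqr(x: pd.Series) -> str:
    if len(x) == 0:
        return ""
    return f"{x.median():.1f} [{x.quantile(0.25):.1f}–{x.quantile(0.75):.1f}]"
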