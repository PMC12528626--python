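"""Synthetic prostate-MRI cohort generator.

Emulates the statistical structure of a three-facility prostate-MRI
population screened for clinically significant prostate cancer (csPCa):
ages roughly normal, PSA log-normal with a configurable missing fraction,
a four-category DWI image-quality (IQ) mix dominated by optimal/mild
series, csPCa prevalence around 25%, and PI-RADS assignment whose
sensitivity may depend on IQ.  Defaults reproduce the marginal statistics
of such a cohort (csPCa 25%, overall abnormal interpretation rate ~0.45,
cancer detection rate ~0.24, PSA missing ~17.7%).

The generative model, in order:

1. Confounders: facility ~ categorical, age ~ Normal, log PSA ~ Normal
   (PSA then masked missing at random).
2. Disease: csPCa ~ Bernoulli(logistic(alpha + b_age z_age +
   b_psa z_logpsa + facility offset)), with the intercept calibrated so
   the marginal prevalence equals ``cspca_base_prev``.
3. IQ: an exam-level category from ``iq_probs``; the exam's series are
   planted so the best series category equals it (the best series defines
   the exam grade downstream).
4. Reading: a csPCa exam receives PI-RADS >= 3 with probability
   ``detection_sensitivity_by_iq[iq]`` (score drawn from {3,4,5}); a benign
   exam with probability ``false_positive_rate_by_iq[iq]`` (score from
   {3,4}); all other exams get PI-RADS 1-2.
5. Pathology: csPCa exams are confirmed; benign PI-RADS >= 3 exams are
   biopsied with ``confirmation_prob_given_pirads3plus``; benign PI-RADS
   1-2 with ``systematic_biopsy_prob_given_pirads12``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .cohort import CohortTable, ExamRecord, IQCategory, SeriesRecord

__all__ = ["SimConfig", "ConfounderStrengths", "generate_cohort", "generate_ratings"]


def _check_probs(v: Sequence[float], name: str) -> tuple[float, ...]:
    arr = tuple(float(x) for x in v)
    if any(not (0.0 <= x <= 1.0) for x in arr):
        raise ValueError(f"{name} entries must lie in [0, 1], got {arr}")
    return arr


def _check_simplex(v: Sequence[float], name: str) -> tuple[float, ...]:
    arr = _check_probs(v, name)
    if not math.isclose(sum(arr), 1.0, abs_tol=1e-8):
        raise ValueError(f"{name} must sum to 1, got sum {sum(arr)}")
    return arr


class ConfounderStrengths(BaseModel):
    """Log-odds coefficients tying confounders to csPCa risk."""

    model_config = ConfigDict(frozen=True)

    age_per_sd: float = 0.25
    logpsa_per_sd: float = 0.6
    facility_offsets: tuple[float, float, float] = (0.0, 0.1, -0.1)


class SimConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Defaults describe a ~13,000-exam three-facility cohort: csPCa
    prevalence 0.25, PSA missing in 17.7%, series-level IQ mix
    52.7/36.6/9.8/0.8% (optimal/mild/moderate/severe), IQ-independent
    sensitivity 0.95 and false-positive rate 0.28 so that AIR ~ 0.45 and
    CDR ~ 0.24 overall.
    """

    model_config = ConfigDict(frozen=True, validate_default=True)

    n_exams: int = Field(default=12947, ge=0)
    seed: int = 0
    facility_probs: tuple[float, float, float] = (0.531, 0.215, 0.254)
    age_mean: float = 65.5
    age_sd: float = 8.4
    psa_log_mean: float = math.log(6.3)
    psa_log_sd: float = 0.5
    psa_missing_frac: float = 0.177
    iq_probs: tuple[float, float, float, float] = (0.528, 0.366, 0.098, 0.008)
    series_per_exam_probs: tuple[float, float, float] = (0.946, 0.049, 0.005)
    cspca_base_prev: float = 0.25
    confounder_strengths: ConfounderStrengths = ConfounderStrengths()
    detection_sensitivity_by_iq: tuple[float, float, float, float] = (0.95, 0.95, 0.95, 0.95)
    false_positive_rate_by_iq: tuple[float, float, float, float] = (0.28, 0.28, 0.28, 0.28)
    confirmation_prob_given_pirads3plus: float = 0.85
    systematic_biopsy_prob_given_pirads12: float = 0.20
    zone_pz_frac: float = 0.8
    # Probability that an exam's grade carries a radiologist source tag, per
    # IQ category.  Mirrors the review design: every model-severe series is
    # radiologist-reviewed, while mild/optimal grades mostly come from the
    # model, with a small radiologist-scored subset.
    radiologist_review_probs_by_iq: tuple[float, float, float, float] = (0.10, 0.08, 0.15, 1.0)

    @field_validator("facility_probs")
    @classmethod
    def _fac(cls, v):
        return _check_simplex(v, "facility_probs")

    @field_validator("iq_probs")
    @classmethod
    def _iq(cls, v):
        return _check_simplex(v, "iq_probs")

    @field_validator("series_per_exam_probs")
    @classmethod
    def _ser(cls, v):
        return _check_simplex(v, "series_per_exam_probs")

    @field_validator(
        "detection_sensitivity_by_iq",
        "false_positive_rate_by_iq",
        "radiologist_review_probs_by_iq",
    )
    @classmethod
    def _rates(cls, v, info):
        return _check_probs(v, info.field_name)

    @model_validator(mode="after")
    def _scalars(self):
        for name in (
            "psa_missing_frac",
            "cspca_base_prev",
            "confirmation_prob_given_pirads3plus",
            "systematic_biopsy_prob_given_pirads12",
            "zone_pz_frac",
        ):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {x}")
        if self.age_sd <= 0 or self.psa_log_sd <= 0:
            raise ValueError("age_sd and psa_log_sd must be positive")
        return self


def _calibrate_intercept(eta0: np.ndarray, target: float) -> float:
    """Solve mean(sigmoid(alpha + eta0)) = target for alpha."""
    from scipy.optimize import brentq

    def gap(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + eta0))))) - target

    lo = math.log(target / (1 - target)) - abs(eta0).max() - 1.0
    hi = math.log(target / (1 - target)) + abs(eta0).max() + 1.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


# Obscured-percentage distribution within the severe (>=30%) category:
# most severe series sit just past the threshold (~78% at 30-40%).
_SEVERE_PCTS = np.array([30, 40, 50, 60, 70, 80, 90, 100])
_SEVERE_WEIGHTS = np.array([0.45, 0.33, 0.10, 0.05, 0.03, 0.02, 0.01, 0.01])
_PCT_BY_CAT = {IQCategory.OPTIMAL: 0, IQCategory.MILD: 10, IQCategory.MODERATE: 20}


def generate_cohort(config: SimConfig, seed: int | None = None) -> CohortTable:
    """Draw one synthetic cohort; deterministic under a fixed seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_exams
    cs = config.confounder_strengths

    facility_idx = rng.choice(3, size=n, p=np.asarray(config.facility_probs))
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age = np.clip(age, 18.0, None)
    log_psa = rng.normal(config.psa_log_mean, config.psa_log_sd, size=n)
    psa = np.exp(log_psa)
    psa_missing = rng.random(n) < config.psa_missing_frac

    z_age = (age - config.age_mean) / config.age_sd
    z_psa = (log_psa - config.psa_log_mean) / config.psa_log_sd
    base = config.cspca_base_prev
    if n == 0 or not 0.0 < base < 1.0:
        disease = np.full(n, bool(base == 1.0))
    else:
        eta0 = (
            cs.age_per_sd * z_age
            + cs.logpsa_per_sd * z_psa
            + np.asarray(cs.facility_offsets)[facility_idx]
        )
        # intercept calibrated so the marginal prevalence equals the target
        # even under non-neutral confounder strengths
        alpha = _calibrate_intercept(eta0, base)
        disease = rng.random(n) < 1.0 / (1.0 + np.exp(-(alpha + eta0)))

    iq = rng.choice(4, size=n, p=np.asarray(config.iq_probs))

    sens = np.asarray(config.detection_sensitivity_by_iq)[iq]
    fpr = np.asarray(config.false_positive_rate_by_iq)[iq]
    u = rng.random(n)
    flagged = np.where(disease, u < sens, u < fpr)

    pirads = np.empty(n, dtype=int)
    lo = rng.choice([1, 2], size=n)
    hi_pos = rng.choice([3, 4, 5], size=n)
    hi_fp = rng.choice([3, 4], size=n)
    pirads[:] = lo
    pirads[flagged & disease] = hi_pos[flagged & disease]
    pirads[flagged & ~disease] = hi_fp[flagged & ~disease]

    v = rng.random(n)
    confirmed = np.where(
        disease,
        True,
        np.where(
            flagged,
            v < config.confirmation_prob_given_pirads3plus,
            v < config.systematic_biopsy_prob_given_pirads12,
        ),
    )

    pz = rng.random(n) < config.zone_pz_frac
    zone = np.where(disease, np.where(pz, "PZ", "TZ"), "none")

    rad_reviewed = rng.random(n) < np.asarray(config.radiologist_review_probs_by_iq)[iq]

    n_series = rng.choice([1, 2, 3], size=n, p=np.asarray(config.series_per_exam_probs))
    biopsy_idx = rng.choice(3, size=n, p=np.asarray(_BIOPSY_PROBS))

    exams: list[ExamRecord] = []
    series: list[SeriesRecord] = []
    width = max(5, len(str(max(n, 1))))
    for i in range(n):
        eid = f"E{i:0{width}d}"
        cat = IQCategory(int(iq[i]))
        exams.append(
            ExamRecord(
                exam_id=eid,
                patient_id=f"P{i:0{width}d}",
                age=round(float(age[i]), 1),
                psa=None if psa_missing[i] else round(float(psa[i]), 2),
                facility=("I", "II", "III")[facility_idx[i]],
                biopsy_status=("naive", "prev_benign", "unknown")[int(biopsy_idx[i])],
                pirads=int(pirads[i]),
                confirmed=bool(confirmed[i]),
                cspca=bool(disease[i]),
                dominant_zone=str(zone[i]),
                exam_iq=cat,
                iq_source="radiologist" if rad_reviewed[i] else "model",
            )
        )
        series.extend(_plant_series(rng, eid, cat, int(n_series[i]), bool(rad_reviewed[i])))

    return CohortTable(exams, series, provenance=f"synthetic n={n} seed={config.seed if seed is None else seed}")


_BIOPSY_PROBS = (0.31, 0.30, 0.39)  # naive / prev_benign / unknown


def _draw_pct(rng: np.random.Generator, cat: IQCategory) -> int:
    if cat is IQCategory.SEVERE:
        return int(rng.choice(_SEVERE_PCTS, p=_SEVERE_WEIGHTS))
    return _PCT_BY_CAT[cat]


def _plant_series(
    rng: np.random.Generator, exam_id: str, exam_cat: IQCategory, k: int, rad: bool
) -> list[SeriesRecord]:
    """Plant k series whose minimum category equals the exam category.

    The first series carries the exam's category; extra series are drawn
    at or above it (worse or equal), so the best-series rule recovers the
    planted grade.  Radiologist-reviewed exams get a scored obscured
    percentage; others only a model category.
    """
    cats = [exam_cat]
    for _ in range(k - 1):
        cats.append(IQCategory(int(rng.integers(int(exam_cat), 4))))
    out = []
    for j, cat in enumerate(cats):
        if rad:
            out.append(
                SeriesRecord(
                    exam_id=exam_id,
                    series_id=f"{exam_id}_s{j}",
                    obscured_pct=_draw_pct(rng, cat),
                )
            )
        else:
            out.append(
                SeriesRecord(
                    exam_id=exam_id,
                    series_id=f"{exam_id}_s{j}",
                    model_category=cat,
                )
            )
    return out


def generate_ratings(
    n_items: int,
    n_raters: int,
    true_categories: Sequence[IQCategory],
    confusion: np.ndarray,
    seed: int,
) -> list[dict[str, IQCategory]]:
    """Draw per-item rater categories from a row-stochastic confusion matrix.

    Each rater's category is drawn independently given the item's true
    category; row i of ``confusion`` is the distribution of assigned
    categories for true category i.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (4, 4):
        raise ValueError(f"confusion must be 4x4, got {confusion.shape}")
    if np.any(confusion < 0) or not np.allclose(confusion.sum(axis=1), 1.0):
        raise ValueError("confusion rows must be non-negative and sum to 1")
    if len(true_categories) != n_items:
        raise ValueError("true_categories length must equal n_items")
    rng = np.random.default_rng(seed)
    out = []
    for item in range(n_items):
        row = confusion[int(true_categories[item])]
        draws = rng.choice(4, size=n_raters, p=row)
        out.append({f"r{r + 1}": IQCategory(int(draws[r])) for r in range(n_raters)})
    return out
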