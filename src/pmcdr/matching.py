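"""Repeated coarsened exact matching of optimal-IQ controls to targets.

Each artifact-severity group (mild / moderate / severe, radiologist-graded)
is matched against the optimal-IQ control pool on four confounders: age and
PSA, coarsened into quantile bins, and facility and pre-MRI biopsy status,
which are never coarsened.  Age and PSA each get two coarsenings — narrow
(6 equal-sized bins) and wide (3 bins) — with a dedicated bin for missing
PSA at both levels.

Matching proceeds in rounds.  In a round every target must receive exactly
one control, searched first among pool members exact on the narrow bins and,
failing that, on the wide bins; ties are broken uniformly at random.  A
round in which any target finds no candidate is discarded whole and
consumes no controls.  Matched controls leave the pool between rounds, so a
cohort that completes r rounds is an exact 1:r match.  Matching is run
independently per severity category, so one control may serve several
categories (but never twice within one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, IQCategory

__all__ = [
    "BinSpec",
    "MatchedCohort",
    "RoundAssignment",
    "compute_bins",
    "assign_bins",
    "match_round",
    "repeated_matching",
    "match_all_categories",
    "exam_match_frame",
]

NARROW_K = 6
WIDE_K = 3


@dataclass(frozen=True)
class BinSpec:
    """Quantile coarsening of one variable at one level (narrow or wide).

    ``edges`` are the interior quantile cut points; values fall into
    right-closed intervals, i.e. bin(v) = #{edges e : v > e}.  Missing
    values map to the dedicated bin -1 when ``missing_bin`` is set.
    """

    variable: str
    level: str  # "narrow" | "wide"
    edges: tuple[float, ...]
    missing_bin: bool = False

    def assign(self, value: float | None) -> int:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            if not self.missing_bin:
                raise ValueError(f"{self.variable}: missing value but no missing bin")
            return -1
        return int(sum(value > e for e in self.edges))


def compute_bins(
    values: Sequence[float | None], k: int, variable: str = "x", missing_bin: bool = False
) -> BinSpec:
    """Quantile cut points splitting the non-missing values into ``k``
    near-equal groups.

    With fewer than ``k`` distinct values the spec degenerates to fewer
    bins (duplicate cut points are dropped) with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    arr = np.asarray(
        [v for v in values if v is not None and not (isinstance(v, float) and np.isnan(v))],
        dtype=float,
    )
    if arr.size == 0:
        return BinSpec(variable, "narrow" if k == NARROW_K else "wide", (), missing_bin)
    edges = np.quantile(arr, [i / k for i in range(1, k)])
    uniq = tuple(dict.fromkeys(float(e) for e in edges))
    if len(uniq) < k - 1:
        warnings.warn(
            f"{variable}: fewer than {k} distinct quantiles; using {len(uniq) + 1} bins",
            stacklevel=2,
        )
    return BinSpec(variable, "narrow" if k == NARROW_K else "wide", uniq, missing_bin)


def assign_bins(df: pd.DataFrame, spec: BinSpec) -> np.ndarray:
    col = df[spec.variable]
    return np.asarray([spec.assign(None if pd.isna(v) else float(v)) for v in col])


@dataclass(frozen=True)
class RoundAssignment:
    """One completed round: (target_id, control_id, tier) triples."""

    pairs: tuple[tuple[str, str, str], ...]


@dataclass
class MatchedCohort:
    """Target group with its matched controls and per-control provenance."""

    category: IQCategory | None
    target_ids: list[str]
    control_ids: list[str] = field(default_factory=list)
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["control_id", "target_id", "round", "tier"]
        )
    )
    rounds_completed: int = 0

    @property
    def ratio(self) -> int:
        return self.rounds_completed


class _Pool:
    """Candidate index over the control pool, keyed by match keys.

    Insertion-ordered dicts and explicit id lists keep candidate selection
    deterministic under a fixed seed (no dependence on str hashing).
    """

    def __init__(self, ids: Sequence[str], narrow_keys: Sequence[tuple], wide_keys: Sequence[tuple]):
        self.narrow: dict[tuple, list[str]] = {}
        self.wide: dict[tuple, list[str]] = {}
        self.available: dict[str, bool] = {}
        for i, nk, wk in zip(ids, narrow_keys, wide_keys):
            self.narrow.setdefault(nk, []).append(i)
            self.wide.setdefault(wk, []).append(i)
            self.available[i] = True

    def candidates(self, key: tuple, tier: str, taken: set[str]) -> list[str]:
        table = self.narrow if tier == "narrow" else self.wide
        return [i for i in table.get(key, ()) if self.available[i] and i not in taken]

    def remove(self, ids: Sequence[str]) -> None:
        for i in ids:
            self.available[i] = False


def _match_keys(df: pd.DataFrame, bins: Mapping[tuple[str, str], BinSpec]) -> tuple[list, list]:
    narrow, wide = [], []
    cols = {name: assign_bins(df, spec) for name, spec in bins.items()}
    fac = df["facility"].tolist()
    bio = df["biopsy_status"].tolist()
    a_n = cols[("age", "narrow")]
    a_w = cols[("age", "wide")]
    p_n = cols[("psa", "narrow")]
    p_w = cols[("psa", "wide")]
    for i in range(len(df)):
        narrow.append((fac[i], bio[i], int(a_n[i]), int(p_n[i])))
        wide.append((fac[i], bio[i], int(a_w[i]), int(p_w[i])))
    return narrow, wide


def default_bins(union: pd.DataFrame) -> dict[tuple[str, str], BinSpec]:
    """Narrow (k=6) and wide (k=3) quantile bins for age and PSA, computed
    once on the union of targets and pool; PSA gets a missing bin."""
    return {
        ("age", "narrow"): compute_bins(union["age"].tolist(), NARROW_K, "age"),
        ("age", "wide"): compute_bins(union["age"].tolist(), WIDE_K, "age"),
        ("psa", "narrow"): compute_bins(
            union["psa"].tolist(), NARROW_K, "psa", missing_bin=True
        ),
        ("psa", "wide"): compute_bins(union["psa"].tolist(), WIDE_K, "psa", missing_bin=True),
    }


def match_round(
    targets: pd.DataFrame,
    pool: _Pool,
    target_keys: Sequence[tuple[tuple, tuple]],
    rng: np.random.Generator,
) -> RoundAssignment | None:
    """Attempt one round: one control per target, narrow tier first.

    Targets are visited in a seeded random order.  Returns ``None`` when
    any target has no candidate at either tier; in that case nothing is
    consumed from the pool.
    """
    order = rng.permutation(len(target_keys))
    taken: set[str] = set()
    pairs: list[tuple[str, str, str]] = []
    ids = targets["exam_id"].tolist()
    for idx in order:
        nk, wk = target_keys[idx]
        tier = "narrow"
        cands = pool.candidates(nk, "narrow", taken)
        if not cands:
            tier = "wide"
            cands = pool.candidates(wk, "wide", taken)
        if not cands:
            return None
        chosen = cands[int(rng.integers(len(cands)))]
        taken.add(chosen)
        pairs.append((ids[idx], chosen, tier))
    return RoundAssignment(tuple(pairs))


def repeated_matching(
    targets: pd.DataFrame,
    pool_df: pd.DataFrame,
    *,
    max_rounds: int = 20,
    retries_per_round: int = 10,
    seed: int = 0,
    category: IQCategory | None = None,
) -> MatchedCohort:
    """Run rounds until one fails (after order retries) or ``max_rounds``.

    Bin cut points are computed once on the union of targets and the
    initial pool.  A failed round is retried with a fresh random visiting
    order up to ``retries_per_round`` times, since visiting order alone can
    make a feasible round fail.
    """
    result = MatchedCohort(category=category, target_ids=targets["exam_id"].tolist())
    if len(targets) == 0 or len(pool_df) == 0:
        return result
    overlap = set(result.target_ids) & set(pool_df["exam_id"])
    if overlap:
        raise ValueError(f"targets and pool must be disjoint; shared ids {sorted(overlap)[:5]}")

    union = pd.concat([targets, pool_df], ignore_index=True)
    bins = default_bins(union)
    t_narrow, t_wide = _match_keys(targets, bins)
    p_narrow, p_wide = _match_keys(pool_df, bins)
    pool = _Pool(pool_df["exam_id"].tolist(), p_narrow, p_wide)
    target_keys = list(zip(t_narrow, t_wide))

    rng = np.random.default_rng(seed)
    rows = []
    for rnd in range(1, max_rounds + 1):
        assignment = None
        for _ in range(retries_per_round):
            assignment = match_round(targets, pool, target_keys, rng)
            if assignment is not None:
                break
        if assignment is None:
            break
        pool.remove([c for _, c, _ in assignment.pairs])
        result.control_ids.extend(c for _, c, _ in assignment.pairs)
        rows.extend(
            {"control_id": c, "target_id": t, "round": rnd, "tier": tier}
            for t, c, tier in assignment.pairs
        )
        result.rounds_completed = rnd
    if rows:
        result.provenance = pd.DataFrame(rows)
    return result


def exam_match_frame(cohort: CohortTable) -> pd.DataFrame:
    """Covariate frame used by the matcher (one row per exam)."""
    df = cohort.exams_frame()
    return df[["exam_id", "age", "psa", "facility", "biopsy_status", "exam_iq", "iq_source"]]


def match_all_categories(
    cohort: CohortTable,
    *,
    seed: int = 0,
    max_rounds: int = 20,
    retries_per_round: int = 10,
) -> dict[IQCategory, MatchedCohort]:
    """Match each artifact category independently against the optimal pool.

    Targets are the radiologist-graded mild / moderate / severe exams; the
    control pool is every exam graded optimal by either radiologists or the
    model.  Each category sees its own fresh copy of the pool, so a control
    can appear in several categories.
    """
    df = exam_match_frame(cohort)
    ungraded = df["exam_iq"].isna()
    if ungraded.any():
        raise ValueError(
            f"{int(ungraded.sum())} exams have no exam-level IQ; grade the cohort first"
        )
    pool_df = df[df["exam_iq"] == str(IQCategory.OPTIMAL)].reset_index(drop=True)
    out: dict[IQCategory, MatchedCohort] = {}
    ss = np.random.SeedSequence(seed)
    subseeds = ss.spawn(3)
    for cat, sub in zip((IQCategory.MILD, IQCategory.MODERATE, IQCategory.SEVERE), subseeds):
        tgt = df[(df["exam_iq"] == str(cat)) & (df["iq_source"] == "radiologist")]
        tgt = tgt.reset_index(drop=True)
        if len(tgt) == 0:
            warnings.warn(f"no radiologist-graded {cat} targets; empty matched cohort")
            out[cat] = MatchedCohort(category=cat, target_ids=[])
            continue
        out[cat] = repeated_matching(
            tgt,
            pool_df,
            max_rounds=max_rounds,
            retries_per_round=retries_per_round,
            seed=int(sub.generate_state(1)[0] % (2**31)),
            category=cat,
        )
    return out
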