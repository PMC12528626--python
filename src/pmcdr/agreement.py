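"""Inter-rater and model-vs-rater agreement statistics.

Two kappa estimators are provided: a Fleiss-type multi-rater generalized
kappa (observed pairwise agreement against chance agreement from pooled
category marginals) for panels of raters, and Cohen's quadratic weighted
kappa for two-way comparisons such as model vs radiologist consensus.
Values are labelled with the Landis-Koch verbal bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "AgreementResult",
    "generalized_kappa",
    "weighted_kappa",
    "label_kappa",
    "confusion_matrix",
]


@dataclass(frozen=True)
class AgreementResult:
    kappa: float | None
    kind: str  # "generalized_multirater" | "weighted_quadratic"
    label: str | None
    n_items: int
    n_raters: int | None = None
    n_dropped: int = 0


LANDIS_KOCH_BANDS = (
    (0.81, "almost perfect"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (0.00, "slight"),
)


def label_kappa(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa value.

    Bands: 0.81-1.00 almost perfect, 0.61-0.80 substantial, 0.41-0.60
    moderate, 0.21-0.40 fair, 0.00-0.20 slight, below 0.00 poor.  The
    value is first rounded half-up to 2 decimals so it always falls inside
    a printed band.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    r = float(Decimal(repr(kappa)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    if r < 0.0:
        return "poor"
    for lo, name in LANDIS_KOCH_BANDS:
        if r >= lo:
            return name
    return "slight"


def generalized_kappa(ratings) -> AgreementResult:
    """Fleiss-type multi-rater kappa from an items x raters category matrix.

    ``ratings`` is an array-like of shape (n_items, n_raters) of category
    codes; cells may be None/NaN, in which case the item is dropped (the
    drop count is reported).  Chance agreement comes from the pooled
    category marginals; observed agreement is the mean over items of the
    pairwise agreement rate.
    """
    arr = pd.DataFrame(ratings)
    n_raters_total = arr.shape[1]
    if arr.shape[0] < 2 or n_raters_total < 2:
        raise ValueError("generalized_kappa needs >= 2 items and >= 2 raters")
    complete = arr.dropna()
    n_dropped = arr.shape[0] - complete.shape[0]
    if complete.shape[0] < 2:
        raise ValueError("fewer than 2 complete items after dropping missing cells")
    codes = complete.to_numpy()
    cats = sorted({c for row in codes for c in row}, key=lambda c: (str(type(c)), c))
    k = len(cats)
    index = {c: i for i, c in enumerate(cats)}
    n_items, n = codes.shape
    counts = np.zeros((n_items, k), dtype=float)
    for i in range(n_items):
        for c in codes[i]:
            counts[i, index[c]] += 1
    p_j = counts.sum(axis=0) / (n_items * n)
    p_e = float((p_j**2).sum())
    if k == 1:
        # a single category everywhere: chance agreement is 1, kappa undefined
        return AgreementResult(None, "generalized_multirater", None, n_items, n, n_dropped)
    p_i = ((counts * (counts - 1)).sum(axis=1)) / (n * (n - 1))
    p_o = float(p_i.mean())
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(kappa, "generalized_multirater", label_kappa(kappa), n_items, n, n_dropped)


def quadratic_weights(k: int) -> np.ndarray:
    """Disagreement weights w_ij = (i - j)^2 / (k - 1)^2."""
    idx = np.arange(k)
    return (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2


def weighted_kappa(confusion, weights: str | np.ndarray = "quadratic") -> AgreementResult:
    """Weighted kappa from a k x k confusion-count matrix.

    kappa = 1 - sum(w o) / sum(w e) with o the observed cell proportions,
    e the independence expectation from the row/column marginals, and w
    the quadratic disagreement weights (or 'identity' for Cohen's
    unweighted kappa, or an explicit matrix).
    """
    o = np.asarray(confusion, dtype=float)
    if o.ndim != 2 or o.shape[0] != o.shape[1]:
        raise ValueError(f"confusion must be square, got {o.shape}")
    if np.any(o < 0):
        raise ValueError("confusion counts must be non-negative")
    total = o.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    k = o.shape[0]
    if isinstance(weights, str):
        if weights == "quadratic":
            w = quadratic_weights(k)
        elif weights == "identity":
            w = 1.0 - np.eye(k)
        else:
            raise ValueError(f"unknown weights {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)
    p = o / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    e = np.outer(r, c)
    denom = float((w * e).sum())
    if denom == 0:
        # all mass in a single category: chance agreement is perfect
        return AgreementResult(None, "weighted_quadratic", None, int(total))
    kappa = 1.0 - float((w * p).sum()) / denom
    return AgreementResult(kappa, "weighted_quadratic", label_kappa(kappa), int(total))


def confusion_matrix(pred, truth, categories=None) -> pd.DataFrame:
    """Counts of truth (rows) against predictions (columns).

    Returned frame has a MultiIndex-free layout: integer counts plus a
    companion ``proportions`` attribute giving, per cell, the proportion
    over its prediction column (how the raters distribute within each
    model call).
    """
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    if categories is None:
        categories = sorted(set(pred) | set(truth))
    tab = pd.crosstab(
        pd.Categorical(truth, categories=categories),
        pd.Categorical(pred, categories=categories),
        dropna=False,
    )
    tab.index.name = "truth"
    tab.columns.name = "pred"
    col_tot = tab.sum(axis=0).replace(0, np.nan)
    tab.attrs["proportions"] = tab.div(col_tot, axis=1)
    return tab
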