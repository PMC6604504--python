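"""Aggregate reports and the nonparametric statistics used on quiz scores.

Percentages follow the half-up rounding convention of the published
summaries, which mix integer ("95%") and one-decimal ("94.6%") precision;
raw fractions are always carried alongside.  County-quiz scores are ordinal
with heavy ties at 5, hence the Kruskal-Wallis rank test (with the tie
correction) across counties and Spearman's rank correlation against length
of residence.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "round_half_up",
    "percentage",
    "item_accuracy",
    "KruskalWallisResult",
    "kruskal_wallis",
    "kruskal_wallis_null_rejection",
    "spearman_rho",
]


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as used for the
    published percentages; banker's rounding would flip e.g. 22.25 -> 22.2."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, digits: int = 1) -> Optional[float]:
    """100*numerator/denominator rounded half-up; None (undefined, never 0)
    for an empty denominator."""
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, digits)


def item_accuracy(
    records: pd.DataFrame,
    flag_columns: Sequence[str],
    subgroup: Optional[pd.Series] = None,
    digits: int = 1,
) -> pd.DataFrame:
    """Per-component accuracy over a record table.

    ``flag_columns`` are boolean correctness columns (True/False/None);
    ``subgroup`` restricts the denominator (e.g. quiz passers).  Records
    where a component was not administered (None/NaN) are excluded from
    that component's denominator.  Empty subgroups yield an undefined
    (None) percentage, flagged rather than reported as zero.
    """
    df = records if subgroup is None else records.loc[np.asarray(subgroup, dtype=bool)]
    rows = []
    for col in flag_columns:
        vals = df[col].dropna() if col in df else pd.Series(dtype=object)
        den = int(len(vals))
        num = int(vals.astype(bool).sum())
        rows.append(
            {
                "component": col,
                "numerator": num,
                "denominator": den,
                "pct_raw": 100.0 * num / den if den else None,
                "pct": percentage(num, den, digits),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KruskalWallisResult:
    h: float
    df: int
    pvalue: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Kruskal-Wallis H across groups, with midranks and the tie-correction
    divisor 1 - sum(t^3 - t)/(N^3 - N); df = groups - 1, p from the
    chi-square approximation.  All-tied data yields H = 0."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_div = 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))
    if tie_div == 0.0:  # every observation identical
        h = 0.0
    else:
        h /= tie_div
    df = len(groups) - 1
    return KruskalWallisResult(h=float(h), df=df, pvalue=float(stats.chi2.sf(h, df)))


def kruskal_wallis_null_rejection(
    n_groups: int,
    group_size: int,
    reps: int,
    seed: int,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the chi-square cut under the null (all groups from
    one continuous distribution), estimated over ``reps`` simulated
    datasets.  Continuous draws are tie-free, so the batched H needs no tie
    divisor."""
    rng = np.random.default_rng(seed)
    n = n_groups * group_size
    x = rng.random((reps, n))
    order = np.argsort(x, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(reps)[:, None]
    ranks[rows, order] = np.arange(1, n + 1)
    r = ranks.reshape(reps, n_groups, group_size).sum(axis=2)
    h = 12.0 / (n * (n + 1)) * (r**2 / group_size).sum(axis=1) - 3.0 * (n + 1)
    crit = stats.chi2.ppf(1 - alpha, n_groups - 1)
    return float((h > crit).mean())


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank-order correlation: the product-moment correlation of
    midranks.  Undefined (raises) when either ranking has zero variance."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length sequences with at least 3 pairs")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("rank correlation undefined: a ranking has zero variance")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
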