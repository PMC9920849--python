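"""Pearson correlations with significance stars and the |r| > 0.6 flag.

Stagewise matrices correlate per-replicate measurements within one growth
stage; the combined matrix correlates per-landrace trait summaries averaged
over stages.  Missing data are handled pairwise (available-case), which
maximizes n under whole-cell missingness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .exceptions import InsufficientDataError, UndefinedStatisticError
from .traits import landrace_trait_means

__all__ = [
    "CorrelationMatrix",
    "pearson_r",
    "correlation_pvalue",
    "star_code",
    "staged_correlations",
    "combined_correlations",
]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two paired vectors.

    Pairs with any missing member are dropped first.  Requires at least 3
    complete pairs and non-zero variance in both margins.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise InsufficientDataError("x and y must be paired (equal length)")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise InsufficientDataError(
            f"need >= 3 complete pairs, got {xa.size}"
        )
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return max(-1.0, min(1.0, r))


def star_code(p: float) -> str:
    """Map a p-value to the conventional star code (ns, *, **, ***)."""
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def correlation_pvalue(r: float, n: int) -> tuple[float, str]:
    """Two-sided p-value for a Pearson r via the t transform, plus stars.

    ``t = r sqrt(n-2) / sqrt(1-r^2)`` with ``n - 2`` df.  |r| = 1 is the
    degenerate short-circuit: p = 0, three stars.
    """
    if n < 3:
        raise InsufficientDataError("need n >= 3 for a correlation p-value")
    if abs(r) >= 1.0:
        return 0.0, "***"
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * t_dist.sf(abs(t), n - 2))
    return p, star_code(p)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric correlation matrix with per-pair n, p and annotation.

    ``stars`` carries the significance code for stagewise matrices; for the
    combined landrace-level matrix ``flagged`` marks pairs with |r| > 0.6
    (strict), the working definition of a meaningful association there.
    """

    labels: tuple[str, ...]
    r: pd.DataFrame
    n: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    flagged: pd.DataFrame | None = None


def _pairwise_matrix(wide: pd.DataFrame, flag_threshold: float | None) -> CorrelationMatrix:
    cols = list(wide.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    p = np.full((k, k), np.nan)
    stars = np.full((k, k), "ns", dtype=object)
    np.fill_diagonal(r, 1.0)
    for i in range(k):
        xi = wide[cols[i]].to_numpy(dtype=float)
        n[i, i] = int(np.isfinite(xi).sum())
        p[i, i] = 0.0
        stars[i, i] = "***"
        for j in range(i + 1, k):
            xj = wide[cols[j]].to_numpy(dtype=float)
            keep = np.isfinite(xi) & np.isfinite(xj)
            n[i, j] = n[j, i] = int(keep.sum())
            try:
                rij = pearson_r(xi[keep], xj[keep])
                pij, sij = correlation_pvalue(rij, int(keep.sum()))
            except (InsufficientDataError, UndefinedStatisticError):
                stars[i, j] = stars[j, i] = "NA"
                continue
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            stars[i, j] = stars[j, i] = sij
    idx = pd.Index(cols)
    flagged = None
    if flag_threshold is not None:
        flagged = pd.DataFrame(np.abs(r) > flag_threshold, index=idx, columns=idx)
        np.fill_diagonal(flagged.values, True)
    return CorrelationMatrix(
        labels=tuple(cols),
        r=pd.DataFrame(r, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        stars=pd.DataFrame(stars, index=idx, columns=idx),
        flagged=flagged,
    )


def staged_correlations(
    table: pd.DataFrame,
    stage: str,
    traits: Iterable[str] | None = None,
    pool_landraces: bool = True,
) -> CorrelationMatrix:
    """Trait-by-trait correlations of per-replicate values within one stage.

    By default all landraces' replicates at the stage are pooled, giving the
    largest n; with ``pool_landraces=False`` the landrace cell means are
    correlated instead.  Pairs with insufficient data get an "NA" star cell
    rather than failing.
    """
    sub = table[table["stage"] == stage]
    if sub.empty:
        raise InsufficientDataError(f"no records at stage {stage!r}")
    if traits is not None:
        sub = sub[sub["trait"].isin(list(traits))]
    if pool_landraces:
        wide = sub.pivot_table(
            index=["landrace", "block", "rep"],
            columns="trait",
            values="value",
            aggfunc="mean",
        )
    else:
        wide = sub.pivot_table(index="landrace", columns="trait", values="value")
    if traits is not None:
        wide = wide[[t for t in traits if t in wide.columns]]
    return _pairwise_matrix(wide, flag_threshold=None)


def combined_correlations(
    landrace_means: pd.DataFrame | None = None,
    table: pd.DataFrame | None = None,
    traits: Iterable[str] | None = None,
    flag_threshold: float = 0.6,
) -> CorrelationMatrix:
    """Landrace-level correlations of stage-averaged trait summaries.

    Accepts either a precomputed landrace x trait matrix or a raw trait
    table (aggregated via :func:`landrace_trait_means`).  Pairs with
    |r| strictly greater than ``flag_threshold`` are flagged.
    """
    if landrace_means is None:
        if table is None:
            raise InsufficientDataError("provide landrace_means or table")
        landrace_means = landrace_trait_means(table, traits=traits)
    return _pairwise_matrix(landrace_means, flag_threshold=flag_threshold)
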