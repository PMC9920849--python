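"""ANOVA, studentized-range quantiles, Tukey HSD and compact letter displays.

The sums of squares, the studentized-range distribution and the
insert-and-absorb letter algorithm are implemented from first principles —
they are the statistical core the rest of the pipeline is built on — and are
cross-checked in the test suite against independent references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, ndtr
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .exceptions import DesignError, GourdstatsError, InsufficientDataError

__all__ = [
    "SourceRow",
    "AnovaTable",
    "PairwiseResult",
    "oneway_anova",
    "rcbd_anova",
    "studentized_range_q",
    "tukey_pairwise",
    "compact_letter_display",
    "mean_separation",
]


@dataclass(frozen=True)
class SourceRow:
    """One ANOVA source: degrees of freedom, SS, MS and F (NaN if undefined)."""

    df: int
    ss: float
    ms: float
    f: float


@dataclass(frozen=True)
class AnovaTable:
    """ANOVA decomposition for a one-way or randomized-block design."""

    design: str  # "one-way" | "rcbd"
    sources: Mapping[str, SourceRow]
    n_total: int
    grand_mean: float
    n_per_group: tuple[int, ...]

    @property
    def msg(self) -> float:
        """Mean square due to genotype (the treatment factor)."""
        return self.sources["genotype"].ms

    @property
    def mse(self) -> float:
        """Mean square of error."""
        return self.sources["error"].ms

    @property
    def df_error(self) -> int:
        return self.sources["error"].df

    @property
    def f(self) -> float:
        return self.sources["genotype"].f

    @property
    def f_pvalue(self) -> float:
        """Right-tail p-value of the genotype F test (NaN if F undefined)."""
        fval = self.f
        if not math.isfinite(fval):
            return float("nan")
        return float(f_dist.sf(fval, self.sources["genotype"].df, self.df_error))


def _clean_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    cleaned = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        arr = arr[np.isfinite(arr)]
        cleaned.append(arr)
    return cleaned


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """One-way fixed-effects ANOVA from raw group values.

    ``SS_between = sum n_i (ybar_i - ybar)^2`` with ``G - 1`` df;
    ``SS_within = sum sum (y - ybar_i)^2`` with ``N - G`` df.  Missing
    values (NaN) are dropped per group.  If every within-group deviation is
    zero, MSE = 0 and F is reported as NaN (undefined), not raised.
    """
    cleaned = _clean_groups(groups)
    cleaned = [g for g in cleaned if g.size > 0]
    if len(cleaned) < 2:
        raise InsufficientDataError("need at least 2 non-empty groups")
    ns = np.array([g.size for g in cleaned])
    if not np.any(ns >= 2):
        raise InsufficientDataError(
            "all groups are singletons: no within-group (error) df"
        )
    n_total = int(ns.sum())
    grand = float(np.concatenate(cleaned).mean())
    group_means = np.array([g.mean() for g in cleaned])
    ssb = float(np.sum(ns * (group_means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(cleaned, group_means)))
    df_b = len(cleaned) - 1
    df_w = n_total - len(cleaned)
    msb = ssb / df_b
    msw = ssw / df_w
    f = msb / msw if msw > 0 else (0.0 if msb == 0 else float("nan"))
    sources = {
        "genotype": SourceRow(df=df_b, ss=ssb, ms=msb, f=f),
        "error": SourceRow(df=df_w, ss=ssw, ms=msw, f=float("nan")),
    }
    return AnovaTable(
        design="one-way",
        sources=sources,
        n_total=n_total,
        grand_mean=grand,
        n_per_group=tuple(int(n) for n in ns),
    )


def rcbd_anova(cells: np.ndarray | Sequence[Sequence[float]]) -> AnovaTable:
    """Randomized-complete-block ANOVA on a genotype x block cell matrix.

    Decomposes total SS into genotype (df G-1), block (df r-1) and error
    (df (G-1)(r-1)).  Requires a complete matrix: a missing (NaN) cell must
    be handled upstream by available-case exclusion of the genotype.
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 2:
        raise DesignError("cells must be a 2-D genotype x block matrix")
    if np.isnan(y).any():
        raise DesignError(
            "missing cell in the genotype x block matrix; exclude incomplete "
            "genotypes upstream (available-case) before the RCBD fit"
        )
    g, r = y.shape
    if g < 2:
        raise DesignError("need at least 2 genotypes")
    if r < 2:
        raise DesignError("need at least 2 blocks (replications)")
    grand = float(y.mean())
    ss_total = float(((y - grand) ** 2).sum())
    ss_g = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_b = float(g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_e = max(ss_total - ss_g - ss_b, 0.0)
    df_g, df_b, df_e = g - 1, r - 1, (g - 1) * (r - 1)
    ms_g, ms_b, ms_e = ss_g / df_g, ss_b / df_b, ss_e / df_e
    f_g = ms_g / ms_e if ms_e > 0 else (0.0 if ms_g == 0 else float("nan"))
    f_b = ms_b / ms_e if ms_e > 0 else float("nan")
    sources = {
        "genotype": SourceRow(df=df_g, ss=ss_g, ms=ms_g, f=f_g),
        "block": SourceRow(df=df_b, ss=ss_b, ms=ms_b, f=f_b),
        "error": SourceRow(df=df_e, ss=ss_e, ms=ms_e, f=float("nan")),
    }
    return AnovaTable(
        design="rcbd",
        sources=sources,
        n_total=g * r,
        grand_mean=grand,
        n_per_group=(r,) * g,
    )


# ---------------------------------------------------------------------------
# Studentized range distribution
# ---------------------------------------------------------------------------

_Z_NODES, _Z_WEIGHTS = np.polynomial.legendre.leggauss(160)
# integration window for the inner normal integral; the N(0,1) density is
# negligible outside it and the range factor is bounded by 1
_Z_LO, _Z_HI = -9.0, 9.0
_Z = 0.5 * (_Z_HI - _Z_LO) * _Z_NODES + 0.5 * (_Z_HI + _Z_LO)
_ZW = 0.5 * (_Z_HI - _Z_LO) * _Z_WEIGHTS
_PHI_Z = np.exp(-0.5 * _Z * _Z) / math.sqrt(2.0 * math.pi)
_CDF_Z = ndtr(_Z)

_S_NODES, _S_WEIGHTS = np.polynomial.legendre.leggauss(160)


def _range_cdf_inf(w: float, k: int) -> float:
    """P(range of k independent N(0,1) <= w); the df -> infinity limit form."""
    if w <= 0:
        return 0.0
    inner = (_CDF_Z - ndtr(_Z - w)) ** (k - 1)
    return float(k * np.sum(_ZW * _PHI_Z * inner))


def _studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range by numerical integration.

    Integrates the normal-range probability over the distribution of the
    scale factor S = sqrt(chi2_df / df); for infinite df the scale collapses
    to 1 and the limit form is used directly.
    """
    if q <= 0:
        return 0.0
    if math.isinf(df):
        return _range_cdf_inf(q, k)
    sd = 1.0 / math.sqrt(2.0 * df)
    lo = max(0.0, 1.0 - 12.0 * sd)
    hi = 1.0 + 12.0 * sd if df > 2 else 9.0
    s = 0.5 * (hi - lo) * _S_NODES + 0.5 * (hi + lo)
    sw = 0.5 * (hi - lo) * _S_WEIGHTS
    # density of S: f(s) = nu^{nu/2} s^{nu-1} exp(-nu s^2/2) / (Gamma(nu/2) 2^{nu/2-1})
    log_c = 0.5 * df * math.log(df) - gammaln(0.5 * df) - (0.5 * df - 1.0) * math.log(2.0)
    with np.errstate(divide="ignore"):
        log_dens = log_c + (df - 1.0) * np.log(np.maximum(s, 1e-300)) - 0.5 * df * s * s
    dens = np.exp(log_dens)
    inner = (_CDF_Z[None, :] - ndtr(_Z[None, :] - q * s[:, None])) ** (k - 1)
    prange = k * np.sum(_ZW[None, :] * _PHI_Z[None, :] * inner, axis=1)
    return float(np.sum(sw * dens * prange))


@lru_cache(maxsize=512)
def studentized_range_q(k: int, df: float, alpha: float = 0.05) -> float:
    """Upper-``alpha`` quantile of the studentized range with ``k`` groups.

    Computed by root-finding on the numerically integrated CDF; ``df`` may
    be ``math.inf`` (the normal-range limit).  Accurate to ~3 decimals
    against published critical-value tables.
    """
    if k < 2 or int(k) != k:
        raise GourdstatsError(f"k must be an integer >= 2, got {k!r}")
    if not (df >= 1):
        raise GourdstatsError(f"df must be >= 1, got {df!r}")
    if not 0.0 < alpha < 1.0:
        raise GourdstatsError(f"alpha must lie in (0, 1), got {alpha!r}")
    target = 1.0 - alpha
    func = lambda q: _studentized_range_cdf(q, int(k), float(df)) - target
    lo, hi = 1e-3, 10.0
    while func(hi) < 0 and hi < 1e4:
        hi *= 2.0
    return float(brentq(func, lo, hi, xtol=1e-9, rtol=1e-12))


# ---------------------------------------------------------------------------
# Tukey HSD and compact letter display
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseResult:
    """All pairwise Tukey(-Kramer) comparisons among group means."""

    labels: tuple[str, ...]
    means: tuple[float, ...]
    ns: tuple[int, ...]
    diff: np.ndarray  # mean_i - mean_j
    se: np.ndarray
    q_stat: np.ndarray
    significant: np.ndarray  # bool, symmetric, False diagonal
    q_crit: float
    alpha: float
    degenerate: bool = False


def tukey_pairwise(
    anova: AnovaTable,
    means: Sequence[float],
    ns: Sequence[int],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> PairwiseResult:
    """Tukey HSD pairwise tests, Tukey-Kramer adjusted for unequal n.

    ``q_obs = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))``; a pair is
    significant when ``q_obs`` exceeds the studentized-range critical value
    at the ANOVA's error df.  ``MSE == 0`` is degenerate: every pair with a
    non-zero difference is flagged significant.
    """
    m = np.asarray(means, dtype=float)
    n = np.asarray(ns, dtype=float)
    k = m.size
    if k < 2:
        raise InsufficientDataError("need at least two groups to compare")
    if labels is None:
        labels = tuple(f"G{i + 1}" for i in range(k))
    diff = m[:, None] - m[None, :]
    mse = anova.mse
    if mse <= 0:
        sig = diff != 0
        np.fill_diagonal(sig, False)
        q_stat = np.where(diff != 0, np.inf, 0.0)
        return PairwiseResult(
            labels=tuple(labels), means=tuple(m), ns=tuple(int(x) for x in n),
            diff=diff, se=np.zeros_like(diff), q_stat=q_stat,
            significant=sig, q_crit=float("nan"), alpha=alpha, degenerate=True,
        )
    se = np.sqrt(mse / 2.0 * (1.0 / n[:, None] + 1.0 / n[None, :]))
    q_stat = np.abs(diff) / se
    q_crit = studentized_range_q(k, float(anova.df_error), alpha)
    sig = q_stat > q_crit
    np.fill_diagonal(sig, False)
    return PairwiseResult(
        labels=tuple(labels), means=tuple(m), ns=tuple(int(x) for x in n),
        diff=diff, se=se, q_stat=q_stat, significant=sig,
        q_crit=q_crit, alpha=alpha,
    )


def _letter(index: int) -> str:
    if index < 26:
        return chr(ord("a") + index)
    hi, lo = divmod(index - 26, 26)
    return chr(ord("a") + hi) + chr(ord("a") + lo)


def compact_letter_display(pairwise: PairwiseResult) -> dict[str, str]:
    """Insert-and-absorb letter coding of a pairwise significance matrix.

    Starts from a single letter column containing every group; each
    significant pair still sharing a column splits that column in two
    (dropping one member from each copy); columns that become subsets of
    another are absorbed.  The result satisfies: two groups share at least
    one letter iff their pair is not significant.  Letters are assigned in
    descending group-mean order starting at 'a'.
    """
    labels = list(pairwise.labels)
    k = len(labels)
    sig = np.asarray(pairwise.significant, dtype=bool)
    # letter columns as bitmasks; invariant: no column is a subset of another
    columns: list[int] = [(1 << k) - 1]
    for i in range(k):
        bit_i = 1 << i
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            both = bit_i | (1 << j)
            split = [m for m in columns if m & both == both]
            if not split:
                continue
            columns = [m for m in columns if m & both != both]
            for m in split:
                for cand in (m & ~bit_i, m & ~(1 << j)):
                    if not cand:
                        continue
                    if any(cand | o == o for o in columns):
                        continue  # cand absorbed by an existing superset
                    columns = [o for o in columns if o | cand != cand]
                    columns.append(cand)
    # order columns by the best (highest-mean) member so 'a' tags the top group
    order = sorted(range(k), key=lambda i: (-pairwise.means[i], labels[i]))
    rank = {g: r for r, g in enumerate(order)}

    def members(mask: int) -> list[int]:
        return [g for g in range(k) if mask >> g & 1]

    columns.sort(key=lambda mask: min(rank[g] for g in members(mask)))
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for idx, mask in enumerate(columns):
        for g in sorted(members(mask), key=lambda g: rank[g]):
            letters[labels[g]].append(_letter(idx))
    return {lab: "".join(ls) for lab, ls in letters.items()}


def mean_separation(
    table,
    trait: str,
    alpha: float = 0.05,
):
    """Joint landrace-x-stage mean separation for one trait.

    Treats every landrace-stage cell with data as one treatment level of a
    one-way ANOVA on the raw within-cell measurements, then letters all
    cells jointly — so letters are comparable both across landraces within
    a stage and across stages within a landrace.  Returns a DataFrame with
    columns ``landrace, stage, mean, n, letters``.
    """
    import pandas as pd

    sub = table[(table["trait"] == trait) & table["value"].notna()]
    if sub.empty:
        raise InsufficientDataError(f"no present values for trait {trait!r}")
    groups: list[np.ndarray] = []
    keys: list[tuple[str, str]] = []
    for (landrace, stage), vals in sub.groupby(["landrace", "stage"], sort=True)["value"]:
        groups.append(vals.to_numpy())
        keys.append((landrace, stage))
    if len(groups) < 2:
        raise InsufficientDataError(
            f"trait {trait!r} has fewer than two landrace-stage cells"
        )
    anova = oneway_anova(groups)
    means = [float(g.mean()) for g in groups]
    ns = [int(g.size) for g in groups]
    labels = [f"{lr}@{st}" for lr, st in keys]
    pw = tukey_pairwise(anova, means, ns, alpha=alpha, labels=labels)
    letters = compact_letter_display(pw)
    return pd.DataFrame(
        {
            "landrace": [lr for lr, _ in keys],
            "stage": [st for _, st in keys],
            "mean": means,
            "n": ns,
            "letters": [letters[lab] for lab in labels],
        }
    )
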