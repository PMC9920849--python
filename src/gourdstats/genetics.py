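"""Quantitative-genetic parameter estimation from ANOVA mean squares.

For a genotype trial with ``r`` replications the expected mean squares give

    sigma2_e = MSE
    sigma2_g = (MSG - MSE) / r          (truncated at 0, flagged)
    sigma2_p = sigma2_g + sigma2_e

from which the coefficients of variation (PCV/GCV/ECV = sqrt(variance) /
grand mean x 100), broad-sense heritability h2 = sigma2_g / sigma2_p x 100,
and the expected genetic advance under truncation selection
GA = k * sigma2_g / sqrt(sigma2_p) (k = 2.063 at 5% selection intensity)
all follow.  Heritability above 50% is conventionally read as a meaningful
genetic signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anova import rcbd_anova
from .exceptions import GourdstatsError
from .traits import cell_means

__all__ = [
    "DEFAULT_SELECTION_K",
    "VarianceComponents",
    "variance_components",
    "coefficients_of_variation",
    "heritability_broad",
    "genetic_advance",
    "genetic_parameter_table",
    "parameters_to_frame",
]

#: Standardized selection differential at 5% selection intensity.
DEFAULT_SELECTION_K = 2.063


def variance_components(msg: float, mse: float, r: int) -> tuple[float, float, float, bool]:
    """Genotypic, environmental and phenotypic variances from mean squares.

    Returns ``(sigma2_g, sigma2_e, sigma2_p, truncated)`` where ``truncated``
    reports that a negative moment estimate ``(MSG - MSE)/r`` was clipped
    to zero (keeps h2 inside [0, 100]).
    """
    if msg < 0 or mse < 0:
        raise GourdstatsError("mean squares must be non-negative")
    if r < 1:
        raise GourdstatsError(f"replications r must be >= 1, got {r}")
    raw = (msg - mse) / r
    truncated = raw < 0
    sigma2_g = max(raw, 0.0)
    sigma2_e = mse
    return sigma2_g, sigma2_e, sigma2_g + sigma2_e, truncated


def coefficients_of_variation(
    sigma2_g: float, sigma2_e: float, grand_mean: float
) -> tuple[float, float, float]:
    """(PCV, GCV, ECV) in percent: sqrt(variance) / grand mean x 100."""
    if grand_mean <= 0:
        raise GourdstatsError("grand mean must be positive for a CV")
    sigma2_p = sigma2_g + sigma2_e
    pcv = np.sqrt(sigma2_p) / grand_mean * 100.0
    gcv = np.sqrt(sigma2_g) / grand_mean * 100.0
    ecv = np.sqrt(sigma2_e) / grand_mean * 100.0
    return float(pcv), float(gcv), float(ecv)


def heritability_broad(sigma2_g: float, sigma2_p: float) -> tuple[float, bool]:
    """Broad-sense heritability in percent and its > 50% significance call.

    Undefined (NaN, not significant) when the phenotypic variance is zero.
    """
    if sigma2_p == 0:
        return float("nan"), False
    h2 = sigma2_g / sigma2_p * 100.0
    return float(h2), h2 > 50.0


def genetic_advance(
    sigma2_g: float,
    sigma2_p: float,
    grand_mean: float,
    k: float = DEFAULT_SELECTION_K,
) -> tuple[float, float]:
    """Expected genetic advance ``GA = k sigma2_g / sqrt(sigma2_p)``.

    Returns GA in trait units and as a percentage of the grand mean.
    With no genotypic variance GA is zero regardless of sigma2_p.
    """
    if sigma2_g == 0:
        return 0.0, 0.0
    if sigma2_p <= 0:
        raise GourdstatsError("sigma2_p must be positive when sigma2_g > 0")
    ga = k * sigma2_g / np.sqrt(sigma2_p)
    ga_pct = ga / grand_mean * 100.0 if grand_mean > 0 else float("nan")
    return float(ga), float(ga_pct)


@dataclass(frozen=True)
class VarianceComponents:
    """One trait's full genetic-parameter record (one report-table row)."""

    trait: str
    msg: float
    mse: float
    r: int
    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    grand_mean: float
    pcv: float
    gcv: float
    ecv: float
    h2: float
    h2_significant: bool
    ga: float
    ga_percent_mean: float
    k: float
    negative_truncated: bool

    @classmethod
    def from_mean_squares(
        cls,
        trait: str,
        msg: float,
        mse: float,
        r: int,
        grand_mean: float,
        k: float = DEFAULT_SELECTION_K,
    ) -> "VarianceComponents":
        s2g, s2e, s2p, truncated = variance_components(msg, mse, r)
        pcv, gcv, ecv = coefficients_of_variation(s2g, s2e, grand_mean)
        h2, h2_sig = heritability_broad(s2g, s2p)
        ga, ga_pct = genetic_advance(s2g, s2p, grand_mean, k=k) if s2p > 0 else (0.0, 0.0)
        return cls(
            trait=trait, msg=msg, mse=mse, r=r,
            sigma2_g=s2g, sigma2_e=s2e, sigma2_p=s2p,
            grand_mean=grand_mean, pcv=pcv, gcv=gcv, ecv=ecv,
            h2=h2, h2_significant=h2_sig, ga=ga, ga_percent_mean=ga_pct,
            k=k, negative_truncated=truncated,
        )


def _plot_mean_matrix(table: pd.DataFrame, trait: str, stages: Sequence[str] | None):
    """Genotype x block matrix of plot means (averaged over reps and stages)."""
    sub = table[(table["trait"] == trait) & table["value"].notna()]
    if stages is not None:
        sub = sub[sub["stage"].isin(list(stages))]
    if sub.empty:
        return None, None
    # average reps within each stage cell, then stages, so stages weigh equally
    per_stage = sub.groupby(["landrace", "block", "stage"], sort=True)["value"].mean()
    plot = per_stage.groupby(["landrace", "block"]).mean().unstack("block")
    complete = plot.dropna(axis=0, how="any")
    dropped = sorted(set(plot.index) - set(complete.index))
    return complete, dropped


def genetic_parameter_table(
    table: pd.DataFrame,
    traits: Iterable[str] | None = None,
    stages: Sequence[str] | None = None,
    k: float = DEFAULT_SELECTION_K,
) -> list[VarianceComponents]:
    """Estimate genetic parameters for each trait of a long-format table.

    Per trait: genotype x block plot means (replication unit = block, so
    ``r`` is the block count) feed an RCBD ANOVA whose MSG/MSE yield the
    variance components; the grand mean is the mean of all present raw
    values.  Genotypes with an incomplete block profile are excluded
    available-case; traits with fewer than two genotypes are skipped with
    a warning.
    """
    if traits is None:
        traits = list(pd.unique(table["trait"]))
    out: list[VarianceComponents] = []
    for trait in traits:
        plot, dropped = _plot_mean_matrix(table, trait, stages)
        if plot is None or plot.shape[0] < 2 or plot.shape[1] < 2:
            warnings.warn(
                f"trait {trait!r}: fewer than 2 complete genotypes/blocks; skipped",
                stacklevel=2,
            )
            continue
        if dropped:
            warnings.warn(
                f"trait {trait!r}: excluded genotypes with incomplete blocks: "
                f"{dropped}",
                stacklevel=2,
            )
        anova = rcbd_anova(plot.to_numpy())
        sub = table[(table["trait"] == trait) & table["value"].notna()]
        if stages is not None:
            sub = sub[sub["stage"].isin(list(stages))]
        grand_mean = float(sub["value"].mean())
        out.append(
            VarianceComponents.from_mean_squares(
                trait=trait,
                msg=anova.msg,
                mse=anova.mse,
                r=plot.shape[1],
                grand_mean=grand_mean,
                k=k,
            )
        )
    return out


def parameters_to_frame(rows: Sequence[VarianceComponents]) -> pd.DataFrame:
    """Tabulate parameter rows in the conventional report-column order."""
    return pd.DataFrame(
        [
            {
                "trait": v.trait,
                "sigma2_g": v.sigma2_g,
                "sigma2_e": v.sigma2_e,
                "sigma2_p": v.sigma2_p,
                "grand_mean": v.grand_mean,
                "pcv": v.pcv,
                "gcv": v.gcv,
                "ecv": v.ecv,
                "h2": v.h2,
                "ga": v.ga,
                "msg": v.msg,
                "mse": v.mse,
                "r": v.r,
                "ga_percent_mean": v.ga_percent_mean,
                "h2_significant": v.h2_significant,
                "negative_truncated": v.negative_truncated,
            }
            for v in rows
        ]
    )
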