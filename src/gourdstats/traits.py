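"""Trait-table I/O, derived traits and cell-mean aggregation.

The universal data carrier is a long-format :class:`pandas.DataFrame` with
columns ``landrace, block, stage, trait, rep, value``; a missing value is a
real NaN (written as an empty CSV field), never a sentinel number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DataFormatError, GourdstatsError

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trait_table",
    "write_trait_table",
    "moisture_content",
    "derive_moisture",
    "cell_means",
    "cell_mean_matrix",
    "landrace_trait_means",
]

REQUIRED_COLUMNS = ("landrace", "block", "stage", "trait", "rep", "value")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trait table from CSV.

    Empty ``value`` fields become NaN (explicit missing).  A missing required
    column raises :class:`DataFormatError` naming the column; a non-numeric
    value raises :class:`DataFormatError` with the 1-based data row number.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise DataFormatError(f"required column {col!r} missing from {path}")
    value_str = raw["value"].str.strip()
    stripped = value_str.replace("", np.nan)
    try:
        # numpy's strtod is correctly rounded, so written tables re-read exactly
        value = stripped.astype(float)
    except (ValueError, TypeError):
        coerced = pd.to_numeric(stripped, errors="coerce")
        bad = coerced.isna() & stripped.notna()
        row = int(bad.idxmax()) + 1
        raise DataFormatError(
            f"non-numeric value {value_str[bad.idxmax()]!r} at data row {row}"
        ) from None
    try:
        rep = pd.to_numeric(raw["rep"]).astype(int)
    except (ValueError, TypeError) as exc:
        raise DataFormatError(f"non-integer rep field: {exc}") from exc
    table = pd.DataFrame(
        {
            "landrace": raw["landrace"],
            "block": raw["block"],
            "stage": raw["stage"],
            "trait": raw["trait"],
            "rep": rep,
            "value": value.astype(float),
        }
    )
    dup = table.duplicated(subset=["landrace", "block", "stage", "trait", "rep"])
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise DataFormatError(f"duplicate observation key at data row {row}")
    return table


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trait table to CSV; missing values become empty fields."""
    table.to_csv(path, index=False, na_rep="")


def moisture_content(fresh_mass, dry_mass):
    """Moisture content in percent: ``(fresh - dry) / fresh * 100``.

    Accepts scalars or arrays.  Requires ``fresh_mass > 0`` and
    ``0 <= dry_mass <= fresh_mass``; the result lies in [0, 100] and is
    invariant to rescaling both masses by the same positive factor.
    """
    fresh = np.asarray(fresh_mass, dtype=float)
    dry = np.asarray(dry_mass, dtype=float)
    if np.any(fresh <= 0):
        raise GourdstatsError("fresh mass must be positive")
    if np.any(dry < 0) or np.any(dry > fresh):
        raise GourdstatsError("dry mass must lie in [0, fresh mass]")
    out = (fresh - dry) / fresh * 100.0
    if out.ndim == 0:
        return float(out)
    return out


def derive_moisture(
    table: pd.DataFrame,
    fresh_trait: str = "SFM",
    dry_trait: str = "SDM",
    out_trait: str = "SMC",
) -> pd.DataFrame:
    """Append per-sample moisture-content records derived from mass pairs.

    Fresh/dry records are matched on (landrace, block, stage, rep).  The
    ratio is computed per sample, not from mean masses — the two differ, and
    per-sample averaging is the aggregation the downstream cell means use.
    Pairs where either mass is missing, the fresh mass is non-positive or
    the dry mass exceeds the fresh mass yield a missing derived value.
    """
    key = ["landrace", "block", "stage", "rep"]
    fresh = table[table["trait"] == fresh_trait].set_index(key)["value"]
    dry = table[table["trait"] == dry_trait].set_index(key)["value"]
    common = fresh.index.intersection(dry.index)
    f = fresh.loc[common].to_numpy(dtype=float)
    d = dry.loc[common].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        smc = (f - d) / f * 100.0
    invalid = ~np.isfinite(smc) | (f <= 0) | (d < 0) | (d > f)
    smc = np.where(invalid, np.nan, smc)
    derived = pd.DataFrame(common.to_frame(index=False))
    derived["trait"] = out_trait
    derived["value"] = smc
    derived = derived[["landrace", "block", "stage", "trait", "rep", "value"]]
    return pd.concat([table, derived], ignore_index=True)


def cell_means(
    table: pd.DataFrame,
    trait: str | None = None,
    stage: str | None = None,
) -> pd.DataFrame:
    """Per-landrace cell means over present values.

    Returns a DataFrame with columns ``landrace, trait, stage, mean, n``.
    ``n`` counts the contributing (non-missing) observations; a cell with
    ``n == 0`` has a missing mean.  Order of input records is irrelevant.
    """
    sub = table
    if trait is not None:
        sub = sub[sub["trait"] == trait]
    if stage is not None:
        sub = sub[sub["stage"] == stage]
    grouped = sub.groupby(["landrace", "trait", "stage"], sort=True)["value"]
    out = grouped.agg(mean="mean", n="count").reset_index()
    out["n"] = out["n"].astype(int)
    return out


def cell_mean_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Landrace x (trait, stage) matrices of cell means and their n."""
    cm = cell_means(table)
    means = cm.pivot(index="landrace", columns=["trait", "stage"], values="mean")
    counts = cm.pivot(index="landrace", columns=["trait", "stage"], values="n").fillna(0).astype(int)
    return means, counts


def landrace_trait_means(
    table: pd.DataFrame, traits: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-landrace trait summaries: stage-level cell means averaged over stages.

    Each stage contributes equally (mean of available cell means), so
    unequal within-cell replication does not skew the summary.  Landraces
    with no data for a trait are missing for that column.
    """
    cm = cell_means(table)
    if traits is not None:
        cm = cm[cm["trait"].isin(list(traits))]
    agg = cm.groupby(["landrace", "trait"], sort=True)["mean"].mean().reset_index()
    wide = agg.pivot(index="landrace", columns="trait", values="mean")
    if traits is not None:
        wide = wide[[t for t in traits if t in wide.columns]]
    wide.columns.name = None
    return wide
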