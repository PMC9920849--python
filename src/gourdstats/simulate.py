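"""Synthetic randomized-complete-block (RCBD) trial generator.

Emulates a multi-trait, multi-stage bottle gourd field trial: genotypes
(landraces) replicated across blocks, with repeated measurements per plot at
a sequence of growth stages.  Every observation follows the additive model

    y_ijks = mu + tau_s + g_i + b_j + (gs)_is + eps_ijks

with g_i ~ N(0, sigma2_g) drawn once per landrace, b_j ~ N(0, sigma2_b) once
per block, an optional genotype-by-stage interaction (gs)_is ~ N(0,
sigma2_gxs), and i.i.d. residuals eps ~ N(0, sigma2_e).  Because the true
variance components are configuration inputs, every downstream estimator can
be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "TraitSpec",
    "TrialConfig",
    "TruthComponents",
    "simulate_trait_table",
    "apply_missingness",
    "simulate_trial",
    "truth_components",
    "default_trial_config",
    "REFERENCE_LANDRACES",
    "SHOOT_STAGES",
    "INTACT_STAGES",
    "HARVEST_STAGES",
]

#: The 18 landrace labels of the reference field trial.
REFERENCE_LANDRACES: tuple[str, ...] = (
    "KSP", "KSC", "KRI", "NRC", "NSRC", "NSRP", "NqSC", "DSI", "ESC",
    "BG-19", "BG-24", "BG-26", "BG-27", "BG-31", "BG-70", "BG-80", "BG-81",
    "BG-100/GC",
)

#: Shoot harvest stages, days after sowing.
SHOOT_STAGES: tuple[str, ...] = ("42 DAS", "49 DAS", "56 DAS", "63 DAS")
#: Intact-fruit measurement stages, days after anthesis.
INTACT_STAGES: tuple[str, ...] = (
    "0 DAA", "1 DAA", "2 DAA", "3 DAA", "4 DAA", "5 DAA",
)
#: Harvested-fruit stages, days after anthesis.
HARVEST_STAGES: tuple[str, ...] = ("7 DAA", "14 DAA", "21 DAA", "28 DAA")


@dataclass(frozen=True)
class TraitSpec:
    """Per-trait simulation parameters.

    Parameters
    ----------
    mu
        Grand mean, in the trait's units.
    sigma2_g
        Genotypic variance between landraces.
    sigma2_e
        Residual (environmental) variance of a single measurement.
    sigma2_b
        Block (plot) variance; defaults to 0.
    sigma2_gxs
        Genotype-by-stage interaction variance; defaults to 0.
    stages
        Stage axis for this trait; falls back to the trial-level axis.
    stage_effects
        Additive offset per stage, aligned with ``stages``; default all zero.
    """

    mu: float
    sigma2_g: float
    sigma2_e: float
    sigma2_b: float = 0.0
    sigma2_gxs: float = 0.0
    stages: tuple[str, ...] | None = None
    stage_effects: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_e", "sigma2_b", "sigma2_gxs"):
            v = getattr(self, name)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ConfigurationError(
                    f"{name} must be a finite non-negative variance, got {v!r}"
                )
        if self.stages is not None and len(set(self.stages)) != len(self.stages):
            raise ConfigurationError("trait stage labels must be unique")
        if self.stage_effects is not None and self.stages is not None:
            if len(self.stage_effects) != len(self.stages):
                raise ConfigurationError(
                    "stage_effects must align one-to-one with stages"
                )


@dataclass(frozen=True)
class TrialConfig:
    """Full description of one simulated RCBD trial.

    ``missing_spec`` maps ``(landrace, stage)`` pairs to the probability that
    the whole cell (every block and replicate, every trait measured at that
    stage) is unobservable — mirroring non-harvestable shoots and aborted
    fruits in real trials.
    """

    traits: Mapping[str, TraitSpec]
    stages: tuple[str, ...] = SHOOT_STAGES
    n_landraces: int = 18
    n_blocks: int = 3
    n_within: int = 10
    landraces: tuple[str, ...] | None = None
    genetic_correlation: float = 0.0
    missing_spec: Mapping[tuple[str, str], float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landraces < 2:
            raise ConfigurationError("need at least 2 landraces")
        if self.n_blocks < 2:
            raise ConfigurationError("need at least 2 blocks")
        if self.n_within < 1:
            raise ConfigurationError("n_within must be >= 1")
        if not self.traits:
            raise ConfigurationError("at least one trait is required")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigurationError("stage labels must be unique")
        if not -1.0 <= self.genetic_correlation <= 1.0:
            raise ConfigurationError("genetic_correlation must lie in [-1, 1]")
        if self.landraces is not None and len(self.landraces) != self.n_landraces:
            raise ConfigurationError(
                "landraces list length must equal n_landraces"
            )
        for key, p in self.missing_spec.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"missingness probability for {key} outside [0, 1]: {p}"
                )

    def landrace_labels(self) -> tuple[str, ...]:
        if self.landraces is not None:
            return tuple(self.landraces)
        return tuple(f"LR{i + 1:02d}" for i in range(self.n_landraces))

    def block_labels(self) -> tuple[str, ...]:
        return tuple(f"B{j + 1}" for j in range(self.n_blocks))

    def trait_stages(self, trait: str) -> tuple[str, ...]:
        spec = self.traits[trait]
        return tuple(spec.stages) if spec.stages is not None else tuple(self.stages)


@dataclass(frozen=True)
class TruthComponents:
    """Configured (true) variance components for one trait."""

    sigma2_g: float
    sigma2_e: float

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_e

    @property
    def h2(self) -> float:
        """True broad-sense heritability in percent; 0 when both variances vanish."""
        if self.sigma2_p == 0.0:
            return 0.0
        return self.sigma2_g / self.sigma2_p * 100.0


def simulate_trait_table(config: TrialConfig) -> pd.DataFrame:
    """Draw a complete long-format trait table (no missingness applied).

    Returns a DataFrame with columns ``landrace, block, stage, trait, rep,
    value`` holding exactly ``n_landraces * n_blocks * n_within *
    sum(len(stages per trait))`` records.  Genotype effects are drawn once
    per (trait, landrace) and block effects once per (trait, block); with
    ``genetic_correlation`` rho > 0 the genotype effects of different traits
    share a common landrace factor, inducing cross-trait correlation rho at
    the genetic level.  Bit-identical output for identical ``rng_seed``.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    sim_seed, _ = ss.spawn(2)
    rng = np.random.default_rng(sim_seed)

    landraces = config.landrace_labels()
    blocks = config.block_labels()
    n_l, n_b, n_w = config.n_landraces, config.n_blocks, config.n_within
    rho = config.genetic_correlation

    shared_u = rng.standard_normal(n_l)
    frames: list[pd.DataFrame] = []
    for trait in config.traits:
        spec = config.traits[trait]
        stages = config.trait_stages(trait)
        effects = spec.stage_effects if spec.stage_effects is not None else (0.0,) * len(stages)
        if len(effects) != len(stages):
            raise ConfigurationError(
                f"stage_effects for trait {trait!r} must align with its stages"
            )
        own_v = rng.standard_normal(n_l)
        g = math.sqrt(spec.sigma2_g) * (
            rho * shared_u + math.sqrt(1.0 - rho * rho) * own_v
        )
        b = math.sqrt(spec.sigma2_b) * rng.standard_normal(n_b)
        gxs = (
            math.sqrt(spec.sigma2_gxs) * rng.standard_normal((n_l, len(stages)))
            if spec.sigma2_gxs > 0.0
            else np.zeros((n_l, len(stages)))
        )
        for s_idx, stage in enumerate(stages):
            eps = math.sqrt(spec.sigma2_e) * rng.standard_normal((n_l, n_b, n_w))
            values = (
                spec.mu
                + effects[s_idx]
                + g[:, None, None]
                + b[None, :, None]
                + gxs[:, s_idx, None, None]
                + eps
            )
            frames.append(
                pd.DataFrame(
                    {
                        "landrace": np.repeat(landraces, n_b * n_w),
                        "block": np.tile(np.repeat(blocks, n_w), n_l),
                        "stage": stage,
                        "trait": trait,
                        "rep": np.tile(np.arange(1, n_w + 1), n_l * n_b),
                        "value": values.ravel(),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return table


def apply_missingness(
    table: pd.DataFrame,
    missing_spec: Mapping[tuple[str, str], float],
    rng_seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Blank out whole landrace-stage cells with the configured probabilities.

    One Bernoulli draw per (landrace, stage) key decides the fate of the
    entire cell: every block, replicate and trait observed at that stage.
    This reproduces the all-or-nothing NA pattern of field trials where a
    landrace's shoots are simply not harvestable at a stage.  Deterministic
    given ``rng_seed``; keys are processed in sorted order.
    """
    for key, p in missing_spec.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(
                f"missingness probability for {key} outside [0, 1]: {p}"
            )
    out = table.copy()
    rng = np.random.default_rng(rng_seed)
    for (landrace, stage), p in sorted(missing_spec.items()):
        u = rng.random()
        if u < p:
            mask = (out["landrace"] == landrace) & (out["stage"] == stage)
            out.loc[mask, "value"] = np.nan
    return out


def simulate_trial(config: TrialConfig) -> pd.DataFrame:
    """Simulate a trial and apply the configured missingness in one call."""
    table = simulate_trait_table(config)
    if not config.missing_spec:
        return table
    _, miss_seed = np.random.SeedSequence(config.rng_seed).spawn(2)
    return apply_missingness(table, config.missing_spec, miss_seed)


def truth_components(config: TrialConfig, trait: str) -> TruthComponents:
    """Configured true variance components for ``trait`` (recovery targets)."""
    if trait not in config.traits:
        raise KeyError(f"unknown trait {trait!r}")
    spec = config.traits[trait]
    return TruthComponents(sigma2_g=spec.sigma2_g, sigma2_e=spec.sigma2_e)


def default_trial_config(seed: int = 0, genetic_correlation: float = 0.0) -> TrialConfig:
    """The reference trial conditions: 18 landraces x 3 blocks x 10 samples.

    Shoot traits (SL, SW, SFM, SDM) are observed at 42-63 DAS; peduncle and
    fruit dimensions (PL, PW, FL, FW) at 0-5 DAA (intact) and 7-28 DAA
    (harvested); fruit mass (FM) at harvested stages only.  Per-trait grand
    means and variance components follow the reference trial's reported
    genetic-parameter table; stage offsets reproduce the reported growth
    trends (shoots elongating, peduncles shortening, fruits expanding).
    Shoot moisture content (SMC) is not simulated — it is derived from
    SFM/SDM pairs by :func:`gourdstats.traits.derive_moisture`.
    """
    all_daa = INTACT_STAGES + HARVEST_STAGES
    traits = {
        "SL": TraitSpec(mu=312.1, sigma2_g=7296.5, sigma2_e=4156.0,
                        stages=SHOOT_STAGES,
                        stage_effects=(-30.0, -10.0, 10.0, 30.0)),
        "SW": TraitSpec(mu=0.7, sigma2_g=0.1, sigma2_e=0.09,
                        stages=SHOOT_STAGES),
        "SFM": TraitSpec(mu=16.4, sigma2_g=47.4, sigma2_e=35.0,
                         stages=SHOOT_STAGES,
                         stage_effects=(-2.0, -0.5, 0.5, 2.0)),
        "SDM": TraitSpec(mu=1.8, sigma2_g=0.4, sigma2_e=0.3,
                         stages=SHOOT_STAGES,
                         stage_effects=(-0.2, 0.0, 0.0, 0.2)),
        "PL": TraitSpec(mu=4.1, sigma2_g=5.2, sigma2_e=1.8,
                        stages=all_daa,
                        stage_effects=(2.0, 1.2, 0.6, 0.0, -0.6, -1.2,
                                       1.5, 0.5, -0.5, -1.5)),
        "PW": TraitSpec(mu=0.4, sigma2_g=3.1e-2, sigma2_e=5.6e-3,
                        stages=all_daa,
                        stage_effects=(-0.15, -0.09, -0.03, 0.03, 0.09, 0.15,
                                       -0.10, 0.00, 0.05, 0.10)),
        "FL": TraitSpec(mu=3.3, sigma2_g=3.4, sigma2_e=1.9,
                        stages=all_daa,
                        stage_effects=(-1.5, -0.9, -0.3, 0.3, 0.9, 1.5,
                                       0.5, 1.0, 1.5, 2.0)),
        "FW": TraitSpec(mu=2.0, sigma2_g=1.2, sigma2_e=0.6,
                        stages=all_daa,
                        stage_effects=(-0.9, -0.55, -0.2, 0.15, 0.5, 0.9,
                                       0.3, 0.6, 0.9, 1.2)),
        "FM": TraitSpec(mu=0.6, sigma2_g=0.2, sigma2_e=1.7e-2,
                        stages=HARVEST_STAGES,
                        stage_effects=(-0.15, -0.05, 0.05, 0.15)),
    }
    missing: dict[tuple[str, str], float] = {("BG-19", "42 DAS"): 1.0}
    for s in SHOOT_STAGES:
        missing[("NSRC", s)] = 1.0
    for lr in ("NqSC", "NRC", "NSRC"):
        for s in all_daa:
            missing[(lr, s)] = 0.35
    return TrialConfig(
        traits=traits,
        stages=SHOOT_STAGES,
        n_landraces=18,
        n_blocks=3,
        n_within=10,
        landraces=REFERENCE_LANDRACES,
        genetic_correlation=genetic_correlation,
        missing_spec=missing,
        rng_seed=seed,
    )
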