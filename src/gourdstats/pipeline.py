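"""End-to-end orchestration: simulate/read -> derive -> analyze -> report.

One :func:`run_pipeline` call produces the full set of report artifacts —
mean-separation tables, stagewise and combined correlation matrices, the
PCA eigenvalue/loading/score tables, the UPGMA dendrogram in Newick form
and the genetic-parameter table — plus a JSON manifest recording the
configuration hash, seeds, applied thresholds and per-stage record counts.
Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anova import mean_separation
from .correlate import combined_correlations, staged_correlations
from .exceptions import ConfigurationError
from .genetics import DEFAULT_SELECTION_K, genetic_parameter_table, parameters_to_frame
from .multivariate import (
    euclidean_dissimilarity,
    kaiser_retain,
    mean_impute,
    pca_correlation,
    significant_loadings,
    tree_to_newick,
    upgma,
    zscore_standardize,
)
from .simulate import TraitSpec, TrialConfig, default_trial_config, simulate_trial
from .traits import derive_moisture, landrace_trait_means, read_trait_table, write_trait_table

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and inputs for one reproducible pipeline run."""

    output_dir: str | Path = "gourdstats_run"
    input_path: str | Path | None = None  # CSV; None -> simulate
    trial: TrialConfig | None = None  # None -> default reference trial
    seed: int = 0
    alpha: float = 0.05
    loading_threshold: float = 0.6
    correlation_threshold: float = 0.6
    kaiser_boundary: float = 1.0
    selection_k: float = DEFAULT_SELECTION_K
    derive_moisture_trait: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        for name in ("loading_threshold", "correlation_threshold",
                     "kaiser_boundary", "selection_k"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class RunReport:
    """Paths and summaries produced by one pipeline run."""

    output_dir: Path
    manifest: dict
    files: dict[str, Path] = field(default_factory=dict)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["output_dir"] = str(d["output_dir"])
    if d["input_path"] is not None:
        d["input_path"] = str(d["input_path"])
    if d["trial"] is not None:
        d["trial"]["missing_spec"] = {
            f"{lr}|{st}": p for (lr, st), p in d["trial"]["missing_spec"].items()
        }
    return d


def _config_hash(config: RunConfig) -> str:
    # the hash covers everything that affects the analysis; the output
    # directory is location, not configuration
    payload = _config_dict(config)
    payload.pop("output_dir")
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig (and optional nested trial config) from YAML/JSON."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    trial = None
    if "trial" in raw and raw["trial"] is not None:
        t = dict(raw.pop("trial"))
        traits = {
            name: TraitSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in spec.items()
            })
            for name, spec in t.pop("traits").items()
        }
        missing = {
            tuple(key.split("|", 1)): p
            for key, p in (t.pop("missing_spec", {}) or {}).items()
        }
        for name in ("stages", "landraces"):
            if t.get(name) is not None:
                t[name] = tuple(t[name])
        trial = TrialConfig(traits=traits, missing_spec=missing, **t)
    return RunConfig(trial=trial, **raw)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every analysis stage and write the report artifacts.

    Stage order: obtain data (simulate or read CSV), derive moisture
    content, joint landrace-x-stage mean separation per trait, stagewise
    and combined correlations, correlation PCA with Kaiser retention,
    UPGMA clustering (Newick export), genetic parameters, manifest.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(output_dir=outdir, manifest={})
    log: list[dict] = []
    caught: list[str] = []

    if config.input_path is not None:
        table = read_trait_table(config.input_path)
        source = str(config.input_path)
    else:
        trial = config.trial
        if trial is None:
            trial = default_trial_config(seed=config.seed)
        elif trial.rng_seed != config.seed:
            trial = dataclasses.replace(trial, rng_seed=config.seed)
        table = simulate_trial(trial)
        source = "simulated"
    log.append({"stage": "input", "records": int(len(table)),
                "present": int(table["value"].notna().sum())})

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        if config.derive_moisture_trait and {"SFM", "SDM"} <= set(table["trait"]):
            table = derive_moisture(table)
            log.append({"stage": "derive_moisture", "records": int(len(table))})
        data_path = outdir / "trait_table.csv"
        write_trait_table(table, data_path)
        report.files["trait_table"] = data_path

        sep_frames = []
        for trait in sorted(table["trait"].unique()):
            sep = mean_separation(table, trait, alpha=config.alpha)
            sep.insert(0, "trait", trait)
            sep_frames.append(sep)
        separation = pd.concat(sep_frames, ignore_index=True)
        sep_path = outdir / "mean_separation.csv"
        separation.to_csv(sep_path, index=False, float_format="%.6g")
        report.files["mean_separation"] = sep_path
        log.append({"stage": "mean_separation", "cells": int(len(separation))})

        staged_rows = []
        for stage in sorted(table["stage"].unique()):
            cm = staged_correlations(table, stage)
            r_long = cm.r.stack().rename("r").reset_index()
            r_long.columns = ["trait_a", "trait_b", "r"]
            r_long = r_long[r_long["trait_a"] < r_long["trait_b"]]
            r_long.insert(0, "stage", stage)
            r_long["n"] = [
                cm.n.loc[a, b] for a, b in zip(r_long["trait_a"], r_long["trait_b"])
            ]
            r_long["p"] = [
                cm.p.loc[a, b] for a, b in zip(r_long["trait_a"], r_long["trait_b"])
            ]
            r_long["stars"] = [
                cm.stars.loc[a, b] for a, b in zip(r_long["trait_a"], r_long["trait_b"])
            ]
            staged_rows.append(r_long)
        staged = pd.concat(staged_rows, ignore_index=True)
        staged_path = outdir / "correlations_staged.csv"
        staged.to_csv(staged_path, index=False, float_format="%.6g")
        report.files["correlations_staged"] = staged_path
        log.append({"stage": "correlations_staged", "pairs": int(len(staged))})

        lmeans = landrace_trait_means(table)
        combined = combined_correlations(
            landrace_means=lmeans, flag_threshold=config.correlation_threshold
        )
        comb = combined.r.round(6)
        comb_path = outdir / "correlations_combined.csv"
        flagged = combined.flagged.copy()
        comb.to_csv(comb_path)
        report.files["correlations_combined"] = comb_path
        log.append({"stage": "correlations_combined",
                    "flagged_pairs": int((flagged.to_numpy().sum() - len(comb)) // 2)})

        imputed = mean_impute(lmeans)
        pca = pca_correlation(imputed)
        eig = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(pca.eigenvalues))],
                "eigenvalue": pca.eigenvalues,
                "variability_pct": pca.variability,
                "cumulative_pct": pca.cumulative,
                "retained": [
                    i in set(kaiser_retain(pca.eigenvalues, config.kaiser_boundary))
                    for i in range(len(pca.eigenvalues))
                ],
            }
        )
        eig_path = outdir / "pca_eigenvalues.csv"
        eig.to_csv(eig_path, index=False, float_format="%.6g")
        load_path = outdir / "pca_loadings.csv"
        loadings = pca.loadings.round(6).copy()
        mask = significant_loadings(pca, config.loading_threshold)
        for col in mask.columns:
            loadings[f"{col}_significant"] = mask[col]
        loadings.to_csv(load_path)
        scores_path = outdir / "pca_scores.csv"
        pca.scores.round(6).to_csv(scores_path)
        report.files["pca_eigenvalues"] = eig_path
        report.files["pca_loadings"] = load_path
        report.files["pca_scores"] = scores_path
        log.append({"stage": "pca", "retained": len(pca.retained)})

        Z = zscore_standardize(imputed)
        D = euclidean_dissimilarity(Z)
        tree = upgma(D)
        nwk_path = outdir / "dendrogram.nwk"
        nwk_path.write_text(tree_to_newick(tree) + "\n")
        report.files["dendrogram"] = nwk_path
        log.append({"stage": "upgma", "leaves": tree.n_leaves})

        params = genetic_parameter_table(table, k=config.selection_k)
        params_frame = parameters_to_frame(params)
        params_path = outdir / "genetic_parameters.csv"
        params_frame.to_csv(params_path, index=False, float_format="%.6g")
        report.files["genetic_parameters"] = params_path
        log.append({"stage": "genetic_parameters", "traits": int(len(params_frame))})

        caught = sorted({str(w.message) for w in wlist})

    manifest = {
        "package_version": __version__,
        "source": source,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "thresholds": {
            "alpha": config.alpha,
            "loading_threshold": config.loading_threshold,
            "correlation_threshold": config.correlation_threshold,
            "kaiser_boundary": config.kaiser_boundary,
            "selection_k": config.selection_k,
        },
        "stages": log,
        "warnings": caught,
        "files": {k: str(v.name) for k, v in report.files.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    report.files["manifest"] = manifest_path
    report.manifest = manifest
    return report
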