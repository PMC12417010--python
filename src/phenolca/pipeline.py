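"""End-to-end phenotyping pipeline and its file interfaces.

Orchestrates: cohort generation or loading -> multiple imputation ->
standardization -> mixture fits over a class-count range -> metric table
and composite selection -> stability analyses -> parsimonious model ->
outcome comparison. Every stochastic stage draws its seed from a named
substream of the single global seed, recorded in the run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import engine, impute, outcomes, parsimonious, selection, stability

__all__ = ["PipelineConfig", "run_pipeline", "validate_input", "stage_seed"]

_STAGES = ("synthetic", "impute", "em", "vlmr", "stability", "parsimonious")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=(int(global_seed), _STAGES.index(stage)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    seed: int = 0
    output_dir: str = "phenolca_run"
    # input: either CSV paths or synthetic generation
    cohort_csv: str | None = None
    dictionary_csv: str | None = None
    synthetic: bool = True
    inject_missing: bool = True
    # analysis
    k_min: int = 1
    k_max: int = 6
    structure: str = "diagonal-varying"
    n_starts: int = 20
    # imputation
    m_imputations: int = 5
    n_cycles: int = 10
    # selection
    min_class_fraction: float = 0.05
    vlmr_alpha: float = 0.05
    bic_tolerance: float = 20.0
    vlmr_mode: str = "bootstrap"
    n_boot: int = 49
    n_refits: int = 20
    # stability
    n_stability_sims: int = 200
    n_sensitivity_starts: int = 20
    # parsimonious
    max_vars: int = 6
    n_folds: int = 5
    run_stability: bool = True
    run_parsimonious: bool = True
    run_outcomes: bool = True
    follow_up_days: int = 90

    def __post_init__(self) -> None:
        if self.k_min != 1:
            raise ValueError("the class-count range must start at 1")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def validate_input(cohort_csv, dictionary_csv) -> pd.DataFrame:
    """Validate a cohort CSV against its data dictionary.

    Checks roster completeness, numeric parsing, duplicate ids and that no
    outcome column is tagged class-defining; returns the parsed table.
    """
    table = pd.read_csv(cohort_csv)
    dictionary = pd.read_csv(dictionary_csv)
    missing_cols = [n for n in dictionary["name"] if n not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV lacks dictionary column(s): {missing_cols}")
    if "patient_id" in table.columns and table["patient_id"].duplicated().any():
        dup = table.loc[table["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient_id {dup!r}")
    class_defining = dictionary.loc[
        dictionary["role"] == "class_defining", "name"].tolist()
    bad_roles = [n for n in class_defining
                 if n in cohort_mod.OUTCOME_COLUMNS]
    if bad_roles:
        raise ValueError(f"outcome column(s) tagged class_defining: {bad_roles}")
    for name in class_defining:
        col = pd.to_numeric(table[name], errors="coerce")
        newly_bad = col.isna() & table[name].notna()
        if newly_bad.any():
            raise ValueError(f"non-numeric cell in column {name!r}")
        table[name] = col
        if col.notna().sum() and col.dropna().nunique() == 1:
            import warnings

            warnings.warn(f"class-defining column {name!r} is constant",
                          stacklevel=2)
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    params = cohort_mod.default_cohort_params()
    try:
        # ---- stage: cohort -------------------------------------------------
        if config.synthetic:
            table = cohort_mod.generate_cohort(
                params, stage_seed(config.seed, "synthetic"))
            if config.inject_missing:
                table = cohort_mod.inject_missingness(
                    table, params.variable_specs,
                    stage_seed(config.seed, "synthetic") + 1)
            cohort_mod.write_cohort(table, params, outdir / "cohort.csv",
                                    outdir / "dictionary.csv")
        else:
            table = validate_input(config.cohort_csv, config.dictionary_csv)
        manifest["stages"]["cohort"] = {"n": int(len(table))}

        roster = cohort_mod.class_defining_names(params)
        roster = [v for v in roster if v in table.columns]
        binary = [v for v in cohort_mod.binary_names(params) if v in roster]
        log_vars = [v for v in cohort_mod.log_scale_names(params)
                    if v in roster]

        # ---- stage: imputation --------------------------------------------
        imputed = impute.mice_impute(
            table, roster, binary=binary, m=config.m_imputations,
            n_cycles=config.n_cycles, seed=stage_seed(config.seed, "impute"))
        for i, t in enumerate(imputed.tables, start=1):
            t.to_csv(outdir / f"imputed_{i}.csv", index=False)
        imputed.mask.to_csv(outdir / "missingness_mask.csv", index=False)
        manifest["stages"]["impute"] = {
            "m": imputed.m,
            "missing_cells": int(imputed.mask.to_numpy().sum()),
        }

        # ---- stage: fit & select ------------------------------------------
        analysis_table = impute.consensus_table(imputed, binary=binary)
        analysis_table.to_csv(outdir / "consensus.csv", index=False)
        data = engine.standardize(analysis_table, roster, binary=binary,
                                  log_vars=log_vars)
        metrics, fits = selection.compute_selection_metrics(
            data, k_max=config.k_max, structure=config.structure,
            n_starts=config.n_starts, seed=stage_seed(config.seed, "em"),
            n_refits=config.n_refits, vlmr_mode=config.vlmr_mode,
            n_boot=config.n_boot)
        # summary CSV: one row per metric, one column per class count
        metrics.drop(columns=["converged"]).T.to_csv(outdir / "metrics_table.csv")
        sel = selection.select_model(
            metrics, min_class_fraction=config.min_class_fraction,
            bic_tolerance=config.bic_tolerance, alpha=config.vlmr_alpha,
            n=data.n)
        best_fit = fits[sel.k]
        (outdir / "selection.json").write_text(json.dumps({
            "selected_k": sel.k, "candidates": sel.candidates,
            "fallback": sel.fallback, "trace": sel.trace,
        }, indent=2))
        (outdir / "model.json").write_text(json.dumps({
            "fit": engine.fit_to_json(best_fit),
            "scaler": _scaler_doc(data),
        }, indent=2))
        manifest["stages"]["selection"] = {
            "selected_k": sel.k, "fallback": sel.fallback,
            "bic": {int(k): float(metrics.loc[k, "bic"]) for k in metrics.index},
        }
        labels = best_fit.labels

        # ---- stage: imputation stability ----------------------------------
        if sel.k > 1:
            imp_stab = impute.imputation_assignment_stability(
                imputed, sel.k, binary=binary, log_vars=log_vars,
                structure=config.structure,
                seed=stage_seed(config.seed, "impute"))
            manifest["stages"]["imputation_stability"] = {
                "agreement": imp_stab}

        # ---- stage: stability ---------------------------------------------
        if config.run_stability and sel.k > 1:
            mc = stability.monte_carlo_stability(
                data, sel.k, n_sims=config.n_stability_sims,
                seed=stage_seed(config.seed, "stability"),
                reference=best_fit, structure=config.structure)
            ms = stability.multi_start_sensitivity(
                data, sel.k, n_starts=config.n_sensitivity_starts,
                seed=stage_seed(config.seed, "stability"),
                structure=config.structure)
            pd.DataFrame({"agreement": mc.agreements}).to_csv(
                outdir / "stability_replicates.csv", index=False)
            (outdir / "stability.json").write_text(json.dumps({
                "monte_carlo": mc.to_dict(),
                "multi_start": ms.to_dict(),
            }, indent=2))
            manifest["stages"]["stability"] = {
                "monte_carlo_agreement": mc.mean_agreement,
                "multi_start_agreement": ms.mean_agreement,
            }
        elif config.run_stability:
            manifest["stages"]["stability"] = {
                "skipped": "single-class model; stability is undefined"}

        # ---- stage: parsimonious ------------------------------------------
        if config.run_parsimonious and sel.k > 1:
            pfit = parsimonious.greedy_forward_selection(
                data, labels, max_vars=config.max_vars,
                n_folds=config.n_folds,
                seed=stage_seed(config.seed, "parsimonious"),
                k=sel.k, structure=config.structure)
            card = pfit.to_dict()
            card["fit"] = engine.fit_to_json(pfit.final_fit)
            card["scaler"] = _scaler_doc(data.select(pfit.selected))
            (outdir / "parsimonious.json").write_text(json.dumps(card, indent=2))
            manifest["stages"]["parsimonious"] = {
                "selected": pfit.selected,
                "cv_accuracy": pfit.cv_accuracy[-1],
            }

        # ---- stage: outcomes ----------------------------------------------
        if config.run_outcomes and sel.k == 2 and config.synthetic:
            summary = outcomes.class_summary(analysis_table, labels,
                                             variables=roster)
            summary.to_csv(outdir / "class_summary.csv")
            times = table["survival_time_days"].to_numpy()
            events = table["death_indicator"].to_numpy()
            curves = {}
            for c in (0, 1):
                curve = outcomes.km_estimate(times[labels == c],
                                             events[labels == c],
                                             config.follow_up_days)
                curves[f"class_{c + 1}"] = curve.to_dict()
            lr_stat, lr_p = outcomes.logrank_test(times, events, labels)
            try:
                hr = outcomes.proportional_hazards(times, events, labels,
                                                   reference=0).to_dict()
            except ValueError as exc:
                hr = {"error": str(exc)}
            (outdir / "survival.json").write_text(json.dumps({
                "curves": curves,
                "logrank": {"statistic": lr_stat, "p_value": lr_p},
                "cox": hr,
            }, indent=2))
            manifest["stages"]["outcomes"] = {
                "logrank_p": lr_p,
                "hazard_ratio": hr.get("hazard_ratio"),
            }
    except Exception as exc:  # partial manifest for debugging
        manifest["error"] = {"stage": _last_stage(manifest), "message": str(exc)}
        manifest["runtime_s"] = time.time() - t0
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["runtime_s"] = time.time() - t0
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _last_stage(manifest: dict) -> str:
    stages = list(manifest.get("stages", {}))
    return stages[-1] if stages else "init"


def _scaler_doc(data: engine.ScaledMatrix) -> dict:
    return {
        "columns": list(data.columns),
        "means": data.means.tolist(),
        "sds": data.sds.tolist(),
        "binary": list(data.binary),
        "log_transformed": list(data.log_transformed),
    }


def assign_classes(model_doc: dict, table: pd.DataFrame) -> pd.DataFrame:
    """Score new patients with a saved (full or parsimonious) model."""
    fit = engine.fit_from_json(model_doc["fit"])
    scaler = model_doc["scaler"]
    X = table[scaler["columns"]].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("assignment requires complete rows for the model's "
                         "variables")
    log_idx = [scaler["columns"].index(c) for c in scaler["log_transformed"]]
    X[:, log_idx] = np.log(X[:, log_idx])
    X = (X - np.asarray(scaler["means"])) / np.asarray(scaler["sds"])
    post = engine.responsibilities(fit, X)
    out = pd.DataFrame({
        "assigned_class": post.argmax(axis=1) + 1,
        "max_posterior": post.max(axis=1),
    })
    if "patient_id" in table.columns:
        out.insert(0, "patient_id", table["patient_id"].to_numpy())
    return out
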