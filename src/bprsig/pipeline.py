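"""End-to-end orchestration.

A schema-validated :class:`PipelineConfig` drives the full workflow:
simulate (optional) -> preprocess -> explore -> diffexpr -> tune -> train ->
transfer -> validate.  Every artifact lands in a run directory together with
a JSON manifest recording the config hash, all seeds, data shapes at each
stage and the numeric outputs, so a rerun with the same config reproduces
the manifest bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import bpr, crossplatform, diffexpr, exploratory, preprocess, validate
from .io import (ExpressionMatrix, PhenotypeTable, read_annotation,
                 read_expression_matrix, read_phenotype_table,
                 write_expression_matrix, write_phenotype_table)
from .simulate import (FeatureMapping, SimulationConfig, simulate_cohort,
                       simulate_second_platform)

__all__ = ["PipelineConfig", "run_pipeline", "make_demo_config",
           "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateStage(_Strict):
    enabled: bool = True
    n_features: int = 2000
    frac_annotated: float = 0.9
    n_cases: int = 11
    n_controls: int = 6
    frac_paired_lobes: float = 6 / 11
    frac_explant: float = 5 / 11
    n_diff: int = 150
    effect_size: float = 1.5
    n_batch: int = 100
    batch_effect: float = 1.0
    within_patient_rho: float = 0.7
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 1.0
    val_n_cases: int = 31
    val_n_controls: int = 15
    platform_map: dict = Field(default_factory=lambda: {
        "frac_one_to_one": 0.8, "frac_many_to_one": 0.1,
        "frac_one_to_many": 0.08, "drop_frac": 0.02})
    platform_distortion: dict = Field(default_factory=lambda: {
        "scale_sd": 0.2, "shift_sd": 0.5, "noise_sd": 0.2})


class InputPaths(_Strict):
    expression: Optional[str] = None
    annotation: Optional[str] = None
    phenotype: Optional[str] = None
    validation_expression: Optional[str] = None
    validation_annotation: Optional[str] = None
    validation_phenotype: Optional[str] = None


class PreprocessStage(_Strict):
    min_mean: float = 4.0
    cov_fraction: float = 0.10
    collapse_pairs: bool = True
    prefer_lobe: Literal["upper", "lower"] = "upper"


class ExploreStage(_Strict):
    n_components: int = 2


class DiffexprStage(_Strict):
    design: Literal["unpaired", "paired"] = "unpaired"
    fdr_alpha: float = 0.10


class TuneStage(_Strict):
    enabled: bool = True
    grid: list[int] = Field(default_factory=lambda: list(range(50, 251, 10)))
    iterations: int = 2000
    burn_in: int = 500
    fixed_selection: bool = False


class TrainStage(_Strict):
    k: Optional[int] = None  # None -> take the tuned size
    n_factors: int = 2
    iterations: int = 10_000
    burn_in: int = 2_000
    prior_var_intercept: float = 100.0
    prior_var_coef: float = 4.0


class TransferStage(_Strict):
    aggregate: Literal["mean", "median"] = "mean"
    method: Literal["mean_prob", "prob_at_mean"] = "mean_prob"


class ValidateStage(_Strict):
    cutoff: str = "youden"  # 'youden' or a numeric string


class PipelineConfig(_Strict):
    """Whole-pipeline configuration; every random stage has an explicit seed."""

    seed: int = 0
    contrast: Literal["all", "biopsy", "explant"] = "all"
    simulate: SimulateStage = Field(default_factory=SimulateStage)
    inputs: InputPaths = Field(default_factory=InputPaths)
    preprocess: PreprocessStage = Field(default_factory=PreprocessStage)
    explore: ExploreStage = Field(default_factory=ExploreStage)
    diffexpr: DiffexprStage = Field(default_factory=DiffexprStage)
    tune: TuneStage = Field(default_factory=TuneStage)
    train: TrainStage = Field(default_factory=TrainStage)
    transfer: TransferStage = Field(default_factory=TransferStage)
    validate_stage: ValidateStage = Field(default_factory=ValidateStage)


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig.model_validate(data)


def make_demo_config(scale: str = "tiny") -> PipelineConfig:
    """Ready-to-run synthetic configs.

    ``tiny``: minutes-scale smoke configuration (small feature count and
    grid, light MCMC).  ``paper_shape``: cohort sizes matching the study
    (11 cases + 6 controls training; 31 + 15 validation) and the 50-250
    model-size grid.
    """
    if scale == "tiny":
        return PipelineConfig(
            simulate=SimulateStage(n_features=800, n_diff=60, n_batch=30,
                                   val_n_cases=12, val_n_controls=8),
            tune=TuneStage(grid=[20, 40, 60], iterations=400, burn_in=100),
            train=TrainStage(iterations=2000, burn_in=500),
        )
    if scale == "paper_shape":
        return PipelineConfig(
            simulate=SimulateStage(),
            tune=TuneStage(grid=list(range(50, 251, 10))),
            train=TrainStage(),
        )
    raise ValueError("scale must be 'tiny' or 'paper_shape'")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def _load_inputs(cfg: PipelineConfig):
    p = cfg.inputs
    for attr in ("expression", "phenotype"):
        path = getattr(p, attr)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"input path missing for {attr!r}: {path}")
    X = read_expression_matrix(p.expression, p.annotation)
    pheno = read_phenotype_table(p.phenotype)
    X_val = pheno_val = mapping = None
    if p.validation_expression:
        X_val = read_expression_matrix(p.validation_expression,
                                       p.validation_annotation)
        pheno_val = read_phenotype_table(p.validation_phenotype)
        mapping = crossplatform.derive_mapping(X.annotation, X_val.annotation)
    return X, pheno, X_val, pheno_val, mapping


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the configured workflow; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "shapes": {},
    }
    stage = "setup"
    try:
        # ---- stage 1: data ------------------------------------------------
        if config.simulate.enabled:
            stage = "simulate"
            sim = config.simulate
            sim_cfg = SimulationConfig(
                n_features=sim.n_features, frac_annotated=sim.frac_annotated,
                n_cases=sim.n_cases, n_controls=sim.n_controls,
                frac_paired_lobes=sim.frac_paired_lobes,
                frac_explant=sim.frac_explant, n_diff=sim.n_diff,
                effect_size=sim.effect_size, n_batch=sim.n_batch,
                batch_effect=sim.batch_effect,
                within_patient_rho=sim.within_patient_rho,
                baseline_mean=sim.baseline_mean, baseline_sd=sim.baseline_sd,
                noise_sd=sim.noise_sd, seed=config.seed,
            )
            X, pheno, truth = simulate_cohort(sim_cfg)
            X_val_src, pheno_val, _ = simulate_cohort(
                sim_cfg, n_cases=sim.val_n_cases,
                n_controls=sim.val_n_controls, frac_paired_lobes=0.0,
                frac_explant=1.0, cohort_seed=config.seed + 1,
                sample_prefix="V")
            X_val, mapping = simulate_second_platform(
                X_val_src, sim.platform_map, sim.platform_distortion,
                seed=config.seed + 2)
            write_expression_matrix(X, out / "training_expression.tsv")
            write_phenotype_table(pheno, out / "training_phenotype.tsv")
            write_phenotype_table(pheno_val, out / "validation_phenotype.tsv")
            manifest["stages"]["simulate"] = {
                "seed": config.seed, "validation_cohort_seed": config.seed + 1,
                "platform_seed": config.seed + 2,
                "n_diff_features": len(truth.diff_features),
            }
        else:
            stage = "load_inputs"
            X, pheno, X_val, pheno_val, mapping = _load_inputs(config)
            manifest["stages"]["load_inputs"] = {
                "expression": config.inputs.expression}
        manifest["shapes"]["input"] = [X.n_features, X.n_samples]

        # ---- stage 2: preprocess -----------------------------------------
        stage = "preprocess"
        pp = config.preprocess
        X_filt, report = preprocess.filter_features(X, pp.min_mean)
        if pp.collapse_pairs:
            X_one, pheno_one = preprocess.collapse_lobe_pairs(
                X_filt, pheno, pp.prefer_lobe)
        else:
            X_one, pheno_one = X_filt, pheno
        manifest["stages"]["preprocess"] = {
            "filter": asdict(report),
            "n_samples_after_collapse": X_one.n_samples,
        }
        manifest["shapes"]["filtered"] = [X_filt.n_features, X_filt.n_samples]
        manifest["shapes"]["collapsed"] = [X_one.n_features, X_one.n_samples]

        # ---- stage 3: exploratory ----------------------------------------
        stage = "explore"
        X_cov = preprocess.select_top_cov(X_filt, pp.cov_fraction)
        pca_res = exploratory.pca(X_cov, config.explore.n_components)
        D = exploratory.pearson_distance_matrix(X_cov)
        dendro = exploratory.average_linkage_cluster(D, X_cov.sample_ids)
        (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        explore_out = {
            "variance_explained": pca_res.variance_explained.tolist(),
            "n_top_cov_features": X_cov.n_features,
        }
        try:
            explore_out["paired_correlations"] = \
                exploratory.paired_correlation_summary(X_filt, pheno)
        except ValueError:
            explore_out["paired_correlations"] = None
        manifest["stages"]["explore"] = explore_out

        # ---- stage 4: differential expression ----------------------------
        stage = "diffexpr"
        contrast = config.contrast
        keep_types = {"all": ("biopsy", "explant", "control"),
                      "biopsy": ("biopsy", "control"),
                      "explant": ("explant", "control")}[contrast]
        sel = pheno_one.table["sample_type"].isin(keep_types)
        ids = list(pheno_one.table.loc[sel, "sample_id"])
        X_tr = X_one.subset_samples(ids)
        pheno_tr = pheno_one.subset(ids)
        y_tr = pheno_tr.y()
        if config.diffexpr.design == "paired":
            # lobe contrast (lower vs upper) within complete case pairs,
            # taken from the pre-collapse matrix
            cases = pheno.table[pheno.table["phenotype"] == 1]
            counts = cases.groupby("patient_id")["sample_id"].count()
            sub = cases[cases["patient_id"].isin(counts[counts == 2].index)]
            Xp = X_filt.subset_samples(list(sub["sample_id"]))
            arm = (sub["lobe"] == "lower").astype(int).to_numpy()
            de = diffexpr.moderated_t(Xp, arm, design="paired",
                                      pairs=list(sub["patient_id"]))
        else:
            de = diffexpr.moderated_t(X_tr, y_tr, design="unpaired")
        de.table.to_csv(out / "diffexpr.tsv", sep="\t", index=False)
        n_sig = int((de.table["q"] <= config.diffexpr.fdr_alpha).sum())
        manifest["stages"]["diffexpr"] = {
            "d0": de.d0, "s0_sq": de.s0_sq,
            "n_significant_at_fdr": n_sig,
            "fdr_alpha": config.diffexpr.fdr_alpha,
        }

        # ---- stage 5: tune ------------------------------------------------
        stage = "tune"
        settings = {
            "n_factors": config.train.n_factors,
            "prior": {"var_intercept": config.train.prior_var_intercept,
                      "var_coef": config.train.prior_var_coef},
            "mcmc": {"iterations": config.tune.iterations,
                     "burn_in": config.tune.burn_in, "seed": config.seed},
            "fixed_selection": config.tune.fixed_selection,
        }
        if config.tune.enabled:
            trace = bpr.tune_model_size(X_tr, y_tr, config.tune.grid, settings)
            trace.to_dataframe().to_csv(out / "model_selection.tsv",
                                        sep="\t", index=False)
            chosen_k = trace.chosen_k
            manifest["stages"]["tune"] = {
                "grid": trace.sizes, "sum_deviance": trace.sum_deviance,
                "misclassification_rate": trace.misclassification_rate,
                "chosen_k": chosen_k, "seed": config.seed,
            }
        else:
            chosen_k = config.train.k
            if chosen_k is None:
                raise ValueError("tune disabled and no train.k given")

        # ---- stage 6: train -----------------------------------------------
        stage = "train"
        k = config.train.k or chosen_k
        train_settings = {
            "n_factors": config.train.n_factors,
            "prior": settings["prior"],
            "mcmc": {"iterations": config.train.iterations,
                     "burn_in": config.train.burn_in,
                     "seed": config.seed + 10},
        }
        results = bpr.train_signature(X_tr, y_tr, k, train_settings)
        results.save(out / "signature_model")
        manifest["stages"]["train"] = {
            "k": int(k), "seed": config.seed + 10,
            "posterior_mean": results.params.tolist(),
        }

        # ---- stage 7: transfer + validate ---------------------------------
        if X_val is not None:
            stage = "transfer"
            tr = crossplatform.transfer_predict(
                results, X_val, mapping,
                aggregate=config.transfer.aggregate,
                method=config.transfer.method)
            rep = tr["mapping_report"]
            manifest["stages"]["transfer"] = {
                "n_signature_features": rep.n_signature_features,
                "n_mapped": rep.n_mapped,
                "coverage_fraction": rep.coverage_fraction,
                "dropped_zero_variance": tr["dropped_zero_variance"],
            }

            stage = "validate"
            y_val = pheno_val.y(tr["sample_ids"])
            cut = config.validate_stage.cutoff
            report = validate.validation_report(
                tr["probabilities"], y_val, tr["sample_ids"],
                cutoff="youden" if cut == "youden" else float(cut))
            (out / "validation_report.json").write_text(
                json.dumps(_jsonable(report), indent=2, sort_keys=True))
            manifest["stages"]["validate"] = {
                "auc": report["auc"], "youden": report["youden"],
                "percent": report["percent"],
                "wilcoxon_p": report["wilcoxon"]["p_value"],
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = _jsonable(manifest)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
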