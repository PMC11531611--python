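"""End-to-end pipeline: simulate -> build MSNs -> metrics -> group stats ->
predict -> validate, driven by one YAML config with a single master seed.

Every stochastic stage derives its own seed from the master seed by fixed
offsets, so a rerun with the same config reproduces all outputs. A manifest
(config hash, effective seeds, package version) is written next to the
stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, groupstats, io, msn, pls, synthetic, validation
from .synthetic import SyntheticCohortSpec, derive_seed

log = logging.getLogger("msnpred")

DEFAULT_DENSITIES = tuple(round(0.05 * i, 2) for i in range(1, 9))  # 0.05..0.40


@dataclass
class PipelineConfig:
    output_dir: str = "msnpred_out"
    feature_table: str | None = None  # paths; None -> simulate
    cohort_table: str | None = None
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    include_unthresholded: bool = True
    metric: str = "degree"  # predictor metric: degree | strength
    outcome: str = "brief_gec"
    a_max: int = 10
    dof_mode: str = "corrected"
    standardize: bool = True
    bootstrap_b: int = 1000
    cv_scheme: str = "both"  # loo | kfold | both
    cv_k: int = 20
    cv_reps: int = 100
    cv_mode: str = "replicate"
    master_seed: int = 0
    simulate: dict = field(default_factory=dict)  # SyntheticCohortSpec overrides

    def __post_init__(self) -> None:
        for d in self.densities:
            if not 0 < d <= 1:
                raise ValueError(f"density {d} outside (0, 1]")
        if self.metric not in ("degree", "strength"):
            raise ValueError("metric must be 'degree' or 'strength'")
        if self.cv_scheme not in ("loo", "kfold", "both"):
            raise ValueError("cv_scheme must be loo, kfold or both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "densities" in raw:
            raw["densities"] = tuple(raw["densities"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig, out: Path):
    if config.feature_table and config.cohort_table:
        wide = io.read_feature_table(config.feature_table)
        cohort = io.read_cohort_table(config.cohort_table)
        spec = None
    else:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", config.master_seed)
        if "outcome_weights" not in overrides:
            overrides["outcome_weights"] = synthetic.example_outcome_weights()
        target_r2 = overrides.pop("target_r2", 0.4)
        spec = SyntheticCohortSpec(**overrides)
        wide, cohort, _ = synthetic.simulate_cohort(spec, target_r2=target_r2)
        io.write_feature_table(wide, out / "features.csv")
        io.write_cohort_table(cohort, out / "cohort.csv")
    missing = cohort.index.difference(wide.index)
    if len(missing):
        raise ValueError(f"cohort subjects missing from feature table: {list(missing)}")
    return wide, cohort.loc[wide.index], spec


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "master_seed": config.master_seed,
        "stages": {},
    }
    try:
        wide, cohort, spec = _load_or_simulate(config, out)
        if spec is not None:
            regions, features = spec.regions, spec.features
        else:
            from .lexicon import FEATURES, dk_regions

            regions, features = dk_regions(), FEATURES
        values = wide.to_numpy(float).reshape(len(wide), len(regions), len(features))
        report["stages"]["input"] = {"n_subjects": len(wide), "n_regions": len(regions)}

        # --- networks and metrics across the density grid
        densities: list[float | None] = list(config.densities)
        if config.include_unthresholded:
            densities.append(None)
        global_strength = {}
        metric_tables: dict[float | None, msn.NodalMetricsTable] = {}
        for d in densities:
            mt = msn.metrics_from_features(values, list(wide.index), regions, d)
            metric_tables[d] = mt
            label = "unthresholded" if d is None else f"{d:g}"
            mt.degree.to_csv(out / f"degree_density_{label}.csv")
            mt.strength.to_csv(out / f"strength_density_{label}.csv")
            global_strength[label] = mt.global_strength
        pd.DataFrame(global_strength).to_csv(out / "global_mean_strength.csv")
        report["stages"]["msn"] = {"densities": [str(d) for d in densities]}

        # --- group comparison: global strength across densities, nodal at
        # the unthresholded network (FDR across regions)
        gs = pd.DataFrame(
            {f"{d:g}": metric_tables[d].global_strength for d in config.densities}
        )
        glm_global = groupstats.group_comparison_table(gs, cohort)
        glm_global.to_csv(out / "glm_global_strength.csv")
        nodal = metric_tables[None].strength if config.include_unthresholded else \
            metric_tables[config.densities[-1]].strength
        glm_nodal = groupstats.group_comparison_table(nodal, cohort)
        glm_nodal.to_csv(out / "glm_nodal_strength.csv")
        demo = groupstats.compare_demographics(cohort)
        (out / "demographics.txt").write_text(
            "sex M/F by group (TBI, control): "
            f"{demo['sex_table'].tolist()}\n"
            f"Fisher exact OR = {demo['sex_odds_ratio']:.2f}, "
            f"p = {demo['sex_fisher_p']:.2f}\n"
            f"age ANOVA F{demo['age_anova_df']} = {demo['age_anova_F']:.3f}, "
            f"p = {demo['age_anova_p']:.2f}\n"
        )
        report["stages"]["group_comparison"] = {
            "min_p_fdr_global": float(glm_global["p_fdr"].min()),
            "min_p_fdr_nodal": float(glm_nodal["p_fdr"].min()),
            "sex_odds_ratio": demo["sex_odds_ratio"],
        }

        # --- prediction per density (patients only)
        if config.outcome not in cohort.columns:
            raise ValueError(f"outcome column {config.outcome!r} missing from cohort")
        patients = cohort[cohort["group"] == "TBI"]
        patients = patients[patients[config.outcome].notna()]
        cv_config = validation.CVConfig(
            mode=config.cv_mode, a_max=config.a_max, dof_mode=config.dof_mode,
            scale=config.standardize,
        )
        pred_rows = []
        cv_seed = derive_seed(config.master_seed, "cv")
        boot_seed = derive_seed(config.master_seed, "bootstrap")
        for d in config.densities:
            mt = metric_tables[d]
            table = mt.degree if config.metric == "degree" else mt.strength
            X = table.loc[patients.index].astype(float)
            y = patients[config.outcome]
            sel, model, fit = validation.full_data_fit(X, y, patients, cv_config)
            row = {"density": d, "n_components": sel.a_star, "no_model": sel.no_model}
            if not sel.no_model:
                loo = validation.loo_cv(X, y, patients, cv_config)
                row.update(
                    full_r2=fit.predicted_r2, full_r=fit.pearson_r, full_mae=fit.mae,
                    loo_r2=loo.metrics.predicted_r2, loo_r=loo.metrics.pearson_r,
                    loo_mae=loo.metrics.mae,
                )
                if config.cv_scheme in ("kfold", "both"):
                    kf = validation.repeated_kfold_cv(
                        X, y, patients, k=config.cv_k, reps=config.cv_reps,
                        seed=cv_seed, config=cv_config,
                    )
                    row.update(
                        kfold_mean_r2=kf.mean_r2, kfold_median_r2=kf.median_r2,
                        kfold_ci_lo=kf.ci_mean_r2[0], kfold_ci_hi=kf.ci_mean_r2[1],
                    )
                X_res, _ = pls.residualize_predictors(X, patients)
                ci = pls.bootstrap_weights_bca(
                    X_res, y, sel.a_star, B=config.bootstrap_b, seed=boot_seed,
                    scale=config.standardize,
                )
                ci.weights.to_csv(out / f"weights_density_{d:g}.csv")
            pred_rows.append(row)
        pred_table = pd.DataFrame(pred_rows).set_index("density")
        pred_table.to_csv(out / "prediction_summary.csv")
        report["stages"]["prediction"] = {
            "n_patients": len(patients),
            "densities_with_model": [
                float(d) for d, r in pred_table.iterrows() if not r["no_model"]
            ],
        }
    except Exception as exc:  # mark partial outputs, then re-raise
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        log.error("pipeline failed: %s", exc)
        raise
    report["seeds"] = {
        stage: derive_seed(config.master_seed, stage) for stage in
        ("profiles", "features", "demographics", "outcome", "bootstrap", "cv")
    }
    (out / "manifest.json").write_text(json.dumps(report, indent=2, default=str))
    if (out / "FAILED").exists():
        (out / "FAILED").unlink()
    return report
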