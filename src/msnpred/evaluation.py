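"""End-to-end evaluation scenarios exercising the full pipeline.

These are the package's positive- and negative-control experiments: each
builds synthetic cohorts with known ground truth, runs the actual analysis
(MSN construction, metrics, residualization, AIC component selection, PLS
fit, bootstrap, cross-validation, group GLMs) and returns summary numbers.
They back both the acceptance checks and the demonstration outputs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import groupstats, msn, pls, synthetic, validation
from .synthetic import SyntheticCohortSpec, example_outcome_weights

_MOD = 2**31 - 1


def _sub_seed(seed: int, salt: int) -> int:
    return (int(seed) * 9176 + salt) % _MOD


def clinical_table_demographics() -> dict:
    """Demographic comparison on the published cohort counts.

    Reconstructs the sex-by-group table (patients 54 M / 29 F, controls
    20 M / 13 F) as a cohort and runs the demographic comparison.
    """
    rows = ([("TBI", "M")] * 54 + [("TBI", "F")] * 29
            + [("control", "M")] * 20 + [("control", "F")] * 13)
    rng = np.random.default_rng(0)
    cohort = pd.DataFrame(
        {
            "group": [g for g, _ in rows],
            "sex": [s for _, s in rows],
            "age_at_scan": rng.uniform(6, 15.5, len(rows)),
            "eTIV": rng.normal(1.45e6, 1.3e5, len(rows)),
        },
        index=[f"s{i}" for i in range(len(rows))],
    )
    return groupstats.compare_demographics(cohort)


def planted_patient_cohort(
    seed: int,
    n_patients: int = 59,
    target_r2: float = 0.5,
    density: float = 0.35,
):
    """Synthetic patient cohort with the canonical planted degree signal.

    Returns (X_degree, y, patients_cohort) restricted to the patient group,
    ready for the prediction pipeline.
    """
    spec = SyntheticCohortSpec(
        n_patients=n_patients, n_controls=10, seed=seed,
        density_for_outcome=density,
        outcome_weights=example_outcome_weights(),
    )
    _, cohort, metrics = synthetic.simulate_cohort(spec, target_r2=target_r2)
    patients = cohort[cohort["group"] == "TBI"]
    X = metrics.degree.loc[patients.index].astype(float)
    y = patients["brief_gec"]
    return X, y, patients


def one_component_selection_rate(
    seed: int, n_replicates: int = 100, n: int = 200, p: int = 68,
    a_max: int = 5,
) -> float:
    """Fraction of one-latent-component datasets where AIC retains 1.

    Data: X = t u' + noise, y = t + noise, so exactly one predictive latent
    dimension exists; the corrected-DoF AIC scan should retain one
    component nearly always.
    """
    hits = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(_sub_seed(seed, 1000 + r))
        t = rng.standard_normal(n)
        u = rng.standard_normal(p)
        X = np.outer(t, u) + 0.8 * rng.standard_normal((n, p))
        y = t + 0.7 * rng.standard_normal(n)
        sel = pls.select_components_aic(X, y, a_max)
        hits += sel.a_star == 1
    return hits / n_replicates


def weight_recovery(
    seed: int, n_patients: int = 300, target_r2: float = 0.4, B: int = 500,
) -> dict:
    """Recovery of the planted degree weights by bootstrap-mean PLS weights.

    Returns the cosine similarity between the bootstrap-mean native-scale
    weights and the true weights on the planted support, plus CI coverage
    summaries for planted and null predictors.
    """
    X, y, patients = planted_patient_cohort(seed, n_patients, target_r2)
    X_res, _ = pls.residualize_predictors(X, patients)
    sel = pls.select_components_aic(X_res, y, 10)
    a = max(sel.a_star, 1)
    ci = pls.bootstrap_weights_bca(X_res, y, a, B=B,
                                   seed=_sub_seed(seed, 77))
    truth = example_outcome_weights()
    support = list(truth)
    w_true = np.array([truth[r] for r in support])
    w_boot = ci.boot_mean[support].to_numpy()
    cosine = float(w_boot @ w_true
                   / (np.linalg.norm(w_boot) * np.linalg.norm(w_true)))
    planted = ci.weights.loc[support]
    excludes = (planted["lower"] > 0) | (planted["upper"] < 0)
    strongest = max(support, key=lambda r: abs(truth[r]))
    nulls = ci.weights.drop(index=support)
    null_cover = float(((nulls["lower"] <= 0) & (nulls["upper"] >= 0)).mean())
    return {
        "n_components": a,
        "cosine": cosine,
        "strongest_ci_excludes_zero": bool(excludes.loc[strongest]),
        "planted_ci_exclusion_rate": float(excludes.mean()),
        "null_ci_coverage": null_cover,
    }


def train_cv_gap(
    seed: int, n_cohorts: int = 11, n_patients: int = 59, target_r2: float = 0.5,
) -> dict:
    """Full-data vs leave-one-out predicted R^2 over replicate cohorts.

    Each cohort plants the canonical signal at the given population R^2;
    cohorts where AIC retains zero components generate no model and are
    excluded from the medians (models that are not generated have no
    performance to report). The expected pattern is a strongly optimistic
    full-data R^2 and a small but positive LOO R^2.
    """
    fulls, loos, comps = [], [], []
    for r in range(n_cohorts):
        X, y, patients = planted_patient_cohort(
            _sub_seed(seed, 2000 + r), n_patients, target_r2
        )
        config = validation.CVConfig()
        sel, model, fit = validation.full_data_fit(X, y, patients, config)
        if sel.no_model:
            continue
        loo = validation.loo_cv(X, y, patients,
                                replace(config, fixed_components=sel.a_star))
        fulls.append(fit.predicted_r2)
        loos.append(loo.metrics.predicted_r2)
        comps.append(sel.a_star)
    return {
        "n_cohorts": n_cohorts,
        "n_modeled": len(fulls),
        "median_full_r2": float(np.median(fulls)) if fulls else np.nan,
        "median_loo_r2": float(np.median(loos)) if loos else np.nan,
        "median_components": float(np.median(comps)) if comps else np.nan,
    }


def null_loo_performance(seed: int, n_seeds: int = 20, n_patients: int = 59) -> dict:
    """LOO predicted R^2 on cohorts with no planted outcome signal.

    The outcome is pure noise. Run leakage-free (strict mode: confound
    residualization and AIC component selection are refit inside every
    training fold) so that held-out predictions cannot correlate with the
    held-out outcomes by construction leakage; the predicted R^2 is then
    typically negative (a retained a*=0 predicts the training mean).
    """
    values = []
    for r in range(n_seeds):
        spec = SyntheticCohortSpec(
            n_patients=n_patients, n_controls=10,
            seed=_sub_seed(seed, 3000 + r),
            outcome_weights={}, outcome_noise_sd=10.0, outcome_intercept=50.0,
        )
        _, cohort, metrics = synthetic.simulate_cohort(spec)
        patients = cohort[cohort["group"] == "TBI"]
        X = metrics.degree.loc[patients.index].astype(float)
        y = synthetic.generate_outcome(metrics, spec).loc[patients.index]
        config = validation.CVConfig(mode="strict", a_max=6)
        loo = validation.loo_cv(X, y, patients, config)
        values.append(loo.metrics.predicted_r2)
    values = np.asarray(values)
    return {
        "n_seeds": n_seeds,
        "max_loo_r2": float(values.max()),
        "median_loo_r2": float(np.median(values)),
        "frac_nonpositive": float((values <= 0).mean()),
    }


def null_group_test_calibration(
    seed: int, n_sims: int = 500, n_per_group: int = 30, n_regions: int = 20,
) -> dict:
    """Empirical false-positive rate of FDR-corrected nodal group tests.

    Reduced-size null cohorts (no group effect): the fraction of
    (simulation, region) pairs with p_fdr < alpha must not exceed alpha
    beyond binomial noise — BH control makes it conservative.
    """
    alpha = 0.05
    rejections = 0
    total = 0
    any_rejection = 0
    for r in range(n_sims):
        spec = SyntheticCohortSpec(
            n_patients=n_per_group, n_controls=n_per_group,
            n_regions=n_regions, seed=_sub_seed(seed, 4000 + r),
        )
        wide = synthetic.generate_features(spec)
        cohort = synthetic.generate_demographics(spec)
        values = wide.to_numpy().reshape(len(wide), n_regions, spec.n_features)
        metrics = msn.metrics_from_features(values, list(wide.index),
                                            spec.regions, None)
        table = groupstats.group_comparison_table(metrics.strength, cohort)
        hits = int((table["p_fdr"] < alpha).sum())
        rejections += hits
        any_rejection += hits > 0
        total += n_regions
    rate = rejections / total
    se = np.sqrt(alpha * (1 - alpha) / total)
    return {
        "n_sims": n_sims,
        "rejection_rate": float(rate),
        "familywise_rate": float(any_rejection / n_sims),
        "bound": float(alpha + 2 * se),
    }
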