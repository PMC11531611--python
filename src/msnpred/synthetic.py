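"""Synthetic cohorts with the statistical structure the analysis assumes.

The real study data (regional cortical morphometry plus executive-function
outcomes in a paediatric TBI cohort) are not public, so this module generates
stand-in cohorts: region-specific feature profiles shared across subjects,
correlated Gaussian subject noise, optional standardized group shifts,
demographic confounds (age, sex, eTIV), and an outcome planted linearly on
nodal degree (or strength) of the subject's thresholded similarity network
with controllable signal strength.

Everything is driven by one ``SyntheticCohortSpec`` and an explicit seed;
identical (spec, seed) pairs reproduce bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import msn
from .lexicon import FEATURES, dk_regions, generic_regions

_SEED_MOD = 2**31 - 1
# fixed offsets fanning one master seed out to the stochastic stages
SEED_OFFSETS = {
    "profiles": 11,
    "features": 23,
    "demographics": 37,
    "outcome": 53,
    "bootstrap": 71,
    "cv": 89,
}


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed = (master * 1000003 + fixed offset) mod 2^31-1."""
    return (int(master_seed) * 1000003 + SEED_OFFSETS[stage]) % _SEED_MOD


@dataclass
class SyntheticCohortSpec:
    """Generating-model parameters for one synthetic cohort.

    ``group_effect`` maps region label -> {feature: shift}, with shifts in
    standardized units (multiples of ``subject_noise_sd``) added to patients.
    ``outcome_weights`` maps region label -> coefficient on that region's
    nodal degree (or strength, see ``outcome_metric``) at density
    ``density_for_outcome``.
    """

    n_patients: int = 83
    n_controls: int = 33
    n_regions: int = 68
    n_features: int = 7
    regional_profile_scale: float = 1.0
    subject_noise_sd: float = 1.0
    cross_feature_corr: float = 0.3
    group_effect: dict[str, dict[str, float]] = field(default_factory=dict)
    age_range_years: tuple[float, float] = (6.0, 15.5)
    male_fraction: float = 0.64
    etiv_mean_sd: tuple[float, float] = (1.45e6, 1.3e5)
    outcome_weights: dict[str, float] = field(default_factory=dict)
    outcome_noise_sd: float = 1.0
    outcome_intercept: float = 50.0
    density_for_outcome: float = 0.35
    outcome_metric: str = "degree"  # or "strength"
    confound_effects: dict[str, float] | None = None  # optional leakage into outcome
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_regions", "n_features"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("subject_noise_sd", "outcome_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("male_fraction", "cross_feature_corr"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.density_for_outcome <= 1:
            raise ValueError("density_for_outcome must lie in (0, 1]")
        if self.regional_profile_scale <= 0:
            raise ValueError("regional_profile_scale must be positive")
        if not (self.etiv_mean_sd[0] > 0 and self.etiv_mean_sd[1] > 0):
            raise ValueError("etiv_mean_sd entries must be positive")
        if self.age_range_years[0] >= self.age_range_years[1]:
            raise ValueError("age_range_years must be an increasing interval")
        if self.outcome_metric not in ("degree", "strength"):
            raise ValueError("outcome_metric must be 'degree' or 'strength'")
        regions = set(self.regions)
        for label in self.group_effect:
            if label not in regions:
                raise ValueError(f"group_effect: unknown region label {label!r}")
            for feat in self.group_effect[label]:
                if feat not in self.features:
                    raise ValueError(f"group_effect: unknown feature {feat!r}")
        bad = [r for r in self.outcome_weights if r not in regions]
        if bad:
            raise ValueError(f"outcome_weights: unknown region label(s) {bad}")

    @property
    def regions(self) -> tuple[str, ...]:
        return dk_regions() if self.n_regions == 68 else generic_regions(self.n_regions)

    @property
    def features(self) -> tuple[str, ...]:
        if self.n_features == 7:
            return FEATURES
        return tuple(f"f{i + 1}" for i in range(self.n_features))

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def subject_ids(self) -> list[str]:
        pats = [f"p{i + 1:03d}" for i in range(self.n_patients)]
        ctrs = [f"c{i + 1:03d}" for i in range(self.n_controls)]
        return pats + ctrs


def example_outcome_weights() -> dict[str, float]:
    """The canonical planted fronto-temporal weight pattern (mixed signs).

    Regions chosen once, as plausible executive-function-relevant nodes;
    used by tests and the demonstration pipeline as the ground truth.
    """
    return {
        "lh_superiorfrontal": 1.0,
        "rh_superiorfrontal": 0.9,
        "lh_rostralmiddlefrontal": 0.8,
        "rh_medialorbitofrontal": -0.8,
        "lh_parstriangularis": 0.6,
        "rh_insula": -0.6,
        "lh_temporalpole": 0.5,
        "rh_parahippocampal": -0.5,
        "lh_inferiortemporal": 0.4,
        "rh_superiortemporal": -0.4,
    }


def _feature_cov(spec: SyntheticCohortSpec) -> np.ndarray:
    """Compound-symmetric within-region feature covariance."""
    f, rho, sd = spec.n_features, spec.cross_feature_corr, spec.subject_noise_sd
    corr = np.full((f, f), rho)
    np.fill_diagonal(corr, 1.0)
    return corr * sd**2


def generate_features(spec: SyntheticCohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate the subjects x (regions x features) wide feature table.

    Region-specific base profiles (drawn once per seed) are shared by every
    subject; subject noise is Gaussian with the configured within-region
    cross-feature correlation; patients additionally receive the configured
    standardized group shifts.
    """
    if seed is None:
        seed = derive_seed(spec.seed, "features")
    rng = np.random.default_rng(seed)
    regions, features = spec.regions, spec.features
    r, f, n = spec.n_regions, spec.n_features, spec.n_subjects

    profiles = spec.regional_profile_scale * rng.standard_normal((r, f))
    cov = _feature_cov(spec)
    if spec.subject_noise_sd > 0:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(f))
        noise = rng.standard_normal((n, r, f)) @ chol.T
    else:
        noise = np.zeros((n, r, f))

    values = profiles[None, :, :] + noise
    shift = np.zeros((r, f))
    for label, per_feature in spec.group_effect.items():
        i = regions.index(label)
        for feat, delta in per_feature.items():
            shift[i, features.index(feat)] = delta * spec.subject_noise_sd
    values[: spec.n_patients] += shift[None, :, :]

    cols = [f"{reg}_{feat}" for reg in regions for feat in features]
    wide = pd.DataFrame(values.reshape(n, r * f), index=spec.subject_ids(), columns=cols)
    wide.index.name = "subject_id"
    return wide


def generate_demographics(spec: SyntheticCohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Cohort metadata table: group, sex, age at scan, eTIV (+ injury fields).

    Ages uniform over ``age_range_years``; sex Bernoulli(male_fraction);
    eTIV Gaussian. Patients get an injury age earlier than the scan age and
    the implied injury-scan interval, mirroring the clinical table layout.
    """
    if seed is None:
        seed = derive_seed(spec.seed, "demographics")
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    ids = spec.subject_ids()
    lo, hi = spec.age_range_years
    age = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.random(n) < spec.male_fraction, "M", "F")
    etiv = rng.normal(spec.etiv_mean_sd[0], spec.etiv_mean_sd[1], size=n)
    group = np.array(["TBI"] * spec.n_patients + ["control"] * spec.n_controls)

    interval_days = rng.uniform(1, 89, size=n)
    age_at_injury = np.where(group == "TBI", age - interval_days / 365.25, np.nan)
    interval = np.where(group == "TBI", interval_days, np.nan)
    severity = np.where(
        group == "TBI", np.where(rng.random(n) < 0.57, "mild", "moderate_severe"), "NA"
    )

    return pd.DataFrame(
        {
            "subject_id": ids,
            "group": group,
            "sex": sex,
            "age_at_scan": age,
            "age_at_injury": age_at_injury,
            "injury_scan_interval": interval,
            "severity": severity,
            "eTIV": etiv,
        }
    ).set_index("subject_id")


def planted_linear_predictor(
    metrics: msn.NodalMetricsTable, spec: SyntheticCohortSpec
) -> np.ndarray:
    """intercept + sum_r w_r * metric_r per subject (noise-free part)."""
    table = metrics.degree if spec.outcome_metric == "degree" else metrics.strength
    missing = [r for r in spec.outcome_weights if r not in table.columns]
    if missing:
        raise ValueError(f"outcome_weights regions not present in metrics: {missing}")
    lp = np.full(len(table), float(spec.outcome_intercept))
    for region, w in spec.outcome_weights.items():
        lp += w * table[region].to_numpy(dtype=float)
    return lp


def generate_outcome(
    metrics: msn.NodalMetricsTable,
    spec: SyntheticCohortSpec,
    seed: int | None = None,
    cohort: pd.DataFrame | None = None,
) -> pd.Series:
    """Outcome_i = intercept + sum_r w_r * degree_i(r) + Gaussian noise.

    ``cohort`` is only needed when ``spec.confound_effects`` plants additional
    demographic terms (off by default, so residualization tests can toggle it).
    """
    if metrics.density is not None and not np.isclose(
        metrics.density, spec.density_for_outcome
    ):
        raise ValueError(
            f"metrics computed at density {metrics.density}, spec plants the outcome "
            f"at {spec.density_for_outcome}"
        )
    if seed is None:
        seed = derive_seed(spec.seed, "outcome")
    rng = np.random.default_rng(seed)
    y = planted_linear_predictor(metrics, spec)
    if spec.confound_effects:
        if cohort is None:
            raise ValueError("confound_effects set but no cohort table supplied")
        c = cohort.loc[list(metrics.subjects)]
        terms = {
            "age": c["age_at_scan"].to_numpy(float),
            "sex": (c["sex"] == "M").to_numpy(float),
            "eTIV": c["eTIV"].to_numpy(float),
        }
        terms["age:sex"] = terms["age"] * terms["sex"]
        for name, coef in spec.confound_effects.items():
            y = y + coef * terms[name]
    y = y + rng.normal(0.0, spec.outcome_noise_sd, size=len(y))
    return pd.Series(y, index=list(metrics.subjects), name="brief_gec")


def outcome_noise_for_r2(
    metrics: msn.NodalMetricsTable, spec: SyntheticCohortSpec, target_r2: float
) -> float:
    """Noise SD making the generating-model population R^2 equal the target.

    R^2 = Var(lp) / (Var(lp) + sd^2) with Var(lp) estimated from the realized
    linear predictor over the supplied (large) cohort, so sd =
    sqrt(Var(lp) * (1 - R^2) / R^2).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    lp = planted_linear_predictor(metrics, spec)
    var_lp = float(np.var(lp, ddof=1))
    if var_lp == 0:
        raise ValueError("planted linear predictor has zero variance")
    return float(np.sqrt(var_lp * (1 - target_r2) / target_r2))


def simulate_cohort(
    spec: SyntheticCohortSpec,
    target_r2: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, msn.NodalMetricsTable]:
    """End-to-end convenience: features, cohort (+outcome), nodal metrics.

    When ``target_r2`` is given the outcome noise SD is calibrated so the
    generating model's population R^2 equals it; otherwise the spec's
    ``outcome_noise_sd`` is used as-is.
    """
    features = generate_features(spec)
    cohort = generate_demographics(spec)
    values = features.to_numpy().reshape(spec.n_subjects, spec.n_regions, spec.n_features)
    metrics = msn.metrics_from_features(
        values, list(features.index), spec.regions, spec.density_for_outcome
    )
    if spec.outcome_weights:
        if target_r2 is not None:
            spec = replace(spec, outcome_noise_sd=outcome_noise_for_r2(metrics, spec, target_r2))
        outcome = generate_outcome(metrics, spec, cohort=cohort)
        cohort = cohort.assign(brief_gec=outcome)
    return features, cohort, metrics
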