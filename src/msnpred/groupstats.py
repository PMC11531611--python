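"""Covariate-adjusted group contrasts of network metrics.

Each metric is modelled by ordinary least squares as
``metric ~ group + age + sex + age:sex + eTIV`` with group coded
control=0 / TBI=1 and sex F=0 / M=1. Age is mean-centered before forming the
age-by-sex interaction (reduces collinearity; the group coefficient is
unaffected). The group t statistic is converted to Hedge's g with the
small-sample correction J = 1 - 3/(4*df - 1), and p-values are
Benjamini-Hochberg adjusted within their correction family (across
densities for the global metric, across regions for nodal metrics).

Demographic comparisons mirror the clinical-table conventions: Fisher's
exact test (odds ratio) for sex by group and a one-way ANOVA for age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONFOUNDS = ("age", "sex", "age:sex", "eTIV")


@dataclass
class GroupGLMResult:
    unit: str
    beta_group: float
    t_stat: float
    df_residual: int
    hedges_g: float
    p_value: float
    n_patients: int
    n_controls: int
    p_fdr: float | None = None


def design_matrix(cohort: pd.DataFrame, include_group: bool = True) -> pd.DataFrame:
    """Intercept + (group) + centered age + sex + age:sex + eTIV."""
    sex = (cohort["sex"] == "M").astype(float)
    age_c = cohort["age_at_scan"].astype(float) - cohort["age_at_scan"].mean()
    cols = {"intercept": np.ones(len(cohort))}
    if include_group:
        cols["group"] = (cohort["group"] == "TBI").astype(float)
    cols.update(
        {
            "age": age_c,
            "sex": sex,
            "age:sex": age_c * sex,
            "eTIV": cohort["eTIV"].astype(float),
        }
    )
    return pd.DataFrame(cols, index=cohort.index)


def hedges_g_from_t(t: float, n1: int, n2: int, df: int) -> float:
    """Hedge's g from a t statistic, corrected for unequal group sizes.

    g = t * sqrt(1/n1 + 1/n2) * J with J = 1 - 3/(4*df - 1).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 subjects")
    if df < 1:
        raise ValueError("residual degrees of freedom must be positive")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2) * j)


def fit_group_glm(metric: pd.Series | np.ndarray, cohort: pd.DataFrame,
                  unit: str = "global") -> GroupGLMResult:
    """OLS fit of metric ~ group + age + sex + age:sex + eTIV."""
    if isinstance(metric, pd.Series):
        metric = metric.loc[cohort.index]
    y = np.asarray(metric, dtype=float)
    groups = cohort["group"].to_numpy()
    n1 = int((groups == "TBI").sum())
    n2 = int((groups == "control").sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be represented")
    X = design_matrix(cohort)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="intercept").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        a, b = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); most collinear "
            f"terms: {corr.index[a]!r} and {corr.columns[b]!r}"
        )
    fit = sm.OLS(y, X.to_numpy()).fit()
    idx = list(X.columns).index("group")
    beta = float(fit.params[idx])
    t = float(fit.tvalues[idx])
    if np.var(y) == 0:  # constant metric: define t = 0 rather than 0/0
        beta, t = 0.0, 0.0
    df_resid = int(fit.df_resid)
    p = 1.0 if t == 0 else float(fit.pvalues[idx])
    g = hedges_g_from_t(t, n1, n2, df_resid)
    return GroupGLMResult(
        unit=unit, beta_group=beta, t_stat=t, df_residual=df_resid,
        hedges_g=g, p_value=p, n_patients=n1, n_controls=n2,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_comparison_table(
    metrics: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Fit the group GLM for every column of ``metrics``; FDR across columns.

    Used both for the global metric across densities (columns = densities)
    and for nodal metrics across regions (columns = regions) — the FDR
    family is the set of columns passed in.
    """
    results = [fit_group_glm(metrics[c], cohort, unit=str(c)) for c in metrics.columns]
    p_adj = fdr_adjust([r.p_value for r in results])
    for r, q in zip(results, p_adj):
        r.p_fdr = float(q)
    return pd.DataFrame(
        [
            {
                "unit": r.unit,
                "beta_group": r.beta_group,
                "t_stat": r.t_stat,
                "df_residual": r.df_residual,
                "hedges_g": r.hedges_g,
                "p_value": r.p_value,
                "p_fdr": r.p_fdr,
            }
            for r in results
        ]
    ).set_index("unit")


def compare_demographics(cohort: pd.DataFrame) -> dict:
    """Sex-by-group Fisher's exact test and one-way ANOVA on age at scan.

    The odds ratio is reported as the conditional maximum-likelihood estimate
    (as R's ``fisher.test`` prints) alongside the sample cross-product ratio.
    """
    tbi = cohort[cohort["group"] == "TBI"]
    ctl = cohort[cohort["group"] == "control"]
    if len(tbi) == 0 or len(ctl) == 0:
        raise ValueError("both groups must be present")
    table = np.array(
        [
            [(tbi["sex"] == "M").sum(), (tbi["sex"] == "F").sum()],
            [(ctl["sex"] == "M").sum(), (ctl["sex"] == "F").sum()],
        ],
        dtype=int,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("sex-by-group table has an empty row or column")
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    or_cmle = stats.contingency.odds_ratio(table, kind="conditional").statistic
    a, b = table[0]
    c, d = table[1]
    or_sample = (a * d) / (b * c) if b * c > 0 else np.inf
    f_stat, anova_p = stats.f_oneway(
        tbi["age_at_scan"].to_numpy(float), ctl["age_at_scan"].to_numpy(float)
    )
    if np.isnan(f_stat):  # zero within-group variance and equal means
        f_stat, anova_p = 0.0, 1.0
    return {
        "sex_table": table,
        "sex_odds_ratio": float(or_cmle),
        "sex_odds_ratio_sample": float(or_sample),
        "sex_fisher_p": float(fisher_p),
        "age_anova_F": float(f_stat),
        "age_anova_df": (1, len(cohort) - 2),
        "age_anova_p": float(anova_p),
    }
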