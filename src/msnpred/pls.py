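"""PLS1 regression machinery for brain-behaviour outcome prediction.

Implements NIPALS partial least squares with a univariate response on
column-standardized predictors, together with:

* confound residualization of predictor columns (eTIV, age, sex, age x sex),
* the corrected (unbiased, trace-based) degrees of freedom of a PLS model,
  computed as tr(d yhat / d y) by forward-mode differentiation of the NIPALS
  recursion — a PLS fit is nonlinear in y, so its effective complexity
  exceeds the naive one-per-component count,
* AIC-based component selection at the first local minimum of the
  Mallows-form AIC(a) = RSS_a/n + 2 DoF(a) sigma_a^2 / n,
* predicted R^2 (1 - normalised MSE), Pearson r and MAE fit metrics,
* bias-corrected and accelerated (BCa) bootstrap intervals for the
  per-predictor weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .groupstats import design_matrix


@dataclass
class ConfoundModel:
    """Per-column least-squares coefficients on the confound design."""

    confound_names: tuple[str, ...]
    coefficients: pd.DataFrame  # confound term x predictor column
    column_means: pd.Series


def residualize_predictors(
    X: pd.DataFrame, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, ConfoundModel]:
    """Regress eTIV, age, sex and age x sex out of every predictor column.

    Residual columns are orthogonal to the confound design; the original
    column means are added back so the scale of each predictor is preserved.
    """
    cohort = cohort.loc[X.index]
    for col in ("age_at_scan", "sex", "eTIV"):
        if cohort[col].isna().any():
            sid = cohort.index[cohort[col].isna()][0]
            raise ValueError(f"missing confound {col!r} for subject {sid!r}")
    D = design_matrix(cohort, include_group=False).to_numpy()
    Xv = X.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(D, Xv, rcond=None)
    resid = Xv - D @ coef
    means = Xv.mean(axis=0)
    out = pd.DataFrame(resid + means, index=X.index, columns=X.columns)
    model = ConfoundModel(
        confound_names=("intercept", "age", "sex", "age:sex", "eTIV"),
        coefficients=pd.DataFrame(
            coef, index=["intercept", "age", "sex", "age:sex", "eTIV"], columns=X.columns
        ),
        column_means=pd.Series(means, index=X.columns),
    )
    return out, model


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 state (all component counts up to A_max at once)."""

    columns: tuple[str, ...]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    W: np.ndarray  # p x A weight vectors (unit norm)
    P: np.ndarray  # p x A X-loadings
    q: np.ndarray  # A response loadings
    T: np.ndarray  # n x A scores
    scale: bool = True

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def coefficients(self, a: int) -> np.ndarray:
        """Regression coefficients on the standardized predictor scale."""
        if not 0 <= a <= self.n_components:
            raise ValueError(f"a={a} exceeds the {self.n_components} fitted components")
        if a == 0:
            return np.zeros(len(self.columns))
        W, P, q = self.W[:, :a], self.P[:, :a], self.q[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def coefficients_native(self, a: int) -> np.ndarray:
        """Coefficients mapped back to the predictors' native scale."""
        return self.coefficients(a) / self.x_scale


def fit_pls1(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    a_max: int,
    scale: bool = True,
    center: bool = True,
) -> PLSModel:
    """NIPALS PLS1 on (optionally) column-standardized X and centered y.

    Components are extracted by w_a = X_a' y / ||.||, t_a = X_a w_a, with X
    deflated by t_a p_a' after each component. Extraction stops early if a
    score vector degenerates (residual X orthogonal to y).
    """
    if isinstance(X, pd.DataFrame):
        columns = tuple(map(str, X.columns))
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        columns = tuple(f"x{j}" for j in range(Xv.shape[1]))
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xv.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not 1 <= a_max <= min(n - 1, p):
        raise ValueError(f"a_max must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")

    x_mean = Xv.mean(axis=0) if center else np.zeros(p)
    if scale:
        x_scale = Xv.std(axis=0, ddof=1)
        if np.any(x_scale == 0):
            j = int(np.flatnonzero(x_scale == 0)[0])
            raise ValueError(f"zero-variance predictor column {columns[j]!r}")
    else:
        x_scale = np.ones(p)
    y_mean = yv.mean() if center else 0.0

    Xa = (Xv - x_mean) / x_scale
    yc = yv - y_mean
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    T = np.zeros((n, a_max))
    used = 0
    for a in range(a_max):
        s = Xa.T @ yc
        ns = np.linalg.norm(s)
        if ns < 1e-12 * max(1.0, np.abs(yc).max()):
            break
        w = s / ns
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        pa = Xa.T @ t / tt
        qa = float(yc @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        Xa = Xa - np.outer(t, pa)
        used += 1
    return PLSModel(
        columns=columns, x_mean=x_mean, x_scale=x_scale, y_mean=float(y_mean),
        W=W[:, :used], P=P[:, :used], q=q[:used], T=T[:, :used], scale=scale,
    )


def pls_predict(
    model: PLSModel, X_new: pd.DataFrame | np.ndarray, a: int
) -> np.ndarray:
    """Predict new responses with the first ``a`` components.

    Applies the training centering/scaling, the coefficient vector, and adds
    back the training response mean. ``a=0`` predicts the training mean.
    """
    if isinstance(X_new, pd.DataFrame):
        if tuple(map(str, X_new.columns)) != model.columns:
            raise ValueError("X_new column labels do not match the training matrix")
        Xv = X_new.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X_new, dtype=float)
        if Xv.shape[1] != len(model.columns):
            raise ValueError("X_new has the wrong number of columns")
    Z = (Xv - model.x_mean) / model.x_scale
    return model.y_mean + Z @ model.coefficients(a)


def _fitted_trace_path(
    X: np.ndarray, y: np.ndarray, a_max: int, scale: bool
) -> np.ndarray:
    """tr(d yhat / d y) for a = 0..a_max by forward-mode differentiation.

    Every NIPALS quantity is propagated together with its Jacobian with
    respect to the raw response vector y. The centering map contributes
    trace 1 (the a=0 / intercept-only model); each component adds the trace
    of d(q_a t_a)/dy. The deflated X depends on y through earlier scores, so
    its Jacobian is carried as an (n, p, n) tensor.
    """
    n, p = X.shape
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    Xa = (X - x_mean) / x_scale
    yc = y - y.mean()
    C = np.eye(n) - np.ones((n, n)) / n  # d yc / d y
    dXa = np.zeros((n, p, n))
    dyc = C
    traces = np.zeros(a_max + 1)
    traces[0] = 1.0
    for a in range(1, a_max + 1):
        s = Xa.T @ yc
        ds = np.einsum("ipk,i->pk", dXa, yc) + Xa.T @ dyc
        ns = np.linalg.norm(s)
        if ns < 1e-12:
            traces[a:] = traces[a - 1]
            break
        w = s / ns
        # d(s/||s||) = (I - w w')/||s|| ds
        dw = (ds - np.outer(w, w @ ds)) / ns
        t = Xa @ w
        dt = np.einsum("ipk,p->ik", dXa, w) + Xa @ dw
        tt = float(t @ t)
        dtt = 2.0 * (t @ dt)
        pa = Xa.T @ t / tt
        dpa = (np.einsum("ipk,i->pk", dXa, t) + Xa.T @ dt) / tt - np.outer(
            pa, dtt
        ) / tt
        qa = float(yc @ t) / tt
        dqa = (t @ dyc + yc @ dt) / tt - qa * dtt / tt
        # contribution of q_a * t_a to the fitted values
        dfit = np.outer(t, dqa) + qa * dt
        traces[a] = traces[a - 1] + np.trace(dfit)
        dXa -= np.einsum("ik,p->ipk", dt, pa) + np.einsum("i,pk->ipk", t, dpa)
        Xa = Xa - np.outer(t, pa)
    return traces


def pls_dof(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    a: int,
    mode: str = "corrected",
    scale: bool = True,
) -> float:
    """Degrees of freedom of the a-component PLS1 fit. DoF(0) = 1 always."""
    if a < 0:
        raise ValueError("component count must be nonnegative")
    if mode == "naive":
        return float(a + 1)
    if mode != "corrected":
        raise ValueError(f"unknown DoF mode {mode!r}")
    if a == 0:
        return 1.0
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yv = np.asarray(y, dtype=float).ravel()
    if a > min(Xv.shape[0] - 1, Xv.shape[1]):
        raise ValueError(f"a={a} exceeds min(n-1, p)")
    return float(_fitted_trace_path(Xv, yv, a, scale)[a])


@dataclass
class ComponentSelection:
    """AIC scan over candidate component counts and the retained a*."""

    a_max: int
    dof: np.ndarray  # index a = 0..a_max
    rss: np.ndarray
    aic: np.ndarray
    a_star: int
    mode: str

    @property
    def no_model(self) -> bool:
        """True when AIC retains zero components ('no model generated')."""
        return self.a_star == 0


def _first_local_minimum(aic: np.ndarray) -> int:
    """Smallest a >= 1 that is a local minimum of the AIC path.

    A candidate must improve on every smaller model scanned so far (running
    minimum, which guards against spurious late dips in the noisy high-a
    tail) and must not be beaten by the next model; at the upper boundary,
    a_max qualifies if AIC is still decreasing into it. Returns 0 ('no
    model generated') when no candidate qualifies.
    """
    a_max = len(aic) - 1
    running_min = aic[0]
    for a in range(1, a_max + 1):
        if aic[a] < running_min and (a == a_max or aic[a] <= aic[a + 1]):
            return a
        running_min = min(running_min, aic[a])
    return 0


def aic_from_rss_dof(rss: np.ndarray, dof: np.ndarray, n: int) -> np.ndarray:
    """Mallows-form AIC for a PLS path: RSS/n + 2 DoF sigma^2 / n.

    The residual variance sigma^2 = RSS / (n - DoF) is estimated per model,
    so the penalty diverges as the effective DoF approaches the sample size
    — exactly the regime where an overfit PLS model must be rejected. Models
    with DoF >= n - 1 get infinite AIC.
    """
    rss = np.asarray(rss, dtype=float)
    dof = np.asarray(dof, dtype=float)
    capped = np.minimum(dof, n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / (n - capped)
        aic = rss / n + 2.0 * dof * sigma2 / n
    aic = np.where(dof >= n - 1, np.inf, aic)
    return aic


def select_components_aic(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    a_max: int,
    mode: str = "corrected",
    scale: bool = True,
) -> ComponentSelection:
    """Retain the component count at the first local minimum of AIC.

    AIC follows :func:`aic_from_rss_dof` with the corrected (trace-based)
    DoF by default; DoF(0) = 1 (intercept-only model). a* = 0 means no
    model is generated.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    a_max = int(min(a_max, Xv.shape[0] - 1, Xv.shape[1]))
    model = fit_pls1(Xv, yv, a_max, scale=scale)
    a_fit = model.n_components
    yc = yv - yv.mean()
    rss = np.empty(a_max + 1)
    rss[0] = float(yc @ yc)
    fitted = np.zeros(n)
    for a in range(1, a_max + 1):
        if a <= a_fit:
            fitted = fitted + model.q[a - 1] * model.T[:, a - 1]
        r = yc - fitted
        rss[a] = float(r @ r)
    if mode == "corrected":
        dof = _fitted_trace_path(Xv, yv, a_max, scale)
        dof[a_fit + 1:] = dof[a_fit] if a_fit < a_max else dof[-1]
    else:
        dof = np.arange(a_max + 1, dtype=float) + 1.0
    aic = aic_from_rss_dof(rss, dof, n)
    a_star = _first_local_minimum(aic)
    return ComponentSelection(a_max=a_max, dof=dof, rss=rss, aic=aic, a_star=a_star, mode=mode)


@dataclass
class FitMetrics:
    predicted_r2: float
    pearson_r: float
    p_of_r: float
    mae: float


def compute_fit_metrics(y_pred, y_obs) -> FitMetrics:
    """Predicted R^2 = 1 - MSE(pred, obs) / MSE(obs, mean(obs)); r; MAE.

    Predicted R^2 is negative for models that predict worse than the
    observed mean (a signature of overfitting).
    """
    yp = np.asarray(y_pred, dtype=float).ravel()
    yo = np.asarray(y_obs, dtype=float).ravel()
    if yp.shape != yo.shape:
        raise ValueError("prediction and observation vectors differ in length")
    if len(yo) < 3:
        raise ValueError("need at least 3 observations")
    mse_null = float(np.mean((yo - yo.mean()) ** 2))
    if mse_null == 0:
        raise ValueError("observed outcome has zero variance")
    mse = float(np.mean((yp - yo) ** 2))
    predicted_r2 = 1.0 - mse / mse_null
    if np.ptp(yp) == 0:  # constant prediction: correlation undefined
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(yp, yo)
    return FitMetrics(
        predicted_r2=float(predicted_r2), pearson_r=float(r), p_of_r=float(p),
        mae=float(np.mean(np.abs(yp - yo))),
    )


def bca_interval(
    boot: np.ndarray,
    point: float | np.ndarray,
    jack: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """BCa interval endpoints from bootstrap replicates of a statistic.

    ``boot`` is (B,) or (B, p); ``jack`` the (n,) or (n, p) jackknife
    replicates used for the acceleration (0 when omitted). The bias term
    comes from the bootstrap distribution's position relative to the point
    estimate; degenerate (all-equal) bootstrap distributions collapse the
    interval onto the point value.
    """
    boot = np.asarray(boot, dtype=float)
    if boot.ndim == 1:
        boot = boot[:, None]
    point = np.atleast_1d(np.asarray(point, dtype=float))
    B, p = boot.shape
    if p != len(point):
        raise ValueError("bootstrap replicate width does not match the point estimate")
    lo = np.empty(p)
    hi = np.empty(p)
    z_alpha = stats.norm.ppf(alpha / 2.0)
    if jack is not None:
        jack = np.asarray(jack, dtype=float)
        if jack.ndim == 1:
            jack = jack[:, None]
        jm = jack.mean(axis=0)
        num = ((jm - jack) ** 3).sum(axis=0)
        den = 6.0 * (((jm - jack) ** 2).sum(axis=0)) ** 1.5
        accel = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    else:
        accel = np.zeros(p)
    for j in range(p):
        bj = boot[:, j]
        if np.all(bj == bj[0]):
            lo[j] = hi[j] = bj[0]
            continue
        frac = np.clip(np.mean(bj < point[j]), 1.0 / (B + 1), B / (B + 1.0))
        z0 = stats.norm.ppf(frac)
        a1 = stats.norm.cdf(z0 + (z0 + z_alpha) / (1 - accel[j] * (z0 + z_alpha)))
        a2 = stats.norm.cdf(z0 + (z0 - z_alpha) / (1 - accel[j] * (z0 - z_alpha)))
        lo[j] = np.quantile(bj, a1)
        hi[j] = np.quantile(bj, a2)
    return lo, hi


@dataclass
class BootstrapWeightCI:
    """Per-predictor point weight with 95% BCa bounds."""

    weights: pd.DataFrame  # columns: weight, lower, upper
    n_bootstrap: int
    component_count: int
    redrawn: int = 0
    boot_mean: pd.Series = field(default=None)  # type: ignore[assignment]


def _weight_statistic(model: PLSModel, a: int) -> np.ndarray:
    """Native-scale coefficient vector: the per-predictor weight."""
    return model.coefficients_native(a)


def bootstrap_weights_bca(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    a: int,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    scale: bool = True,
) -> BootstrapWeightCI:
    """Subject-resampling BCa bootstrap of the per-predictor PLS weights.

    Each resample refits the PLS model with the component count held at
    ``a``; the replicate statistic is the native-scale coefficient vector,
    sign-aligned to the point estimate (PLS component signs are arbitrary).
    Resamples with a zero-variance predictor column are redrawn (counted).
    """
    if a < 1:
        raise ValueError("bootstrap requires at least one retained component")
    if B < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    yv = np.asarray(y, dtype=float).ravel()
    Xv = X.to_numpy(dtype=float)
    n = len(yv)
    rng = np.random.default_rng(seed)
    point_model = fit_pls1(X, yv, a, scale=scale)
    point = _weight_statistic(point_model, a)

    boot = np.empty((B, len(point)))
    redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        Xb, yb = Xv[idx], yv[idx]
        if scale and np.any(Xb.std(axis=0, ddof=1) == 0):
            redrawn += 1
            if redrawn > 50 * B:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        m = fit_pls1(Xb, yb, a, scale=scale)
        w = _weight_statistic(m, min(a, m.n_components))
        if w @ point < 0:
            w = -w
        boot[b] = w
        b += 1

    jack = np.empty((n, len(point)))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        m = fit_pls1(Xv[mask], yv[mask], a, scale=scale)
        w = _weight_statistic(m, min(a, m.n_components))
        jack[i] = -w if w @ point < 0 else w
        mask[i] = True

    lo, hi = bca_interval(boot, point, jack, alpha=alpha)
    table = pd.DataFrame(
        {"weight": point, "lower": lo, "upper": hi}, index=list(X.columns)
    )
    table["degenerate"] = (table["lower"] > table["weight"]) | (
        table["upper"] < table["weight"]
    )
    return BootstrapWeightCI(
        weights=table, n_bootstrap=B, component_count=a, redrawn=redrawn,
        boot_mean=pd.Series(boot.mean(axis=0), index=list(X.columns)),
    )
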