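"""Survey-weighted Weibull accelerated failure time model.

Parametrization follows the log-time location-scale convention:

    log T = mu + x.beta + sigma * W,   W ~ standard minimum extreme value,

so S(t|x) = exp(-exp((log t - mu - x.beta)/sigma)).  Optimization runs on
(mu, beta, log sigma) by damped Newton with analytic gradient and Hessian;
covariance is the inverse observed information at the optimum.  Estimates from
multiply-imputed datasets are pooled with Rubin's rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .roster import CategoricalSpec

logger = logging.getLogger(__name__)

__all__ = [
    "WeibullAFTFit",
    "PooledEstimates",
    "normalize_weights",
    "build_design",
    "fit_weibull_aft",
    "hazard_ratios",
    "pooled_hazard_ratios",
    "predict_risk",
    "linear_predictor",
    "pool_rubin",
]


class ConvergenceError(RuntimeError):
    pass


def normalize_weights(
    weights: np.ndarray, n_cycles: int = 1, rescale_mean_one: bool = True
) -> np.ndarray:
    """Divide pooled survey weights by the number of cycles and (optionally)
    rescale to mean 1 for likelihood-based inference."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    w = w / n_cycles
    if rescale_mean_one:
        w = w / w.mean()
    return w


def build_design(
    cohort: pd.DataFrame,
    predictors: Sequence[str],
    roster: Sequence[CategoricalSpec],
) -> tuple[np.ndarray, list[str]]:
    """Dummy-encode the requested predictors against their declared reference
    levels; predictors absent from the roster (e.g. "age", a frozen linear
    predictor) are taken as continuous covariates."""
    spec_by_name = {s.name: s for s in roster}
    cols: list[np.ndarray] = []
    names: list[str] = []
    for p in predictors:
        spec = spec_by_name.get(p)
        if spec is None:
            if p not in cohort.columns:
                raise KeyError(f"predictor {p!r} neither in roster nor in cohort")
            vals = cohort[p].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"continuous predictor {p!r} has missing values")
            cols.append(vals)
            names.append(p)
            continue
        col = cohort[p]
        if isinstance(col.dtype, pd.CategoricalDtype):
            values = col.astype(object).to_numpy()
        else:
            values = col.to_numpy()
        known = set(spec.levels)
        bad = {v for v in pd.unique(values) if not (pd.isna(v) or v in known)}
        if bad:
            raise ValueError(f"unknown category level(s) {bad} for {p!r}")
        if pd.isna(values).any():
            raise ValueError(f"predictor {p!r} has missing values; impute first")
        for lvl in spec.non_ref_levels:
            cols.append((values == lvl).astype(float))
            names.append(f"{p}[{lvl}]")
    X = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    return X, names


@dataclass
class WeibullAFTFit:
    """Fitted survey-weighted Weibull AFT model."""

    mu: float
    beta: pd.Series  # indexed by design-column name
    log_sigma: float
    cov: pd.DataFrame  # over ["mu", *columns, "log_sigma"]
    loglik: float
    loglik_null: float
    effective_n: float
    n_events: float
    columns: list[str]
    predictors: list[str]
    roster: list[CategoricalSpec]
    weights_mean_normalized: bool = True
    scale_fixed: bool = False

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    @property
    def shape(self) -> float:
        return 1.0 / self.sigma

    def params_vector(self) -> pd.Series:
        vals = [self.mu] + list(self.beta.to_numpy()) + [self.log_sigma]
        return pd.Series(vals, index=["mu"] + self.columns + ["log_sigma"])

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "shape": self.shape,
            "beta": self.beta.to_dict(),
            "cov": self.cov.to_numpy().tolist(),
            "cov_index": list(self.cov.index),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "effective_n": self.effective_n,
            "n_events": self.n_events,
            "columns": self.columns,
            "predictors": self.predictors,
        }


def _loglik_parts(theta: np.ndarray, X: np.ndarray, y: np.ndarray, d: np.ndarray,
                  w: np.ndarray, fixed_log_sigma: float | None):
    p = X.shape[1]
    mu = theta[0]
    beta = theta[1 : 1 + p]
    s = fixed_log_sigma if fixed_log_sigma is not None else theta[1 + p]
    eta = mu + X @ beta
    inv_sig = np.exp(-s)
    z = (y - eta) * inv_sig
    ez = np.exp(np.clip(z, -745.0, 700.0))
    with np.errstate(over="ignore", invalid="ignore"):
        ll = float(np.sum(w * (d * (z - s - y) - ez)))
    return ll, z, ez, inv_sig


def _grad_hess(theta, X, y, d, w, fixed_log_sigma):
    ll, z, ez, inv_sig = _loglik_parts(theta, X, y, d, w, fixed_log_sigma)
    Xt = np.column_stack([np.ones(len(y)), X])
    g_eta = w * (ez - d) * inv_sig
    grad_loc = Xt.T @ g_eta
    h_eta = -w * ez * inv_sig**2
    H_loc = Xt.T @ (Xt * h_eta[:, None])
    if fixed_log_sigma is None:
        g_s = float(np.sum(w * (z * (ez - d) - d)))
        cross = w * inv_sig * (d - ez * (1.0 + z))
        H_cross = Xt.T @ cross
        H_ss = float(np.sum(w * (z * d - z * ez * (1.0 + z))))
        k = H_loc.shape[0]
        grad = np.concatenate([grad_loc, [g_s]])
        H = np.zeros((k + 1, k + 1))
        H[:k, :k] = H_loc
        H[:k, k] = H[k, :k] = H_cross
        H[k, k] = H_ss
        return ll, grad, H
    return ll, grad_loc, H_loc


def _ascent_direction(H: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Solve (-H + tau*I) step = grad with Levenberg-Marquardt damping so the
    direction is an ascent direction even where the log-likelihood is not
    concave (it is not globally concave in (mu, beta, log sigma))."""
    A = -H
    scale = max(1.0, float(np.max(np.abs(np.diag(A)))))
    tau = 0.0
    for _ in range(60):
        try:
            c = np.linalg.cholesky(A + tau * np.eye(A.shape[0]))
            step = np.linalg.solve(c.T, np.linalg.solve(c, grad))
            return step
        except np.linalg.LinAlgError:
            tau = max(2.0 * tau, 1e-8 * scale)
    return grad / scale  # last resort: gradient step


def _newton(theta0, X, y, d, w, fixed_log_sigma, tol_scale, max_iter=200):
    theta = theta0.copy()
    ll, grad, H = _grad_hess(theta, X, y, d, w, fixed_log_sigma)
    tol = 1e-8 * tol_scale
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            return theta, ll, H, True
        step = _ascent_direction(H, grad)
        t = 1.0
        improved = False
        for _ in range(50):
            cand = theta + t * step
            ll_new = _loglik_parts(cand, X, y, d, w, fixed_log_sigma)[0]
            if np.isfinite(ll_new) and ll_new > ll + 1e-13 * max(1.0, abs(ll)):
                improved = True
                break
            t *= 0.5
        if not improved:
            # no ascent along the damped direction: accept current point if the
            # gradient is small at a looser tolerance, otherwise report failure
            return theta, ll, H, np.max(np.abs(grad)) < 1e-4 * tol_scale
        theta = theta + t * step
        ll, grad, H = _grad_hess(theta, X, y, d, w, fixed_log_sigma)
    return theta, ll, H, np.max(np.abs(grad)) < tol


def fit_weibull_aft(
    cohort: pd.DataFrame,
    predictors: Sequence[str],
    roster: Sequence[CategoricalSpec],
    *,
    time_col: str = "time",
    event_col: str = "event",
    weight_col: str | None = "weight",
    normalize: bool = True,
    fix_sigma: float | None = None,
    n_restarts: int = 3,
) -> WeibullAFTFit:
    """Maximize the weighted Weibull AFT log-likelihood.

    Censored rows contribute log S(t|x), events log f(t|x).  Also fits the null
    (intercept + scale) model on the same rows and weights.
    """
    t = cohort[time_col].to_numpy(dtype=float)
    d = cohort[event_col].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("all follow-up times must be positive")
    if d.sum() == 0:
        raise ValueError("no events in the data")
    if weight_col is None:
        w = np.ones(len(cohort))
    else:
        w = cohort[weight_col].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    if normalize:
        w = w / w.mean()
    y = np.log(t)
    X, columns = build_design(cohort, predictors, roster)

    fixed_s = None if fix_sigma is None else float(np.log(fix_sigma))

    # exponential-style starting intercept: log(total exposure / total events)
    mu0 = float(np.log(np.sum(w * t) / np.sum(w * d)))
    s0 = 0.0 if fixed_s is None else fixed_s
    tol_scale = max(1.0, float(np.sum(w)))

    # null model (intercept + scale)
    Xn = np.empty((len(y), 0))
    th0 = np.array([mu0]) if fixed_s is not None else np.array([mu0, s0])
    th_null, ll_null, _, ok_null = _newton(th0, Xn, y, d, w, fixed_s, tol_scale)
    if not ok_null:
        raise ConvergenceError("null model failed to converge")

    mu_n = th_null[0]
    s_n = fixed_s if fixed_s is not None else th_null[-1]
    p = X.shape[1]
    if fixed_s is not None:
        start = np.concatenate([[mu_n], np.zeros(p)])
    else:
        start = np.concatenate([[mu_n], np.zeros(p), [s_n]])

    rng = np.random.default_rng(0)
    theta = ll = H = None
    for attempt in range(n_restarts + 1):
        init = start if attempt == 0 else start + rng.normal(0, 0.05, size=start.shape)
        theta, ll, H, ok = _newton(init, X, y, d, w, fixed_s, tol_scale)
        if ok:
            break
    else:
        pass
    if not ok:
        raise ConvergenceError("Weibull AFT fit failed to converge after restarts")

    cov = np.linalg.inv(-H)
    cov = 0.5 * (cov + cov.T)
    if fixed_s is not None:
        index = ["mu"] + columns
        log_sigma = fixed_s
        beta = pd.Series(theta[1 : 1 + p], index=columns)
    else:
        index = ["mu"] + columns + ["log_sigma"]
        log_sigma = float(theta[-1])
        beta = pd.Series(theta[1 : 1 + p], index=columns)
    return WeibullAFTFit(
        mu=float(theta[0]),
        beta=beta,
        log_sigma=float(log_sigma),
        cov=pd.DataFrame(cov, index=index, columns=index),
        loglik=float(ll),
        loglik_null=float(ll_null),
        effective_n=float(np.sum(w)),
        n_events=float(np.sum(w * d)),
        columns=columns,
        predictors=list(predictors),
        roster=list(roster),
        weights_mean_normalized=normalize,
        scale_fixed=fix_sigma is not None,
    )


def hazard_ratios(fit: WeibullAFTFit, alpha: float = 0.05) -> pd.DataFrame:
    """HR = exp(-beta/sigma) per non-reference level; delta-method CI on the
    log-HR scale using the joint covariance of (beta, log sigma)."""
    zc = stats.norm.ppf(1 - alpha / 2)
    inv_sig = 1.0 / fit.sigma
    rows = []
    for col in fit.columns:
        b = float(fit.beta[col])
        log_hr = -b * inv_sig
        var_b = float(fit.cov.loc[col, col])
        if fit.scale_fixed:
            var = var_b * inv_sig**2
        else:
            var_s = float(fit.cov.loc["log_sigma", "log_sigma"])
            cov_bs = float(fit.cov.loc[col, "log_sigma"])
            # g = -b*exp(-s): dg/db = -exp(-s), dg/ds = b*exp(-s)
            var = (
                inv_sig**2 * var_b
                + (b * inv_sig) ** 2 * var_s
                - 2 * inv_sig * (b * inv_sig) * cov_bs
            )
        se = float(np.sqrt(max(var, 0.0)))
        with np.errstate(over="ignore"):
            ci_low, ci_high = float(np.exp(log_hr - zc * se)), float(np.exp(log_hr + zc * se))
        rows.append(
            {
                "term": col,
                "log_hr": log_hr,
                "se_log_hr": se,
                "hr": float(np.exp(log_hr)),
                "ci_low": ci_low,
                "ci_high": ci_high,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def linear_predictor(fit: WeibullAFTFit, cohort: pd.DataFrame) -> np.ndarray:
    """x.beta (no intercept) under the fit's encoding."""
    X, cols = build_design(cohort, fit.predictors, fit.roster)
    if cols != fit.columns:
        raise ValueError("encoding mismatch between fit and cohort")
    return X @ fit.beta.to_numpy()


def predict_risk(
    fit: WeibullAFTFit,
    cohort: pd.DataFrame,
    t: float | np.ndarray,
    *,
    subject_horizon: bool = False,
    max_age: float = 75.0,
) -> np.ndarray:
    """P(T <= t | x) = 1 - exp(-exp((log t - mu - x.beta)/sigma)).

    With subject_horizon=True the evaluation time is min(t, max_age - age)
    per subject."""
    tt = np.broadcast_to(np.asarray(t, dtype=float), (len(cohort),)).copy()
    if subject_horizon:
        tt = np.minimum(tt, max_age - cohort["age"].to_numpy(dtype=float))
    if np.any(tt <= 0):
        raise ValueError("evaluation times must be positive")
    eta = fit.mu + linear_predictor(fit, cohort)
    z = (np.log(tt) - eta) / fit.sigma
    return -np.expm1(-np.exp(np.clip(z, -745.0, 700.0)))


def survival_matrix(fit: WeibullAFTFit, cohort: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    """Model survival S(t|x_i) for every subject (rows) at every time (cols)."""
    times = np.asarray(times, dtype=float)
    eta = fit.mu + linear_predictor(fit, cohort)
    with np.errstate(divide="ignore"):
        logt = np.log(times)
    z = (logt[None, :] - eta[:, None]) / fit.sigma
    out = np.exp(-np.exp(np.clip(z, -745.0, 700.0)))
    out[:, times <= 0] = 1.0
    return out


@dataclass
class PooledEstimates:
    """Rubin's-rules pooling of m Weibull AFT fits on (mu, beta, log sigma)."""

    estimates: pd.Series
    within: pd.Series
    between: pd.Series
    total: pd.Series
    df: pd.Series
    m: int

    def se(self) -> pd.Series:
        return np.sqrt(self.total)


def pool_rubin(fits: Sequence[WeibullAFTFit]) -> PooledEstimates:
    """Pool parameter estimates across imputed-dataset fits.

    total variance T = W + (1 + 1/m) B; small-sample df per Rubin:
    (m-1)(1 + W/((1+1/m)B))^2."""
    if not fits:
        raise ValueError("no fits to pool")
    cols0 = fits[0].columns
    for f in fits[1:]:
        if f.columns != cols0:
            raise ValueError("mismatched encodings across fits")
    m = len(fits)
    params = pd.concat([f.params_vector() for f in fits], axis=1)
    variances = pd.concat(
        [pd.Series(np.diag(f.cov.to_numpy()), index=f.cov.index) for f in fits], axis=1
    )
    qbar = params.mean(axis=1)
    W = variances.mean(axis=1)
    if m > 1:
        B = params.var(axis=1, ddof=1)
    else:
        B = pd.Series(0.0, index=qbar.index)
    T = W + (1.0 + 1.0 / m) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * B / W
        df = (m - 1) * (1.0 + 1.0 / r.replace(0.0, np.nan)) ** 2
    df = df.fillna(np.inf)
    return PooledEstimates(estimates=qbar, within=W, between=B, total=T, df=df, m=m)


def pooled_hazard_ratios(fits: Sequence[WeibullAFTFit], alpha: float = 0.05) -> pd.DataFrame:
    """Rubin-pooled hazard ratios: per-dataset log-HRs (delta-method variances)
    pooled on the log-HR scale, CI from total variance with Rubin df."""
    tables = [hazard_ratios(f, alpha=alpha) for f in fits]
    terms = tables[0].index
    m = len(fits)
    rows = []
    for term in terms:
        est = np.array([tb.loc[term, "log_hr"] for tb in tables])
        var = np.array([tb.loc[term, "se_log_hr"] ** 2 for tb in tables])
        qbar = est.mean()
        W = var.mean()
        B = est.var(ddof=1) if m > 1 else 0.0
        T = W + (1 + 1 / m) * B
        if m > 1 and B > 0:
            df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
            tcrit = stats.t.ppf(1 - alpha / 2, df)
        else:
            df = np.inf
            tcrit = stats.norm.ppf(1 - alpha / 2)
        se = np.sqrt(T)
        with np.errstate(over="ignore"):
            ci_low, ci_high = float(np.exp(qbar - tcrit * se)), float(np.exp(qbar + tcrit * se))
        rows.append(
            {
                "term": term,
                "log_hr": qbar,
                "se_log_hr": se,
                "within_var": W,
                "between_var": B,
                "total_var": T,
                "df": df,
                "hr": float(np.exp(qbar)),
                "ci_low": ci_low,
                "ci_high": ci_high,
            }
        )
    return pd.DataFrame(rows).set_index("term")
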