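"""Predictive-performance measures for a fitted Weibull AFT risk model.

Six measures: Nagelkerke R^2, IPCW integrated Brier score, Harrell's c-index,
discrimination slope, calibration-in-the-large and calibration slope, plus
decile calibration curves.  Censoring is handled explicitly: observed risk via
the weighted Kaplan-Meier estimator, Brier contributions reweighted by the
censoring-distribution KM (Graf's estimator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aftmodel import WeibullAFTFit, fit_weibull_aft, linear_predictor, predict_risk, survival_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PerformanceReport",
    "CalibrationCurve",
    "km_estimate",
    "nagelkerke_r2",
    "integrated_brier_score",
    "harrell_c_index",
    "concordance_index",
    "discrimination_slope",
    "calibration_in_the_large",
    "calibration_slope",
    "calibration_curve",
    "evaluate_model",
]

MEASURE_KEYS = (
    "nagelkerke_r2",
    "integrated_brier",
    "c_index",
    "discrimination_slope",
    "calibration_in_the_large",
    "calibration_slope",
)


@dataclass
class PerformanceReport:
    nagelkerke_r2: float
    integrated_brier: float
    c_index: float
    discrimination_slope: float
    calibration_in_the_large: float
    calibration_slope: float
    horizon: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in MEASURE_KEYS} | {"horizon": self.horizon}


# ---------------------------------------------------------------------------
# Kaplan-Meier


def _km_curve(time, event, weights):
    """Weighted product-limit estimator; returns (event_times, survival)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    w = np.ones_like(time) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(time, kind="stable")
    t, e, w = time[order], event[order], w[order]
    uniq, start = np.unique(t, return_index=True)
    total = w.sum()
    # weight of risk set just before each unique time
    cum_before = np.concatenate([[0.0], np.cumsum(w)])[start]
    at_risk = total - cum_before
    d = np.add.reduceat(w * e, start)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, d / at_risk, 0.0)
    surv = np.clip(np.cumprod(np.clip(1.0 - frac, 0.0, 1.0)), 0.0, 1.0)
    keep = d > 0
    return uniq[keep], surv[keep]


def km_estimate(time, event, weights=None, t: float = None):
    """Weighted KM survival probability at time t (right-continuous)."""
    times, surv = _km_curve(time, event, weights)
    return _km_eval(times, surv, np.asarray(t, dtype=float))


def _km_eval(times, surv, t):
    idx = np.searchsorted(times, t, side="right")
    vals = np.concatenate([[1.0], surv])
    return vals[idx] if np.ndim(t) else float(vals[idx])


# ---------------------------------------------------------------------------
# six measures


def nagelkerke_r2(fit: WeibullAFTFit) -> float:
    """R^2 = [1 - exp(-2(l1-l0)/n)] / [1 - exp(2*l0/n)], n = effective n."""
    n = fit.effective_n
    l1, l0 = fit.loglik, fit.loglik_null
    denom = 1.0 - np.exp(2.0 * l0 / n)
    if denom == 0.0:
        raise ZeroDivisionError("degenerate null model: Nagelkerke denominator is 0")
    return float((1.0 - np.exp(-2.0 * (l1 - l0) / n)) / denom)


def integrated_brier_score(
    fit: WeibullAFTFit,
    cohort: pd.DataFrame,
    tau: float = 5.0,
    *,
    weights: bool = True,
) -> float:
    """Graf-style IPCW integrated Brier score over [0, tau]."""
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=float)
    w = cohort["weight"].to_numpy(dtype=float) if weights else np.ones(len(cohort))
    w = w / w.mean()
    return _ipcw_ibs(fit, cohort, time, event, w, tau)


def _ipcw_ibs(fit, cohort, time, event, w, tau):
    # censoring-distribution KM (events/censorings swapped)
    g_times, g_surv = _km_curve(time, 1.0 - event, w)
    grid = np.unique(np.concatenate([[0.0], np.sort(time[(event == 1) & (time <= tau)]), [tau]]))
    S = survival_matrix(fit, cohort, grid)  # n x len(grid)
    g_at_grid = _km_eval(g_times, g_surv, grid)
    # left limit G(t-) at each subject's own time
    g_at_ti_minus = _km_eval(g_times, g_surv, np.nextafter(time, -np.inf))
    n = len(time)
    dropped = 0
    bs = np.zeros(len(grid))
    for j, t in enumerate(grid):
        died = (time <= t) & (event == 1)
        at_risk = time > t
        contrib = np.zeros(n)
        ok_d = died & (g_at_ti_minus > 0)
        dropped += int(np.sum(died & (g_at_ti_minus <= 0)))
        contrib[ok_d] = S[ok_d, j] ** 2 / g_at_ti_minus[ok_d]
        if g_at_grid[j] > 0:
            contrib[at_risk] = (1.0 - S[at_risk, j]) ** 2 / g_at_grid[j]
        else:
            dropped += int(np.sum(at_risk))
        bs[j] = np.sum(w * contrib) / np.sum(w)
    if dropped:
        logger.warning("IPCW truncation dropped %d subject-contributions", dropped)
    return float(np.trapezoid(bs, grid) / tau)


def concordance_index(time, event, risk, weights=None) -> float:
    """Harrell's c on raw arrays.

    Comparable pairs (i, j): t_i < t_j and delta_i = 1; concordant when the
    earlier failure has the higher predicted risk; risk ties count 1/2.
    O(n log n) via a Fenwick tree over risk ranks."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    risk = np.asarray(risk, dtype=float)
    w = np.ones_like(time) if weights is None else np.asarray(weights, dtype=float)
    n = len(time)
    _, rank = np.unique(risk, return_inverse=True)
    n_ranks = rank.max() + 1
    tree = np.zeros(n_ranks + 1)

    def add(i, v):
        i += 1
        while i <= n_ranks:
            tree[i] += v
            i += i & (-i)

    def prefix(i):  # sum of ranks [0, i]
        i += 1
        s = 0.0
        while i > 0:
            s += tree[i]
            i -= i & (-i)
        return s

    order = np.argsort(time, kind="stable")
    conc = disc = tied = 0.0
    total_inserted = 0.0
    i = n - 1
    while i >= 0:
        j = i
        while j >= 0 and time[order[j]] == time[order[i]]:
            j -= 1
        # subjects with strictly larger time are already in the tree
        for k in range(j + 1, i + 1):
            s = order[k]
            if event[s] == 1:
                below = prefix(rank[s] - 1) if rank[s] > 0 else 0.0
                upto = prefix(rank[s])
                eq = upto - below
                above = total_inserted - upto
                # tree holds the later-failing partners: concordant when the
                # earlier failure s carries the higher risk
                conc += w[s] * below
                disc += w[s] * above
                tied += w[s] * eq
        for k in range(j + 1, i + 1):
            s = order[k]
            add(rank[s], w[s])
            total_inserted += w[s]
        i = j
    denom = conc + disc + tied
    if denom == 0:
        raise ValueError("no comparable pairs")
    return float((conc + 0.5 * tied) / denom)


def harrell_c_index(
    fit: WeibullAFTFit, cohort: pd.DataFrame, horizon: float = 5.0, *, weighted: bool = False
) -> float:
    risk = predict_risk(fit, cohort, horizon)
    w = cohort["weight"].to_numpy(dtype=float) if weighted else None
    return concordance_index(cohort["time"], cohort["event"], risk, weights=w)


def discrimination_slope(
    fit: WeibullAFTFit, cohort: pd.DataFrame, t: float = 5.0
) -> float:
    """Weighted mean predicted t-risk of events minus that of non-events.

    Events: death by t.  Non-events: event-free follow-up >= t.  Subjects
    censored before t have unknown t-status and are excluded."""
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=float)
    w = cohort["weight"].to_numpy(dtype=float)
    risk = predict_risk(fit, cohort, t)
    is_event = (event == 1) & (time <= t)
    is_nonevent = time >= t
    if not is_event.any() or not is_nonevent.any():
        raise ValueError("event or non-event group empty at the requested horizon")
    mean_e = np.average(risk[is_event], weights=w[is_event])
    mean_ne = np.average(risk[is_nonevent], weights=w[is_nonevent])
    return float(mean_e - mean_ne)


def calibration_in_the_large(
    fit: WeibullAFTFit, cohort: pd.DataFrame, t: float = 5.0
) -> float:
    """(1 - KM survival at t) minus the weighted mean predicted t-risk;
    negative values indicate overprediction."""
    w = cohort["weight"].to_numpy(dtype=float)
    observed = 1.0 - km_estimate(cohort["time"], cohort["event"], w, t)
    predicted = float(np.average(predict_risk(fit, cohort, t), weights=w))
    return float(observed - predicted)


def calibration_slope(fit: WeibullAFTFit, cohort: pd.DataFrame) -> float:
    """Coefficient on the frozen linear predictor when a Weibull AFT with its
    own intercept and scale is refit to the cohort; 1 = perfect."""
    lp = linear_predictor(fit, cohort)
    if np.var(lp) <= 0:
        raise ValueError("degenerate linear predictor (zero variance)")
    frame = cohort[["time", "event", "weight"]].copy()
    frame["lp"] = lp
    refit = fit_weibull_aft(frame, ["lp"], roster=[], weight_col="weight")
    return float(refit.beta["lp"])


@dataclass
class CalibrationCurve:
    table: pd.DataFrame  # columns: bin, mean_predicted, observed_km, count
    horizon: float


def calibration_curve(
    fit: WeibullAFTFit,
    cohort: pd.DataFrame,
    t: float = 5.0,
    n_bins: int = 10,
) -> CalibrationCurve:
    """Weighted-quantile decile bins of predicted t-risk with KM observed risk."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    risk = predict_risk(fit, cohort, t)
    w = cohort["weight"].to_numpy(dtype=float)
    order = np.argsort(risk, kind="stable")
    cw = np.cumsum(w[order])
    cuts = cw / cw[-1]
    bin_of_sorted = np.minimum((cuts * n_bins).astype(int), n_bins - 1)
    bins = np.empty(len(risk), dtype=int)
    bins[order] = bin_of_sorted
    if len(np.unique(risk)) < n_bins:
        logger.warning("fewer distinct risks than bins; bins merged")
    rows = []
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=float)
    for b in range(n_bins):
        m = bins == b
        if not m.any():
            continue
        obs = 1.0 - km_estimate(time[m], event[m], w[m], t)
        rows.append(
            {
                "bin": b,
                "mean_predicted": float(np.average(risk[m], weights=w[m])),
                "observed_km": float(obs),
                "count": int(m.sum()),
            }
        )
    return CalibrationCurve(table=pd.DataFrame(rows), horizon=t)


def evaluate_model(
    fit: WeibullAFTFit,
    cohort: pd.DataFrame,
    horizon: float = 5.0,
) -> PerformanceReport:
    """All six measures at the given horizon."""
    return PerformanceReport(
        nagelkerke_r2=nagelkerke_r2(fit),
        integrated_brier=integrated_brier_score(fit, cohort, tau=horizon),
        c_index=harrell_c_index(fit, cohort, horizon=horizon),
        discrimination_slope=discrimination_slope(fit, cohort, t=horizon),
        calibration_in_the_large=calibration_in_the_large(fit, cohort, t=horizon),
        calibration_slope=calibration_slope(fit, cohort),
        horizon=horizon,
    )
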