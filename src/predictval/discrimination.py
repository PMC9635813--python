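"""Discrimination metrics for survival risk predictions.

Royston's D (prognostic separation on the log-hazard-ratio scale),
fixed-horizon ROC AUC with a DeLong confidence interval, and
median-split Kaplan-Meier curves with a log-rank comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .survival import KMCurve, cox_fit, km_fit, logrank_test

#: Royston's scaling constant sqrt(8/pi)
KAPPA = math.sqrt(8.0 / math.pi)


class DegenerateHorizonError(ValueError):
    """No cases or no controls at the requested horizon."""


def _blom_rankits(x: np.ndarray) -> np.ndarray:
    """Expected standard-normal order statistics Phi^-1((i - 3/8)/(n + 1/4)),
    with tied values receiving the average of their rankits."""
    n = x.size
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    # average rankits over ties
    uniq, inv = np.unique(x, return_inverse=True)
    if uniq.size < n:
        sums = np.bincount(inv, weights=z)
        counts = np.bincount(inv)
        z = (sums / counts)[inv]
    return z


@dataclass
class RoystonD:
    d: float
    se: float
    degenerate: bool = False


def royston_d(pi_values, times, events) -> RoystonD:
    """Royston-Sauerbrei D statistic.

    Ranks the prognostic values, replaces them with Blom rankits
    scaled by kappa = sqrt(8/pi), and fits a one-covariate Cox model
    on the scaled rankits; D is the fitted coefficient and SE its
    standard error.  D estimates the log hazard ratio between the two
    equal-sized risk groups obtained by splitting the prognostic index
    at its median.
    """
    pi_values = np.asarray(pi_values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if pi_values.size < 10:
        raise ValueError("need at least 10 observations")
    if not np.all(np.isfinite(pi_values)):
        raise ValueError("prognostic values must be finite")
    if np.ptp(pi_values) == 0.0:
        return RoystonD(0.0, 0.0, degenerate=True)
    z = _blom_rankits(pi_values) / KAPPA
    fit = cox_fit(z[:, None], times, events, names=["rankit"])
    return RoystonD(float(fit.coef[0]), float(fit.se[0]))


# ---------------------------------------------------------------------------
# Fixed-horizon ROC


@dataclass
class HorizonAUC:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    n_excluded: int
    horizon: float


def _delong_variance(cases: np.ndarray, controls: np.ndarray, auc: float) -> float:
    """DeLong structural-component variance of the Mann-Whitney AUC."""
    m, n = cases.size, controls.size
    # placement of each case among controls and vice versa
    v10 = np.empty(m)
    for i, x in enumerate(cases):
        v10[i] = (np.sum(x > controls) + 0.5 * np.sum(x == controls)) / n
    v01 = np.empty(n)
    for j, y in enumerate(controls):
        v01[j] = (np.sum(cases > y) + 0.5 * np.sum(cases == y)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def horizon_auc(risk, times, events, horizon: float, alpha: float = 0.05,
                ci_method: str = "delong", n_boot: int = 2000,
                seed: int | None = None) -> HorizonAUC:
    """AUC of a predicted death probability at a fixed horizon.

    Cases are deaths (any cause) at or before the horizon; controls
    are patients followed to the horizon or beyond without dying by it
    (under administrative censoring at exactly the horizon, survivors
    have time equal to it); patients censored alive before the horizon
    are excluded.  The AUC is the Mann-Whitney
    concordance of risk between cases and controls with half credit
    for ties; the CI is DeLong (default) or a seeded bootstrap.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    is_case = events & (times <= horizon)
    is_control = ~is_case & (times >= horizon)
    excluded = ~(is_case | is_control)
    cases = risk[is_case]
    controls = risk[is_control]
    if cases.size == 0 or controls.size == 0:
        raise DegenerateHorizonError(
            f"degenerate horizon {horizon}: {cases.size} cases, "
            f"{controls.size} controls")

    def _auc(c, k):
        # Mann-Whitney U via rank sums; ties get half credit
        comb = np.concatenate([c, k])
        ranks = stats.rankdata(comb)
        u = ranks[:c.size].sum() - c.size * (c.size + 1) / 2.0
        return u / (c.size * k.size)

    auc = float(_auc(cases, controls))
    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "delong":
        var = _delong_variance(cases, controls, auc)
        half = z * math.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            reps[b] = _auc(rng.choice(cases, cases.size, replace=True),
                           rng.choice(controls, controls.size, replace=True))
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return HorizonAUC(auc, float(max(lo, 0.0)), float(min(hi, 1.0)),
                      int(cases.size), int(controls.size),
                      int(excluded.sum()), float(horizon))


# ---------------------------------------------------------------------------
# Median split


@dataclass
class MedianSplit:
    low: KMCurve
    high: KMCurve
    statistic: float
    p_value: float
    threshold: float


def median_split(risk, times, events) -> MedianSplit:
    """Dichotomize at the median risk and compare survival curves.

    The high-risk group is risk strictly greater than the median;
    ties at the median go to the low-risk group.  Returns the two
    Kaplan-Meier curves and the log-rank test.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if risk.size < 4:
        raise ValueError("need at least 4 observations")
    med = float(np.median(risk))
    high = risk > med
    if high.all() or not high.any():
        raise ValueError("no split possible: all risks identical at the median")
    stat, p = logrank_test(times, events, high.astype(int))
    return MedianSplit(
        low=km_fit(times[~high], events[~high]),
        high=km_fit(times[high], events[high]),
        statistic=stat, p_value=p, threshold=med,
    )


def roc_points(risk, times, events, horizon: float):
    """ROC coordinates (fpr, tpr, threshold) at a fixed horizon, using
    the same case/control definition as :func:`horizon_auc`; plot-ready."""
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    is_case = events & (times <= horizon)
    is_control = ~is_case & (times >= horizon)
    cases, controls = risk[is_case], risk[is_control]
    if cases.size == 0 or controls.size == 0:
        raise DegenerateHorizonError(f"degenerate horizon {horizon}")
    thresholds = np.unique(np.concatenate([risk, [np.inf]]))[::-1]
    tpr = [(cases >= th).mean() for th in thresholds]
    fpr = [(controls >= th).mean() for th in thresholds]
    import pandas as pd

    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
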