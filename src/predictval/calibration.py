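"""Calibration of predicted survival against observed outcomes.

Predicted-vs-observed tables by subgroup, the Integrated Calibration
Index (ICI), and smoothed calibration curves.  The smoother follows
the survival-calibration recipe of Austin and colleagues: regress the
all-cause event on a restricted-cubic-spline basis of the
complementary log-log of predicted risk in a Cox model, then read the
"observed" risk at the horizon off the fitted model (Breslow
baseline).  ICI is the mean absolute difference between predicted and
smoothed observed risk; it is computed on the mortality scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .survival import (breslow_cumulative_hazard, breslow_hazard_at, cox_fit,
                       km_at, km_fit)

log = logging.getLogger(__name__)

RISK_CLIP = 1e-6

#: Harrell's default knot quantiles by knot count
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's truncated-power form).

    Returns an (n, k-1) design: the identity column plus k-2 nonlinear
    terms, linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = knots.size
    if k < 3:
        raise ValueError("need at least 3 knots")
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (pos3(x - tj)
                - pos3(x - tk1) * (tk - tj) / (tk - tk1)
                + pos3(x - tk) * (tk1 - tj) / (tk - tk1))
        cols.append(term / norm)
    return np.column_stack(cols)


def default_knots(x: np.ndarray, n_knots: int = 3) -> np.ndarray:
    qs = _KNOT_QUANTILES.get(n_knots)
    if qs is None:
        qs = np.linspace(0.05, 0.95, n_knots)
    return np.quantile(np.asarray(x, dtype=float), qs)


def _cll(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), RISK_CLIP, 1.0 - RISK_CLIP)
    return np.log(-np.log(1.0 - p))


@dataclass
class CalibrationCurve:
    """Smoothed calibration curve with predicted-risk density and ICI."""

    horizon: float
    grid: np.ndarray
    grid_observed: np.ndarray
    per_patient_predicted: np.ndarray
    per_patient_observed: np.ndarray
    density_grid: np.ndarray
    density: np.ndarray
    ici: float
    n_knots: int
    degenerate: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "predicted": self.grid,
            "observed_smoothed": self.grid_observed,
            "identity": self.grid,
        })


def _smoother(predicted_risk, times, events, horizon, n_knots):
    """Fit the RCS-Cox smoother; returns a callable risk -> smoothed
    observed risk at the horizon, or None if degenerate."""
    cll = _cll(predicted_risk)
    if np.std(cll) < 1e-8:
        return None
    knots = default_knots(cll, n_knots)
    if np.unique(knots).size < knots.size:
        return None
    X = rcs_basis(cll, knots)
    try:
        fit = cox_fit(X, times, events)
    except Exception as exc:  # noqa: BLE001 - any fit failure degrades
        log.warning("calibration smoother Cox fit failed (%s); "
                    "falling back to marginal KM", exc)
        return None
    et, H0 = breslow_cumulative_hazard(X, times, events, fit.coef)
    h0 = breslow_hazard_at(et, H0, horizon)

    def smooth(p):
        b = rcs_basis(_cll(p), knots)
        lp = np.clip(b @ fit.coef, -500, 500)
        return 1.0 - np.exp(-h0 * np.exp(lp))

    return smooth


def ici(predicted_risk, times, events, horizon: float,
        knots: int = 3) -> CalibrationCurve:
    """Integrated Calibration Index at a fixed horizon.

    ``predicted_risk`` is the predicted all-cause death probability by
    the horizon.  The observed counterpart is the RCS-Cox smoothed
    risk evaluated per patient; ICI is the mean absolute difference.
    Follow-up is administratively truncated at the horizon before the
    smoother is fitted, so the proportional-hazards working model only
    has to hold locally over the window it is read out on.
    Near-constant predictions fall back to the marginal Kaplan-Meier
    risk at the horizon for every patient (flagged ``degenerate``).
    """
    predicted_risk = np.clip(np.asarray(predicted_risk, dtype=float),
                             RISK_CLIP, 1.0 - RISK_CLIP)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if predicted_risk.size < 2:
        raise ValueError("need at least 2 observations")
    events = events & (times <= horizon)
    times = np.minimum(times, horizon)

    smooth = _smoother(predicted_risk, times, events, horizon, knots)
    degenerate = smooth is None
    if degenerate:
        km = km_fit(times, events)
        marginal = 1.0 - km_at(km, horizon).survival
        observed = np.full_like(predicted_risk, marginal)

        def smooth(p):  # noqa: F811 - degenerate fallback
            return np.full(np.asarray(p).shape, marginal)
    else:
        observed = smooth(predicted_risk)

    grid = np.linspace(predicted_risk.min(), predicted_risk.max(), 101)
    grid_obs = np.asarray(smooth(grid))
    icival = float(np.mean(np.abs(predicted_risk - observed)))

    dgrid = np.linspace(0.0, 1.0, 201)
    if np.std(predicted_risk) > 0:
        kde = stats.gaussian_kde(predicted_risk)
        dens = kde(dgrid)
    else:
        dens = np.zeros_like(dgrid)
    return CalibrationCurve(
        horizon=float(horizon), grid=grid, grid_observed=grid_obs,
        per_patient_predicted=predicted_risk, per_patient_observed=observed,
        density_grid=dgrid, density=dens, ici=icival, n_knots=knots,
        degenerate=degenerate,
    )


def calibration_curve(predicted_risk, times, events, horizon: float,
                      grid, knots: int = 3) -> CalibrationCurve:
    """Smoothed calibration curve evaluated on a supplied grid of
    predicted risks (otherwise identical to :func:`ici`)."""
    curve = ici(predicted_risk, times, events, horizon, knots)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool) & (times <= horizon)
    times = np.minimum(times, horizon)
    smooth = _smoother(curve.per_patient_predicted, times, events,
                       horizon, knots)
    if smooth is None:
        km = km_fit(times, events)
        marginal = 1.0 - km_at(km, horizon).survival
        grid_obs = np.full_like(grid, marginal)
    else:
        grid_obs = np.asarray(smooth(grid))
    curve.grid = grid
    curve.grid_observed = grid_obs
    return curve


# ---------------------------------------------------------------------------
# Predicted-vs-observed tables


@dataclass
class CalibrationRow:
    stratum: str
    horizon: float
    n: int
    predicted: float
    predicted_ci: tuple
    observed: float
    observed_ci: tuple


@dataclass
class CalibrationTable:
    rows: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{
            "stratum": r.stratum, "horizon": r.horizon, "n": r.n,
            "predicted": r.predicted,
            "predicted_low": r.predicted_ci[0],
            "predicted_high": r.predicted_ci[1],
            "observed": r.observed,
            "observed_low": r.observed_ci[0],
            "observed_high": r.observed_ci[1],
        } for r in self.rows])


def predicted_observed_table(predictions, times, events, horizons,
                             strata) -> CalibrationTable:
    """Tabulate mean predicted vs Kaplan-Meier observed survival.

    Parameters
    ----------
    predictions : mapping horizon -> array of predicted S(t) per patient.
    strata : mapping stratum label -> boolean mask over patients.

    The predicted CI is a normal-approximation CI of the mean; the
    observed CI is the Greenwood complementary-log-log interval.
    Empty strata are omitted with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    z = stats.norm.ppf(0.975)
    table = CalibrationTable()
    for label, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"stratum {label!r} is empty; omitted")
            continue
        km = km_fit(times[mask], events[mask])
        for h in horizons:
            pred = np.asarray(predictions[h], dtype=float)[mask]
            mean = float(pred.mean())
            sem = float(pred.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            obs = km_at(km, h)
            table.rows.append(CalibrationRow(
                stratum=str(label), horizon=float(h), n=n,
                predicted=mean,
                predicted_ci=(max(0.0, mean - z * sem), min(1.0, mean + z * sem)),
                observed=obs.survival,
                observed_ci=(obs.ci_low, obs.ci_high),
            ))
    return table
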