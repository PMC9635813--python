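"""Nonparametric and semiparametric survival estimation.

Kaplan-Meier product-limit curves with Greenwood variance, log-rank
tests, and a Cox proportional-hazards fitter (Newton-Raphson on the
partial likelihood, Efron or Breslow tie handling) with a Breslow
baseline-hazard estimator.  The Cox fitter is deliberately self-
contained so that both tie conventions share one convergence contract
(max |gradient| < 1e-8, at most 50 iterations, step-halving on a
likelihood decrease) and so the calibration stage can reuse its
baseline estimator; lifelines is used as an independent cross-check in
the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class CoxConvergenceError(RuntimeError):
    """Newton iterations failed to converge (e.g. monotone likelihood
    under perfect separation)."""


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``greenwood_sum`` is the running Greenwood sum
    ``sum d_i / (n_i (n_i - d_i))`` used for variance and CIs;
    ``variance`` is ``S(t)^2`` times that sum.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_sum: np.ndarray
    variance: np.ndarray
    max_followup: float
    n: int

    def step_index(self, t: float) -> int:
        """Index of the last event time <= t, or -1 before the first."""
        return int(np.searchsorted(self.event_times, t, side="right")) - 1


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood variance.

    At tied times events precede censorings (censored-at-event-time
    convention): a patient censored at t is still at risk for the
    event at t.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = times.size

    uniq = np.unique(t_sorted[e_sorted])
    at_risk = np.empty(uniq.size)
    d = np.empty(uniq.size)
    for k, t in enumerate(uniq):
        at_risk[k] = np.sum(t_sorted >= t)
        d[k] = np.sum(e_sorted & (t_sorted == t))
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
    gw = np.cumsum(gw_terms)
    with np.errstate(invalid="ignore"):
        var = surv ** 2 * gw
    var = np.where(np.isfinite(var), var, 0.0)  # S=0 steps: variance 0
    return KMCurve(uniq, at_risk, d, surv, gw, var,
                   max_followup=float(times.max()), n=n)


@dataclass
class KMEstimate:
    survival: float
    ci_low: float
    ci_high: float
    beyond_support: bool = False


def km_at(curve: KMCurve, t: float, alpha: float = 0.05,
          transform: str = "cll") -> KMEstimate:
    """Survival at ``t`` with a Greenwood-based confidence interval.

    ``transform`` selects the CI scale: complementary log-log
    (default, bounded in (0,1)), "log", or "plain" (linear).
    Past the last follow-up time the last value is returned flagged
    ``beyond_support``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = curve.step_index(t)
    beyond = t > curve.max_followup
    if idx < 0:
        return KMEstimate(1.0, 1.0, 1.0, beyond)
    s = float(curve.survival[idx])
    gw = float(curve.greenwood_sum[idx])
    z = stats.norm.ppf(1 - alpha / 2)
    if s <= 0.0:
        return KMEstimate(0.0, 0.0, 0.0, beyond)
    if s >= 1.0 or gw == 0.0:
        return KMEstimate(s, s, s, beyond)
    if transform == "cll":
        se_theta = np.sqrt(gw) / abs(np.log(s))
        lo = s ** np.exp(z * se_theta)
        hi = s ** np.exp(-z * se_theta)
    elif transform == "log":
        se = np.sqrt(gw)
        lo, hi = s * np.exp(-z * se), min(1.0, s * np.exp(z * se))
    elif transform == "plain":
        se = s * np.sqrt(gw)
        lo, hi = max(0.0, s - z * se), min(1.0, s + z * se)
    else:
        raise ValueError(f"unknown CI transform {transform!r}")
    return KMEstimate(s, float(lo), float(hi), beyond)


def logrank_test(times, events, groups):
    """Two-group log-rank test; returns (chi-squared statistic, p)."""
    from lifelines.statistics import logrank_test as _lr

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.size}")
    m0, m1 = groups == labels[0], groups == labels[1]
    res = _lr(times[m0], times[m1], event_observed_A=events[m0],
              event_observed_B=events[m1])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    coef: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    ties: str
    names: list

    def summary(self):
        import pandas as pd

        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "HR": self.hr,
            "HR 95% low": self.ci_low, "HR 95% high": self.ci_high,
            "p": self.p_values,
        }, index=self.names)


def _cox_loglik(beta, X, times, events, ties):
    """Partial log-likelihood, gradient and Hessian (negative of the
    observed information).  O(n log n + n p^2) single pass over event
    times in decreasing order with running risk-set sums."""
    n, p = X.shape
    order = np.argsort(-times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]
    eta = Xs @ beta
    # guard against overflow in exp
    w = np.exp(np.clip(eta, -500, 500))

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            wx = w[j] * Xs[j]
            S0 += w[j]
            S1 += wx
            S2 += np.outer(wx, Xs[j])
            j += 1
        tied = np.arange(i, j)[es[i:j]]
        d = tied.size
        if d > 0:
            ll += float(eta[tied].sum())
            grad += Xs[tied].sum(axis=0)
            wD = w[tied]
            D0 = float(wD.sum())
            D1 = (wD[:, None] * Xs[tied]).sum(axis=0)
            D2 = np.einsum("i,ij,ik->jk", wD, Xs[tied], Xs[tied])
            for ell in range(d):
                f = ell / d if ties == "efron" else 0.0
                den = S0 - f * D0
                m1 = (S1 - f * D1) / den
                m2 = (S2 - f * D2) / den
                ll -= np.log(den)
                grad -= m1
                hess += m2 - np.outer(m1, m1)
        i = j
    return ll, grad, hess


def cox_fit(X, times, events, names=None, ties: str = "efron",
            tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Raises :class:`CoxConvergenceError` on non-convergence or a
    monotone likelihood (perfect separation) instead of returning a
    silent result.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(times).size == X.shape[1]:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n, p = X.shape
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if n <= p:
        raise ValueError(f"n={n} must exceed number of covariates p={p}")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate column")
    if not events.any():
        raise ValueError("no events observed")
    if names is None:
        names = [f"x{k}" for k in range(p)]

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik(beta, X, times, events, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}")
        # step-halving on likelihood decrease; the acceptance slack is
        # relative to |ll| since near the optimum the likelihood moves
        # by less than float64 resolution on large samples
        scale = 1.0
        ll_slack = 1e-10 * (abs(ll) + 1.0)
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = _cox_loglik(cand, X, times, events, ties)
            if ll_new >= ll - ll_slack:
                break
            scale /= 2.0
        else:
            raise CoxConvergenceError("step-halving failed to improve likelihood")
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.max(np.abs(scale * step)) < 1e-10:
            # parameter change below numerical resolution: the gradient
            # is as small as double precision permits
            converged = True
            break
        if np.max(np.abs(beta)) > 80:
            raise CoxConvergenceError(
                "coefficients diverging (monotone likelihood / perfect separation)")
    if not converged and np.max(np.abs(grad)) >= tol:
        raise CoxConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(max |gradient| = {np.max(np.abs(grad)):.3g})")

    cov = np.linalg.inv(hess)
    cov = (cov + cov.T) / 2.0
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    hr = np.exp(beta)
    return CoxFit(
        coef=beta, cov=cov, se=se, hr=hr,
        ci_low=np.exp(np.clip(beta - z * se, -700, 700)),
        ci_high=np.exp(np.clip(beta + z * se, -700, 700)),
        p_values=2 * stats.norm.sf(np.abs(beta / np.where(se > 0, se, np.inf))),
        log_likelihood=float(ll), n_iter=it, converged=True, ties=ties,
        names=list(names),
    )


def breslow_cumulative_hazard(X, times, events, beta):
    """Breslow baseline cumulative hazard H0 at each unique event time.

    Returns (event_times, H0) for the covariate origin x = 0;
    ``H(t | x) = H0(t) * exp(x @ beta)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(times).size:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    w = np.exp(np.clip(X @ np.asarray(beta, dtype=float), -500, 500))
    uniq = np.unique(times[events])
    h0 = np.empty(uniq.size)
    for k, t in enumerate(uniq):
        d = np.sum(events & (times == t))
        s0 = w[times >= t].sum()
        h0[k] = d / s0
    return uniq, np.cumsum(h0)


def breslow_hazard_at(event_times, H0, t: float) -> float:
    idx = int(np.searchsorted(event_times, t, side="right")) - 1
    return 0.0 if idx < 0 else float(H0[idx])
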