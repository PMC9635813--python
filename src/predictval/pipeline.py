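"""End-to-end external-validation pipeline.

Runs the full validation of the scoring engine against a cohort:
administrative censoring at 10 years, per-patient prediction at 5 and
10 years, per-ER-stratum discrimination (Royston D, median-split
curves, fixed-horizon AUC) and calibration (predicted-vs-observed
tables, ICI, smoothed curves with predicted-risk density), overall
Kaplan-Meier curves, a multivariable all-cause Cox model, and a
baseline characteristics table.  The report is a plain JSON-able
structure; tables and curve coordinates are exported as CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import ici as compute_ici
from .calibration import predicted_observed_table
from .cohort import Cohort, baseline_table, censor_at
from .discrimination import (DegenerateHorizonError, horizon_auc,
                             median_split, roc_points, royston_d)
from .engine import CoefficientSet, predict_cohort
from .survival import CoxConvergenceError, cox_fit, km_at, km_fit

log = logging.getLogger(__name__)


@dataclass
class ValidationConfig:
    horizons: tuple = (5.0, 10.0)
    censor_years: float = 10.0
    knots: int = 3
    strata_var: str = "er"
    clamp: bool = True


class PipelineError(RuntimeError):
    """A named pipeline stage failed."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _round(x, nd=10):
    """Stable rounding so reports are byte-identical across runs."""
    if isinstance(x, float):
        return round(x, nd)
    return x


def _km_readout(km, t):
    est = km_at(km, t)
    return {"survival": _round(est.survival), "ci_low": _round(est.ci_low),
            "ci_high": _round(est.ci_high),
            "beyond_support": est.beyond_support}


#: Table-2-style multivariable covariate coding: age and size linear,
#: grade as a linear score, nodes as a count, indicators for screening
#: detection, ER-negative status and each adjuvant treatment.  Patients
#: with unknown detection mode are excluded (their count is logged).
_COX_COVARIATES = [
    "age", "screening", "size", "grade", "nodes", "er_negative",
    "hormone", "chemo", "trastuzumab",
]


def _cox_table(cohort: Cohort):
    df = cohort.to_frame()
    known = df["detection"] != "unknown"
    n_excl = int((~known).sum())
    if n_excl:
        log.info("multivariable Cox: excluding %d patients with unknown "
                 "detection mode", n_excl)
    df = df[known]
    X = np.column_stack([
        df["age_years"].to_numpy(float),
        (df["detection"] == "screening").to_numpy(float),
        df["size_mm"].to_numpy(float),
        df["grade"].to_numpy(float),
        df["nodes"].to_numpy(float),
        (df["er"] == "negative").to_numpy(float),
        df["hormone"].to_numpy(float),
        df["chemo"].to_numpy(float),
        df["trastuzumab"].to_numpy(float),
    ])
    keep = [k for k in range(X.shape[1]) if X[:, k].std() > 0]
    times = df["followup_days"].to_numpy(float) / 365.25
    events = df["dead"].to_numpy(bool)
    fit = cox_fit(X[:, keep], times, events,
                  names=[_COX_COVARIATES[k] for k in keep])
    out = {}
    for i, name in enumerate(fit.names):
        out[name] = {"hr": _round(float(fit.hr[i])),
                     "ci_low": _round(float(fit.ci_low[i])),
                     "ci_high": _round(float(fit.ci_high[i])),
                     "p": _round(float(fit.p_values[i]))}
    return out, n_excl


def _subgroup_masks(df: pd.DataFrame) -> dict:
    """Subgroups for the predicted-vs-observed table: ER status, age
    group, tumour size, nodal burden, adjuvant-therapy combination."""
    masks = {
        "all": np.ones(len(df), dtype=bool),
        "er_positive": (df["er"] == "positive").to_numpy(),
        "er_negative": (df["er"] == "negative").to_numpy(),
        "age_lt50": (df["age_years"] < 50).to_numpy(),
        "age_50_65": ((df["age_years"] >= 50) & (df["age_years"] < 65)).to_numpy(),
        "age_ge65": (df["age_years"] >= 65).to_numpy(),
        "size_lt20": (df["size_mm"] < 20).to_numpy(),
        "size_20_50": ((df["size_mm"] >= 20) & (df["size_mm"] < 50)).to_numpy(),
        "size_ge50": (df["size_mm"] >= 50).to_numpy(),
        "nodes_0": (df["nodes"] == 0).to_numpy(),
        "nodes_1_3": ((df["nodes"] >= 1) & (df["nodes"] <= 3)).to_numpy(),
        "nodes_ge4": (df["nodes"] >= 4).to_numpy(),
        "hormone_only": (df["hormone"] & ~df["chemo"] & ~df["trastuzumab"]).to_numpy(),
        "chemo_only": (~df["hormone"] & df["chemo"] & ~df["trastuzumab"]).to_numpy(),
        "hormone_chemo": (df["hormone"] & df["chemo"]).to_numpy(),
        "trastuzumab": df["trastuzumab"].to_numpy(),
    }
    return masks


def run_validation(cohort: Cohort, coeffs: CoefficientSet,
                   config: ValidationConfig | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Execute the full validation and return the report dict.

    If ``out_dir`` is given, the report JSON, tables and plot-ready
    curve coordinates (ROC, calibration, KM) are written there.
    """
    config = config or ValidationConfig()
    artifacts: dict[str, pd.DataFrame] = {}
    report: dict = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except (DegenerateHorizonError, CoxConvergenceError,
                    ValueError) as exc:
                raise PipelineError(name, exc) from exc
        return deco

    @stage("censor")
    def cohort10():
        return censor_at(cohort, config.censor_years)

    @stage("predict")
    def preds():
        return predict_cohort(cohort10, coeffs, config.horizons,
                              clamp=config.clamp)

    df = cohort10.to_frame()
    times = df["followup_days"].to_numpy(float) / 365.25
    events = df["dead"].to_numpy(bool)

    report["metadata"] = {
        "package_version": __version__,
        "coefficients_version": coeffs.version,
        "n": len(cohort10),
        "horizons": list(config.horizons),
        "censor_years": config.censor_years,
        "knots": config.knots,
        "config_hash": hashlib.sha256(
            json.dumps({"horizons": list(config.horizons),
                        "censor": config.censor_years,
                        "knots": config.knots,
                        "coeffs": coeffs.version},
                       sort_keys=True).encode()).hexdigest()[:16],
    }

    @stage("baseline_table")
    def bt():
        return baseline_table(cohort10, group_var=config.strata_var)

    report["baseline_table"] = [
        {"variable": r.variable, "test": r.test,
         "p_value": _round(r.p_value) if r.p_value is not None else None}
        for r in bt.rows
    ]
    artifacts["baseline_table"] = bt.to_frame()

    @stage("cox_multivariable")
    def cox_result():
        return _cox_table(cohort10)

    report["cox_all_cause"], report["metadata"]["cox_excluded_unknown_detection"] = cox_result

    # overall KM by stratum
    strata = ("positive", "negative")
    stratum_masks = {s: (df["er"] == s).to_numpy() for s in strata}
    report["km_overall"] = {}
    for s in strata:
        m = stratum_masks[s]
        if m.sum() == 0:
            log.warning("stratum %r is empty; omitted from report", s)
            continue
        km = km_fit(times[m], events[m])
        report["km_overall"][s] = {
            f"{h:g}y": _km_readout(km, h) for h in config.horizons}

    # discrimination & calibration per stratum and horizon; risk is the
    # predicted all-cause mortality by the horizon
    report["discrimination"] = {}
    report["calibration"] = {}
    for s in ("all",) + strata:
        m = np.ones(len(df), bool) if s == "all" else stratum_masks[s]
        if m.sum() == 0:
            log.warning("stratum %r is empty; omitted from report", s)
            continue
        disc_s, cal_s = {}, {}
        for h in config.horizons:
            key = f"{h:g}y"
            risk = 1.0 - preds[f"S_{h:g}"].to_numpy(float)[m]
            t_h = np.minimum(times[m], h)
            e_h = events[m] & (times[m] <= h)
            entry: dict = {}
            try:
                d = royston_d(risk, t_h, e_h)
                entry["royston_d"] = _round(d.d)
                entry["royston_d_se"] = _round(d.se)
            except (ValueError, CoxConvergenceError) as exc:
                log.warning("Royston D failed for %s %s: %s", s, key, exc)
                entry["royston_d"] = None
            try:
                a = horizon_auc(risk, times[m], events[m], h)
                entry["auc"] = _round(a.auc)
                entry["auc_ci"] = [_round(a.ci_low), _round(a.ci_high)]
                artifacts[f"roc_{s}_{h:g}y"] = roc_points(
                    risk, times[m], events[m], h)
            except DegenerateHorizonError as exc:
                log.warning("AUC degenerate for %s %s: %s", s, key, exc)
                entry["auc"] = None
            try:
                ms = median_split(risk, t_h, e_h)
                entry["median_split_logrank_p"] = _round(ms.p_value)
                lowt = km_at(ms.low, h)
                hight = km_at(ms.high, h)
                entry["km_low_risk"] = _round(lowt.survival)
                entry["km_high_risk"] = _round(hight.survival)
            except ValueError as exc:
                log.warning("median split failed for %s %s: %s", s, key, exc)
            disc_s[key] = entry

            curve = compute_ici(risk, times[m], events[m], h,
                                knots=config.knots)
            cal_s[key] = {
                "ici": _round(curve.ici),
                "degenerate_smoother": curve.degenerate,
                "mean_predicted_survival": _round(float(1.0 - risk.mean())),
                "observed_survival": _km_readout(
                    km_fit(times[m], events[m]), h),
            }
            artifacts[f"calibration_curve_{s}_{h:g}y"] = pd.DataFrame({
                "predicted": curve.grid,
                "observed_smoothed": curve.grid_observed,
                "identity": curve.grid,
            })
            artifacts[f"risk_density_{s}_{h:g}y"] = pd.DataFrame({
                "risk": curve.density_grid, "density": curve.density,
            })
        report["discrimination"][s] = disc_s
        report["calibration"][s] = cal_s

    @stage("predicted_observed")
    def po():
        predictions = {h: preds[f"S_{h:g}"].to_numpy(float)
                       for h in config.horizons}
        return predicted_observed_table(
            predictions, times, events, config.horizons, _subgroup_masks(df))

    artifacts["predicted_observed"] = po.to_frame()
    report["predicted_observed"] = [
        {k: _round(v) if isinstance(v, float) else v
         for k, v in row.items()}
        for row in po.to_frame().to_dict(orient="records")
    ]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for name, frame in artifacts.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        log.info("wrote report and %d artifact tables to %s",
                 len(artifacts), out)
    return report
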