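"""Competing-risk prognostic scoring engine (PREDICT-style, v2.1 layout).

The model scores one patient with three linear predictors:

* PI — prognostic index for breast-cancer-specific mortality: a sum of
  weighted, fractional-polynomial-transformed covariates (per ER
  stratum), each centred at the development-cohort mean.
* MI — mortality index for other-cause mortality, a function of age
  alone: ``a * ((age/10)^2 - b)``.
* TE — treatment effect: the sum of the log hazard ratios of the
  adjuvant treatments actually received (hormone therapy counts only
  in the ER-positive stratum).

Survival probabilities follow from baseline log cumulative hazards
``L0(t)`` via the double-exponential composition

    bS(t) = exp(-exp(L0_breast(t) + PI + TE))
    oS(t) = exp(-exp(L0_other(t)  + MI))
    S(t)  = bS(t) * oS(t)          (independent competing risks)

Note the "baseline survival at time t" term inside exp(-exp(.)) is the
baseline *log cumulative hazard* — the only reading under which the
composition yields probabilities in (0, 1); equivalently
``bS = exp(-H0(t) * e^(PI+TE))`` with ``H0 = exp(L0)``.

Coefficient sets are versioned YAML/JSON configurations; every term is
expressed in a small transform DSL so that tests can run on toy
coefficient sets and the shipped v2.1 transcription is plain data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import Cohort, PatientRecord

log = logging.getLogger(__name__)

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class CoefficientError(ValueError):
    """Invalid coefficient configuration."""


class RangeError(ValueError):
    """Covariate or horizon outside the admissible range."""


# ---------------------------------------------------------------------------
# Transform DSL


@dataclass(frozen=True)
class TransformSpec:
    """Fractional-polynomial transform ``g((x + shift)/divisor)``.

    ``power`` is the FP power (0 means natural log); ``with_log``
    multiplies the result by ``ln((x+shift)/divisor)`` — the repeated-
    power convention for FP2 models (e.g. ``(age/10)^-2 * ln(age/10)``).
    """

    divisor: float = 1.0
    power: float = 1.0
    with_log: bool = False
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.power not in FP_POWERS:
            raise CoefficientError(
                f"power {self.power} not an admissible FP power {FP_POWERS}")
        if self.divisor == 0:
            raise CoefficientError("divisor must be non-zero")

    def __call__(self, x: float) -> float:
        u = (x + self.shift) / self.divisor
        if u <= 0:
            raise RangeError(f"transform argument {u} <= 0 (x={x})")
        v = math.log(u) if self.power == 0.0 else u ** self.power
        if self.with_log:
            v *= math.log(u)
        return v


@dataclass(frozen=True)
class PITerm:
    """One additive PI contribution.

    Numeric terms contribute ``coefficient * (transform(x) - center)``;
    categorical terms contribute a per-level offset (the offset already
    includes any coefficient).
    """

    covariate: str
    coefficient: float = 0.0
    transform: TransformSpec | None = None
    center: float = 0.0
    levels: Mapping[str, float] | None = None

    def evaluate(self, record: PatientRecord) -> float:
        value = getattr(record, self.covariate)
        if self.levels is not None:
            key = str(value).lower()
            if key not in self.levels:
                raise RangeError(
                    f"level {value!r} of {self.covariate} has no offset")
            return float(self.levels[key])
        tf = self.transform or TransformSpec()
        return self.coefficient * (tf(float(value)) - self.center)


# ---------------------------------------------------------------------------
# Baseline log cumulative hazards


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline log cumulative hazard L0(t), t in years.

    Either parametric — ``L0(t) = intercept + sum_k coef_k * g_k(t)``
    with ``g_k`` drawn from the same FP basis as the covariate DSL — or
    a year-indexed lookup table with linear interpolation between the
    tabulated (monotone) values.
    """

    kind: str                                   # "parametric" | "table"
    intercept: float = 0.0
    terms: tuple = ()                           # (coef, power, with_log)
    years: tuple = ()
    log_cum_hazard: tuple = ()
    support: tuple = (1e-6, 15.0)

    def __call__(self, t: float) -> float:
        lo, hi = self.support
        if not (lo <= t <= hi):
            raise RangeError(f"t={t} outside baseline support [{lo}, {hi}]")
        if self.kind == "table":
            return float(np.interp(t, self.years, self.log_cum_hazard))
        v = self.intercept
        for coef, power, with_log in self.terms:
            g = math.log(t) if power == 0.0 else t ** power
            if with_log:
                g *= math.log(t)
            v += coef * g
        return v

    def cum_hazard(self, t: float) -> float:
        if t <= 0:
            return 0.0
        return math.exp(self(t))

    def check_monotone(self, n_grid: int = 200) -> None:
        lo, hi = self.support
        ts = np.linspace(lo, hi, n_grid)
        vals = np.array([self(t) for t in ts])
        if np.any(np.diff(vals) < -1e-10):
            raise CoefficientError(
                "baseline log cumulative hazard is decreasing over its support")


# ---------------------------------------------------------------------------
# Coefficient sets


#: defaults as printed in the model's published description
MI_A_DEFAULT = 0.0698252
MI_B_DEFAULT = 34.23391957

REQUIRED_TREATMENTS = ("hormone", "chemo", "trastuzumab")

_RECORD_FIELDS = set(PatientRecord.__dataclass_fields__)


@dataclass
class CoefficientSet:
    """Versioned model weights for the scoring engine."""

    version: str
    pi_terms: Mapping[str, Sequence[PITerm]]        # "positive"/"negative"
    baseline_breast: Mapping[str, BaselineSpec]
    baseline_other: BaselineSpec
    treatments: Mapping[str, float]                 # name -> log hazard ratio
    mi_a: float = MI_A_DEFAULT
    mi_b: float = MI_B_DEFAULT
    ranges: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in REQUIRED_TREATMENTS:
            if name not in self.treatments:
                raise CoefficientError(f"missing treatment entry {name!r}")
        for stratum, terms in self.pi_terms.items():
            for term in terms:
                if term.covariate not in _RECORD_FIELDS:
                    raise CoefficientError(
                        f"PI term references unknown field {term.covariate!r} "
                        f"(stratum {stratum!r})")
        for spec in (*self.baseline_breast.values(), self.baseline_other):
            spec.check_monotone()

    def range_of(self, name: str) -> tuple | None:
        r = self.ranges.get(name)
        return tuple(r) if r is not None else None


_TERM_KEYS = {"covariate", "coefficient", "transform", "center", "levels"}
_TRANSFORM_KEYS = {"divisor", "power", "with_log", "shift"}
_BASELINE_KEYS = {"kind", "intercept", "terms", "years", "log_cum_hazard", "support"}
_TOP_KEYS = {"version", "pi_terms", "baseline_breast", "baseline_other",
             "treatments", "mi", "ranges"}


def _build_term(d: Mapping) -> PITerm:
    unknown = set(d) - _TERM_KEYS
    if unknown:
        raise CoefficientError(f"unknown PI term key(s): {sorted(unknown)}")
    tf = None
    if "transform" in d and d["transform"] is not None:
        td = dict(d["transform"])
        bad = set(td) - _TRANSFORM_KEYS
        if bad:
            raise CoefficientError(f"unknown transform key(s): {sorted(bad)}")
        tf = TransformSpec(**td)
    levels = d.get("levels")
    return PITerm(
        covariate=d["covariate"],
        coefficient=float(d.get("coefficient", 0.0)),
        transform=tf,
        center=float(d.get("center", 0.0)),
        levels={str(k).lower(): float(v) for k, v in levels.items()}
        if levels is not None else None,
    )


def _build_baseline(d: Mapping) -> BaselineSpec:
    unknown = set(d) - _BASELINE_KEYS
    if unknown:
        raise CoefficientError(f"unknown baseline key(s): {sorted(unknown)}")
    kind = d.get("kind", "parametric")
    if kind == "table":
        years = tuple(float(y) for y in d["years"])
        vals = tuple(float(v) for v in d["log_cum_hazard"])
        if len(years) != len(vals) or len(years) < 2:
            raise CoefficientError("baseline table needs >= 2 (year, value) pairs")
        if any(np.diff(years) <= 0):
            raise CoefficientError("baseline table years must be increasing")
        return BaselineSpec(kind="table", years=years, log_cum_hazard=vals,
                            support=(years[0], years[-1]))
    terms = tuple(
        (float(t["coef"]), float(t.get("power", 1.0)), bool(t.get("with_log", False)))
        for t in d.get("terms", ())
    )
    support = tuple(d.get("support", (1e-6, 15.0)))
    return BaselineSpec(kind="parametric", intercept=float(d.get("intercept", 0.0)),
                        terms=terms, support=support)


def coefficient_set_from_dict(d: Mapping) -> CoefficientSet:
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise CoefficientError(f"unknown top-level key(s): {sorted(unknown)}")
    if "version" not in d:
        raise CoefficientError("version label is mandatory")
    mi = d.get("mi", {})
    return CoefficientSet(
        version=str(d["version"]),
        pi_terms={
            str(stratum): [_build_term(t) for t in terms]
            for stratum, terms in d.get("pi_terms", {}).items()
        },
        baseline_breast={
            str(stratum): _build_baseline(b)
            for stratum, b in d["baseline_breast"].items()
        },
        baseline_other=_build_baseline(d["baseline_other"]),
        treatments={str(k): float(v) for k, v in d["treatments"].items()},
        mi_a=float(mi.get("a", MI_A_DEFAULT)),
        mi_b=float(mi.get("b", MI_B_DEFAULT)),
        ranges={str(k): tuple(v) for k, v in d.get("ranges", {}).items()},
    )


def load_coefficients(path) -> CoefficientSet:
    """Load and fully validate a coefficient configuration (YAML or JSON)."""
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, Mapping):
        raise CoefficientError(f"coefficient file {path} is not a mapping")
    return coefficient_set_from_dict(d)


def default_coefficients() -> CoefficientSet:
    """The packaged v2.1 coefficient transcription."""
    ref = resources.files("predictval") / "data" / "predict_v21.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return coefficient_set_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Scoring


def _clamped(record: PatientRecord, coeffs: CoefficientSet, clamp: bool) -> PatientRecord:
    import dataclasses as _dc

    updates = {}
    for name in ("age_years", "size_mm", "nodes"):
        rng = coeffs.range_of(name)
        if rng is None:
            continue
        v = getattr(record, name)
        if v < rng[0] or v > rng[1]:
            if not clamp:
                raise RangeError(
                    f"record {record.id!r}: {name}={v} outside {rng}")
            clamped = min(max(v, rng[0]), rng[1])
            if name == "nodes":
                clamped = int(clamped)
            log.warning("record %r: clamped %s from %s to %s",
                        record.id, name, v, clamped)
            updates[name] = clamped
    return _dc.replace(record, **updates) if updates else record


def compute_pi(record: PatientRecord, coeffs: CoefficientSet,
               clamp: bool = True) -> float:
    """Prognostic index: sum of weighted, centred covariate transforms
    for the record's ER stratum."""
    if record.er not in coeffs.pi_terms:
        raise CoefficientError(f"no PI terms for ER stratum {record.er!r}")
    rec = _clamped(record, coeffs, clamp)
    return float(sum(term.evaluate(rec) for term in coeffs.pi_terms[record.er]))


def compute_mi(age_years: float, coeffs: CoefficientSet) -> float:
    """Other-cause mortality index ``a * ((age/10)^2 - b)``."""
    if age_years <= 0:
        raise RangeError(f"age must be positive, got {age_years}")
    return coeffs.mi_a * ((age_years / 10.0) ** 2 - coeffs.mi_b)


def compute_te(record: PatientRecord, coeffs: CoefficientSet) -> float:
    """Treatment effect: sum of log hazard ratios of received adjuvant
    treatments relevant to the record's ER stratum.

    Hormone therapy contributes only for ER-positive tumours; a hormone
    flag on an ER-negative record is ignored with a logged warning.
    Radiotherapy carries no effect term in this model.
    """
    te = 0.0
    if record.hormone:
        if record.er == "positive":
            te += coeffs.treatments["hormone"]
        else:
            log.warning("record %r: hormone therapy flag on ER-negative "
                        "record; term excluded", record.id)
    if record.chemo:
        te += coeffs.treatments["chemo"]
    if record.trastuzumab:
        te += coeffs.treatments["trastuzumab"]
    return float(te)


def breast_survival(t: float, pi: float, te: float, stratum: str,
                    coeffs: CoefficientSet) -> float:
    """bS(t) = exp(-exp(L0_breast(t) + PI + TE)); bS(0) = 1."""
    if t == 0:
        return 1.0
    l0 = coeffs.baseline_breast[stratum](t)
    return math.exp(-math.exp(l0 + pi + te))


def other_survival(t: float, mi: float, coeffs: CoefficientSet) -> float:
    """oS(t) = exp(-exp(L0_other(t) + MI)); oS(0) = 1."""
    if t == 0:
        return 1.0
    return math.exp(-math.exp(coeffs.baseline_other(t) + mi))


@dataclass(frozen=True)
class RiskPrediction:
    """Linear predictors and survival probabilities for one patient."""

    id: str
    pi: float
    mi: float
    te: float
    horizons: tuple
    breast_surv: tuple
    other_surv: tuple
    overall_surv: tuple

    def survival_at(self, t: float) -> float:
        return self.overall_surv[self.horizons.index(t)]

    def mortality_at(self, t: float) -> float:
        """All-cause death probability by t: 1 - S(t)."""
        return 1.0 - self.survival_at(t)


def predict_overall_survival(record: PatientRecord, coeffs: CoefficientSet,
                             horizons: Sequence[float] = (5.0, 10.0),
                             clamp: bool = True) -> RiskPrediction:
    """Score one patient: PI, MI, TE and bS/oS/S at each horizon."""
    pi = compute_pi(record, coeffs, clamp=clamp)
    mi = compute_mi(record.age_years, coeffs)
    te = compute_te(record, coeffs)
    bs, os_, s = [], [], []
    for t in horizons:
        b = breast_survival(t, pi, te, record.er, coeffs)
        o = other_survival(t, mi, coeffs)
        bs.append(b)
        os_.append(o)
        s.append(b * o)
    return RiskPrediction(
        id=record.id, pi=pi, mi=mi, te=te,
        horizons=tuple(float(t) for t in horizons),
        breast_surv=tuple(bs), other_surv=tuple(os_), overall_surv=tuple(s),
    )


def predict_cohort(cohort: Cohort, coeffs: CoefficientSet,
                   horizons: Sequence[float] = (5.0, 10.0),
                   clamp: bool = True):
    """Score every patient; returns a DataFrame with one row per patient."""
    import pandas as pd

    rows = []
    for rec in cohort:
        pred = predict_overall_survival(rec, coeffs, horizons, clamp=clamp)
        row = {"id": rec.id, "er": rec.er, "pi": pred.pi, "mi": pred.mi,
               "te": pred.te}
        for i, t in enumerate(pred.horizons):
            key = f"{t:g}"
            row[f"bS_{key}"] = pred.breast_surv[i]
            row[f"oS_{key}"] = pred.other_surv[i]
            row[f"S_{key}"] = pred.overall_surv[i]
        rows.append(row)
    return pd.DataFrame(rows)
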