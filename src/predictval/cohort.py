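"""Patient-level cohort handling.

Reads and validates cohort CSV files, applies administrative censoring,
and builds baseline characteristics tables ("Table 1" style) with
group-comparison tests.

A cohort row describes one early-breast-cancer patient at primary
surgery: age, menopausal status, detection mode, tumour size, grade,
positive axillary nodes, ER/HER2/Ki67 status, adjuvant treatment flags,
and follow-up outcome (time in days, vital status, cause of death).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_YEAR = 365.25

MENOPAUSE_LEVELS = ("pre", "post", "unknown")
DETECTION_LEVELS = ("screening", "symptoms", "unknown")
ER_LEVELS = ("positive", "negative")
TRI_LEVELS = ("positive", "negative", "unknown")
CAUSE_LEVELS = ("breast", "other", "unknown")

#: admissible age range (years); records outside are rejected at read time
AGE_RANGE = (18.0, 100.0)


class CohortSchemaError(ValueError):
    """A mandatory column is missing or unmappable."""


class CohortRowError(ValueError):
    """One or more rows failed validation; message lists row ids and fields."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates, treatments and follow-up outcome."""

    id: str
    age_years: float
    menopause: str
    detection: str
    size_mm: float
    grade: int
    nodes: int
    er: str
    her2: str
    ki67: str
    hormone: bool
    chemo: bool
    trastuzumab: bool
    radiotherapy: bool
    followup_days: float
    dead: bool
    cause: str | None = None

    def __post_init__(self) -> None:
        problems = validate_record_fields(dataclasses.asdict(self))
        if problems:
            raise CohortRowError(
                f"record {self.id!r}: " + "; ".join(problems)
            )

    @property
    def followup_years(self) -> float:
        return self.followup_days / DAYS_PER_YEAR


def validate_record_fields(d: Mapping[str, object]) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    problems: list[str] = []

    def _num(name):
        try:
            return float(d[name])  # type: ignore[arg-type]
        except (TypeError, ValueError):
            problems.append(f"field {name}: unparseable value {d[name]!r}")
            return None

    age = _num("age_years")
    if age is not None and not (AGE_RANGE[0] <= age <= AGE_RANGE[1]):
        problems.append(f"field age_years: {age} outside {AGE_RANGE}")
    size = _num("size_mm")
    if size is not None and size <= 0:
        problems.append(f"field size_mm: must be positive, got {size}")
    if d["grade"] not in (1, 2, 3):
        problems.append(f"field grade: must be 1, 2 or 3, got {d['grade']!r}")
    nodes = d["nodes"]
    if not isinstance(nodes, (int, np.integer)) or nodes < 0:
        problems.append(f"field nodes: must be a non-negative integer, got {nodes!r}")
    fup = _num("followup_days")
    if fup is not None and fup < 0:
        problems.append(f"field followup_days: must be >= 0, got {fup}")
    for name, levels in (
        ("menopause", MENOPAUSE_LEVELS),
        ("detection", DETECTION_LEVELS),
        ("er", ER_LEVELS),
        ("her2", TRI_LEVELS),
        ("ki67", TRI_LEVELS),
    ):
        if d[name] not in levels:
            problems.append(f"field {name}: {d[name]!r} not in {levels}")
    if d["cause"] is not None:
        if not d["dead"]:
            problems.append("field cause: present but patient not dead")
        elif d["cause"] not in CAUSE_LEVELS:
            problems.append(f"field cause: {d['cause']!r} not in {CAUSE_LEVELS}")
    return problems


@dataclass
class Cohort:
    """Ordered, validated collection of :class:`PatientRecord`."""

    records: list[PatientRecord]
    source: str | None = None
    schema_version: str = "1"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must be non-empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.records])
        return df

    @property
    def times_years(self) -> np.ndarray:
        return np.array([r.followup_years for r in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([r.dead for r in self.records], dtype=bool)

    def subset(self, mask: Sequence[bool]) -> "Cohort":
        recs = [r for r, m in zip(self.records, mask) if m]
        return Cohort(recs, source=self.source, schema_version=self.schema_version)


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}

#: canonical CSV column order
COLUMNS = [
    "id", "age_years", "menopause", "detection", "size_mm", "grade",
    "nodes", "er", "her2", "ki67", "hormone", "chemo", "trastuzumab",
    "radiotherapy", "followup_days", "dead", "cause",
]


def _parse_bool(v: object, field_name: str) -> bool:
    s = str(v).strip().lower()
    if s not in _BOOL_MAP:
        raise ValueError(f"field {field_name}: unparseable boolean {v!r}")
    return _BOOL_MAP[s]


def read_cohort(path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read a cohort CSV into a validated :class:`Cohort`.

    Parameters
    ----------
    path : str, Path or file-like
        UTF-8 CSV with a header row.
    schema : mapping, optional
        Maps canonical column names (see :data:`COLUMNS`) to the names
        actually used in the file. Identity mapping by default.

    Raises
    ------
    CohortSchemaError
        if a mandatory column cannot be mapped.
    CohortRowError
        listing every offending row id and field if any row fails
        validation; no partial cohort is returned.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c: c for c in COLUMNS}
    if schema:
        colmap.update(schema)
    missing = [c for c in COLUMNS if c != "cause" and colmap[c] not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {missing}")

    records: list[PatientRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        rid = str(row[colmap["id"]]).strip()
        label = rid if rid else f"row {idx + 2}"  # header is line 1
        try:
            cause_col = colmap["cause"]
            cause_raw = str(row[cause_col]).strip().lower() if cause_col in df.columns else ""
            rec = PatientRecord(
                id=rid,
                age_years=float(row[colmap["age_years"]]),
                menopause=str(row[colmap["menopause"]]).strip().lower(),
                detection=str(row[colmap["detection"]]).strip().lower(),
                size_mm=float(row[colmap["size_mm"]]),
                grade=int(row[colmap["grade"]]),
                nodes=int(row[colmap["nodes"]]),
                er=str(row[colmap["er"]]).strip().lower(),
                her2=str(row[colmap["her2"]]).strip().lower(),
                ki67=str(row[colmap["ki67"]]).strip().lower(),
                hormone=_parse_bool(row[colmap["hormone"]], "hormone"),
                chemo=_parse_bool(row[colmap["chemo"]], "chemo"),
                trastuzumab=_parse_bool(row[colmap["trastuzumab"]], "trastuzumab"),
                radiotherapy=_parse_bool(row[colmap["radiotherapy"]], "radiotherapy"),
                followup_days=float(row[colmap["followup_days"]]),
                dead=_parse_bool(row[colmap["dead"]], "dead"),
                cause=cause_raw or None,
            )
            records.append(rec)
        except (ValueError, CohortRowError) as exc:
            errors.append(f"row {idx + 2} (id {label!r}): {exc}")
    if errors:
        raise CohortRowError("; ".join(errors))
    return Cohort(records, source=str(path) if isinstance(path, (str,)) else None)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to canonical CSV (round-trips through read_cohort)."""
    df = cohort.to_frame()[COLUMNS]
    df["cause"] = df["cause"].fillna("")
    df.to_csv(path, index=False)


def cohort_from_csv_text(text: str) -> Cohort:
    return read_cohort(io.StringIO(text))


def censor_at(cohort: Cohort, horizon_years: float) -> Cohort:
    """Administratively censor follow-up at ``horizon_years``.

    Records followed beyond the horizon get followup = horizon and are
    marked alive (death from any cause is the event of interest only
    inside the horizon). Idempotent.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    horizon_days = horizon_years * DAYS_PER_YEAR
    out = []
    for r in cohort:
        if r.followup_days > horizon_days:
            r = dataclasses.replace(
                r, followup_days=horizon_days, dead=False, cause=None
            )
        out.append(r)
    return Cohort(out, source=cohort.source, schema_version=cohort.schema_version)


# ---------------------------------------------------------------------------
# Baseline ("Table 1") summaries


@dataclass
class BaselineRow:
    variable: str
    kind: str                       # "continuous" | "count" | "categorical"
    summaries: dict                 # stratum -> summary (str or per-level dict)
    test: str
    p_value: float | None


@dataclass
class BaselineTable:
    group_var: str
    strata: list[str]
    stratum_sizes: dict
    rows: list[BaselineRow]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            recs.append({
                "variable": row.variable, "kind": row.kind, "test": row.test,
                "p_value": row.p_value,
                **{f"{s}": str(row.summaries[s]) for s in self.strata},
            })
        return pd.DataFrame(recs)


def contingency_pvalue(table: np.ndarray | Sequence[Sequence[float]]):
    """Pearson chi-squared p for a contingency table.

    Yates continuity correction is applied for 2x2 tables and no
    correction for larger tables — the convention under which the
    published baseline-table p-values are recomputable from their
    printed counts. Returns (statistic, p, dof); (nan, None, dof) for
    degenerate tables with a zero margin.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return float("nan"), None, (tab.shape[0] - 1) * (tab.shape[1] - 1)
    correction = tab.shape == (2, 2)
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=correction)
    return float(chi2), float(p), int(dof)


#: default classification of cohort variables for the baseline table
_CONTINUOUS = ("age_years", "size_mm")
_COUNT = ("nodes",)
_CATEGORICAL = (
    "menopause", "detection", "grade", "her2", "ki67",
    "hormone", "chemo", "trastuzumab", "radiotherapy",
)


def baseline_table(
    cohort: Cohort,
    group_var: str = "er",
    variables: Iterable[str] | None = None,
    t_test: str = "welch",
) -> BaselineTable:
    """Baseline characteristics by stratum with group-comparison tests.

    Continuous variables: mean (SD), two-sample t-test (Welch by
    default, ``t_test="pooled"`` for the equal-variance variant).
    Count-like skewed variables (nodes): median [IQR], Mann-Whitney.
    Categorical variables: counts (%), Pearson chi-squared via
    :func:`contingency_pvalue`; "unknown" levels are retained as
    categories.
    """
    df = cohort.to_frame()
    levels = [lv for lv in df[group_var].unique()]
    # stable, canonical-ish ordering
    levels = sorted(map(str, levels))
    if len(levels) < 2:
        raise ValueError(f"group variable {group_var!r} has fewer than 2 levels")
    groups = {lv: df[df[group_var].astype(str) == lv] for lv in levels}
    sizes = {lv: len(g) for lv, g in groups.items()}

    if variables is None:
        variables = [v for v in (*_CONTINUOUS, *_COUNT, *_CATEGORICAL)
                     if v != group_var]

    rows: list[BaselineRow] = []
    for var in variables:
        if var in _CONTINUOUS:
            xs = [groups[lv][var].astype(float).to_numpy() for lv in levels]
            summ = {lv: f"{x.mean():.1f} ({x.std(ddof=1):.1f})"
                    for lv, x in zip(levels, xs)}
            if len(levels) == 2:
                _, p = stats.ttest_ind(xs[0], xs[1], equal_var=(t_test == "pooled"))
                name = "t-test (Welch)" if t_test == "welch" else "t-test (pooled)"
            else:
                _, p = stats.f_oneway(*xs)
                name = "one-way ANOVA"
            rows.append(BaselineRow(var, "continuous", summ, name, float(p)))
        elif var in _COUNT:
            xs = [groups[lv][var].astype(float).to_numpy() for lv in levels]
            summ = {}
            for lv, x in zip(levels, xs):
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                summ[lv] = f"{med:.1f} [{q3 - q1:.1f}]"
            if len(levels) == 2:
                _, p = stats.mannwhitneyu(xs[0], xs[1], alternative="two-sided")
                name = "Mann-Whitney"
            else:
                _, p = stats.kruskal(*xs)
                name = "Kruskal-Wallis"
            rows.append(BaselineRow(var, "count", summ, name, float(p)))
        else:
            cat_levels = sorted(df[var].astype(str).unique())
            tab = np.array([
                [int((groups[lv][var].astype(str) == cl).sum()) for lv in levels]
                for cl in cat_levels
            ], dtype=float)
            summ = {
                lv: {cl: f"{int(tab[i, j])} ({100 * tab[i, j] / max(sizes[lv], 1):.1f}%)"
                     for i, cl in enumerate(cat_levels)}
                for j, lv in enumerate(levels)
            }
            if tab.shape[0] < 2:
                rows.append(BaselineRow(var, "categorical", summ,
                                        "chi-squared", None))
                continue
            stat, p, _ = contingency_pvalue(tab)
            test = "chi-squared (Yates)" if tab.shape == (2, 2) else "chi-squared"
            if p is None:
                test += " [not applicable: zero margin]"
            rows.append(BaselineRow(var, "categorical", summ, test, p))
    return BaselineTable(group_var, levels, sizes, rows)
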