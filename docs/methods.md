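# Methods

This note documents the statistical model, the validation procedures,
the synthetic-data generator, and the numerical choices made where the
design was genuinely open. Nothing here states an empirical result
that the test-suite or `scripts/acceptance.py` does not itself
compute.

## Scoring model

The engine scores one early-breast-cancer patient at primary surgery
with three linear predictors and composes survival under independent
competing risks:

- **Prognostic index (PI)** — breast-cancer-specific log-hazard
  offset: `PI = sum_k beta_k * (g_k(x_k) - c_k)` over the ER stratum's
  term list, where each `g_k` is a fractional-polynomial transform
  (`((x + shift)/divisor)^p`, `p in {-2,-1,-0.5,0,0.5,1,2,3}`, `p = 0`
  meaning natural log, optionally multiplied by the log for
  repeated-power FP2 terms) and `c_k` centres the term at the
  development-cohort mean. Categorical covariates (detection mode,
  HER2, Ki67, and grade in the ER-negative stratum) contribute
  per-level offsets; "unknown" is an explicit level with its own
  offset.
- **Mortality index (MI)** — other-cause log-hazard offset from age
  alone, `MI = a((age/10)^2 - b)` with defaults `a = 0.0698252`,
  `b = 34.23391957`; its root is at age `10*sqrt(b) ≈ 58.5` years.
- **Treatment effect (TE)** — the sum of log hazard ratios of
  received adjuvant treatments. Hormone therapy applies only in the
  ER-positive stratum (a hormone flag on an ER-negative record is
  ignored with a warning); radiotherapy is recorded for subgrouping
  but carries no term.

Survival: `bS(t) = exp(-exp(L0_b(t) + PI + TE))`,
`oS(t) = exp(-exp(L0_o(t) + MI))`, `S(t) = bS(t) * oS(t)`. The
"baseline at time t" term inside the double exponential is the
baseline **log cumulative hazard** `L0(t) = ln H0(t)` — the only
reading under which the composition yields probabilities in (0, 1);
equivalently `bS = exp(-H0(t) e^{PI+TE})`. Baselines may be
parametric (an FP expansion in `t`, as in the shipped v2.1 config) or
year-indexed lookup tables with linear interpolation; monotonicity is
checked on a grid at load time. The shipped parametric baselines are
monotone from ~0.25–0.3 years; their declared support starts there,
which is immaterial at the 5/10-year horizons the pipeline reports.

Out-of-range covariates (ages beyond 25–85, sizes beyond 1–300 mm)
are clamped to the configured bounds with a logged warning; strict
mode raises instead. The shipped `predict_v21.yaml` is a
transcription of the publicly released PREDICT v2.1 weights; because
the source grades chemotherapy by regimen generation while a yes/no
cohort flag cannot, the single chemo entry uses the
second-generation-regimen log hazard ratio (-0.248). Every
correctness test runs on toy coefficient sets (exponential baselines,
single-term PIs), so no guarantee depends on the transcription.

## Survival estimation

Kaplan–Meier curves carry the full risk table and the running
Greenwood sum `sum d_i/(n_i(n_i - d_i))`; at tied times events
precede censorings. Pointwise confidence intervals use the
complementary log-log transform by default (bounded in (0, 1); plain
and log scales available). The log-rank test delegates to lifelines.

The Cox fitter maximizes the partial likelihood by Newton–Raphson
with Efron (default) or Breslow tie handling under one convergence
contract: max |gradient| < 1e-8, at most 50 iterations, step-halving
on a likelihood decrease. The step-acceptance slack is relative to
|log L| and iteration also stops when the parameter change falls
below 1e-10 — near the optimum of a large-sample likelihood the
objective moves by less than float64 resolution, and demanding
further gradient reduction would loop without progress. Diverging
coefficients (monotone likelihood under perfect separation) raise a
diagnostic error rather than returning a silent result. The Breslow
baseline cumulative hazard estimator at the covariate origin supports
absolute-risk readouts. The test-suite cross-checks coefficients and
standard errors against lifelines on tied and untied data, and
against brute-force grid maximization on a 5-point fixture.

## Discrimination

- **Royston D**: rank the risk scores, replace them by Blom rankits
  `Phi^-1((i - 3/8)/(n + 1/4))` (ties averaged), scale by
  `kappa = sqrt(8/pi)`, and fit a one-covariate Cox model; D is the
  coefficient and its SE the reported SE. D estimates the log hazard
  ratio between the two half-cohorts obtained by splitting the risk
  score at its median; for a unit-coefficient standard-normal
  prognostic index the large-sample value is `kappa ≈ 1.596`, which
  the suite recovers by simulation. D depends on the scores only
  through their ranks.
- **Fixed-horizon AUC**: cases are deaths by the horizon, controls
  are patients followed to the horizon or beyond without dying by it,
  and patients censored alive earlier are excluded — a plain binary
  ROC at the horizon (IPCW reweighting is deliberately out of scope).
  The AUC is the Mann–Whitney concordance with half credit for ties;
  the CI is DeLong by default, with a seeded bootstrap alternative.
- **Median split**: high risk = strictly above the median; ties at
  the median go to the low-risk group (deterministic); the groups are
  compared by log-rank and returned as KM curves.

The pipeline ranks patients by predicted all-cause mortality by the
horizon (`1 - S(t)`), which folds PI, MI and TE into one score that
is comparable across ER strata; any rank-preserving alternative gives
the same D and AUC.

## Calibration

Predicted-vs-observed tables report, per subgroup and horizon, the
mean predicted `S(t)` with a normal-approximation CI of the mean
against the KM estimate with its Greenwood cll CI.

The ICI smoother regresses the all-cause event on a restricted cubic
spline basis (Harrell's truncated-power form) of
`cll(p) = ln(-ln(1 - p))` of predicted risk in a Cox model, then
reads each patient's "observed" risk at the horizon off the fitted
model with the Breslow baseline; ICI is the mean absolute difference
between predicted and smoothed observed risk, on the mortality scale.
Choices:

- 3 knots at the 10th/50th/90th percentiles of the cll-transformed
  risk by default (configurable; 4 and 5 knots use Harrell's default
  quantiles).
- Predicted risks are clipped to `[1e-6, 1 - 1e-6]` before the cll
  transform.
- **Follow-up is truncated at the horizon before the smoother is
  fitted.** The proportional-hazards working model then only has to
  hold over the window it is read out on; fitting it over a longer
  follow-up and reading it at an earlier horizon leaves a visible
  bias in the smoothed risks even on perfectly calibrated data.
- Near-constant predictions (SD of cll below 1e-8, or a failed
  smoother fit) fall back to the marginal KM risk at the horizon for
  every patient, flagged `degenerate`.
- The predicted-risk density (Gaussian KDE) is exported with every
  curve for density-annotated calibration plots.

## Synthetic cohorts

The generator emulates a hospital-based cohort of 873 patients (85%
ER-positive) treated 2001–2016. Per ER stratum it draws age from a
truncated normal (ER+ 58.5 ± 12.7, ER- 55.6 ± 13.1 years, bounds
25–95 — deliberately wider than the engine's admissible range, which
clamps at scoring time as it would on real data), tumour size from a
moment-matched truncated log-normal (ER+ 21.1 ± 12.8, ER-
26.4 ± 14.0 mm), positive nodes from a zero-inflated negative
binomial targeting a median of 0 with upper quartiles of 1–2, and
grade/menopause/detection/HER2/Ki67 from the stratum's category
frequencies. Adjuvant treatment combinations follow the reported mix
(e.g. 51.8% of ER-positive patients on hormone therapy alone; every
ER-negative patient on chemotherapy). Covariates are sampled
independently within stratum: the real joint dependence (grade with
size, nodes with size) is not identifiable from marginal summaries,
so joint-distribution features of real data are **not** emulated, and
passing tests say nothing about them.

Event times come from the engine's own model by inverse-transform
sampling: independent uniforms set the breast-cause and other-cause
cumulative-hazard targets, each solved for `t` by monotone bisection
to 1e-8 years over the baseline support (no solution within support
means no event). Administrative censoring uses uniform accrual over
15 years with a study end guaranteeing 5 years of potential
follow-up, then a hard cap at 10 years — so nobody is censored before
5 years, mirroring the design of the cohort being emulated. A single
top-level seed is split (`numpy.random.SeedSequence.spawn`) into
covariate and outcome streams so stages are independently
reproducible, and the emitted truth table (PI/MI/TE and `S(t)` per
patient) is byte-exact recomputable by the engine.

## Baseline tables

Continuous variables get mean (SD) and a two-sample t-test (Welch by
default; the pooled variant is an option), the node count gets median
[IQR] and Mann–Whitney, and categoricals get counts (%) with Pearson
chi-squared — Yates continuity correction for 2×2 tables and none for
larger ones, the convention under which published baseline-table
p-values recompute exactly from their printed counts. "Unknown"
levels are retained as categories; zero-margin tables report the test
as not applicable instead of crashing.

## Pipeline and problem sizes

`run_validation` censors at 10 years, scores every patient at 5 and
10 years, and assembles per-stratum discrimination and calibration,
overall KM readouts, a multivariable all-cause Cox model (age and
size linear, grade as a linear score, nodes as a count, indicators
for screening detection, ER-negative status and each treatment;
patients with unknown detection mode are excluded and counted), and
the subgroup predicted-vs-observed table. Reports round floats to 10
decimals and serialize with sorted keys, so a fixed seed yields
byte-identical JSON. The test-suite and acceptance script run
simulations at n = 500–20,000 with 20–100 replicates for the
recovery checks — sizes at which the Monte-Carlo error of each target
is several times smaller than its tolerance.

## Known limitations

- Within-stratum covariate independence in the generator (above).
- The ROC treats censored-before-horizon patients by exclusion; under
  heavy non-administrative censoring an IPCW estimator would be
  preferable.
- The calibration smoother inherits the proportional-hazards
  assumption of its working model; flexible-hazard alternatives are
  out of scope.
- No time-varying covariates, stratified Cox, or frailty terms; no
  re-estimation of model coefficients.
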