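# Methods

This note documents the statistical conventions, default parameters and
design choices behind `emavar`, and what the package's simulation-based
validation does and does not establish.

## Model and estimation

Candidate models are VAR(p) systems over the selected diary variables
with exogenous columns appended in a fixed order (intercept, lags 1..p,
trend, weekday dummies, outlier dummies by variable then day, user
controls). Estimation is equation-wise ordinary least squares; a
constraint set fixes chosen coefficients to exactly zero by removing them
from that equation's regressor set. Because every equation shares the
same regressor matrix, this is the maximum-likelihood estimator of the
unconstrained system and a reasonable, fast approximation under
constraints (cross-equation GLS is deliberately out of scope).
Coefficient standard errors and p-values are classical OLS (t reference
with per-equation residual degrees of freedom); heteroscedasticity is
handled by the validity gate, not by robust covariance.

The system log-likelihood is Gaussian with additive constants,
`logL = -T_eff/2 (V ln 2π + ln det Σ̂ + V)` with `Σ̂ = E'E/T_eff` (MLE
divisor) and `T_eff = T - p`. Information criteria are
`AIC = -2 logL + 2k` and `BIC = -2 logL + k ln T`, where **T is the
nominal diary length** (not `T_eff`) and **k counts freely estimated
regression coefficients** across equations, intercepts included,
constrained positions and covariance entries excluded. This convention
is pinned by published idiographic VAR reports: their four printed
(AIC, BIC, T) triples give `(BIC - AIC)/(ln T - 2)` equal to the
integers 10, 4, 15 and 6 to within 0.004, which no `T_eff`-based variant
reproduces. The identity `BIC - AIC = k (ln T - 2)` therefore holds
exactly for every fit and is asserted throughout the test suite.
Absolute AIC/BIC levels are only comparable between models of the same
transformed data; the ranking makes no Jacobian adjustment when log and
raw models are mixed, mirroring the procedure it automates.

## Pruning

Pruning candidates are all lag and exogenous coefficients (never
intercepts) with p-value above `alpha`. One coefficient is constrained
per step — the globally highest p-value, ties broken by the fixed
equation/regressor order — and the step stands only if the chosen
criterion strictly decreased on refit; otherwise it is reverted and
pruning stops. After every accepted constraint the four validity checks
are re-run and recorded. Under AIC a candidate is only accepted when its
squared t-ratio is (approximately) below 2, under BIC below `ln T`; BIC
is therefore the criterion of choice for sparsity-recovery experiments
(it is model-selection consistent for true zeros, AIC by design is not),
and the validation suite's sparsity study uses it.

## Validity gate

A model is valid only if **all** of the following hold at the shared
level `alpha` (default 0.05):

* stability — all companion-matrix eigenvalues strictly inside the unit
  circle;
* white noise — Ljung–Box `Q = n(n+2) Σ_{j≤h} r_j²/(n-j)` per variable,
  χ²(h) reference, `h = min(12, floor(T_eff/4))`, no degrees-of-freedom
  reduction for fitted lags;
* homoscedasticity — the same statistic on squared residuals;
* normality — Jarque–Bera `n/6 (S² + (K-3)²/4)`, χ²(2) reference, per
  variable.

Each test is individually calibrated (Monte-Carlo size 4–6% at n=200;
see the validation suite), but the gate is a conjunction of seven
verdicts, so a *correctly specified* model on clean Gaussian data is
falsely invalidated roughly a quarter of the time — measured at 24%
over 400 replicates. This is an inherent property of the
all-tests-must-pass rule, and it propagates to every downstream quantity
that conditions on validity: on clean synthetic data the search
escalates to outlier dummies it does not need in ~25% of runs, and with
several near-equivalent specifications validating per run, the union of
per-model Granger false positives makes spurious low-proportion edges
appreciably more common than the per-test level suggests. The
proportion weight on each edge is the intended mitigation: an edge
supported by 100% of valid models is a far stronger claim than one
supported by a single model.

## Trend decision

The trend check is a Phillips–Perron `Z_tau` unit-root test per
endogenous variable (regression with intercept and trend, Bartlett
long-run variance at bandwidth `floor(4 (T/100)^{1/4})`, MacKinnon
p-values; the statistic matches R's `PP.test` to five decimals). A
significant result — stationarity around a deterministic trend — adds
one linear day-index regressor system-wide before enumeration. The rule
is applied literally, so trendless stationary series also trigger the
(harmless, usually pruned) trend column; a slope-significance refinement
was considered and rejected to stay faithful to the automated procedure
being reimplemented.

## Search space and redundancy

The enumeration is the Cartesian product lag × weekday (only with
calendar dates and timestamps enabled) × log × per-variable outlier
severity (none ≺ 3.5 ≺ 3.0 ≺ 2.5 SD; 2.5 only when explicitly allowed),
visited simplest-first in a linear extension of the complexity partial
order. A candidate is skipped as redundant when an already-valid tested
spec shares its lag/weekday/log/trend factors and dominates it with
weaker-or-equal outlier severity everywhere. Outlier days are detected
once per spec family, on the residuals of the same spec with no outlier
dummies (single pass, no re-detection after pruning), and reported
1-based on the original diary day scale. Bookkeeping is exact:
`tested + skipped_redundant = enumerated` on every run, infeasible specs
(more regressors than effective observations, collinear designs,
negative values under the log branch) are recorded under `tested` with
their reason.

## Granger aggregation

Within each valid (pruned) model, x → y is tested by a Wald statistic on
the unconstrained coefficients of x's lags in y's equation, χ²(m)
reference; a fully constrained pair counts as non-significant (p = 1).
Edges aggregate over all valid models: proportion = significant models /
valid models, sign class positive/negative/mixed-within when all
contributing models agree, mixed-across otherwise, and the best-ranked
contributing model supplies the headline p-value. Two caveats are
documented rather than "fixed", matching the automated procedure:
the χ² reference is slightly liberal at diary-scale T (measured ~6.5%
at T = 83), and testing pruned models conditions on coefficients having
survived pruning, which roughly doubles the false-positive rate on
true-zero directions (measured 15% vs 8.5% unpruned). No multiplicity
correction is applied across pairs or models; the mitigations are
redundancy filtering, the validity gate, and the proportion weights.

## Synthetic diaries

The generator draws stationary Gaussian VAR(p) series (burn-in 100
steps, started at the stationary mean, seed-deterministic) and layers on
the features the search probes: linear trend, additive weekday profile,
isolated outlier shocks expressed in innovation-SD units (scale-free
detection thresholds), and an optional exponential marginal transform
for right-skewed variables. Scenario presets fix the study conditions
used throughout testing: `null_independent` (two uncoupled AR(1),
φ = 0.5), `coupled_x_to_y` (cross-lag 0.4, the canonical
power/recovery setting), `trended`, `weekday`, `outlier_day20`,
`lognormal`, and `rosmalen_like` — 83 daily bivariate observations with
VAR(2) dynamics, cross-lags −0.4/−0.1 from Activity to Depression, no
reverse coupling, unit innovation SD, and 6-SD shocks on day 4
(Depression) and day 13 (Activity), mimicking the structure (not the
data) of a published single-patient analysis. Cross-lag −0.4 at unit
noise gives an asymptotic z ≈ 4 at T ≈ 100, i.e. a clearly detectable
but diary-scale effect.

What the synthetic validation does **not** establish: real diaries have
bounded discrete scales, missing days (a hard error here by design),
floor effects, and residual structure that fails the gate far more often
than clean Gaussian draws — the published analysis this emulates found
2 valid models out of 43 tested, whereas clean synthetic data validates
~6-8 near-equivalent specifications per run. Passing recovery tests on
synthetic data therefore demonstrates the machinery, not field
performance.

## Numerical and interface choices

* Log transform is `ln(x+1)`, system-wide, because diary scales
  legitimately contain zeros; negative values make the log branch
  infeasible (recorded, not crashed).
* Weekday dummies one-hot Monday–Saturday, Sunday fixed as reference.
* Degenerate fits (zero residual variance) raise, carrying the point
  estimates; constant series are guarded in every diagnostic.
* Ranking ties break by smaller k, then enumeration order; the
  highest-p pruning tie breaks by fixed regressor order — all outputs
  are byte-deterministic given data and configuration.
* Pen width in the summary graph is `1 + 4·proportion` (the simplest
  monotone map); line styles solid/dashed/dash-dot/dotted encode
  positive/negative/mixed-within/mixed-across, with colors
  green/red/orange/gray emitted alongside.
* The DOT writer/reader is a deliberately minimal in-package dialect
  (quoted nodes, quoted `a -> b [...]` edges) sufficient for
  deterministic round-trips without a graphviz dependency.
* Default experiment sizes in the validation suite (500–1000 Monte-Carlo
  replicates, 100–200 recovery runs) balance Monte-Carlo error (±1–2
  points on a rate) against a few minutes of single-CPU runtime.
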