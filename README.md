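# emavar

Automated vector-autoregressive (VAR) model search for **single-subject
daily diary data** (ecological momentary assessment, EMA). Given one
individual's diary — one row per day, two or more variables such as a
depression sum score and minutes of physical activity — the package
answers the idiographic question *"which of this person's symptoms drives
which?"* by exhaustively searching a space of VAR model structures,
keeping only the models whose residuals behave, and aggregating
Granger-causality tests across the surviving models into a weighted,
signed directed graph.

It is intended for researchers and clinicians working with n-of-1
intensive longitudinal data who want a reproducible, scriptable
alternative to hand-built VAR analyses.

## The model

For diary variables $y_t \in \mathbb{R}^V$ observed on days
$t = 1,\dots,T$ the candidate models are VAR(p) systems

$$y_t = c + A_1 y_{t-1} + \cdots + A_p y_{t-p} + B x_t + \varepsilon_t,$$

where $x_t$ collects exogenous regressors (a linear trend, weekday
dummies, 0/1 outlier-day dummies, user-supplied controls) and
$\varepsilon_t$ is Gaussian noise, serially uncorrelated but possibly
contemporaneously correlated. Estimation is equation-wise OLS; the search
varies:

1. **lag order** $p \in \{1..\text{max\_lag}\}$;
2. **trend**: a Phillips–Perron test per variable; a significant result
   (trend stationarity) adds a day-index regressor system-wide (decided
   from the data, not enumerated);
3. **weekday dummies** on/off (only when calendar dates are supplied);
4. **outlier dummies** per variable at escalating severity — days whose
   base-model residual exceeds 3.5, 3.0 (optionally 2.5) sample SDs;
5. **log transformation** $\ln(x+1)$ of all endogenous variables, on/off;
6. **constraint pruning**: the least significant coefficient ($p >
   \alpha$) is fixed to zero and the system refitted, repeatedly, while
   AIC (or BIC) keeps strictly decreasing;
7. **user exogenous variables** selected by label.

A candidate made redundant by an already-valid simpler model (same
lag/weekday/log/trend, weaker-or-equal outlier dummying) is skipped, not
fitted — complexity is escalated only where simple models fail. Every
fitted model passes through a four-test validity gate: companion-matrix
eigenvalue stability, Ljung–Box on residuals (white noise), Ljung–Box on
squared residuals (homoscedasticity), and a skewness–kurtosis
(Jarque–Bera) normality test — all must be nonsignificant for every
variable. Valid models are ranked by ascending AIC (or BIC;
$\mathrm{AIC} = -2\log L + 2k$, $\mathrm{BIC} = -2\log L + k\ln T$ with
$k$ the free-coefficient count).

For each ordered variable pair, x **Granger-causes** y in a model when
the coefficients of x's lags in y's equation are jointly nonzero (Wald
test, $\chi^2_m$). Across valid models each significant pair becomes a
graph edge weighted by the proportion of valid models supporting it,
with a sign class (positive / negative / mixed within a model / mixed
across models) rendered as the line style.

## Worked example

Simulate a diary-like dataset (83 days, VAR(2) dynamics, a negative
Activity→Depression cross-lag, isolated outlier days 4 and 13) and run
the search:

```bash
emavar simulate --scenario rosmalen_like --seed 3 --out diary.csv
emavar run --input diary.csv --date-column date --max-lag 2 --out report_out
```

which prints:

```
48 VAR models out of 72 possible combinations were tested (66.7%).
24 models were not tested due to redundancy.
Of the 48 models tested, 8 met the assumptions of stability, white noise, homoscedasticity and normality.
Models ordered by ascending AIC.
Best model: lag=1 weekday=yes log=yes trend=yes outliers=[3.5sd,3.5sd] with an AIC of -198.75 and a BIC of -174.56.
Granger causality summary:
  Activity -> Depression: sign negative, found in 100% of valid models (best-model p = 0.000335)
```

Reading this: 72 model structures were enumerated; 24 were skipped
because a simpler validated model made them redundant; 8 passed the
four-test gate. Every valid model finds that lagged activity predicts
the next day's depression score with a negative sign — the coupling the
generator actually contains — and no model supports the reverse
direction, so the graph in `report_out/granger.svg` shows a single
thick dashed arrow from Activity to Depression (thickness = proportion
of valid models, dashed = negative). `report_out/` also contains the
full model table (`models.csv`/`models.json`), the Granger summary
(`granger.json`, `granger.dot`) and per-variable time plots.

The same analysis is available as a library:

```python
from emavar import read_diary, RunConfig, run_search

dataset = read_diary("diary.csv", date_column="date")
result = run_search(dataset, RunConfig(max_lag=2, timestamps_enabled=True))
print(result.granger.to_json())
```

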