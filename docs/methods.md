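# Methods

## Model and procedure

`aqproxy` estimates a target pollutant (the running example is black
carbon, BC) from co-measured variables, and uses the estimates to fill
measurement gaps. The statistical model is log-linear:

    log Y = β₀ + Σᵢ βᵢ Xᵢ + ε,    ε ~ N(0, σ²),   p = |inputs| ≤ 3,

where each Xᵢ is a predictor on its analysis scale: natural log for
concentration-like variables (whose marginal distributions are close to
log-normal, so the log transform brings them near normality), identity for
meteorological variables, and the (cos θ, sin θ) pair for wind direction,
with θ in meteorological degrees clockwise from north so that the
north–south component is the cosine. Non-positive values under the log are
set missing rather than offset-shifted: concentrations are physically
positive, and an additive offset would bias low-concentration fits.
Predictions back-transform as Ŷ = exp(β₀ + Σ βᵢXᵢ). No smearing
(retransformation-bias) correction is applied by default — the exponentiated
conditional mean of the log-scale fit is reported as-is, keeping fills
comparable with the fitting scale; users who need unbiased original-scale
means can apply their own smearing factor to the filled series.

The subset cap of three inputs controls overfitting and, more importantly
for imputation, keeps each model's feasibility (all inputs present) high.

### Classification

Pollutant–predictor relationships shift with season and human activity, so
models are fitted separately in eight classes: {winter, spring, summer,
autumn} × {workday, weekend}.

* **Thermal seasons.** A lowess curve (local linear smoothing, default
  span 60 days) is fitted to the daily mean temperature. Days with the
  smoothed curve below 0 °C are winter, above 10 °C summer; days in
  [0, 10] °C are spring when the curve is rising and autumn when falling
  (at exactly zero slope, spring). Smoothing is over the whole record, not
  per calendar year, so a winter that spans New Year is one segment.
  A single global sinusoid was considered and rejected: it cannot represent
  asymmetric season onsets between years (e.g., an early-summer year
  following a late one), which the local smoother handles naturally.
* **Daytype.** Saturdays, Sundays, and public holidays are weekends;
  everything else is a workday. The bundled Finnish list for 2017–2018
  contains the official public holidays plus Midsummer Eve and Christmas
  Eve, which are de facto full holidays in Finland; over
  2017-01-01..2018-12-31 (730 days) this yields 502 workdays and
  228 weekends. Any plain-text date list can be substituted.

### Screening and enumeration

Candidates are screened by the absolute Pearson correlation with the
transformed output, computed over pairwise-complete rows (minimum overlap
24 rows — one day of hourly data; pairwise completion maximizes usable data
under MAR). Candidates with |R| < r_min (default 0.1) are discarded; the
survivors are ordered by |R| descending with alphabetical tie-breaks. All
subsets of size 1..3 are then enumerated in (size, lexicographic) order,
giving Σₖ C(K, k) models — e.g., 1159 for 19 screened variables.

### Robust fitting

Each model is fitted by iteratively reweighted least squares with the Tukey
bisquare weight:

    w(r) = (1 − (r/c)²)²  for |r| ≤ c,  0 otherwise,   c = 4.685,

starting from the unweighted least-squares solution. Each iteration
computes residuals e, the robust scale s = median(|e − median(e)|)/0.6745,
leverages h from the (unweighted) design, standardized adjusted residuals
r = e/(s·√(1−h)), then weights and a weighted refit; convergence when the
maximum relative coefficient change drops below 1e-6 (cap 50 iterations).
c = 4.685 gives 95% efficiency at the Gaussian model while zeroing the
influence of gross outliers.

Two numerical guards:

* A (near-)zero robust scale means a (near-)perfect fit; the solution is
  the least-squares one and iteration stops with unit weights.
* With heavy one-sided contamination the unweighted start can shift
  median(e) so far that the centered MAD zeroes *every* weight; that
  iteration is rescaled by the uncentered MAD (median|e|/0.6745), after
  which iterations proceed normally. The guard only triggers on total
  collapse.

**Standard errors** use the Street–Carroll–Ruppert M-estimator covariance
with Huber's small-sample correction,

    σ̂² = K² · s² · Σψ(u)² / (n − p − 1) / (mean ψ′(u))²,
    cov(β̂) = σ̂² (XᵀX)⁻¹,

with ψ the bisquare influence, u the standardized adjusted residuals, and
K = 1 + (p+1)/n · var(ψ′)/mean(ψ′)². This is the standard robust-regression
inference (MATLAB `robustfit`, statsmodels `RLM`) and reduces to the
classical OLS covariance when no observation is downweighted; the naive
"weighted residual variance" alternative was measured to undercover
(≈88% at 95% nominal) because downweighting shrinks the weighted residual
sum. Coefficient p-values use a t reference with N − p − 1 degrees of
freedom; a model-level p-value comes from the weighted-fit F test.

**Bootstrap averaging.** Five independent subsets of a random 80% of the
class's complete rows are drawn without replacement (independent draws, not
a partition — five 80% subsets cannot be disjoint), the robust fit runs on
each, and the reported coefficients, standard errors, and evaluation
attributes are arithmetic means across subsets, with per-subset values
retained for dispersion. Fraction 1 reduces exactly to the full-data fit.

### Rejection and ranking

Quality control runs on the full-data robust fit, before bootstrap
averaging (models rejected here are not bootstrapped):

* **Multicollinearity.** VIF per input: regress each design column on the
  others (unweighted, with intercept); VIF = 1/(1−R_p²); a single-input
  model has VIF = 1 by definition and exact collinearity reports +∞.
  Reject when max VIF ≥ 5.
* **Residual normality.** Lilliefors test (Kolmogorov–Smirnov with
  estimated mean and variance): the statistic is the sup distance between
  the ECDF of the z-scored residuals and the standard normal CDF. Reject
  the *model* when p < α = 0.05, i.e., when residuals are significantly
  non-normal. The p-value comes from a seeded Monte Carlo null (same
  statistic on standard-normal samples of the same size, add-one
  correction) when `lilliefors_mc_reps > 0`, and from the table
  approximation in `statsmodels` otherwise — the pipeline default, since
  the test runs once per candidate model. No multiplicity correction is
  applied across the ~10³ candidate models.

Accepted models are ranked by adjusted R² descending, compared after
rounding to two decimals (granularity configurable) so that practically
indistinguishable fits fall through to the error criteria; ties break by
MAE ascending, RMSE ascending, number of fitted rows descending (more data,
less uncertainty), then lexicographic input names, making the order total
and permutation-invariant.

Evaluation attributes are computed on the fitting (log) scale:

* adjR² = 1 − (1 − corr(y, ŷ)²) · (N−1)/(N−p−1) — the correlation form,
  which is shift-invariant (a biased predictor can still score 1); the
  signed mean error is therefore reported alongside MAE/RMSE.
* MAE = mean |y − ŷ|; RMSE = √(mean (y − ŷ)²); RMSE ≥ MAE always.

### Cascading imputation

Measured values are never altered. For each missing output slot, the
highest-ranked model of the slot's class with all inputs present supplies
exp(β₀ + Σ βᵢXᵢ), using the bootstrap-averaged coefficients; infeasible
models fall through to the next rank. Slots no accepted model can serve
remain missing and are reported (no fallback value is invented). Every
slot carries a provenance record (measured / model+rank / unfilled), from
which rank-usage fractions per class (buckets 1, 2, 3–10, >10, unfilled)
and per-class diurnal profiles (hourly means ± sd) are summarized. The
*traditional* proxy is the same machinery restricted to rank 1; its
coverage is (measured + filled)/total, and the cascade's coverage is
monotone in ranking depth by construction.

## Synthetic study conditions

The generator produces the structure the method assumes, so every stage is
testable end to end without measurement data. Defaults (the study
conditions used by the tests and the acceptance script):

| parameter | default | rationale |
|---|---|---|
| period | 2017-01-01..2018-12-31, hourly (17 520 rows) | two full seasonal cycles |
| predictors | 10, exponentiated Gaussians, unit log-sd | log-normal pollutants with geometric sd ≈ e |
| log-scale correlation | exchangeable 0.4 | moderate co-emission dependence; keeps true-model VIF ≈ 1.5 |
| harmonics | 24-h amplitude 0.6, 7-day 0.2 (log scale), phased per variable | traffic-like diurnal/weekly cycles |
| true model | log bc = −0.5 + 0.5·log acc_mode + 0.3·log nox + 0.2·log traffic | traffic-dominated composition |
| noise sd | 0.25 (log scale) | var(linear part) ≈ 0.63 ⇒ adjR² ≈ 0.9, the regime the method targets |
| temperature | 5 − 12·cos(2π(doy−28)/365.25) ± 2 °C daily sinusoid | crosses both 0 and 10 °C thresholds; minimum late January |
| wind direction | uniform [0, 360) | exercises the trigonometric decomposition |
| gaps | output 30% in 72-h blocks; predictors 15% in 48-h blocks | long instrument-failure-like MAR outages; predictor gaps force the cascade past rank 1 |

Gap blocks are placed uniformly at random, independent of the data values
(missing-at-random by construction; the point-biserial correlation between
mask and value is ~0 by test). The pre-masking truth table is returned
alongside, so held-out imputation accuracy is computable without
re-generation. Held-out accuracy is evaluated as the correlation between
filled values and truth on masked slots **on the log scale** — the fitting
scale, consistent with all other evaluation in the package.

What the generator does *not* emulate: autocorrelated noise and gap
processes tied to pollution episodes (true air-quality series have both),
inter-site heterogeneity, instrument drift, and detection limits. Passing
the end-to-end tests therefore shows the machinery is correct under the
model's own assumptions, not that any particular field data set satisfies
them.

## Problem sizes

The default test and acceptance runs use the full two-year hourly record
with 10 predictors (175 candidate models per class × 8 classes, each
accepted model bootstrap-averaged over 5 subsets), ~30 s on one CPU; the
unit suite uses a half-year, four-predictor configuration for the
per-operation checks. Statistical calibrations use 100–200 seeded
replicates (Lilliefors null/power, 95%-interval coverage of the robust
fit).

## Known limitations

* The Lilliefors rejection at α = 0.05 is applied per model per class; the
  true model itself is falsely rejected in a class with probability up to
  ≈5%, in which case the next-best subset takes rank 1 there. This is a
  property of the published rejection rule, not of the implementation.
* The correlation-form adjR² rewards any affine relationship; biased
  predictors are caught only by MAE/RMSE and the signed mean error.
* Season boundaries inherit lowess edge effects within roughly half a span
  of the record's ends.
* Imputation uncertainty is limited to per-subset dispersion of the
  bootstrap fits; no prediction intervals are attached to filled values.
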