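# Methods

## Model

The package fits log-linear quasi-Poisson time-series models

    g(μ_t) = α + s(x_t, …, x_{t−L}; η) + confounders,    V(Y) = φμ

where the exposure term *s* lives in a cross-basis: the tensor-style
combination of a predictor-space basis (applied to the exposure values) and
a lag-space basis (applied to the integer lag vector 0…L). Writing **Z**
(n × v_x) for the evaluated predictor basis and **C** ((L+1) × v_ℓ) for the
lag basis, the design contribution of day *t* is

    w_t,(j,k) = Σ_ℓ z_{t−ℓ, j} c_{ℓ, k},   j = 1…v_x, k = 1…v_ℓ,

a sum over the lagged occurrences of each transformed exposure. The
construction is order-symmetric (lagging the transformed series equals
transforming the lagged series), which the tests verify directly. Columns
are stored predictor-basis-major (index = j·v_ℓ + k); the same ordering is
used when prediction contrasts are assembled, and it is recorded in every
serialized recipe.

Estimation is delegated to statsmodels' GLM (Poisson family; the
quasi-Poisson dispersion is the Pearson χ²/df, and the coefficient
covariance is scaled by it). The package's own contribution is everything
around the fit: basis construction, the cross-basis, coefficient extraction,
prediction contrasts, and the information criteria.

## Bases and conventions

* **Natural cubic splines** follow the `splines::ns` construction: a cubic
  B-spline basis on the knot sequence, second derivatives constrained to
  zero at (and beyond) the boundary knots via QR projection, intercept
  column dropped unless requested, linear extrapolation outside the
  boundaries. The df convention is df = #internal knots + 1 (without
  intercept), under which an 11 df × 5 df cross-basis spends exactly 55
  parameters and a 5 df × 5 df one 25. A test compares the construction
  column-by-column with R's `splines::ns`, and another checks the spanned
  space against an independently coded truncated-power natural basis.
* **Knot placement.** Predictor-space knots default to equally spaced
  values over the observed range (equally spaced quantiles are available as
  an option, the usual choice for humidity-type covariates). Lag-space
  knots default to equal spacing on the log-lag scale: knot *i* of *K* is
  exp(i/(K+1)·log L). The transform is log(ℓ) on ℓ ≥ 1; lag 0 always falls
  inside the first interval (the placement of lag 0 on a log axis is a
  convention, fixed here once and recorded in the serialized recipe).
  This concentrates flexibility at short lags, where distributed lag curves
  vary most.
* **Other bases**: linear, polynomial, threshold (hockey-stick terms
  (x−k)₊), strata (interval indicators; with an intercept the indicator
  block partitions unity), constant (the moving-average special case,
  exposed **unscaled** — the lag-sum — with the β_MA = (L+1)·β_sum
  relationship documented and tested), and identity (one indicator per lag,
  the unconstrained DLM; valid only on integer lag inputs).
* **Missingness.** The first L days of the series have incomplete exposure
  history and their cross-basis rows are wholly missing — no padding with
  fabricated pre-sample exposures. Internal missing exposures propagate to
  the L following rows. The fit drops incomplete rows.

## Prediction

All effects are contrasts against a reference exposure: the contrast vector
for (x_p, ℓ) is the outer product of (z_p − z_ref) with row ℓ of **C**,
flattened in column order. Effects are a'η̂; standard errors √(a'Va);
overall effects use the lag-summed contrast so their variance retains the
between-lag covariances (a Monte-Carlo check in the test suite confirms the
quadratic form against 100 000 draws from N(η̂, V)). The prediction design
repeats the transformed exposure across lags — the target is "the effect at
each lag given an exposure", not a temporal sequence. An uncentered mode
exists for bases through the origin. Confidence intervals use normal
quantiles (1.96 at 95%); with n in the thousands a small-sample correction
would be cosmetic. Prediction values outside the observed exposure range
are allowed with a warning (the natural constraint makes extrapolation
linear). Default grid: 50 equally spaced values over the observed range.

## Model selection

QAIC = −2ℒ + 2φ̂k and QBIC = −2ℒ + log(n)·φ̂k, where ℒ is the Poisson
log-likelihood at the fitted mean (the quasi-likelihood convention; note
statsmodels' reported `llf` under estimated scale is ℒ/φ̂ and is rescaled on
extraction), φ̂ the Pearson dispersion, k **all** mean-model parameters
(cross-basis plus confounders and intercept — whole models are compared),
and n the observations actually used. At φ̂ = 1 both reduce to AIC/BIC
exactly. The `search` command tabulates candidate (var df, lag df) pairs
and flags the argmin per criterion without auto-selecting: the criteria can
disagree, and parsimony arguments belong to the analyst.

## Synthetic data generator

The generator emulates a temperature–mortality time series:

* **Exposure**: x_t = mean + A·cos(2πt/365.25) + AR(1) noise. Defaults
  (mean 12 °C, seasonal amplitude 10 °C, stationary sd 3.5 °C, AR
  coefficient 0.8) give a mid-latitude-city-like annual cycle with
  persistent weather anomalies. The innovation variance is scaled by
  (1−ρ²), so the AR coefficient does not change the marginal spread.
* **Baseline**: log-rate intercept log 50 (≈50 events/day), seasonal
  amplitude 0.1, optional linear trend.
* **Surface**: a known f(x, ℓ), stored as a contrast (f(reference, ℓ) = 0).
  Presets: `null`; `linear_decay` (linear × exponential decay);
  `ushape_decay` (quadratic with minimum at the reference × exponential
  decay); `ushape_delayed_cold` (immediate fast-decaying heat arm, cold arm
  peaking near lag 3). The delayed-cold kernels are normalized to unit lag
  sum so the arm strengths are overall log-RRs at scale anchors — roughly
  1.25 overall RR at reference+12 °C and 1.30 at reference−28 °C, the
  magnitude this literature reports for temperature extremes.
* **Counts**: Poisson for φ = 1; for φ > 1 a gamma-Poisson mixture with
  shape μ/(φ−1) and scale (φ−1), giving V(Y) = φμ exactly at every μ.
  Quasi-Poisson defines no generative law; this negative-binomial
  parameterization is the standard stand-in. Default φ = 1.5, n = 5114
  days (14 years). All draws flow from a single integer seed.
* **Burn-in**: the first L days are emitted but flagged; fits drop them via
  the missingness rule above.

What the generator does **not** emulate: multi-pollutant confounding,
day-of-week structure in the rate, influenza epidemics, measurement error
in exposure, or long-memory trends. Passing recovery tests therefore shows
the estimator and its uncertainty are correct under the stated model, not
that any real dataset satisfies that model.

## Validation design

* Structural contracts (cross-basis dimensions, DLM reductions, the
  brute-force quadruple-loop definition of W) are checked exactly, with
  tolerances of 1e−10 to 1e−12 scaled to cell magnitude where summation
  order matters.
* Interval calibration: 200 series of n = 5000 days, φ = 1.5, with a
  quadratic-in-exposure × decaying-lag surface. The lag kernel is the
  least-squares projection of exp(−ℓ/3) onto the fitted lag basis
  (natural spline, 4 df with intercept, L = 10), so the estimand lies in
  the model span and the check isolates inferential calibration from basis
  approximation bias — with a misspecified lag basis, approximation bias
  would be confounded with interval miscalibration. Pointwise 95% coverage
  is required in [0.93, 0.97], and the overall-contrast mean absolute error
  must shrink from n = 1000 to n = 5000. Problem sizes (L = 10 rather
  than 30, a 6-point exposure grid) keep the replication honest while the
  suite stays quick; the calibration result does not depend on them.
* Dispersion recovery, AR(1) autocorrelation, Poisson/NB dispersion
  indices, and the QAIC/QBIC penalty ordering are checked by seeded
  Monte-Carlo with bands set from the corresponding sampling theory.

## Numerical and design choices

* Natural-spline conditioning uses the full QR of the two boundary
  constraint rows; identical inputs give bit-identical matrices, and the
  serialized recipe (resolved knots, boundaries, intercept flags, L,
  exposure range, column order) rebuilds transforms exactly at prediction
  time.
* The covariance passed to prediction is validated for symmetry and
  positive semidefiniteness (eigenvalue floor scaled to the matrix norm);
  a rank-deficient fit fails loudly rather than producing negative
  variances. Quadratic forms are clipped at zero before the square root to
  absorb −0 rounding.
* The moving-average reduction is exposed as the raw lag sum because the
  constant lag basis literally yields Σ_ℓ x_{t−ℓ}; rescaling to a mean is
  a documented coefficient relationship, not a hidden convention.
* Burn-in rows are dropped rather than modelled; with L ≪ n the efficiency
  loss is negligible and no pre-sample exposure needs inventing.

## Limitations

* Completely parametric bases only: no penalized/low-rank smoothers or
  tensor-product penalties, and no GAM backfitting.
* Regular daily series only; no cohort-style per-subject exposure
  histories, and no irregular spacing.
* Wald intervals from GLM asymptotics; no autocorrelation-consistent
  variance estimators.
* The CLI's default confounder model (time spline with a fixed df per year
  plus day-of-week factors) is a convention of this literature, not a
  substitute for substantive confounder reasoning.
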