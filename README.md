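# pydlnm

Distributed lag non-linear models (DLNMs) for daily time-series count data,
built in the style of statsmodels: a `DLNM` model object, a results object
carrying estimates and uncertainty, and prediction utilities that turn fitted
coefficients into exposure–lag–response surfaces.

## The problem

Environmental stressors — heat waves, cold spells, air pollution episodes —
affect health with a delay: today's deaths depend not only on today's
temperature but on the temperatures of the past days or weeks, and the
exposure–response curve itself is non-linear (mortality rises at both
temperature extremes). A DLNM describes both dimensions at once. Its core is
the **cross-basis**: choose a basis for the predictor space (e.g. a natural
cubic spline in temperature, basis matrix **Z**, dimension *v_x*) and a basis
for the lag space (a spline over lags 0…L, basis matrix **C**, dimension
*v_ℓ*), then combine them into *v_x · v_ℓ* cross-basis functions

    w_t,(j,k) = Σ_{ℓ=0}^{L} z_{t−ℓ, j} · c_{ℓ, k}

These columns enter an ordinary GLM — here a quasi-Poisson log-linear model
with E(Y) = μ, V(Y) = φμ — alongside seasonal and calendar confounders.
Familiar models are special cases: **C ≡ I** gives the unconstrained
distributed lag model, **C ≡ 1** the moving-average model, and a linear
predictor basis reduces everything to a classic DLM with lag effects
β = C η̂.

After fitting, effects are linear contrasts of the cross-basis coefficients
η̂ against a reference exposure: a grid **E** of effects over (exposure,
lag) with standard errors from a' V(η̂) a, and overall effects e_tot summing
the lag contributions (their variance keeps all covariances between lags).
On the log link, exp(e_tot) is the overall relative risk of an exposure
versus the reference. Basis dimensions are chosen by quasi-likelihood
information criteria, QAIC = −2ℒ + 2φ̂k and QBIC = −2ℒ + log(n)·φ̂k.

A seeded synthetic-data generator produces overdispersed counts from a known
exposure–lag surface applied to a temperature-like AR(1)+seasonal exposure
process, so the entire pipeline is testable end to end without external data.

## Worked example

Simulate 14 years of daily counts whose log-rate carries a U-shaped
temperature effect — immediate for heat, delayed (peaking near lag 3) for
cold — then fit a 5 df × 5 df spline cross-basis with maximum lag 30 and a
seasonal confounder pair:

```python
import numpy as np, pandas as pd
from pydlnm import (BasisSpec, DLNM, SimConfig, simulate_dataset,
                    to_risk_scale, true_contrast)

cfg = SimConfig(n_days=5114, surface="ushape_delayed_cold",
                dispersion=1.5, max_lag=30, seed=7)
data = simulate_dataset(cfg)
t = np.arange(len(data))
conf = pd.DataFrame({"cos1": np.cos(2*np.pi*t/365.25),
                     "sin1": np.sin(2*np.pi*t/365.25)})

model = DLNM(data["count"], data["exposure"],
             BasisSpec.natural_spline(df=5), BasisSpec.natural_spline(df=5),
             max_lag=30, confounders=conf)
res = model.fit()
print(res.summary())
```

```
Distributed lag non-linear model (quasi-Poisson GLM)
========================================================
Observations used:        5084  (of 5114, first 30 lag-incomplete days dropped)
Cross-basis dimension:    5 x 5 = 25 columns
Predictor basis:          natural_cubic_spline, df=5
Lag basis:                natural_cubic_spline, df=5, max lag 30
Total mean parameters:    28
Dispersion (Pearson):     1.4629
Log-likelihood:           -18393.78
QAIC:                     36869.49
QBIC:                     37137.14
```

The 25 cross-basis columns are the 5×5 products of the two spline bases; the
Pearson dispersion 1.46 estimates the generator's φ = 1.5. Overall relative
risks at the 0.1th/5th/95th/99.9th exposure percentiles, versus a 20 °C
reference:

```python
pcts = np.percentile(data["exposure"], [0.1, 5, 95, 99.9])
rr = to_risk_scale(res.predict_grid(exposures=pcts, reference=20.0))
print(rr[rr["lag"] == "overall"].round(3).to_string(index=False))
```

```
 exposure     lag  effect    sd    rr  rr_low  rr_high
   -7.130 overall   0.211 0.103 1.234   1.008    1.512
   -0.398 overall   0.080 0.033 1.083   1.016    1.156
   24.090 overall   0.031 0.011 1.032   1.009    1.055
   29.952 overall   0.068 0.065 1.070   0.942    1.216
```

Each row sums the 31 lag-specific contrasts for that exposure: extreme cold
carries an overall RR of 1.23 (95% CI 1.01–1.51). The generator's true
overall RRs at these exposures are 1.28, 1.15, 1.03 and 1.16 — each inside
its interval (`true_contrast(cfg, x)` returns the truth). `slice_grid`
extracts the lag curve at one exposure or the exposure curve at one lag.

The same workflow runs from a shell:

```sh
pydlnm simulate --out data/ --seed 7
pydlnm fit --input data/simulated.csv --out fit/ --var-df 5 --lag-df 5
pydlnm predict --fit-dir fit/ --out grid.csv --reference 20
pydlnm search --input data/simulated.csv --out criteria.csv --df-grid 11x5,5x5
```

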