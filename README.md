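# rxdiffusion

Bass diffusion modelling of national-scale drug adoption from monthly
prescription volumes.

## The problem

When a new medicine is introduced (or newly subsidised), it can take years
before prescribing reaches its eventual steady-state volume. How long, and
what drives the uptake — external forces such as regulation, subsidy
listing and marketing, or internal forces such as social contagion among
prescribers? `rxdiffusion` answers these questions retrospectively by
fitting the Bass diffusion model to national monthly prescription time
series, for pharmacoepidemiologists and health-services researchers
working with drug-utilisation data.

## The model

The Bass model writes the hazard of adoption at time *t* as *p + q F(t)*,
where *F(t)* is the fraction already adopted, *p* is the coefficient of
innovation (external force) and *q* the coefficient of imitation
(internal force). Solving *dF/dt = (p + qF)(1 − F)* with *F(0) = 0* gives

    F(t) = (1 − e^{−(p+q)t}) / (1 + (q/p) e^{−(p+q)t})

Applied to prescribing, the smoothed, population-normalised monthly volume
is modelled as *m F(t)* with *m* the saturation level in prescriptions per
100,000 population per month and *t = 0* at the first recorded
prescription. The package

- fits (*p*, *q*, *m*) by multi-start nonlinear least squares,
- classifies each adoption as **external-dominant** (*p* > *q*) or
  **internal-dominant** (*p* < *q*),
- reports the **adoption time**: the closed-form
  *t_f = ln((1 + f q/p)/(1 − f)) / (p + q)* months until the curve reaches a
  fraction *f* (default 0.95) of saturation,
- summarises a cohort of drugs (median/IQR of adoption times and fit R²)
  and compares groups with the Kruskal–Wallis rank test, and
- simulates whole prescription cohorts with known ground truth (seasonal
  and end-of-year safety-net fluctuations, count noise, population growth)
  so the full pipeline can be validated by parameter recovery.

A transcription of a published per-drug adoption table for 103 medicines
subsidised in Australia between 1992 and 2009 is packaged
(`rxdiffusion.load_adoption_table()`), since the underlying prescription
volumes are not public.

## Worked example

Simulate one drug with known parameters, preprocess it, and fit:

```python
import numpy as np
from rxdiffusion import (
    SimulationConfig, simulate_drug, to_normalized, BassDiffusionModel,
)

cfg = SimulationConfig(seed=3)          # 216 months, Poisson noise, seasonality
series = simulate_drug(p=0.004, q=0.055, m=1200.0, onset=24, config=cfg,
                       rng=np.random.default_rng(3), drug_id="sertraline-like")
res = BassDiffusionModel.from_series(to_normalized(series)).fit()
print(res.summary())
```

```
Bass Diffusion Model Results
==============================================
Drug:                       sertraline-like
No. observations (months):  191
Converged:                  True (9 starts)
----------------------------------------------
p (external, /month):       0.00409973
q (internal, /month):       0.054252
m (per 100k /month):        1222.98
p/q ratio:                  7.557e-02
Classification:             internal_dominant
----------------------------------------------
R-squared:                  0.9996
Adj. R-squared:             0.9996
RSS:                        11697.6
----------------------------------------------
Adoption time to 95% of saturation: 96.0 months (8.00 years)
Peak adoption rate at:      44.3 months
```

The generating values (*p* = 0.004, *q* = 0.055, *m* = 1200) are recovered
to within a few percent despite counting noise and seasonality; *q* ≫ *p*
marks this uptake as driven by social contagion, and the fitted curve
takes eight years to reach 95% of its saturation volume.

## Command line

```sh
rxdiffusion simulate --config cfg.yaml --out simdir      # cohort + truth CSVs
rxdiffusion fit --prescriptions p.csv --population pop.csv --out results.csv
rxdiffusion summarize results.csv --out summary.json
rxdiffusion summarize table1                             # packaged 103-drug table
```

`simulate` writes `prescriptions.csv` (drug_id, month, count),
`population.csv` (month, persons), `truth.csv` (generating parameters and
derived adoption times) and a `manifest.json` capturing the config hash and
seed; identical config and seed reproduce identical CSVs byte for byte.
`fit` accepts the same long-format prescriptions CSV (multiple dosage forms
of one drug are summed) with a monthly or annual population file, and writes
one row per drug; drugs that cannot be fitted are excluded with a reason
code in the manifest, never silently dropped. `summarize` reports median/IQR
of adoption time and R², the external/internal split, and the two-group
Kruskal–Wallis comparison.

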