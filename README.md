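# biofilmkin

Kinetic modelling of bacterial biofilm growth and antimicrobial killing
from confocal time series.

Flow-cell biofilms (e.g. *Pseudomonas aeruginosa* imaged by confocal
microscopy and quantified with COMSTAT) produce longitudinal, univariate
measurements — biomass (μm³/μm²), average thickness (μm), live and dead
channels — across several independently inoculated channels and
experiments. `biofilmkin` models these data with semiempirical growth laws
coupled to antibiotic effect and pharmacokinetic models,

    dB/dt = g(B) − h(C(t), B),    B(0) = B0,

where g is exponential (kb·B), logistic (kb·B(1 − B/Bmax)), Gompertz
(kb·B·ln(Bmax/B)) or generalised Bertalanffy (kb·B^λ − kd·B^δ); h is a
nonnegative kill term such as the two-drug interaction model
(k1·C1 + k2·C2 + k12·C1·C2)·B; and C(t) follows bolus, infusion or
interpolated concentration profiles. Companion states cover dead-biofilm
accumulation, post-plateau decline through a depleting endogenous
resource, and dormancy lags. Derived quantities include the level-dependent
doubling time td(t) (with B(t+td) = 2B(t)) and the biofilm-inhibitory
concentration BIC(B) = g(B)/(θ1·B), which for limited growth decreases as
the biofilm approaches its carrying capacity.

The statistical layer fits these models to data by single-series maximum
likelihood (profiled σ, multistart L-BFGS-B on log parameters, AIC and
Hannan-Quinn selection, weighted residuals), by two-stage population
analysis, and by a Laplace-approximate nonlinear mixed-effects estimator
with lognormal inter-channel random effects (empirical-Bayes channel
estimates, CV% variability reporting, optional left-censored likelihood
for detection-floor zeros). A synthetic-data module generates
COMSTAT-like multi-experiment datasets with hierarchical variability,
including presets for the standard study designs. See `docs/methods.md`
for the full model and estimator descriptions.

## Worked example

Simulate a control-growth average-thickness series (logistic, Bmax=52.1 μm,
kb=0.051 1/h, additive noise σ=8.02 μm, 15 points over a week) and refit it:

```python
from biofilmkin import ModelSpec, GrowthParams, fit_single, preset, generate_dataset

design = preset("example1_thickness")
series, truth = generate_dataset(design, seed=7)
spec = ModelSpec(growth=GrowthParams(family="logistic", B0=1.0, kb=0.04, Bmax=45.0))
fit = fit_single(series, spec, free=("kb", "Bmax"), censoring="left_zero", seed=0)
print({k: round(float(v), 3) for k, v in fit.estimates.items()})
print({k: round(float(v), 4) for k, v in fit.se.items()}, "aic", round(fit.aic, 2))
```

```
{'kb': 0.051, 'Bmax': 51.401, 'sigma': 5.127}
{'kb': 0.0028, 'Bmax': 2.7044, 'sigma': 0.9361} aic 93.74
```

The fit recovers the generating growth rate (0.051 1/h) and carrying
capacity (51.4 vs 52.1 μm, within one standard error); `sigma` is the
residual standard deviation in μm and `aic` the Akaike criterion used to
compare competing growth laws. The `censoring="left_zero"` option treats
measurements recorded as 0 as values below the detection floor.

Population analysis of a full two-drug time-kill design (7 experiments × 2
channels across control, single-drug, triple-dose and infusion arms):

```python
from biofilmkin import fit_mixed_effects, channel_specs

design = preset("table1")
series, truth = generate_dataset(design, seed=7)
pop = fit_mixed_effects(series, channel_specs(design),
                        free_fixed=("kb", "Bmax", "k1", "k2", "k12"),
                        random_config=("Bmax",), censoring="left_zero",
                        init={"kb": 0.03, "Bmax": 50.0, "k1": 1e-3,
                              "k2": 1e-3, "k12": 1e-4},
                        outer_method="lbfgsb", seed=0)
print({k: round(float(v), 5) for k, v in pop.fixed_effects.items()},
      round(pop.cv_percent["Bmax"], 1), round(pop.sigma, 2))
```

```
{'kb': 0.04235, 'Bmax': 32.95659, 'k1': 0.00251, 'k2': 0.00458, 'k12': 0.00042} 16.3 7.46
```

against generating values kb=0.0425, Bmax=39.5 (inter-channel CV 21.8%),
k1=0.00301, k2=0.00352, k12=0.000473, σ=8.02: growth and interaction
parameters come back near truth from a single 14-channel realization, while
the per-drug kill rates carry the larger sampling noise expected of deeply
censored post-dose measurements (averages over replicate datasets, as in
`scripts/acceptance.py`, tighten them).

A command-line interface wraps the pipeline:

```sh
biofilmkin generate --preset table1 --seed 7 --out data/
biofilmkin fit --data data/data.csv --config model.yaml \
    --method mixed --free kb,Bmax,k1,k2,k12 --random Bmax --out report.json
biofilmkin compare fit_logistic.json fit_gompertz.json --criterion aic
```

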