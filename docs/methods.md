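# Methods

`biofilmkin` models univariate biofilm measurements — COMSTAT-style biomass
(μm³/μm²), average thickness (μm), substratum area or microcolony volume,
with separate live (GFP) and dead (propidium iodide) channels — as solutions
of a one-state kinetic model forced by antimicrobial concentration profiles,
and estimates the kinetic parameters from longitudinal flow-cell data.

## The kinetic model

The live biofilm level B(t) obeys

    dB/dt = g(B)·X_factor ∓ h(C(t), B),    B(0) = B0,

with a minus sign for inhibitory agents (antibiotics) and a plus sign for
growth-stimulating agents.

**Growth laws g(B).** Exponential (kb·B), logistic (kb·B·(1 − B/Bmax)),
Gompertz (kb·B·ln(Bmax/B)) and generalised Bertalanffy
(kb·B^λ − kd·B^δ with 0 < λ < δ; surface-proportional growth, volume-
proportional loss). The logistic law is the λ=1, δ=2, kd=kb/Bmax special
case of the Bertalanffy family. The first three have closed-form solutions,
used both directly and as oracles for the ODE machinery; the δ=1
Bertalanffy subfamily is also closed (z = B^(1−λ) satisfies a linear ODE), a
fast path the fitting layer exploits. Dormancy is a pure lag: growth is
zero for t < t_lag.

**Derived quantities.** The doubling time td(t) solves B(t+td) = 2B(t); it
is constant (ln2/kb) only for exponential growth and diverges once
B ≥ Bmax/2. For the Gompertz law we derive td from the closed-form
solution, td = −(1/kb)·ln(1 − ln2·e^{kb·t}/ln(Bmax/B0)); a simplified
variant lacking the ln(Bmax/B0) factor circulates in the applied literature
and is available behind `as_printed=True` for comparison, but it does not
satisfy the defining relation and is not used anywhere else. The
biofilm-inhibitory concentration BIC(B) is the constant concentration of a
linearly acting agent (kill rate θ1·C·B) that zeroes the net growth rate:
kb/θ1 (exponential), (kb/θ1)(1 − B/Bmax) (logistic), (kb/θ1)ln(Bmax/B)
(Gompertz). For limited growth it is a decreasing function of the current
biofilm level, not a constant. For the Bertalanffy family we extend the
same definition as g(B)/(θ1·B).

**Agent effects h(C, B).** All effect models are nonnegative and linear in
B: linear (θ1·C·B), threshold (active when C ≥ θ2, boundary inclusive),
saturating Emax (θ1·C/(θ2+C)·B); for two agents, additive and interaction
linear models ((k1·C1 + k2·C2 + k12·C1·C2)·B — the population analysis
parameterisation) and competitive saturating models. The published
competitive fractions are dimensionless; a `scale` multiplier (1/h,
default 1) supplies the maximal kill rate. The threshold model's
discontinuity is handled by computing the exact crossing times of C(t)
through θ2 and restarting the integrator there; a sigmoid-smoothed variant
exists for gradient-based optimisers.

**Agent kinetics C(t).** Intermittent bolus with monoexponential washout
(k = ln2/t_half, superposition over doses), constant-rate infusion with
first-order elimination (parameterised by the plateau css, duration and
t_half, because clearance/volume are not separately needed), and
piecewise-linear interpolation of assayed concentrations (0 before the
first point, hold-last-value after the last, both warned). The worked
examples use the meropenem preset (peak 107.53 mg/L, t½ 0.893 h) and
tobramycin preset (peak 32.79 mg/L, t½ 2.75 h); the population analysis
concentration unit is cu = 1000 ng/mL = 1 mg/L.

**Dead biofilm D(t).** For logistic growth the density-limited part of the
growth law is interpreted as cell death, dD/dt = kb·B²/Bmax + h; for the
Bertalanffy law dD/dt = kd·B^δ + h. Killed biomass feeds D only for
inhibitory agents — stimulation creates live cells and contributes nothing
to the dead channel. The Gompertz law has no rate-form death term; the
dead signal is defined post hoc as D(t) = B0·e^{kb·t} − B(t), the shortfall
from unconstrained exponential growth. That difference is transiently
negative at early times (the Gompertz specific growth rate starts at
kb·ln(Bmax/B0) > kb); values are reported as computed, not clipped. For the
logistic/inhibitory case the identity d(B+D)/dt = kb·B holds exactly (kill
terms cancel) and `conservation_check` verifies the simulated paths against
it by spline differentiation within smooth segments.

**Post-plateau decline.** An endogenous variable X multiplies the growth
rate. Depletion variant: dX/dt = −kl·B, X(0)=1, equivalently
X(t) = 1 − kl·∫B; X eventually turns negative and B declines to zero.
Turnover variant: dX/dt = kp − kq·X − kl·B, X(0)=kp/kq, which admits the
nonzero steady state B* = kp/kl (dB/dt = 0 forces X = 0). Both identities
are property-tested.

**Integration.** `solve_ivp` (LSODA, rtol 1e-8 / atol 1e-10 by default),
restarted at every dose time, infusion stop, threshold crossing and lag
end so discontinuous forcing never crosses a solver step. Negative
overshoots of B or D within ~1e3·atol are clipped to zero; larger
excursions abort with a solver error carrying the last accepted time.

## Statistical layer

Observations y_ij from channel j are modelled as V(t_ij; θ_j) + ε with
Gaussian residuals, additive (sd σ, measurement units — the default, since
the population analysis reports a single σ in measurement units) or
proportional (sd σ·V).

**Censoring.** The data are nonnegative physical quantities truncated at 0
at acquisition. With additive noise comparable to the early-biofilm or
post-kill signal, a large fraction of observations is recorded as exactly 0
and a plain Gaussian likelihood is misspecified (it biases B0 up and kb
down by tens of percent on the population design, where ~30% of
observations are truncated). `censoring="left_zero"` treats observations
recorded as 0 as left-censored, contributing −2·lnΦ(−ŷ/σ); every fit to
the truncated synthetic data uses it. Since continuous noise puts zero
probability on the exact value 0, the rule "y == 0 means censored" is
exact for the generator.

**Single-series ML.** Positive parameters are optimised on the log scale
with L-BFGS-B under wide box bounds, from 8 (default) jittered starts; σ is
profiled analytically (uncensored) or estimated jointly (censored).
Standard errors come from the inverse observed information (central finite
differences); a singular information matrix yields NaN SEs with a
convergence note, not a failure. The Gompertz MLE on sigmoid data typically
sits at the B0 → 0 boundary, where the family limits to a shifted
double-exponential sigmoid — growth-curve comparisons therefore pass
explicit wide bounds so the likelihood is genuinely maximised. When a fit
targets data whose inoculum is a protocol constant far below the noise
floor (e.g. 1 unit against σ ≈ 8), B0 is held fixed: left free it is
unidentifiable, trades off against kb, and skews the growth-rate estimate's
sampling distribution.

**Model selection.** AIC = −2logL + 2p and Hannan-Quinn
HQ = −2logL + 2p·ln(ln n). A stricter variant with penalty 2p·ln(n)
(`hq_as_printed`) matching a verbal description of HQ found in the applied
literature is provided for comparison; the standard form is the default.
Ties break toward fewer parameters; fits to different data are refused.

**Two-stage analysis.** Each channel is fitted independently; the
distribution of the per-channel estimates is summarised as mean, SD and
CV%. Channels whose fit fails are excluded and listed.

**Nonlinear mixed effects (Laplace).** Parameters are lognormal across
channels, θ_j,r = δ_r·exp(η_j,r), η_j ~ N(0, diag(ω²)); CV% =
100·√(exp(ω²) − 1). One random-effect level (channel) is used;
experiment-level effects can be emulated by treating experiments as
channels. The per-channel marginal likelihood is Laplace-approximated:
the joint −2log-density is minimised over η (warm-started across outer
iterations), its Hessian taken by central differences, and
−2logL_j ≈ l_j(η̂) + ln det(H/2) − d·ln(2π). The outer problem (log δ,
log ω, log σ) starts from a naive-pooled fit and is solved by Nelder-Mead
or by L-BFGS-B with coarse finite-difference gradients (the inner solves
are tight enough that the envelope surface is smooth). ω is bounded below
at 1e-3, where the objective continuously reduces to the pooled
likelihood, so a collapsing Ω degrades gracefully. On one-dimensional
random effects the Laplace marginal is validated against 15-node adaptive
Gauss-Hermite quadrature (agreement within 0.5% of −2logL in tests).
Empirical-Bayes channel parameters are the inner modes; weighted residuals
use the EB individual predictions.

**Fast prediction.** Logistic growth with any effect linear in B is a
Bernoulli ODE; substituting u = 1/B gives
B(t) = e^{A(t)}/(1/B0 + ∫₀ᵗ e^{A}·(kb/Bmax)·ds), A = ∫(kb − c(s))ds, which
the estimation layer evaluates by trapezoidal quadrature on a refined grid
whose knots include all dose times (concentration jumps use left limits at
segment ends). Concentration combinations are pre-evaluated once per
channel, so repeated evaluation under new parameters costs a few vector
operations — this is what makes the population fits tractable. The fast
path agrees with LSODA to ~1e-3 relative on the dosing designs (tested);
data generation always uses the general ODE route, keeping generator and
fitter numerically independent.

## Synthetic data generator

The generator emulates multi-experiment flow-cell studies: per channel it
draws lognormal parameter perturbations from per-parameter CV%, simulates
live (and optionally dead) trajectories through the dynamics layer, adds
Gaussian residual noise and truncates negative measurements at zero
(recording the count in the truth sidecar). Presets encode the worked
study designs; their defaults are the study conditions and are not tuned:

* `fig2a`/`fig2b` — logistic / Gompertz growth, B0=0.001, kb=6, Bmax=1,
  additive noise sd 0.1. The time grid is not part of the published
  design; 25 evenly spaced points on [0, 2] time units are used (growth
  saturates by t ≈ 2 at these parameters).
* `fig3a`/`fig3b` — Bertalanffy kb=4, kd=2, δ=1, λ=0.25 / 0.1, noise sd
  0.1, same grid.
* `table1` — logistic growth (B0=1, kb=0.0425 1/h, Bmax=39.5 μm³/μm²) with
  two-drug linear-interaction kill (k1=0.00301, k2=0.00352 1/h/cu,
  k12=0.000473 1/h/cu²), inter-channel CV% (21.8, 11.1, 14.8, 20.9, 7.1),
  additive σ=8.02; 7 experiments × 2 channels sampled every 12 h over
  0–168 h. Five dosing arms cycle over the experiments: control, MEM-only
  bolus at 24 h, TOB-only bolus at 24 h, triple q8h bolus of both drugs at
  74 h, and a 3-h MEM infusion plus TOB bolus at 72 h. Single-drug arms
  are included because with both drugs always co-administered at a fixed
  concentration ratio the three kill coefficients lie on a likelihood
  ridge, which is incompatible with the few-percent standard errors such
  population analyses report; the triple-dose spacing (q8h) and the
  infusion duration (3 h) are conventional dosing choices, as the exact
  schedules are not part of the published design. B0 = 1 measurement unit
  is the assumed inoculum level (plateau reached within the 168-h
  horizon); it is a protocol constant of the design.
* `example1_thickness` — logistic control growth at the average-thickness
  scale (B0=1 μm, Bmax=52.1 μm, kb=0.051 1/h), 15 points over 0–168 h,
  additive σ=8.02.

What the generator does **not** emulate: spatial colony structure, image-
level noise (its residuals are exchangeable Gaussians, whereas real
COMSTAT features correlate across z-stacks and positions), adaptive drug
resistance, seeding/dispersal cycles, or inter-occasion variability
distinct from inter-channel variability. Passing recovery tests therefore
demonstrates the estimators are consistent with their own assumptions at
realistic sizes and noise — not that those assumptions hold for any
particular laboratory system.

## Recovery experiments and their problem sizes

The acceptance script (`scripts/acceptance.py`) re-runs three experiment
families at the sizes of the designs they mirror: 500 simulated datasets
per generating model for the logistic/Gompertz AIC comparison; 20
replicate population datasets (14 channels each) for the mixed-effects
recovery, with a random effect on Bmax (the dominant variability source)
and L-BFGS-B outer optimisation capped at 200 iterations; 50 replicate
single series for the thickness recovery. These sizes keep each experiment
to a few minutes while holding Monte-Carlo error well below the reported
effects.

Two distributional facts about the model-comparison experiments, measured
with this package and stable across reasonable design variations: the
median |ΔAIC| between Gompertz and logistic fits on the fig2 designs is
≈ 1.5–2.5 (the central 90% spans roughly 0.2–7, comfortably containing
published single-realization values); and the Bertalanffy model wins the
AIC comparison on its own data in ≈ 80–87% of realizations, the losses
being near-ties within the extra-parameter penalty.

## Known limitations

* The Laplace approximation is first-order; with very few observations per
  channel and large ω it can deviate from the true marginal (the AGH
  cross-check covers only one random-effect dimension).
* The Bernoulli fast path's quadrature error (~1e-3 relative at default
  grids) is negligible against measurement noise but matters if σ is
  pushed below ~1e-3 of signal; pass `fast=False` for solver-grade
  predictions.
* FOCE/SAEM estimators, covariate models on fixed effects, multivariate
  thickness-distribution data and time-varying carrying capacity are out
  of scope.

## Config schema (YAML)

```yaml
growth:                 # required
  family: logistic      # exponential | logistic | gompertz | bertalanffy
  B0: 1.0
  kb: 0.0425
  Bmax: 39.5            # logistic/gompertz only
  # kd, lam, delta      # bertalanffy only
  # t_lag: 0.0
agent_effect:           # optional
  type: two_agent       # single | two_agent
  model: linear_interaction
  theta1: 0.00301
  theta2: 0.00352
  theta3: 0.000473
effect_sign: inhibit    # inhibit | stimulate
dead_model: none        # none | rate_coupled | gompertz_difference
post_plateau:           # optional: {variant: depletion|turnover, kl, kp, kq}
pk:                     # one per agent
  - agent: MEM
    mode: bolus         # bolus | infusion | interpolated
    t_half: 0.893
    events: [{time: 24.0, peak: 107.53}]
  - agent: TOB
    mode: interpolated
    points: [[0.0, 0.0], [168.0, 0.0]]
```
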