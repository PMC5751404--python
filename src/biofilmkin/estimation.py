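"""Maximum-likelihood fitting of biofilm kinetic models to time series.

Observations are modelled as y_i = V(t_i; θ) + ε_i with Gaussian residuals,
either additive (sd σ, measurement units) or proportional (sd σ·prediction).
The −2·log-likelihood of a series is

    −2logL = n·ln(2πσ²) + SSE/σ²                  (additive)
    −2logL = Σ ln(2πσ²ŷ_i²) + Σ r_i²/(σ²ŷ_i²)     (proportional)

σ is profiled analytically during optimisation, positive kinetic parameters
are optimised on the log scale with box bounds (L-BFGS-B) from several
jittered starts, and standard errors come from the inverse of the observed
information estimated by central finite differences.

Model selection uses the Akaike criterion AIC = −2logL + 2p and the
Hannan-Quinn criterion HQ = −2logL + 2p·ln(ln n); a stricter
``hq_as_printed`` variant with penalty 2p·ln(n) is also provided, matching a
verbal description of HQ that circulates in the applied literature.

Population-level estimation (two-stage and Laplace nonlinear mixed effects)
builds on these pieces; the mixed-effects machinery lives in
:mod:`biofilmkin.population` and is re-exported here.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .agent_kinetics import concentration
from .agent_models import AgentParams, TwoAgentParams
from .dynamics import ModelSpec, simulate_trajectory, solver_breakpoints
from .errors import BiofilmkinError, ConfigurationError, FitError, SolverError
from .growth_models import ANALYTIC_FAMILIES, GrowthParams, solve_growth_analytic

#: objective returned when a parameter proposal cannot be simulated
PENALTY_OBJECTIVE = 1e10

_GROWTH_FIELDS = ("B0", "kb", "Bmax", "kd", "lam", "delta", "t_lag")
_AGENT_FIELDS = ("theta1", "theta2", "theta3", "c1_50", "c2_50", "alpha", "scale")
#: population-analysis aliases for the two-agent linear-interaction model
PARAM_ALIASES = {"k1": "theta1", "k2": "theta2", "k12": "theta3"}


@dataclass(frozen=True)
class SeriesData:
    """One measured time series from a single flow-cell channel."""

    experiment_id: str
    channel_id: str
    variable: str  # biomass | avg_thickness | colony_volume | area
    compartment: str  # live | dead
    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ConfigurationError("times and values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("values must be finite")
        if self.compartment not in ("live", "dead"):
            raise ConfigurationError("compartment must be 'live' or 'dead'")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def key(self) -> tuple[str, str]:
        return (self.experiment_id, self.channel_id)


def _as_series_list(data) -> list[SeriesData]:
    if isinstance(data, SeriesData):
        return [data]
    out = list(data)
    if not out or not all(isinstance(s, SeriesData) for s in out):
        raise ConfigurationError("data must be SeriesData or a non-empty list of SeriesData")
    return out


def data_fingerprint(data) -> str:
    """Stable hash of the observation set, for cross-fit consistency checks."""
    h = hashlib.sha256()
    for s in _as_series_list(data):
        h.update(s.experiment_id.encode())
        h.update(s.channel_id.encode())
        h.update(s.compartment.encode())
        h.update(np.ascontiguousarray(s.times).tobytes())
        h.update(np.ascontiguousarray(s.values).tobytes())
    return h.hexdigest()


def update_spec(spec: ModelSpec, params: dict, strict: bool = True) -> ModelSpec:
    """Return a copy of ``spec`` with named parameter values replaced.

    Growth-law fields (B0, kb, Bmax, kd, lam, delta, t_lag) and agent-effect
    fields (theta1..theta3, c1_50, c2_50, alpha, scale) are recognised, plus
    the population-analysis aliases k1/k2/k12 for the two-agent linear
    coefficients.  With ``strict=False`` agent parameters are silently
    ignored when the spec carries no agent effect — the population layer uses
    this so control-arm channels, whose predictions do not involve the kill
    parameters, accept the population parameter vector.
    """
    gkw, akw = {}, {}
    for name, value in params.items():
        name = PARAM_ALIASES.get(name, name)
        if name in _GROWTH_FIELDS:
            gkw[name] = float(value)
        elif name in _AGENT_FIELDS:
            akw[name] = float(value)
        else:
            raise ConfigurationError(f"unknown parameter {name!r}")
    growth = replace(spec.growth, **gkw) if gkw else spec.growth
    effect = spec.agent_effect
    if akw:
        if effect is None:
            if strict:
                raise ConfigurationError(
                    "agent parameters given but spec has no agent effect"
                )
        else:
            effect = replace(effect, **akw)
    return replace(spec, growth=growth, agent_effect=effect)


# ---------------------------------------------------------------------------
# prediction


def _is_closed_form(spec: ModelSpec, compartment: str) -> bool:
    return (
        compartment == "live"
        and spec.agent_effect is None
        and spec.post_plateau is None
        and spec.growth.family in ANALYTIC_FAMILIES
    )


def _is_bert_delta1(spec: ModelSpec, compartment: str) -> bool:
    """δ=1 Bertalanffy: z = B^(1−λ) satisfies a linear ODE, so B(t) is closed."""
    g = spec.growth
    return (
        compartment == "live"
        and spec.agent_effect is None
        and spec.post_plateau is None
        and g.family == "bertalanffy"
        and g.delta == 1.0
    )


def _bert_delta1_solution(g: GrowthParams, times: np.ndarray) -> np.ndarray:
    te = np.maximum(np.asarray(times, dtype=float) - g.t_lag, 0.0)
    p = 1.0 - g.lam
    z_inf = g.kb / g.kd
    z = z_inf + (g.B0**p - z_inf) * np.exp(-g.kd * p * te)
    return np.maximum(z, 0.0) ** (1.0 / p)


def _is_bernoulli(spec: ModelSpec, compartment: str) -> bool:
    """Logistic growth with an effect linear in B reduces to a Bernoulli ODE."""
    if compartment != "live" or spec.post_plateau is not None:
        return False
    if spec.growth.family != "logistic" or spec.effect_sign != "inhibit":
        return False
    eff = spec.agent_effect
    if isinstance(eff, AgentParams):
        return eff.model == "linear"
    if isinstance(eff, TwoAgentParams):
        return eff.model in ("additive_linear", "linear_interaction")
    return False


class BernoulliPredictor:
    """Fast live-biofilm predictor for logistic growth with linear-in-B kill.

    Substituting u = 1/B turns dB/dt = [kb − c(t)]·B − (kb/Bmax)·B² into a
    linear ODE; B(t) = e^{A(t)} / (1/B0 + ∫₀ᵗ e^{A} q ds) with
    A(t) = ∫₀ᵗ (kb·1[s≥t_lag] − c(s)) ds and q = (kb/Bmax)·1[s≥t_lag].
    The concentration combination c(t) is pre-evaluated once on a refined
    quadrature grid (dose times are grid knots), so repeated evaluation under
    changing kinetic parameters costs a handful of vector operations — the
    workhorse of the population fits.  Accuracy is set by the trapezoidal
    grid spacing; the general LSODA route is the reference in tests.
    """

    def __init__(self, spec: ModelSpec, sample_times, dt: float | None = None):
        st = np.asarray(sample_times, dtype=float)
        t_end = float(st.max()) if len(st) else 1.0
        if dt is None:
            dt = t_end / 2000.0
            if spec.pk:
                dt = min(dt, min(p.t_half for p in spec.pk if p.t_half) / 20.0)
        base = np.arange(0.0, t_end + dt, dt)
        bps = solver_breakpoints(spec, t_end)
        grid = np.union1d(np.union1d(base, st), np.append(bps, [0.0, t_end]))
        grid = grid[(grid >= 0) & (grid <= t_end)]
        self.grid = grid
        self.dt_seg = np.diff(grid)
        self.sample_idx = np.searchsorted(grid, st)
        # C(t) is right-continuous at dose times; each quadrature segment's
        # right endpoint therefore uses the left limit C(t−), or the jump at a
        # dose would be smeared into the preceding segment.
        gridL = np.maximum(grid - 1e-9, 0.0)
        self.t_lag_mask = (grid >= spec.growth.t_lag).astype(float)
        self.t_lag_maskL = (gridL >= spec.growth.t_lag).astype(float)
        eff = spec.agent_effect
        self._mode = None
        if isinstance(eff, AgentParams):
            self._mode = "single"
            self.c1 = np.asarray(concentration(spec.pk[0], grid))
            self.c1L = np.asarray(concentration(spec.pk[0], gridL))
        elif isinstance(eff, TwoAgentParams):
            self._mode = "two"
            self.c1 = np.asarray(concentration(spec.pk[0], grid))
            self.c2 = np.asarray(concentration(spec.pk[1], grid))
            self.c12 = self.c1 * self.c2
            self.c1L = np.asarray(concentration(spec.pk[0], gridL))
            self.c2L = np.asarray(concentration(spec.pk[1], gridL))
            self.c12L = self.c1L * self.c2L
        else:
            self._mode = "none"

    def _cumtrapz(self, f, fL=None):
        """Cumulative trapezoid; ``fL`` supplies left-limit right endpoints."""
        out = np.empty_like(f)
        out[0] = 0.0
        right = f[1:] if fL is None else fL[1:]
        np.cumsum(0.5 * (right + f[:-1]) * self.dt_seg, out=out[1:])
        return out

    def _kill_rate(self, thetas):
        if self._mode == "single":
            return thetas[0] * self.c1, thetas[0] * self.c1L
        if self._mode == "two":
            c = thetas[0] * self.c1 + thetas[1] * self.c2
            cL = thetas[0] * self.c1L + thetas[1] * self.c2L
            if thetas[2] is not None:
                c = c + thetas[2] * self.c12
                cL = cL + thetas[2] * self.c12L
            return c, cL
        return 0.0, 0.0

    def predict_raw(self, B0: float, kb: float, Bmax: float, thetas=()) -> np.ndarray:
        """Evaluate with plain floats (optimiser hot path, no spec objects)."""
        c, cL = self._kill_rate(thetas)
        a = kb * self.t_lag_mask - c
        aL = kb * self.t_lag_maskL - cL
        A = np.clip(self._cumtrapz(a, aL), -700.0, 700.0)
        # extreme optimizer proposals can overflow the running integral; the
        # resulting prediction degenerates to 0 and the objective is penalised
        with np.errstate(over="ignore"):
            eA = np.exp(A)
            q = (kb / Bmax) * self.t_lag_mask
            qL = (kb / Bmax) * self.t_lag_maskL
            integral = self._cumtrapz(eA * q, eA * qL)
            B = eA / (1.0 / B0 + integral)
        return B[self.sample_idx]

    def predict(self, spec: ModelSpec) -> np.ndarray:
        g = spec.growth
        eff = spec.agent_effect
        if self._mode == "single":
            thetas = (eff.theta1,)
        elif self._mode == "two":
            theta3 = eff.theta3 if eff.model == "linear_interaction" else None
            thetas = (eff.theta1, eff.theta2, theta3)
        else:
            thetas = ()
        return self.predict_raw(g.B0, g.kb, g.Bmax, thetas)


def predict(
    spec: ModelSpec,
    times,
    compartment: str = "live",
    rtol: float = 1e-7,
    atol: float = 1e-9,
    fast: bool = True,
    _predictor: BernoulliPredictor | None = None,
) -> np.ndarray:
    """Model prediction V(t; θ) on the observation times.

    Dispatches to the closed-form solution, the Bernoulli fast path, or the
    general ODE integrator, in that order of preference (``fast=False``
    forces the general route).
    """
    times = np.asarray(times, dtype=float)
    if fast and _is_closed_form(spec, compartment):
        return solve_growth_analytic(spec.growth, times)
    if fast and _is_bert_delta1(spec, compartment):
        return _bert_delta1_solution(spec.growth, times)
    if fast and _is_bernoulli(spec, compartment):
        pred = _predictor if _predictor is not None else BernoulliPredictor(spec, times)
        return pred.predict(spec)
    grid = np.union1d(np.asarray([0.0]), times)
    traj = simulate_trajectory(spec, grid, rtol=rtol, atol=atol)
    idx = np.searchsorted(grid, times)
    path = traj.B if compartment == "live" else traj.D
    return path[idx]


# ---------------------------------------------------------------------------
# likelihood


def _sigma_for(sigma, compartment: str) -> float:
    if isinstance(sigma, dict):
        return float(sigma[compartment])
    return float(sigma)


def negloglik(
    data,
    spec: ModelSpec,
    params: dict | None = None,
    sigma=1.0,
    residual_model: str = "additive",
    censoring: str = "none",
    fast: bool = True,
    strict: bool = True,
    _predictors: dict | None = None,
) -> float:
    """−2·log-likelihood of one or more series under Gaussian residuals.

    ``sigma`` may be a scalar (shared across compartments) or a dict keyed by
    compartment.  ``censoring="left_zero"`` treats observations recorded as
    exactly 0 as left-censored at the detection floor (Tobit contribution
    −2·ln Φ(−ŷ/scale)); nonnegative physical measurements are truncated at 0
    during acquisition, so a continuous-noise observation of exactly 0 is a
    censoring event, not a value.  A parameter proposal that cannot be
    simulated (solver failure, invalid parameter combination) returns a large
    finite penalty so optimisers can back away rather than crash.
    """
    series = _as_series_list(data)
    if residual_model not in ("additive", "proportional"):
        raise ConfigurationError("residual_model must be 'additive' or 'proportional'")
    if censoring not in ("none", "left_zero"):
        raise ConfigurationError("censoring must be 'none' or 'left_zero'")
    try:
        sp = update_spec(spec, params, strict=strict) if params else spec
    except (ConfigurationError, BiofilmkinError):
        return PENALTY_OBJECTIVE
    total = 0.0
    for s in series:
        sd = _sigma_for(sigma, s.compartment)
        if not sd > 0:
            raise ConfigurationError("sigma must be > 0")
        try:
            pred_obj = (_predictors or {}).get(id(s))
            yhat = predict(sp, s.times, s.compartment, fast=fast, _predictor=pred_obj)
        except (SolverError, ConfigurationError, ValueError, FloatingPointError):
            return PENALTY_OBJECTIVE
        if not np.all(np.isfinite(yhat)):
            return PENALTY_OBJECTIVE
        if residual_model == "proportional" and np.any(yhat <= 0):
            return PENALTY_OBJECTIVE
        total += _gaussian_neg2ll_terms(s.values, yhat, sd, residual_model, censoring)
    return total


def _gaussian_neg2ll_terms(values, yhat, sd, residual_model, censoring) -> float:
    """Sum of per-observation −2·log-density (or censoring) contributions."""
    scale = sd if residual_model == "additive" else sd * yhat
    r = values - yhat
    if censoring == "left_zero":
        cens = values == 0.0
    else:
        cens = np.zeros(len(values), dtype=bool)
    obs = ~cens
    total = 0.0
    if np.any(obs):
        sc = scale if np.ndim(scale) == 0 else scale[obs]
        z = r[obs] / sc
        total += float(np.sum(np.log(2.0 * math.pi * sc * sc) + z * z)) if np.ndim(sc) \
            else len(z) * math.log(2.0 * math.pi * sc * sc) + float(z @ z)
    if np.any(cens):
        from scipy.special import log_ndtr

        sc = scale if np.ndim(scale) == 0 else scale[cens]
        total += -2.0 * float(np.sum(log_ndtr(-yhat[cens] / sc)))
    return total


def _profiled_neg2ll(series, preds, residual_model: str):
    """Concentrated −2logL with the shared σ at its analytic maximum."""
    n = 0
    sse = 0.0
    logpred = 0.0
    for s, yhat in zip(series, preds):
        r = s.values - yhat
        if residual_model == "proportional":
            if np.any(yhat <= 0):
                return PENALTY_OBJECTIVE, np.nan
            r = r / yhat
            logpred += 2.0 * float(np.sum(np.log(yhat)))
        sse += float(r @ r)
        n += len(r)
    if sse <= 0:
        sse = 1e-300  # exact interpolation; keep the objective finite
    s2 = sse / n
    obj = n * math.log(2.0 * math.pi * s2) + n + logpred
    return obj, math.sqrt(s2)


# ---------------------------------------------------------------------------
# single-series fits


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit to one (or a few joint) series."""

    estimates: dict
    se: dict
    objective: float  # −2·log-likelihood at the optimum
    n_obs: int
    n_params: int
    aic: float
    hq: float
    hq_as_printed: float
    residuals: np.ndarray
    weighted_residuals: np.ndarray
    predictions: np.ndarray
    residual_model: str
    spec: ModelSpec  # spec with the estimates substituted
    free: tuple
    label: str
    convergence: dict
    seed: int | None
    data_hash: str


def _default_init(series: list[SeriesData], spec: ModelSpec, free) -> dict:
    live = [s for s in series if s.compartment == "live"] or series
    values = np.concatenate([s.values for s in live])
    times = np.concatenate([s.times for s in live])
    vmax = float(np.max(values)) if np.max(values) > 0 else 1.0
    order = np.argsort(times)
    tv, vv = times[order], values[order]
    init: dict = {}
    g = spec.growth
    for name in free:
        canon = PARAM_ALIASES.get(name, name)
        cur = getattr(g, canon, None)
        if cur is None and spec.agent_effect is not None:
            cur = getattr(spec.agent_effect, canon, None)
        if canon == "Bmax":
            init[name] = 1.05 * vmax
        elif canon == "B0":
            v0 = vv[0] if len(vv) else vmax
            init[name] = max(float(v0), 0.02 * vmax)
        elif canon == "kb":
            above = tv[vv >= 0.5 * vmax]
            t50 = float(above[0]) if len(above) and above[0] > 0 else float(tv[-1]) / 2
            b0 = init.get("B0", max(float(vv[0]), 0.02 * vmax))
            ratio = max((1.05 * vmax - b0) / b0, 2.0)
            init[name] = math.log(ratio) / max(t50, 1e-6)
        elif cur is not None and cur > 0:
            init[name] = float(cur)
        elif canon == "kd":
            init[name] = 0.5 * init.get("kb", 1.0)
        else:
            init[name] = 1e-3
    return init


_DEFAULT_FREE = {
    "exponential": ("B0", "kb"),
    "logistic": ("B0", "kb", "Bmax"),
    "gompertz": ("B0", "kb", "Bmax"),
    "bertalanffy": ("B0", "kb", "kd", "lam"),
}


def fit_single(
    data,
    spec: ModelSpec,
    free=None,
    init: dict | None = None,
    bounds: dict | None = None,
    residual_model: str = "additive",
    censoring: str = "none",
    multistart: int = 8,
    seed: int | None = None,
    fast: bool = True,
    label: str | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Fit a model to one channel's series by maximum likelihood.

    Positive parameters are optimised on the log scale (L-BFGS-B) from
    ``multistart`` jittered starting points; σ is profiled analytically
    (or optimised jointly when ``censoring="left_zero"``, where no closed
    form exists).  Deterministic given ``seed``.
    """
    series = _as_series_list(data)
    free = tuple(free) if free is not None else _DEFAULT_FREE[spec.growth.family]
    n_obs = sum(len(s.values) for s in series)
    if n_obs < len(free) + 1:
        raise FitError(f"need at least {len(free) + 1} observations to fit {len(free)} parameters")
    init_full = _default_init(series, spec, free)
    if init:
        init_full.update({k: float(v) for k, v in init.items()})
    fit_sigma = censoring != "none"
    opt_names = free + ("sigma",) if fit_sigma else free
    if fit_sigma and "sigma" not in init_full:
        allv = np.concatenate([s.values for s in series])
        init_full["sigma"] = max(float(np.std(allv)) / 2.0, 1e-6)
    x0 = np.log([max(init_full[name], 1e-300) for name in opt_names])
    lo = np.empty_like(x0)
    hi = np.empty_like(x0)
    for i, name in enumerate(opt_names):
        if bounds and name in bounds:
            lo[i], hi[i] = np.log(bounds[name][0]), np.log(bounds[name][1])
        else:
            lo[i], hi[i] = x0[i] - math.log(1e4), x0[i] + math.log(1e4)
    x0 = np.clip(x0, lo, hi)

    predictors = {}
    if fast and _is_bernoulli(spec, "live"):
        for s in series:
            if s.compartment == "live":
                predictors[id(s)] = BernoulliPredictor(spec, s.times)

    def _predictions(sp):
        preds = []
        for s in series:
            yhat = predict(sp, s.times, s.compartment, fast=fast,
                           _predictor=predictors.get(id(s)))
            if not np.all(np.isfinite(yhat)):
                raise SolverError("non-finite prediction")
            preds.append(yhat)
        return preds

    def objective(x):
        vals = np.exp(x)
        params = dict(zip(free, vals))
        try:
            sp = update_spec(spec, params)
            preds = _predictions(sp)
        except (SolverError, ConfigurationError, BiofilmkinError, ValueError,
                FloatingPointError):
            return PENALTY_OBJECTIVE
        if fit_sigma:
            sd = float(vals[-1])
            if residual_model == "proportional" and any(np.any(p <= 0) for p in preds):
                return PENALTY_OBJECTIVE
            return sum(
                _gaussian_neg2ll_terms(s.values, p, sd, residual_model, censoring)
                for s, p in zip(series, preds)
            )
        obj, _ = _profiled_neg2ll(series, preds, residual_model)
        return obj

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(multistart, 1) - 1):
        starts.append(np.clip(x0 + rng.normal(0.0, 0.5, size=len(x0)), lo, hi))
    best = None
    log = []
    for k, xs in enumerate(starts):
        res = minimize(objective, xs, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        log.append({"start": k, "objective": float(res.fun), "success": bool(res.success)})
        if np.isfinite(res.fun) and res.fun < PENALTY_OBJECTIVE and (
            best is None or res.fun < best.fun
        ):
            best = res
    if best is None:
        raise FitError(f"all {len(starts)} starts failed; per-start log: {log}")

    est = dict(zip(opt_names, np.exp(best.x)))
    spec_hat = update_spec(spec, {k: v for k, v in est.items() if k != "sigma"})
    preds = _predictions(spec_hat)
    if fit_sigma:
        sigma_hat = float(est["sigma"])
        obj = sum(
            _gaussian_neg2ll_terms(s.values, p, sigma_hat, residual_model, censoring)
            for s, p in zip(series, preds)
        )
    else:
        obj, sigma_hat = _profiled_neg2ll(series, preds, residual_model)
    est["sigma"] = sigma_hat
    predictions = np.concatenate(preds)
    observed = np.concatenate([s.values for s in series])
    residuals = observed - predictions
    if residual_model == "additive":
        wres = residuals / sigma_hat
    else:
        wres = residuals / (sigma_hat * predictions)
    p = len(free) + 1  # kinetic parameters + σ
    n = n_obs

    se: dict = {name: float("nan") for name in free}
    se["sigma"] = sigma_hat / math.sqrt(2 * n)
    converged = {"starts": log, "best_start": int(np.argmin([e["objective"] for e in log]))}
    if compute_se:
        theta = np.exp(best.x[: len(free)])  # kinetic part only; σ handled above

        def nll_nat(th):
            return negloglik(series, spec, dict(zip(free, th)), sigma=sigma_hat,
                             residual_model=residual_model, censoring=censoring,
                             fast=fast, _predictors=predictors)

        H = _fd_hessian(nll_nat, theta)
        try:
            cov = 2.0 * np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(diag > 0):
                for i, name in enumerate(free):
                    se[name] = float(math.sqrt(diag[i]))
            else:
                converged["se_note"] = "information matrix not positive definite"
        except np.linalg.LinAlgError:
            converged["se_note"] = "singular information matrix; SEs unavailable"

    return FitResult(
        estimates=est,
        se=se,
        objective=float(obj),
        n_obs=n,
        n_params=p,
        aic=float(obj + 2 * p),
        hq=float(obj + 2 * p * math.log(math.log(n))),
        hq_as_printed=float(obj + 2 * p * math.log(n)),
        residuals=residuals,
        weighted_residuals=wres,
        predictions=predictions,
        residual_model=residual_model,
        spec=spec_hat,
        free=free,
        label=label or spec.growth.family,
        convergence=converged,
        seed=seed,
        data_hash=data_fingerprint(series),
    )


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-12)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# model selection


def model_selection(fits, criterion: str = "aic") -> pd.DataFrame:
    """Rank fits of competing models to the same data.

    Ties (within 1e-9) are broken toward the model with fewer parameters.
    Fits to different data are rejected.
    """
    fits = list(fits)
    if not fits:
        raise ConfigurationError("no fits given")
    if criterion not in ("aic", "hq", "hq_as_printed"):
        raise ConfigurationError("criterion must be aic, hq or hq_as_printed")
    ref = fits[0].data_hash
    if any(f.data_hash != ref for f in fits):
        raise ConfigurationError("all fits must be computed on identical data")
    rows = []
    for f in fits:
        rows.append(
            {
                "label": f.label,
                "n_params": f.n_params,
                "objective": f.objective,
                "aic": f.aic,
                "hq": f.hq,
                "hq_as_printed": f.hq_as_printed,
            }
        )
    table = pd.DataFrame(rows)
    crit = table[criterion].round(9)
    table = table.assign(_crit=crit).sort_values(["_crit", "n_params"]).drop(columns="_crit")
    table["rank"] = np.arange(1, len(table) + 1)
    table[f"delta_{criterion}"] = table[criterion] - table[criterion].min()
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# two-stage population analysis


@dataclass
class TwoStageResult:
    """Per-channel fits plus the distribution of their estimates."""

    fits: dict
    excluded: list
    summary: pd.DataFrame


def spec_for(specs, key) -> ModelSpec:
    """Resolve a ModelSpec for a channel key from a spec or a mapping."""
    if isinstance(specs, ModelSpec):
        return specs
    try:
        return specs[key]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"no model spec available for channel {key}") from exc


def group_channels(dataset) -> dict:
    """Group a list of SeriesData by (experiment_id, channel_id)."""
    groups: dict = {}
    for s in _as_series_list(dataset):
        groups.setdefault(s.key, []).append(s)
    return groups


def fit_two_stage(dataset, specs, free=None, seed: int | None = None, **fit_kwargs):
    """Stage 1: independent fit per channel; stage 2: estimate distribution.

    ``specs`` is a single ModelSpec or a mapping (experiment, channel) →
    ModelSpec (needed when channels received different dosing arms).
    Channels whose stage-1 fit fails are excluded and listed.  The summary
    reports mean, SD and CV% = 100·SD/mean of each estimate across channels.
    """
    groups = group_channels(dataset)
    if len(groups) < 2:
        raise FitError("two-stage analysis requires at least 2 channels")
    fits: dict = {}
    excluded: list = []
    for i, (key, series) in enumerate(sorted(groups.items())):
        sub_seed = None if seed is None else seed + i
        try:
            fits[key] = fit_single(series, spec_for(specs, key), free=free,
                                   seed=sub_seed, **fit_kwargs)
        except (FitError, BiofilmkinError) as exc:
            excluded.append((key, str(exc)))
    if len(fits) < 2:
        raise FitError(f"fewer than 2 channels fitted successfully; excluded: {excluded}")
    names = sorted({n for f in fits.values() for n in f.estimates})
    rows = []
    for name in names:
        vals = np.array([f.estimates[name] for f in fits.values() if name in f.estimates])
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        rows.append(
            {"parameter": name, "mean": mean, "sd": sd,
             "cv_percent": 100.0 * sd / mean if mean != 0 else float("nan"),
             "n_channels": len(vals)}
        )
    summary = pd.DataFrame(rows).set_index("parameter")
    return TwoStageResult(fits=fits, excluded=excluded, summary=summary)


# ---------------------------------------------------------------------------
# weighted residuals


def weighted_residuals(fit, data=None):
    """Per-observation weighted residuals (observed − predicted)/scale.

    For single fits the scale is σ (additive) or σ·prediction (proportional).
    For population fits, empirical-Bayes individual predictions are used.
    Observations with zero prediction under proportional scaling are flagged
    (NaN) and a warning is emitted.
    """
    from .population import PopulationFit, population_weighted_residuals

    if isinstance(fit, PopulationFit):
        return population_weighted_residuals(fit, data)
    if not isinstance(fit, FitResult):
        raise ConfigurationError("fit must be a FitResult or PopulationFit")
    if data is None:
        return fit.weighted_residuals
    series = _as_series_list(data)
    sigma = fit.estimates["sigma"]
    out = []
    for s in series:
        yhat = predict(fit.spec, s.times, s.compartment)
        r = s.values - yhat
        if fit.residual_model == "additive":
            out.append(r / sigma)
        else:
            scale = sigma * yhat
            bad = scale == 0
            if np.any(bad):
                warnings.warn(
                    f"{int(bad.sum())} observations with zero prediction excluded "
                    "from proportional weighting", stacklevel=2,
                )
            out.append(np.where(bad, np.nan, r / np.where(bad, 1.0, scale)))
    return np.concatenate(out)


# Lazy re-export of the population layer (avoids a circular import when
# biofilmkin.population is imported directly).
_POPULATION_EXPORTS = (
    "PopulationFit",
    "empirical_bayes",
    "fit_mixed_effects",
    "marginal_neg2loglik",
)


def __getattr__(name):
    if name in _POPULATION_EXPORTS:
        from . import population

        return getattr(population, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
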