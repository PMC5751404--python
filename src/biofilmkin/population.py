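"""Nonlinear mixed-effects estimation by the Laplace approximation.

The hierarchical model for observation i of channel j is

    y_ij = V(t_ij; θ_j) + ε_ij,    ε_ij ~ N(0, σ²)  (or σ·V proportional)
    θ_j,r = δ_r · exp(η_j,r),      η_j ~ N(0, diag(ω²))

with fixed effects δ, lognormal inter-channel random effects on a chosen
subset of the parameters (all kinetic parameters are positive, and
inter-channel variability is conventionally reported as a coefficient of
variation, CV% = 100·sqrt(exp(ω²) − 1)), and residual error ε.

The marginal likelihood of a channel, ∫ p(y_j | η) p(η) dη, is approximated
by the Laplace method: the joint −2·log-density l_j(η) is minimised over η
(the empirical-Bayes mode η̂_j, warm-started across outer iterations), its
Hessian H_j estimated by central differences, and

    −2·log L_j ≈ l_j(η̂_j) + log det(H_j/2) − d·log(2π).

The outer problem — δ, ω and σ, all log-transformed — is solved by
Nelder-Mead from a naive-pooled starting fit.  On one-dimensional random
effects the Laplace marginal can be cross-checked against adaptive
Gauss-Hermite quadrature (:func:`marginal_neg2loglik` with
``method="agh"``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .dynamics import ModelSpec
from .errors import BiofilmkinError, ConfigurationError, FitError

#: names resolved lazily from estimation to avoid a hard import cycle
from . import estimation as _est


def cv_to_omega(cv_percent: float) -> float:
    """ω of a lognormal random effect with the given CV%."""
    cv = cv_percent / 100.0
    return math.sqrt(math.log(1.0 + cv * cv))


def omega_to_cv(omega: float) -> float:
    """CV% of a lognormal random effect with log-scale SD ω."""
    return 100.0 * math.sqrt(math.exp(omega * omega) - 1.0)


@dataclass
class PopulationFit:
    """Result of a mixed-effects fit."""

    fixed_effects: dict
    omega: dict  # parameter -> ω (SD of the log-scale random effect)
    cv_percent: dict
    sigma: float
    eb_estimates: dict  # channel key -> {"eta": {...}, "params": {...}}
    objective: float  # Laplace-approximate marginal −2·log-likelihood
    method: str
    convergence: dict
    seed: int | None
    specs: object  # ModelSpec or mapping used per channel
    free_fixed: tuple
    random_config: tuple
    residual_model: str
    censoring: str = "none"


class _Channel:
    """One flow-cell channel: its series, spec and cached fast predictors."""

    def __init__(self, key, series, spec: ModelSpec, fast: bool = True):
        self.key = key
        self.series = series
        self.spec = spec
        self.predictors = {}
        if fast:
            for s in series:
                if s.compartment == "live" and _est._is_bernoulli(spec, "live"):
                    self.predictors[id(s)] = _est.BernoulliPredictor(spec, s.times)
        self.fast = fast
        # hot path: every series predicted by a cached Bernoulli grid or by
        # the closed-form logistic solution (control channels)
        self.closed_logistic = (
            _est._is_closed_form(spec, "live") and spec.growth.family == "logistic"
        )
        self.raw_ok = fast and all(
            id(s) in self.predictors
            or (s.compartment == "live" and self.closed_logistic)
            for s in series
        )
        eff = spec.agent_effect
        self.theta_defaults = None
        if eff is not None:
            self.theta_defaults = (
                getattr(eff, "theta1", None),
                getattr(eff, "theta2", None),
                getattr(eff, "theta3", None),
            )


def _channel_neg2ll_raw(ch: _Channel, params: dict, sigma: float,
                        residual_model: str, censoring: str) -> float:
    """Inline −2logL for cached-predictor channels; avoids spec rebuilding."""
    g = ch.spec.growth
    B0 = params.get("B0", g.B0)
    kb = params.get("kb", g.kb)
    Bmax = params.get("Bmax", g.Bmax)
    if ch.theta_defaults is None:
        thetas = ()
    else:
        d1, d2, d3 = ch.theta_defaults
        thetas = (params.get("theta1", d1), params.get("theta2", d2),
                  params.get("theta3", d3))
    total = 0.0
    for s in ch.series:
        pred = ch.predictors.get(id(s))
        if pred is not None:
            yhat = pred.predict_raw(B0, kb, Bmax, thetas)
        else:  # closed-form logistic control channel
            te = np.maximum(s.times - g.t_lag, 0.0)
            yhat = Bmax * B0 / (B0 + (Bmax - B0) * np.exp(-kb * te))
        if not np.all(np.isfinite(yhat)):
            return _est.PENALTY_OBJECTIVE
        if residual_model == "proportional" and np.any(yhat <= 0):
            return _est.PENALTY_OBJECTIVE
        total += _est._gaussian_neg2ll_terms(s.values, yhat, sigma,
                                             residual_model, censoring)
    return total


def _build_channels(dataset, specs, fast: bool = True) -> list[_Channel]:
    groups = _est.group_channels(dataset)
    return [
        _Channel(key, series, _est.spec_for(specs, key), fast=fast)
        for key, series in sorted(groups.items())
    ]


def _joint_neg2ll(ch: _Channel, delta: dict, eta: np.ndarray, omega: np.ndarray,
                  sigma: float, random_config, residual_model: str,
                  censoring: str = "none") -> float:
    """−2·log[p(y_j | η) p(η)] for one channel."""
    params = dict(delta)
    for r, name in enumerate(random_config):
        params[name] = delta[name] * math.exp(eta[r])
    if ch.raw_ok:
        canon = {_est.PARAM_ALIASES.get(k, k): v for k, v in params.items()}
        nll = _channel_neg2ll_raw(ch, canon, sigma, residual_model, censoring)
    else:
        nll = _est.negloglik(ch.series, ch.spec, params, sigma=sigma,
                             residual_model=residual_model, censoring=censoring,
                             fast=ch.fast, strict=False, _predictors=ch.predictors)
    prior = float(np.sum(eta * eta / (omega * omega)
                         + np.log(2.0 * math.pi * omega * omega)))
    return nll + prior


def _fd_hessian_abs(f, x: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian with an absolute step (for η near 0)."""
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step * step)
    return H


def _laplace_channel(ch, delta, omega, sigma, random_config, residual_model,
                     censoring="none", eta0=None):
    """Laplace −2logL contribution and the EB mode for one channel."""
    d = len(random_config)
    fun = lambda eta: _joint_neg2ll(ch, delta, eta, omega, sigma,
                                    random_config, residual_model, censoring)
    x0 = np.zeros(d) if eta0 is None else np.asarray(eta0, dtype=float)
    # η̂ precision feeds the Laplace value only at second order; a loose
    # gradient tolerance is ample and keeps warm-started solves to a few steps
    res = minimize(fun, x0, method="BFGS", options={"gtol": 2e-3, "maxiter": 40})
    eta_hat = res.x
    l_hat = float(res.fun)
    if not np.isfinite(l_hat) or l_hat >= _est.PENALTY_OBJECTIVE:
        return _est.PENALTY_OBJECTIVE, eta_hat, None, False
    H = _fd_hessian_abs(fun, eta_hat, step=1e-3)
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    w = np.clip(w, 1e-10, None)
    logdet_half = float(np.sum(np.log(w / 2.0)))
    contrib = l_hat + logdet_half - d * math.log(2.0 * math.pi)
    return contrib, eta_hat, (w, V), bool(res.success)


def _agh_channel(ch, delta, omega, sigma, random_config, residual_model,
                 censoring="none", nodes: int = 15):
    """Adaptive Gauss-Hermite marginal −2logL (1-D random effect only)."""
    if len(random_config) != 1:
        raise ConfigurationError("Gauss-Hermite validation supports one random effect")
    fun = lambda eta: _joint_neg2ll(ch, delta, eta, omega, sigma,
                                    random_config, residual_model, censoring)
    res = minimize(fun, np.zeros(1), method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 200})
    eta_hat = res.x
    H = _fd_hessian_abs(fun, eta_hat, step=1e-3)
    h = max(float(H[0, 0]), 1e-10)
    s = math.sqrt(2.0 / h)
    x, w = np.polynomial.hermite.hermgauss(nodes)
    logterms = np.array(
        [math.log(w[i]) + x[i] ** 2 - 0.5 * fun(eta_hat + s * x[i]) for i in range(nodes)]
    )
    log_marginal = math.log(s) + float(logsumexp(logterms))
    return -2.0 * log_marginal


def marginal_neg2loglik(
    dataset,
    specs,
    fixed_effects: dict,
    omega: dict,
    sigma: float,
    random_config=None,
    residual_model: str = "additive",
    censoring: str = "none",
    method: str = "laplace",
    agh_nodes: int = 15,
    fast: bool = True,
) -> float:
    """Marginal −2·log-likelihood of a dataset at given population parameters.

    ``method="laplace"`` uses the same approximation as the fitter;
    ``method="agh"`` uses adaptive Gauss-Hermite quadrature with
    ``agh_nodes`` nodes (one random effect only) as an independent check.
    """
    random_config = tuple(random_config or omega.keys())
    om = np.array([float(omega[name]) for name in random_config])
    if np.any(om <= 0):
        raise ConfigurationError("omega entries must be > 0")
    channels = _build_channels(dataset, specs, fast=fast)
    total = 0.0
    for ch in channels:
        if method == "laplace":
            contrib, *_ = _laplace_channel(ch, fixed_effects, om, sigma,
                                           random_config, residual_model, censoring)
        elif method == "agh":
            contrib = _agh_channel(ch, fixed_effects, om, sigma, random_config,
                                   residual_model, censoring, nodes=agh_nodes)
        else:
            raise ConfigurationError("method must be 'laplace' or 'agh'")
        total += contrib
    return total


def _pooled_init(channels, free_fixed, residual_model, start: dict | None = None):
    """Naive-pooled fit (η ≡ 0): starting values for δ and σ."""
    all_series = [s for ch in channels for s in ch.series]
    init = _est._default_init(all_series, channels[0].spec, free_fixed)
    if start:
        init.update(start)
    x0 = np.log([max(init[name], 1e-300) for name in free_fixed])
    lo = x0 - math.log(1e4)
    hi = x0 + math.log(1e4)

    def objective(x):
        params = dict(zip(free_fixed, np.exp(x)))
        preds, series = [], []
        for ch in channels:
            try:
                sp = _est.update_spec(ch.spec, params, strict=False)
            except BiofilmkinError:
                return _est.PENALTY_OBJECTIVE
            for s in ch.series:
                try:
                    yhat = _est.predict(sp, s.times, s.compartment, fast=ch.fast,
                                        _predictor=ch.predictors.get(id(s)))
                except (BiofilmkinError, ValueError, FloatingPointError):
                    return _est.PENALTY_OBJECTIVE
                if not np.all(np.isfinite(yhat)):
                    return _est.PENALTY_OBJECTIVE
                preds.append(yhat)
                series.append(s)
        obj, _ = _est._profiled_neg2ll(series, preds, residual_model)
        return obj

    res = minimize(objective, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
    params = dict(zip(free_fixed, np.exp(res.x)))
    # recover the profiled sigma
    preds, series = [], []
    for ch in channels:
        sp = _est.update_spec(ch.spec, params, strict=False)
        for s in ch.series:
            preds.append(_est.predict(sp, s.times, s.compartment, fast=ch.fast,
                                      _predictor=ch.predictors.get(id(s))))
            series.append(s)
    _, sigma = _est._profiled_neg2ll(series, preds, residual_model)
    return params, float(sigma), {"objective": float(res.fun), "success": bool(res.success)}


def fit_mixed_effects(
    dataset,
    specs,
    free_fixed,
    random_config,
    residual_model: str = "additive",
    censoring: str = "none",
    init: dict | None = None,
    init_omega: float = 0.25,
    seed: int | None = None,
    maxiter: int = 1000,
    outer_method: str = "nelder-mead",
    fast: bool = True,
) -> PopulationFit:
    """Fit the hierarchical model by Laplace-approximate maximum likelihood.

    Parameters
    ----------
    dataset:
        List of :class:`~biofilmkin.estimation.SeriesData` (≥ 3 channels).
    specs:
        ModelSpec, or mapping (experiment, channel) → ModelSpec when channels
        received different dosing arms.
    free_fixed:
        Names of the fixed-effect parameters to estimate.
    random_config:
        Subset of ``free_fixed`` carrying lognormal inter-channel random
        effects (diagonal Ω).  One level of random effects (channel) is used;
        experiment-level effects can be emulated by treating experiments as
        channels.
    init, init_omega:
        Optional starting fixed effects; starting ω for every random effect.
        When ``init`` is omitted a naive-pooled fit supplies δ and σ starts.

    Notes
    -----
    If Ω collapses toward zero the objective reduces continuously to the
    pooled likelihood (ω is bounded below at 1e-3), so the fit degrades
    gracefully rather than failing.  Channels whose inner optimisation does
    not converge at the final estimates are listed in
    ``convergence["flagged_channels"]``.
    """
    free_fixed = tuple(free_fixed)
    random_config = tuple(random_config)
    if not random_config:
        raise ConfigurationError("random_config must name at least one parameter")
    if not set(random_config) <= set(free_fixed):
        raise ConfigurationError("random_config must be a subset of free_fixed")
    channels = _build_channels(dataset, specs, fast=fast)
    if len(channels) < 3:
        raise FitError("mixed-effects fitting requires at least 3 channels")

    start = None
    if init is not None:
        start = {k: float(init[k]) for k in free_fixed}
    delta0, sigma0, pooled_info = _pooled_init(channels, free_fixed, residual_model,
                                               start=start)

    n_f, n_r = len(free_fixed), len(random_config)
    z0 = np.concatenate(
        [
            np.log([max(delta0[k], 1e-300) for k in free_fixed]),
            np.full(n_r, math.log(init_omega)),
            [math.log(max(sigma0, 1e-12))],
        ]
    )
    lo = np.concatenate([z0[:n_f] - math.log(1e3), np.full(n_r, math.log(1e-3)),
                         [z0[-1] - math.log(1e2)]])
    hi = np.concatenate([z0[:n_f] + math.log(1e3), np.full(n_r, math.log(3.0)),
                         [z0[-1] + math.log(1e2)]])

    eta_cache: dict = {ch.key: np.zeros(n_r) for ch in channels}

    def unpack(z):
        delta = dict(zip(free_fixed, np.exp(z[:n_f])))
        om = np.exp(z[n_f:n_f + n_r])
        sigma = math.exp(z[-1])
        return delta, om, sigma

    def outer(z):
        delta, om, sigma = unpack(z)
        total = 0.0
        for ch in channels:
            contrib, eta_hat, _, _ = _laplace_channel(
                ch, delta, om, sigma, random_config, residual_model,
                censoring, eta0=eta_cache[ch.key],
            )
            if not np.isfinite(contrib) or contrib >= _est.PENALTY_OBJECTIVE:
                return _est.PENALTY_OBJECTIVE
            eta_cache[ch.key] = eta_hat
            total += contrib
        return total

    if outer_method == "nelder-mead":
        res = minimize(
            outer, z0, method="Nelder-Mead", bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter, "maxfev": 2 * maxiter,
                     "fatol": 5e-3, "xatol": 1e-4, "adaptive": True},
        )
    elif outer_method == "lbfgsb":
        # the inner problems are re-solved to tight tolerance, so the outer
        # surface is smooth enough for coarse finite-difference gradients
        res = minimize(
            outer, z0, method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter, "eps": 1e-3, "ftol": 1e-9, "gtol": 1e-6},
        )
    else:
        raise ConfigurationError("outer_method must be 'nelder-mead' or 'lbfgsb'")
    delta_hat, om_hat, sigma_hat = unpack(res.x)

    eb: dict = {}
    flagged: list = []
    objective = 0.0
    for ch in channels:
        contrib, eta_hat, _, ok = _laplace_channel(
            ch, delta_hat, om_hat, sigma_hat, random_config, residual_model,
            censoring, eta0=eta_cache[ch.key],
        )
        objective += contrib
        if not ok:
            flagged.append(ch.key)
        params = dict(delta_hat)
        for r, name in enumerate(random_config):
            params[name] = delta_hat[name] * math.exp(eta_hat[r])
        eb[ch.key] = {"eta": dict(zip(random_config, eta_hat)), "params": params}
    if flagged:
        warnings.warn(
            f"inner optimisation did not converge for channels {flagged}",
            stacklevel=2,
        )

    omega = dict(zip(random_config, (float(o) for o in om_hat)))
    return PopulationFit(
        fixed_effects=delta_hat,
        omega=omega,
        cv_percent={k: omega_to_cv(v) for k, v in omega.items()},
        sigma=float(sigma_hat),
        eb_estimates=eb,
        objective=float(objective),
        method="laplace",
        convergence={
            "pooled": pooled_info,
            "outer": {"nit": int(res.nit), "nfev": int(res.nfev),
                      "success": bool(res.success), "message": str(res.message)},
            "flagged_channels": flagged,
        },
        seed=seed,
        specs=specs,
        free_fixed=free_fixed,
        random_config=random_config,
        residual_model=residual_model,
        censoring=censoring,
    )


def empirical_bayes(popfit: PopulationFit, series) -> dict:
    """Per-channel empirical-Bayes parameters and predictions.

    Maximises channel likelihood × lognormal prior over η at the population
    estimates.  An empty series returns the prior mode η = 0 (population-
    typical parameters) with ``flag="empty_series"``.
    """
    random_config = popfit.random_config
    om = np.array([popfit.omega[name] for name in random_config])
    if series is None:
        series_list = []
    else:
        series_list = _est._as_series_list(series) if not isinstance(series, list) else series
    n_obs = sum(len(s.values) for s in series_list)
    if n_obs == 0:
        params = dict(popfit.fixed_effects)
        return {
            "eta": {name: 0.0 for name in random_config},
            "params": params,
            "predictions": np.array([]),
            "flag": "empty_series",
        }
    key = series_list[0].key
    spec = _est.spec_for(popfit.specs, key)
    ch = _Channel(key, series_list, spec)
    fun = lambda eta: _joint_neg2ll(ch, popfit.fixed_effects, eta, om,
                                    popfit.sigma, random_config,
                                    popfit.residual_model, popfit.censoring)
    res = minimize(fun, np.zeros(len(random_config)), method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 200})
    eta_hat = res.x
    params = dict(popfit.fixed_effects)
    for r, name in enumerate(random_config):
        params[name] = popfit.fixed_effects[name] * math.exp(eta_hat[r])
    sp = _est.update_spec(spec, params, strict=False)
    preds = np.concatenate(
        [_est.predict(sp, s.times, s.compartment) for s in series_list]
    )
    return {
        "eta": dict(zip(random_config, eta_hat)),
        "params": params,
        "predictions": preds,
        "flag": None,
    }


def population_weighted_residuals(popfit: PopulationFit, data) -> np.ndarray:
    """Weighted residuals against empirical-Bayes individual predictions."""
    if data is None:
        raise ConfigurationError("population weighted residuals require the data")
    groups = _est.group_channels(data)
    out = []
    for key, series in sorted(groups.items()):
        eb = empirical_bayes(popfit, series)
        preds = eb["predictions"]
        obs = np.concatenate([s.values for s in series])
        r = obs - preds
        if popfit.residual_model == "additive":
            out.append(r / popfit.sigma)
        else:
            scale = popfit.sigma * preds
            bad = scale == 0
            if np.any(bad):
                warnings.warn("zero predictions flagged in proportional weighting",
                              stacklevel=2)
            out.append(np.where(bad, np.nan, r / np.where(bad, 1.0, scale)))
    return np.concatenate(out)
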