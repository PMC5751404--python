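"""Likelihoods, single-series fits, model selection, two-stage analysis."""

import math

import numpy as np
import pytest

from biofilmkin import (
    AgentParams,
    ConfigurationError,
    FitError,
    GrowthParams,
    ModelSpec,
    SeriesData,
    fit_single,
    fit_two_stage,
    model_selection,
    negloglik,
    predict,
    solve_growth_analytic,
    update_spec,
    weighted_residuals,
)
from biofilmkin.agent_kinetics import mem_bolus, tob_bolus
from biofilmkin.agent_models import TwoAgentParams

LOGISTIC = GrowthParams(family="logistic", B0=0.001, kb=6.0, Bmax=1.0)


def make_series(times, values, **kw):
    base = dict(experiment_id="E1", channel_id="C1", variable="biomass",
                compartment="live", unit="au")
    base.update(kw)
    return SeriesData(times=np.asarray(times, float),
                      values=np.asarray(values, float), **base)


def noisy_logistic_series(seed, n=20, sigma=0.02, t_end=2.0):
    t = np.linspace(0.0, t_end, n)
    rng = np.random.default_rng(seed)
    clean = solve_growth_analytic(LOGISTIC, t)
    return make_series(t, clean + rng.normal(0, sigma, n))


class TestSeriesData:
    def test_times_must_increase(self):
        with pytest.raises(ConfigurationError):
            make_series([0.0, 1.0, 1.0], [1, 2, 3])

    def test_values_must_be_finite(self):
        with pytest.raises(ConfigurationError):
            make_series([0.0, 1.0], [1.0, np.nan])


class TestUpdateSpec:
    def test_growth_and_agent_aliases(self):
        eff = TwoAgentParams(model="linear_interaction", theta1=0.1, theta2=0.1,
                             theta3=0.1)
        spec = ModelSpec(growth=LOGISTIC, agent_effect=eff,
                         pk=(mem_bolus((1.0,)), tob_bolus((1.0,))))
        new = update_spec(spec, {"kb": 2.0, "k1": 0.5, "k12": 0.25})
        assert new.growth.kb == 2.0
        assert new.agent_effect.theta1 == 0.5
        assert new.agent_effect.theta3 == 0.25

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            update_spec(ModelSpec(growth=LOGISTIC), {"kc": 1.0})


class TestNegloglik:
    def test_zero_residuals_leave_only_normalising_term(self):
        t = np.linspace(0.0, 2.0, 10)
        s = make_series(t, solve_growth_analytic(LOGISTIC, t))
        sigma = 0.3
        expected = 10 * math.log(2 * math.pi * sigma**2)
        assert negloglik(s, ModelSpec(growth=LOGISTIC), sigma=sigma) == pytest.approx(
            expected, rel=1e-9)

    def test_matches_per_point_gaussian_density_sum(self):
        # independent oracle: sum of log N(y | pred, σ²) point by point
        from scipy.stats import norm

        t = np.array([0.0, 0.3, 0.8, 1.2, 1.9])
        y = np.array([0.01, 0.1, 0.4, 0.9, 1.05])
        s = make_series(t, y)
        sigma = 0.21
        pred = solve_growth_analytic(LOGISTIC, t)
        oracle = -2.0 * norm.logpdf(y, loc=pred, scale=sigma).sum()
        assert negloglik(s, ModelSpec(growth=LOGISTIC), sigma=sigma) == pytest.approx(
            oracle, rel=1e-12)

    def test_sse_term_scales_inverse_sigma_squared(self):
        t = np.linspace(0.0, 2.0, 8)
        s = make_series(t, solve_growth_analytic(LOGISTIC, t) + 0.1)
        spec = ModelSpec(growth=LOGISTIC)
        n = len(t)

        def sse_term(sig):
            return negloglik(s, spec, sigma=sig) - n * math.log(2 * math.pi * sig**2)

        assert sse_term(0.1) == pytest.approx(4.0 * sse_term(0.2), rel=1e-9)

    def test_unsimulable_parameters_give_finite_penalty(self):
        s = noisy_logistic_series(0)
        # lam >= delta is an invalid Bertalanffy configuration
        bert = ModelSpec(growth=GrowthParams(family="bertalanffy", B0=0.01, kb=1.0,
                                             kd=0.5, lam=0.3, delta=1.0))
        val = negloglik(s, bert, params={"lam": 2.0}, sigma=0.1)
        assert np.isfinite(val) and val >= 1e9

    def test_censored_contribution_uses_normal_cdf(self):
        from scipy.stats import norm

        t = np.array([0.0, 1.0, 2.0])
        pred = solve_growth_analytic(LOGISTIC, t)
        y = np.array([0.0, pred[1] + 0.05, pred[2]])
        s = make_series(t, y)
        sigma = 0.1
        got = negloglik(s, ModelSpec(growth=LOGISTIC), sigma=sigma,
                        censoring="left_zero")
        expected = (-2 * norm.logcdf(-pred[0] / sigma)
                    - 2 * norm.logpdf(y[1], pred[1], sigma)
                    - 2 * norm.logpdf(y[2], pred[2], sigma))
        assert got == pytest.approx(expected, rel=1e-9)


class TestFitSingle:
    def test_noise_free_recovery(self):
        t = np.linspace(0.0, 2.0, 20)
        s = make_series(t, solve_growth_analytic(LOGISTIC, t))
        fit = fit_single(s, ModelSpec(growth=LOGISTIC), seed=0, multistart=4)
        assert fit.estimates["B0"] == pytest.approx(0.001, rel=1e-4)
        assert fit.estimates["kb"] == pytest.approx(6.0, rel=1e-4)
        assert fit.estimates["Bmax"] == pytest.approx(1.0, rel=1e-4)

    def test_deterministic_given_seed(self):
        s = noisy_logistic_series(5, sigma=0.1)
        f1 = fit_single(s, ModelSpec(growth=LOGISTIC), seed=11, compute_se=False)
        f2 = fit_single(s, ModelSpec(growth=LOGISTIC), seed=11, compute_se=False)
        assert f1.estimates == f2.estimates

    def test_aic_and_hq_definitions(self):
        s = noisy_logistic_series(2, sigma=0.05)
        fit = fit_single(s, ModelSpec(growth=LOGISTIC), seed=0, compute_se=False)
        p, n = fit.n_params, fit.n_obs
        assert fit.aic == pytest.approx(fit.objective + 2 * p)
        assert fit.hq == pytest.approx(fit.objective + 2 * p * math.log(math.log(n)))
        assert fit.hq_as_printed == pytest.approx(fit.objective + 2 * p * math.log(n))

    def test_standard_errors_reported(self):
        s = noisy_logistic_series(3, n=40, sigma=0.02)
        fit = fit_single(s, ModelSpec(growth=LOGISTIC), seed=0)
        for name in ("kb", "Bmax"):
            assert np.isfinite(fit.se[name]) and fit.se[name] > 0
        # Bmax is well determined at the plateau: SE well under the estimate
        assert fit.se["Bmax"] < 0.2 * fit.estimates["Bmax"]

    def test_too_few_observations(self):
        s = make_series([0.0, 1.0], [0.1, 0.4])
        with pytest.raises(FitError):
            fit_single(s, ModelSpec(growth=LOGISTIC))


class TestModelSelection:
    def _fit(self, series, family, **kw):
        g = GrowthParams(family=family, B0=0.001, kb=6.0, Bmax=1.0)
        return fit_single(series, ModelSpec(growth=g), seed=0,
                          compute_se=False, **kw)

    def test_penalty_arithmetic(self):
        # n=100, p=4: AIC penalty 8; HQ 2·4·ln(ln 100) ≈ 12.21; 2·4·ln(100) ≈ 36.84
        n, p = 100, 4
        assert 2 * p == 8
        assert 2 * p * math.log(math.log(n)) == pytest.approx(12.2174, abs=1e-3)
        assert 2 * p * math.log(n) == pytest.approx(36.8414, abs=1e-3)

    def test_single_fit_table(self):
        s = noisy_logistic_series(1, sigma=0.05)
        table = model_selection([self._fit(s, "logistic")])
        assert len(table) == 1 and table.loc[0, "rank"] == 1

    def test_ranking_and_tie_break(self):
        s = noisy_logistic_series(1, sigma=0.05)
        fits = [self._fit(s, "logistic"), self._fit(s, "gompertz")]
        table = model_selection(fits, criterion="aic")
        assert set(table["label"]) == {"logistic", "gompertz"}
        assert list(table["rank"]) == [1, 2]
        assert table["aic"].iloc[0] <= table["aic"].iloc[1]

    def test_mismatched_data_rejected(self):
        f1 = self._fit(noisy_logistic_series(1, sigma=0.05), "logistic")
        f2 = self._fit(noisy_logistic_series(2, sigma=0.05), "gompertz")
        with pytest.raises(ConfigurationError):
            model_selection([f1, f2])


class TestTwoStage:
    def _dataset(self, n_channels=4, cv=0.2, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0.0, 2.0, 20)
        out = []
        omega = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
        for c in range(n_channels):
            bmax = 1.0 * math.exp(rng.normal(0, omega)) if cv > 0 else 1.0
            g = GrowthParams(family="logistic", B0=0.001, kb=6.0, Bmax=bmax)
            vals = solve_growth_analytic(g, t)
            if sigma > 0:
                vals = vals + rng.normal(0, sigma, len(t))
            out.append(make_series(t, vals, channel_id=f"C{c + 1}"))
        return out

    def test_identical_channels_give_zero_spread(self):
        data = self._dataset(n_channels=3, cv=0.0, sigma=0.0)
        res = fit_two_stage(data, ModelSpec(growth=LOGISTIC), seed=0,
                            multistart=2, compute_se=False)
        assert res.summary.loc["Bmax", "sd"] == pytest.approx(0.0, abs=1e-6)

    def test_recovers_generating_cv(self):
        data = self._dataset(n_channels=30, cv=0.2, sigma=0.0, seed=4)
        res = fit_two_stage(data, ModelSpec(growth=LOGISTIC), seed=0,
                            multistart=2, compute_se=False)
        assert res.summary.loc["Bmax", "cv_percent"] == pytest.approx(20.0, abs=6.0)

    def test_corrupt_channel_excluded(self):
        data = self._dataset(n_channels=4, cv=0.1, sigma=0.0, seed=1)
        # a two-point channel cannot support a 3-parameter fit
        data.append(make_series([0.0, 1.0], [0.2, 0.4], channel_id="C99"))
        res = fit_two_stage(data, ModelSpec(growth=LOGISTIC), seed=0,
                            multistart=2, compute_se=False)
        assert ("E1", "C99") in [k for k, _ in res.excluded]
        assert len(res.fits) == 4

    def test_needs_two_channels(self):
        data = self._dataset(n_channels=1)
        with pytest.raises(FitError):
            fit_two_stage(data, ModelSpec(growth=LOGISTIC))


class TestWeightedResiduals:
    def test_perfect_predictions_are_zero(self):
        t = np.linspace(0.0, 2.0, 10)
        s = make_series(t, solve_growth_analytic(LOGISTIC, t))
        fit = fit_single(s, ModelSpec(growth=LOGISTIC), seed=0, compute_se=False)
        assert np.max(np.abs(fit.residuals)) < 1e-6
        # at a fixed scale the weighted residuals are zero too
        np.testing.assert_allclose(weighted_residuals(fit) * fit.estimates["sigma"],
                                   fit.residuals, atol=1e-12)

    def test_standard_normal_under_generating_model(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 2.0, 200)
        sigma = 0.05
        clean = solve_growth_analytic(LOGISTIC, t)
        s = make_series(t, clean + rng.normal(0, sigma, len(t)))
        fit = fit_single(s, ModelSpec(growth=LOGISTIC), seed=0, compute_se=False)
        wr = weighted_residuals(fit)
        n = len(wr)
        assert abs(np.mean(wr)) < 3.0 / math.sqrt(n)
        assert 0.8 < np.std(wr) < 1.2

    def test_invariant_to_joint_unit_rescaling(self):
        t = np.linspace(0.0, 2.0, 15)
        rng = np.random.default_rng(3)
        vals = solve_growth_analytic(LOGISTIC, t) + rng.normal(0, 0.05, len(t))
        s1 = make_series(t, vals)
        s1000 = make_series(t, 1000.0 * vals)
        f1 = fit_single(s1, ModelSpec(growth=LOGISTIC), seed=0, compute_se=False)
        g1000 = GrowthParams(family="logistic", B0=1.0, kb=6.0, Bmax=1000.0)
        f2 = fit_single(s1000, ModelSpec(growth=g1000), seed=0, compute_se=False)
        np.testing.assert_allclose(weighted_residuals(f1), weighted_residuals(f2),
                                   atol=2e-3)


class TestFastPredictor:
    def test_bernoulli_path_matches_ode(self):
        # logistic + two-drug linear kill is a Bernoulli ODE; the quadrature
        # fast path must agree with adaptive integration
        eff = TwoAgentParams(model="linear_interaction", theta1=0.00301,
                             theta2=0.00352, theta3=0.000473)
        g = GrowthParams(family="logistic", B0=1.0, kb=0.0425, Bmax=39.5)
        spec = ModelSpec(growth=g, agent_effect=eff,
                         pk=(mem_bolus((24.0,)), tob_bolus((24.0,))))
        t = np.arange(0.0, 169.0, 12.0)
        fast = predict(spec, t, fast=True)
        slow = predict(spec, t, fast=False, rtol=1e-9, atol=1e-11)
        np.testing.assert_allclose(fast, slow, rtol=2e-3)

    def test_single_agent_threshold_uses_general_path(self):
        eff = AgentParams(model="threshold", theta1=0.01, theta2=20.0)
        g = GrowthParams(family="logistic", B0=1.0, kb=0.05, Bmax=40.0)
        spec = ModelSpec(growth=g, agent_effect=eff, pk=(mem_bolus((24.0,)),))
        t = np.arange(0.0, 73.0, 12.0)
        out = predict(spec, t)
        assert np.all(np.isfinite(out)) and np.all(out >= 0)
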