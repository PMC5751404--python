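"""Full state system: live/dead/endogenous dynamics under dosing."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from biofilmkin import (
    AgentParams,
    ConfigurationError,
    GrowthParams,
    ModelSpec,
    PostPlateau,
    TwoAgentParams,
    bic_concentration,
    conservation_check,
    rhs,
    simulate_trajectory,
    solve_growth_analytic,
)
from biofilmkin.agent_kinetics import PKProfile, mem_bolus, tob_bolus

FIG1_LOGISTIC = GrowthParams(family="logistic", B0=0.001, kb=6.0, Bmax=1.0)


def constant_profile(value, t_end=10.0, name="const"):
    # a flat "measured" profile: holds the agent at a fixed level
    return PKProfile(agent_name=name, mode="interpolated",
                     points=((0.0, value), (t_end, value)))


class TestSpecValidation:
    def test_two_agent_requires_two_profiles(self):
        eff = TwoAgentParams(model="additive_linear", theta1=0.1, theta2=0.1)
        with pytest.raises(ConfigurationError):
            ModelSpec(growth=FIG1_LOGISTIC, agent_effect=eff, pk=(mem_bolus((1.0,)),))

    def test_gompertz_difference_requires_gompertz(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(growth=FIG1_LOGISTIC, dead_model="gompertz_difference")

    def test_rate_coupled_rejects_gompertz(self):
        g = GrowthParams(family="gompertz", B0=0.001, kb=6.0, Bmax=1.0)
        with pytest.raises(ConfigurationError):
            ModelSpec(growth=g, dead_model="rate_coupled")

    def test_turnover_requires_rates(self):
        with pytest.raises(ConfigurationError):
            PostPlateau(variant="turnover", kl=0.1)


class TestRhs:
    def test_logistic_dead_rate_without_agent(self):
        spec = ModelSpec(growth=FIG1_LOGISTIC, dead_model="rate_coupled")
        B = 0.3
        dB, dD, dX = rhs(spec, 0.5, (B, 0.0, 1.0))
        assert dD == pytest.approx(6.0 * B**2 / 1.0)
        assert dB == pytest.approx(6.0 * B * (1 - B))

    def test_extinction_is_absorbing(self):
        eff = AgentParams(model="linear", theta1=1.0)
        spec = ModelSpec(growth=FIG1_LOGISTIC, agent_effect=eff,
                         pk=(constant_profile(5.0),), dead_model="rate_coupled")
        dB, dD, _ = rhs(spec, 1.0, (0.0, 0.2, 1.0))
        assert dB == 0.0 and dD == 0.0

    def test_depletion_with_zero_kl_is_plain_growth(self):
        spec = ModelSpec(growth=FIG1_LOGISTIC,
                         post_plateau=PostPlateau(variant="depletion", kl=0.0))
        t = np.linspace(0.0, 2.0, 41)
        traj = simulate_trajectory(spec, t)
        np.testing.assert_allclose(traj.X, 1.0, atol=1e-9)
        np.testing.assert_allclose(traj.B, solve_growth_analytic(FIG1_LOGISTIC, t),
                                   rtol=1e-6)


class TestSimulate:
    def test_matches_closed_form_without_agent(self):
        t = np.linspace(0.0, 2.0, 41)
        for fam in ("exponential", "logistic", "gompertz"):
            kw = dict(B0=0.001, kb=6.0)
            if fam != "exponential":
                kw["Bmax"] = 1.0
            g = GrowthParams(family=fam, **kw)
            traj = simulate_trajectory(ModelSpec(growth=g), t)
            np.testing.assert_allclose(traj.B, solve_growth_analytic(g, t),
                                       rtol=1e-6)

    def test_holding_concentration_at_bic_freezes_growth(self):
        B_star = 0.37
        theta1 = 1.0
        bic = bic_concentration(FIG1_LOGISTIC, B_star, theta1)
        g = GrowthParams(family="logistic", B0=B_star, kb=6.0, Bmax=1.0)
        spec = ModelSpec(growth=g, agent_effect=AgentParams(model="linear", theta1=theta1),
                         pk=(constant_profile(bic),))
        traj = simulate_trajectory(spec, np.linspace(0.0, 5.0, 51))
        np.testing.assert_allclose(traj.B, B_star, rtol=1e-6)

    def test_depletion_drives_biofilm_to_zero(self):
        spec = ModelSpec(growth=FIG1_LOGISTIC,
                         post_plateau=PostPlateau(variant="depletion", kl=1.5))
        t = np.linspace(0.0, 30.0, 301)
        traj = simulate_trajectory(spec, t)
        peak = traj.B.max()
        assert peak > 0.5  # rises first
        assert traj.B[-1] < 0.01 * peak  # then declines toward zero
        assert traj.X[-1] < 0  # endogenous variable ends negative

    def test_turnover_steady_state(self):
        # dB/dt = 0 needs X = 0, which forces B* = kp/kl
        pp = PostPlateau(variant="turnover", kl=2.0, kp=1.0, kq=0.5)
        spec = ModelSpec(growth=FIG1_LOGISTIC, post_plateau=pp)
        t = np.linspace(0.0, 400.0, 401)
        traj = simulate_trajectory(spec, t)
        assert traj.B[-1] == pytest.approx(pp.kp / pp.kl, rel=1e-3)

    def test_depletion_quadrature_identity(self):
        # X(t) = 1 − kl·∫₀ᵗ B ds
        kl = 1.5
        spec = ModelSpec(growth=FIG1_LOGISTIC,
                         post_plateau=PostPlateau(variant="depletion", kl=kl))
        t = np.linspace(0.0, 10.0, 2001)
        traj = simulate_trajectory(spec, t)
        integral = cumulative_trapezoid(traj.B, t, initial=0.0)
        np.testing.assert_allclose(traj.X, 1.0 - kl * integral, atol=5e-5)

    def test_dormancy_lag_shift(self):
        lag = 0.5
        g = GrowthParams(family="logistic", B0=0.001, kb=6.0, Bmax=1.0, t_lag=lag)
        t = np.linspace(0.0, 2.0, 41)
        traj = simulate_trajectory(ModelSpec(growth=g), t)
        pre = t < lag
        np.testing.assert_allclose(traj.B[pre], 0.001, rtol=1e-9)
        ref = simulate_trajectory(ModelSpec(growth=FIG1_LOGISTIC), t)
        shifted = np.interp(t[~pre] - lag, t, ref.B)
        np.testing.assert_allclose(traj.B[~pre], shifted, rtol=1e-5)

    def test_dead_monotone_under_inhibition(self):
        eff = TwoAgentParams(model="linear_interaction", theta1=0.00301,
                             theta2=0.00352, theta3=0.000473)
        g = GrowthParams(family="logistic", B0=1.0, kb=0.0425, Bmax=39.5)
        spec = ModelSpec(growth=g, agent_effect=eff,
                         pk=(mem_bolus((24.0,)), tob_bolus((24.0,))),
                         dead_model="rate_coupled")
        traj = simulate_trajectory(spec, np.linspace(0.0, 72.0, 289))
        assert np.all(np.diff(traj.D) >= -1e-12)
        assert np.all(traj.B >= 0)

    def test_stimulation_adds_growth_and_no_dead(self):
        eff = AgentParams(model="linear", theta1=0.5)
        spec = ModelSpec(growth=FIG1_LOGISTIC, agent_effect=eff,
                         effect_sign="stimulate", pk=(constant_profile(1.0),),
                         dead_model="rate_coupled")
        t = np.linspace(0.0, 1.0, 41)
        traj = simulate_trajectory(spec, t)
        plain = simulate_trajectory(ModelSpec(growth=FIG1_LOGISTIC), t)
        assert np.all(traj.B[1:] >= plain.B[1:])
        # stimulated biomass is live: only intrinsic turnover feeds D
        spec_nostim = ModelSpec(growth=FIG1_LOGISTIC, dead_model="rate_coupled")
        plain_dead = simulate_trajectory(spec_nostim, t)
        assert traj.D[-1] > 0
        assert traj.D[-1] < 10 * plain_dead.D[-1]

    def test_gompertz_difference_dead_path(self):
        g = GrowthParams(family="gompertz", B0=0.001, kb=6.0, Bmax=1.0)
        t = np.linspace(0.0, 1.0, 21)
        traj = simulate_trajectory(ModelSpec(growth=g, dead_model="gompertz_difference"), t)
        np.testing.assert_allclose(traj.D, 0.001 * np.exp(6.0 * t) - traj.B,
                                   rtol=1e-8, atol=1e-12)

    def test_threshold_crossing_is_a_breakpoint(self):
        # a threshold agent switches off exactly when C(t) falls to θ2
        eff = AgentParams(model="threshold", theta1=0.05, theta2=50.0)
        g = GrowthParams(family="logistic", B0=0.5, kb=0.1, Bmax=2.0)
        spec = ModelSpec(growth=g, agent_effect=eff, pk=(mem_bolus((1.0,)),))
        from biofilmkin.dynamics import solver_breakpoints

        bps = solver_breakpoints(spec, 10.0)
        k = np.log(2) / 0.893
        t_cross = 1.0 + np.log(107.53 / 50.0) / k
        assert np.any(np.isclose(bps, t_cross, atol=1e-8))
        traj = simulate_trajectory(spec, np.linspace(0.0, 10.0, 201))
        assert np.all(np.isfinite(traj.B))

    def test_grid_must_start_at_zero(self):
        with pytest.raises(ConfigurationError):
            simulate_trajectory(ModelSpec(growth=FIG1_LOGISTIC), [1.0, 2.0])

    def test_dose_beyond_horizon_rejected(self):
        spec = ModelSpec(growth=FIG1_LOGISTIC,
                         agent_effect=AgentParams(model="linear", theta1=0.1),
                         pk=(mem_bolus((24.0,)),))
        with pytest.raises(ConfigurationError):
            simulate_trajectory(spec, np.linspace(0.0, 10.0, 11))


class TestConservation:
    def test_no_agent_defect_small(self):
        spec = ModelSpec(growth=FIG1_LOGISTIC, dead_model="rate_coupled")
        t = np.linspace(0.0, 2.0, 2001)
        traj = simulate_trajectory(spec, t)
        defect = conservation_check(traj, spec)
        assert defect < 1e-5 * np.max(6.0 * traj.B)

    def test_mem_dosed_defect_small(self):
        g = GrowthParams(family="logistic", B0=1.0, kb=0.0425, Bmax=39.5)
        eff = AgentParams(model="linear", theta1=0.00301)
        spec = ModelSpec(growth=g, agent_effect=eff, pk=(mem_bolus((24.0,)),),
                         dead_model="rate_coupled")
        t = np.linspace(0.0, 48.0, 4001)
        traj = simulate_trajectory(spec, t)
        defect = conservation_check(traj, spec)
        assert defect < 1e-5 * np.max(g.kb * traj.B)

    def test_wrong_family_rejected(self):
        spec = ModelSpec(growth=FIG1_LOGISTIC)
        traj = simulate_trajectory(spec, np.linspace(0.0, 1.0, 11))
        with pytest.raises(ConfigurationError):
            conservation_check(traj, spec)

    def test_trajectory_tidy_export(self):
        spec = ModelSpec(growth=FIG1_LOGISTIC)
        traj = simulate_trajectory(spec, np.linspace(0.0, 1.0, 5))
        df = traj.to_frame()
        assert list(df.columns) == ["time_h", "variable", "value"]
        assert set(df["variable"]) == {"live", "dead", "X"}
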