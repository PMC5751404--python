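"""Assembly and integration of the full biofilm state system.

The live biofilm B(t) evolves as

    dB/dt = g(B)·X_factor ∓ h(C(t), B),    B(0) = B0,

where g is a growth law (:mod:`biofilmkin.growth_models`), h an agent-effect
model (:mod:`biofilmkin.agent_models`) driven by one or two concentration
profiles C(t) (:mod:`biofilmkin.agent_kinetics`), and the sign is − for
inhibitory and + for stimulatory agents.  Optional companion states:

* dead biofilm D(t): for logistic growth dD/dt = kb·B²/Bmax + h, for the
  Bertalanffy law dD/dt = kd·B^δ + h (killed biomass feeds the dead channel
  for inhibitory agents; stimulation creates live cells and contributes
  nothing to D).  For Gompertz growth there is no rate form; the dead signal
  is defined post hoc as the shortfall from unconstrained exponential
  growth, D(t) = B0·e^{kb·t} − B(t), which can transiently be negative at
  early times (the Gompertz specific growth rate initially exceeds kb) and
  is reported as computed.
* a post-plateau endogenous variable X(t) multiplying the growth rate:
  depletion variant dX/dt = −kl·B with X(0)=1 (the biofilm then declines to
  zero), or turnover variant dX/dt = kp − kq·X − kl·B with X(0)=kp/kq, whose
  nonzero steady state is B* = kp/kl.
* dormancy: the growth term is zero for t < t_lag.

Integration is adaptive (stiff-capable LSODA by default) and restarted at
every dose time, infusion stop and threshold-crossing so that concentration
discontinuities are never smeared across a step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .agent_kinetics import PKProfile, concentration
from .agent_models import AgentParams, TwoAgentParams, effect_single, effect_two_agent
from .errors import ConfigurationError, SolverError
from .growth_models import GrowthParams, growth_rate

DEAD_MODELS = ("none", "rate_coupled", "gompertz_difference")
EFFECT_SIGNS = ("inhibit", "stimulate")
POST_PLATEAU_VARIANTS = ("depletion", "turnover")


@dataclass(frozen=True)
class PostPlateau:
    """Endogenous-variable model for post-plateau biofilm decline."""

    variant: str
    kl: float
    kp: float | None = None
    kq: float | None = None

    def __post_init__(self):
        if self.variant not in POST_PLATEAU_VARIANTS:
            raise ConfigurationError(f"unknown post-plateau variant {self.variant!r}")
        if self.kl < 0:
            raise ConfigurationError("kl must be >= 0")
        if self.variant == "turnover":
            if self.kp is None or self.kp <= 0 or self.kq is None or self.kq <= 0:
                raise ConfigurationError("turnover variant requires kp, kq > 0")

    @property
    def x0(self) -> float:
        return 1.0 if self.variant == "depletion" else self.kp / self.kq


@dataclass(frozen=True)
class ModelSpec:
    """A complete model: growth law, agent effect, PK, companion states."""

    growth: GrowthParams
    agent_effect: AgentParams | TwoAgentParams | None = None
    effect_sign: str = "inhibit"
    pk: tuple[PKProfile, ...] = ()
    dead_model: str = "none"
    post_plateau: PostPlateau | None = None

    def __post_init__(self):
        object.__setattr__(self, "pk", tuple(self.pk))
        if self.effect_sign not in EFFECT_SIGNS:
            raise ConfigurationError(f"effect_sign must be one of {EFFECT_SIGNS}")
        if self.dead_model not in DEAD_MODELS:
            raise ConfigurationError(f"unknown dead_model {self.dead_model!r}")
        if isinstance(self.agent_effect, TwoAgentParams):
            if len(self.pk) != 2:
                raise ConfigurationError("two-agent effects require exactly two PK profiles")
        elif isinstance(self.agent_effect, AgentParams):
            if len(self.pk) != 1:
                raise ConfigurationError("single-agent effects require exactly one PK profile")
        elif self.agent_effect is not None:
            raise ConfigurationError("agent_effect must be AgentParams, TwoAgentParams or None")
        if self.dead_model == "gompertz_difference" and self.growth.family != "gompertz":
            raise ConfigurationError("gompertz_difference dead model requires gompertz growth")
        if self.dead_model == "rate_coupled" and self.growth.family not in (
            "logistic",
            "bertalanffy",
        ):
            raise ConfigurationError(
                "rate_coupled dead model requires logistic or bertalanffy growth"
            )

    def effect_rate(self, t, B):
        """Evaluate h(C(t), B) ≥ 0; 0 when no agent effect is configured."""
        if self.agent_effect is None:
            return 0.0 * np.asarray(B, dtype=float) if np.ndim(B) else 0.0
        if isinstance(self.agent_effect, TwoAgentParams):
            c1 = concentration(self.pk[0], t)
            c2 = concentration(self.pk[1], t)
            return effect_two_agent(self.agent_effect, c1, c2, B)
        c = concentration(self.pk[0], t)
        return effect_single(self.agent_effect, c, B)


@dataclass
class Trajectory:
    """Simulated state paths on a time grid."""

    times: np.ndarray
    B: np.ndarray
    D: np.ndarray
    X: np.ndarray
    C: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns time_h, variable, value (deterministic order)."""
        frames = [
            pd.DataFrame({"time_h": self.times, "variable": "live", "value": self.B}),
            pd.DataFrame({"time_h": self.times, "variable": "dead", "value": self.D}),
            pd.DataFrame({"time_h": self.times, "variable": "X", "value": self.X}),
        ]
        for name in sorted(self.C):
            frames.append(
                pd.DataFrame(
                    {"time_h": self.times, "variable": f"conc:{name}", "value": self.C[name]}
                )
            )
        return pd.concat(frames, ignore_index=True)


def rhs(spec: ModelSpec, t: float, state) -> np.ndarray:
    """Right-hand side of the full system at time t, state = (B, D, X).

    Extinction is absorbing: at B = 0 every derivative involving B is 0.
    Inactive companion states keep zero derivatives.
    """
    B, D, X = (float(s) for s in state)
    if not np.isfinite([B, D, X]).all():
        raise ValueError("non-finite state")
    g = spec.growth
    Bc = max(B, 0.0)
    lagged = t < g.t_lag
    grate = 0.0 if lagged else float(growth_rate(g, Bc))
    x_factor = X if spec.post_plateau is not None else 1.0
    h = float(spec.effect_rate(t, Bc))
    if spec.effect_sign == "inhibit":
        dB = grate * x_factor - h
        h_dead = h
    else:
        dB = grate * x_factor + h
        h_dead = 0.0
    dD = 0.0
    if spec.dead_model == "rate_coupled":
        if spec.growth.family == "logistic":
            dD = (0.0 if lagged else g.kb * Bc * Bc / g.Bmax) + h_dead
        else:  # bertalanffy
            dD = (0.0 if lagged else g.kd * Bc**g.delta) + h_dead
    dX = 0.0
    pp = spec.post_plateau
    if pp is not None:
        if pp.variant == "depletion":
            dX = -pp.kl * Bc
        else:
            dX = pp.kp - pp.kq * X - pp.kl * Bc
    return np.array([dB, dD, dX])


def _threshold_crossings(spec: ModelSpec, t_end: float, base_bps: np.ndarray) -> list[float]:
    """Times where C(t) crosses the threshold θ2 of a (non-smooth) threshold model."""
    eff = spec.agent_effect
    if not (isinstance(eff, AgentParams) and eff.model == "threshold" and not eff.smooth):
        return []
    prof = spec.pk[0]
    theta2 = eff.theta2
    knots = np.unique(np.concatenate([[0.0, t_end], base_bps]))
    knots = knots[(knots >= 0) & (knots <= t_end)]
    out = []
    f = lambda t: concentration(prof, t) - theta2
    eps = 1e-9
    for a, b in zip(knots[:-1], knots[1:]):
        fa, fb = f(a + eps), f(b - eps if b > a + 2 * eps else b)
        if fa == 0.0:
            out.append(a)
        if fa * fb < 0:
            out.append(float(brentq(f, a + eps, b, xtol=1e-12)))
    return out


def solver_breakpoints(spec: ModelSpec, t_end: float) -> np.ndarray:
    """Mandatory integration restart times within (0, t_end)."""
    bps = [np.asarray([], dtype=float)]
    for prof in spec.pk:
        bps.append(prof.breakpoints())
    if spec.growth.t_lag > 0:
        bps.append(np.asarray([spec.growth.t_lag]))
    base = np.unique(np.concatenate(bps)) if bps else np.asarray([])
    cross = _threshold_crossings(spec, t_end, base)
    allbp = np.unique(np.concatenate([base, np.asarray(cross, dtype=float)]))
    return allbp[(allbp > 0) & (allbp < t_end)]


def simulate_trajectory(
    spec: ModelSpec,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the full system and sample it on ``t_grid``.

    The grid must start at 0.  Integration restarts at every solver
    breakpoint (dose, infusion stop, threshold crossing, end of lag), so
    discontinuous forcing never degrades step control.  Small negative
    overshoots of the states (within solver tolerance) are clipped to 0;
    larger excursions raise :class:`SolverError`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ConfigurationError("t_grid must be sorted, start at 0 and have >= 2 points")
    t_end = float(t_grid[-1])
    for prof in spec.pk:
        if prof.mode != "interpolated" and any(ev.time > t_end for ev in prof.events):
            raise ConfigurationError("dose times must lie within the simulation horizon")

    x0 = spec.post_plateau.x0 if spec.post_plateau is not None else 1.0
    state = np.array([spec.growth.B0, 0.0, x0])
    seg_edges = np.unique(
        np.concatenate([[0.0, t_end], solver_breakpoints(spec, t_end)])
    )
    pos_tol = max(1e3 * atol, 1e-9)

    out_t = [0.0]
    out_y = [state.copy()]
    nfev = 0
    fun = lambda t, y: rhs(spec, t, y)
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        interior = t_grid[(t_grid > a) & (t_grid < b)]
        t_eval = np.unique(np.concatenate([interior, [b]]))
        sol = solve_ivp(
            fun, (a, b), state, method=method, rtol=rtol, atol=atol, t_eval=t_eval,
            dense_output=False,
        )
        nfev += sol.nfev
        if not sol.success:
            raise SolverError(
                f"integration failed in segment [{a}, {b}]: {sol.message}",
                last_time=float(sol.t[-1]) if len(sol.t) else a,
            )
        y = sol.y
        low = float(y[:2].min()) if y.size else 0.0  # X may legitimately go negative
        if low < -pos_tol:
            raise SolverError(
                f"state went negative beyond solver tolerance (min {low:.3e})",
                last_time=float(sol.t[int(np.argmin(y[:2].min(axis=0)))]),
            )
        y[:2] = np.maximum(y[:2], 0.0)
        out_t.extend(sol.t.tolist())
        out_y.extend(list(y.T))
        state = y[:, -1].copy()

    out_t = np.asarray(out_t)
    out_y = np.asarray(out_y)
    # sample requested grid (segment ends were integrated exactly)
    idx = np.searchsorted(out_t, t_grid)
    idx = np.clip(idx, 0, len(out_t) - 1)
    # grid points coincide with integrated times by construction
    B = out_y[idx, 0]
    D = out_y[idx, 1]
    X = out_y[idx, 2]
    if spec.dead_model == "gompertz_difference":
        D = spec.growth.B0 * np.exp(spec.growth.kb * t_grid) - B
    if spec.post_plateau is None:
        X = np.ones_like(t_grid)
    C = {prof.agent_name: np.asarray(concentration(prof, t_grid)) for prof in spec.pk}
    diag = {"nfev": int(nfev), "n_segments": len(seg_edges) - 1, "rtol": rtol, "atol": atol}
    return Trajectory(times=t_grid, B=B, D=D, X=X, C=C, diagnostics=diag)


def conservation_check(traj: Trajectory, spec: ModelSpec) -> float:
    """Maximum defect of d(B+D)/dt = kb·B for logistic rate-coupled runs.

    For logistic growth with an inhibitory agent the kill term moves biomass
    from B to D, so total accumulation obeys d(B+D)/dt = kb·B exactly; this
    checks the simulated paths against that identity by differentiating the
    cumulative path B+D with a cubic spline within each smooth segment.
    """
    if spec.growth.family != "logistic" or spec.dead_model != "rate_coupled":
        raise ConfigurationError("conservation check requires logistic rate-coupled spec")
    if spec.agent_effect is not None and spec.effect_sign != "inhibit":
        raise ConfigurationError("conservation check requires an inhibitory agent")
    from scipy.interpolate import CubicSpline

    t = traj.times
    total = traj.B + traj.D
    target = spec.growth.kb * traj.B
    edges = np.concatenate([[t[0]], solver_breakpoints(spec, t[-1]), [t[-1]]])
    defect = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        m = (t >= a) & (t <= b)
        if m.sum() < 5:
            continue
        cs = CubicSpline(t[m], total[m])
        d = cs(t[m], 1) - target[m]
        defect = max(defect, float(np.max(np.abs(d))))
    return defect
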