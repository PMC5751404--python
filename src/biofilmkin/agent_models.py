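"""Agent-effect models h(C, B): the action of antimicrobials on biofilm.

Every model returns a nonnegative rate proportional to the current biofilm
level B; whether the term inhibits (−h) or stimulates (+h) the biofilm is
decided by the dynamics layer, not here.

Single-agent models
-------------------
linear       h = θ1·C·B            (θ1 in 1/h per concentration unit)
threshold    h = θ1·C·B if C ≥ θ2 else 0
saturating   h = θ1·C/(θ2+C)·B     (Emax-type; θ1 in 1/h, θ2 = EC50)

Two-agent models
----------------
additive_linear          h = (θ1·C1 + θ2·C2)·B
linear_interaction       h = (θ1·C1 + θ2·C2 + θ3·C1·C2)·B
competitive_interaction  h = scale·(C1/C1,50 + α·C2/C2,50)
                             / (1 + C1/C1,50 + C2/C2,50)·B
competitive_antagonism   h = scale·C1 / (C1 + C1,50·(1 + C2/C2,50))·B

With α = 0 the competitive-interaction model reduces exactly to competitive
antagonism.  The saturating fractions are dimensionless; ``scale`` (1/h,
default 1) supplies the maximal kill rate, which the published forms leave
implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

SINGLE_AGENT_MODELS = ("linear", "threshold", "saturating")
TWO_AGENT_MODELS = (
    "additive_linear",
    "linear_interaction",
    "competitive_interaction",
    "competitive_antagonism",
)


@dataclass(frozen=True)
class AgentParams:
    """Parameters of a single-agent effect model.

    ``theta2`` is the threshold concentration (threshold model) or the
    half-effect concentration (saturating model).  ``smooth`` replaces the
    threshold step with a logistic sigmoid of relative width
    ``smooth_width``·θ2 — useful for gradient-based optimisers; the default
    is the exact discontinuous form (the boundary C = θ2 counts as active).
    """

    model: str
    theta1: float
    theta2: float | None = None
    smooth: bool = False
    smooth_width: float = 0.02

    def __post_init__(self):
        if self.model not in SINGLE_AGENT_MODELS:
            raise ConfigurationError(
                f"unknown agent model {self.model!r}; choose from {SINGLE_AGENT_MODELS}"
            )
        if self.theta1 < 0:
            raise ConfigurationError("theta1 must be >= 0")
        if self.model in ("threshold", "saturating"):
            if self.theta2 is None or self.theta2 <= 0:
                raise ConfigurationError(f"{self.model} requires theta2 > 0")
        elif self.theta2 is not None:
            raise ConfigurationError("linear model does not take theta2")


@dataclass(frozen=True)
class TwoAgentParams:
    """Parameters of a two-agent effect model.

    theta1/theta2/theta3 are the per-agent and interaction linear
    coefficients (the k1, k2, k12 of the population analysis); c1_50/c2_50
    and alpha parameterise the competitive saturating models.
    """

    model: str
    theta1: float | None = None
    theta2: float | None = None
    theta3: float | None = None
    c1_50: float | None = None
    c2_50: float | None = None
    alpha: float | None = None
    scale: float = 1.0

    def __post_init__(self):
        if self.model not in TWO_AGENT_MODELS:
            raise ConfigurationError(
                f"unknown two-agent model {self.model!r}; choose from {TWO_AGENT_MODELS}"
            )
        if self.model in ("additive_linear", "linear_interaction"):
            if self.theta1 is None or self.theta2 is None:
                raise ConfigurationError(f"{self.model} requires theta1 and theta2")
            if self.theta1 < 0 or self.theta2 < 0:
                raise ConfigurationError("linear coefficients must be >= 0")
            if self.model == "linear_interaction":
                if self.theta3 is None or self.theta3 < 0:
                    raise ConfigurationError("linear_interaction requires theta3 >= 0")
        else:
            if self.c1_50 is None or self.c1_50 <= 0 or self.c2_50 is None or self.c2_50 <= 0:
                raise ConfigurationError(f"{self.model} requires c1_50, c2_50 > 0")
            if self.model == "competitive_interaction":
                if self.alpha is None or self.alpha < 0:
                    raise ConfigurationError("competitive_interaction requires alpha >= 0")
            if self.scale < 0:
                raise ConfigurationError("scale must be >= 0")


def _check_nonneg(**kwargs):
    for name, v in kwargs.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"{name} must be nonnegative")


def effect_single(params: AgentParams, C, B):
    """Single-agent effect rate h(C, B) ≥ 0 (units/h). Vectorised."""
    _check_nonneg(C=C, B=B)
    C = np.asarray(C, dtype=float)
    B_arr = np.asarray(B, dtype=float)
    if params.model == "linear":
        out = params.theta1 * C * B_arr
    elif params.model == "threshold":
        if params.smooth:
            w = params.smooth_width * params.theta2
            gate = 1.0 / (1.0 + np.exp(-(C - params.theta2) / w))
        else:
            gate = (C >= params.theta2).astype(float)
        out = params.theta1 * C * B_arr * gate
    else:  # saturating
        out = params.theta1 * C / (params.theta2 + C) * B_arr
    return out if (np.ndim(C) or np.ndim(B)) else float(out)


def effect_two_agent(params: TwoAgentParams, C1, C2, B):
    """Two-agent effect rate h(C1, C2, B) ≥ 0 (units/h). Vectorised."""
    _check_nonneg(C1=C1, C2=C2, B=B)
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    B_arr = np.asarray(B, dtype=float)
    m = params.model
    if m == "additive_linear":
        out = (params.theta1 * C1 + params.theta2 * C2) * B_arr
    elif m == "linear_interaction":
        out = (params.theta1 * C1 + params.theta2 * C2 + params.theta3 * C1 * C2) * B_arr
    elif m == "competitive_interaction":
        r1 = C1 / params.c1_50
        r2 = C2 / params.c2_50
        out = params.scale * (r1 + params.alpha * r2) / (1.0 + r1 + r2) * B_arr
    else:  # competitive_antagonism
        denom = C1 + params.c1_50 * (1.0 + C2 / params.c2_50)
        out = params.scale * np.where(denom > 0, C1 / np.where(denom > 0, denom, 1.0), 0.0) * B_arr
    scalar = not (np.ndim(C1) or np.ndim(C2) or np.ndim(B))
    return float(out) if scalar else out
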