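"""Biofilm growth laws and derived kinetic quantities.

Four growth laws are supported, each describing the drug-free rate of change
g(B) of a univariate biofilm measurement B (biomass in μm³/μm², average
thickness in μm, or similar):

    exponential   g(B) = kb·B
    logistic      g(B) = kb·B·(1 − B/Bmax)
    gompertz      g(B) = kb·B·ln(Bmax/B)
    bertalanffy   g(B) = kb·B^λ − kd·B^δ,  0 < λ < δ

The exponential, logistic and Gompertz laws have closed-form solutions; the
generalised Bertalanffy law is integrated numerically (see
:mod:`biofilmkin.dynamics`).  The logistic law is the λ=1, δ=2,
kd=kb/Bmax special case of the Bertalanffy law.

Two derived quantities are provided: the (time-varying) doubling time
td(t), defined by B(t+td)=2·B(t), and the biofilm-inhibitory concentration
BIC(B), the constant concentration of a linearly acting agent that makes the
net growth rate zero at biofilm level B.  For limited growth both quantities
depend on the current biofilm level — the doubling time diverges once
B ≥ Bmax/2 and the BIC falls to zero as B approaches Bmax.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

GROWTH_FAMILIES = ("exponential", "logistic", "gompertz", "bertalanffy")

#: families with a closed-form solution B(t)
ANALYTIC_FAMILIES = ("exponential", "logistic", "gompertz")


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic parameters of one growth law.

    Parameters
    ----------
    family:
        One of ``exponential``, ``logistic``, ``gompertz``, ``bertalanffy``.
    B0:
        Initial biofilm level at t=0 (measurement units), > 0.
    kb:
        Growth rate (1/h), > 0.
    Bmax:
        Carrying capacity (measurement units); required by logistic and
        gompertz, rejected by the other families.
    kd:
        Loss-rate coefficient of the Bertalanffy law (units depend on
        ``delta``); required by bertalanffy.
    lam, delta:
        Bertalanffy growth/loss exponents, with 0 < lam < delta.
    t_lag:
        Dormancy lag (h): net growth is zero for t < t_lag.
    """

    family: str
    B0: float
    kb: float
    Bmax: float | None = None
    kd: float | None = None
    lam: float | None = None
    delta: float | None = None
    t_lag: float = 0.0

    def __post_init__(self):
        if self.family not in GROWTH_FAMILIES:
            raise ConfigurationError(
                f"unknown growth family {self.family!r}; choose from {GROWTH_FAMILIES}"
            )
        if not (self.B0 > 0):
            raise ConfigurationError("B0 must be > 0")
        if not (self.kb > 0):
            raise ConfigurationError("kb must be > 0")
        if self.t_lag < 0:
            raise ConfigurationError("t_lag must be >= 0")
        needs_bmax = self.family in ("logistic", "gompertz")
        if needs_bmax:
            if self.Bmax is None or not (self.Bmax > 0):
                raise ConfigurationError(f"{self.family} requires Bmax > 0")
        elif self.Bmax is not None:
            raise ConfigurationError(f"{self.family} does not take Bmax")
        if self.family == "bertalanffy":
            if self.kd is None or self.kd <= 0:
                raise ConfigurationError("bertalanffy requires kd > 0")
            if self.lam is None or self.delta is None:
                raise ConfigurationError("bertalanffy requires lam and delta")
            if not (0 < self.lam < self.delta):
                raise ConfigurationError("bertalanffy requires 0 < lam < delta")
        elif any(v is not None for v in (self.kd, self.lam, self.delta)):
            raise ConfigurationError(
                f"{self.family} does not take kd/lam/delta"
            )


def growth_rate(params: GrowthParams, B) -> np.ndarray | float:
    """Drug-free growth rate g(B) in measurement-units/h.

    Vectorised over ``B``.  B must be nonnegative; the Gompertz rate at B=0
    is defined as 0 by continuity (B·ln(Bmax/B) → 0), and B > Bmax is legal
    for logistic/gompertz (the rate is then negative).
    """
    B_arr = np.asarray(B, dtype=float)
    if np.any(B_arr < 0):
        raise ValueError("biofilm level B must be nonnegative")
    f = params.family
    if f == "exponential":
        out = params.kb * B_arr
    elif f == "logistic":
        out = params.kb * B_arr * (1.0 - B_arr / params.Bmax)
    elif f == "gompertz":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                B_arr > 0,
                params.kb * B_arr * np.log(params.Bmax / np.where(B_arr > 0, B_arr, 1.0)),
                0.0,
            )
    else:  # bertalanffy
        out = params.kb * B_arr**params.lam - params.kd * B_arr**params.delta
        out = np.where(B_arr == 0, 0.0, out)
    return out if np.ndim(B) else float(out)


def solve_growth_analytic(params: GrowthParams, times) -> np.ndarray:
    """Closed-form solution B(t) for the analytic families.

    A dormancy lag is applied by evaluating the solution at max(t−t_lag, 0),
    so B(t) = B0 for t < t_lag.  The Bertalanffy family has no closed form
    and must be integrated via :func:`biofilmkin.dynamics.simulate_trajectory`.
    """
    if params.family not in ANALYTIC_FAMILIES:
        raise ConfigurationError(
            "no closed-form solution for the bertalanffy family; "
            "use dynamics.simulate_trajectory"
        )
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    te = np.maximum(t - params.t_lag, 0.0)
    B0, kb = params.B0, params.kb
    if params.family == "exponential":
        out = B0 * np.exp(kb * te)
    elif params.family == "logistic":
        Bmax = params.Bmax
        out = Bmax * B0 / (B0 + (Bmax - B0) * np.exp(-kb * te))
    else:  # gompertz
        Bmax = params.Bmax
        out = Bmax * np.exp(np.log(B0 / Bmax) * np.exp(-kb * te))
    return np.where(te == 0.0, B0, out)  # initial condition exact to the bit


def doubling_time(params: GrowthParams, t: float, as_printed: bool = False) -> float:
    """Doubling time td(t): the Δ with B(t+Δ) = 2·B(t).

    Constant (ln 2 / kb) only for exponential growth.  For logistic and
    Gompertz growth td increases with t and is returned as ``inf`` once
    B(t) ≥ Bmax/2, where no finite Δ doubles the biofilm.

    ``as_printed=True`` switches the Gompertz branch to the simplified
    published form td = ln(ln2·e^{kb t} + 1)/kb, which ignores the
    ln(Bmax/B0) factor of the closed-form solution; it is retained for
    comparison only and does not satisfy the defining relation in general.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if params.family not in ANALYTIC_FAMILIES:
        raise ConfigurationError("doubling_time requires an analytic family")
    kb = params.kb
    if params.family == "exponential":
        return math.log(2.0) / kb
    te = max(t - params.t_lag, 0.0)
    B0, Bmax = params.B0, params.Bmax
    if params.family == "logistic":
        # from B(t+Δ)=2B(t) on the closed form:
        arg = 0.5 - B0 * math.exp(kb * te) / (2.0 * (Bmax - B0))
        if arg <= 0:
            return math.inf
        return -math.log(arg) / kb
    # gompertz
    if as_printed:
        return math.log(math.log(2.0) * math.exp(kb * te) + 1.0) / kb
    L = math.log(Bmax / B0)
    arg = 1.0 - math.log(2.0) * math.exp(kb * te) / L
    if arg <= 0:
        return math.inf
    return -math.log(arg) / kb


def bic_concentration(params: GrowthParams, B: float, theta1: float) -> float:
    """Biofilm-inhibitory concentration at biofilm level B.

    For a linearly acting agent (kill rate θ1·C·B) the BIC is the constant
    concentration making the net growth rate zero:

        exponential  kb/θ1                     (constant)
        logistic     (kb/θ1)·(1 − B/Bmax)
        gompertz     (kb/θ1)·ln(Bmax/B)

    For the Bertalanffy family — not covered by the published closed forms —
    the same definition g(B) = θ1·C·B is solved directly, giving
    C = g(B)/(θ1·B) (an extension of the framework).  Levels at which the
    intrinsic growth rate is already non-positive yield a 0-floored value
    with a warning.
    """
    if not (B > 0):
        raise ValueError("B must be > 0")
    if not (theta1 > 0):
        raise ValueError("theta1 must be > 0")
    f = params.family
    if f == "exponential":
        return params.kb / theta1
    if f == "logistic":
        val = (params.kb / theta1) * (1.0 - B / params.Bmax)
    elif f == "gompertz":
        val = (params.kb / theta1) * math.log(params.Bmax / B)
    else:  # bertalanffy extension
        val = float(growth_rate(params, B)) / (theta1 * B)
    if val < 0:
        warnings.warn(
            "biofilm level exceeds the zero-growth point; BIC floored at 0",
            stacklevel=2,
        )
        return 0.0
    return val
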