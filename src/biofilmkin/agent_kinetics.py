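"""Concentration-time profiles C(t) of antimicrobial agents.

Three representations cover the flow-cell dosing designs:

* ``bolus`` — each dose instantaneously raises the concentration to its peak,
  followed by monoexponential decay with elimination rate k = ln2/t_half.
  Multiple doses superpose.
* ``infusion`` — constant-rate input with first-order elimination:
  C rises as css·(1 − e^{−k(t−t0)}) toward the plateau css during the
  infusion and decays monoexponentially after it stops.
* ``interpolated`` — piecewise-linear interpolation of measured
  (time, concentration) pairs, for assayed profiles; 0 before the first
  point and held at the last value afterwards.

The meropenem (MEM) and tobramycin (TOB) profiles used throughout the worked
examples are available as presets: MEM peak 107.53 mg/L with t½ = 0.893 h,
TOB peak 32.79 mg/L with t½ = 2.75 h (human-population PK targets).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

PK_MODES = ("bolus", "infusion", "interpolated")

#: concentration unit of the population analysis: 1 cu = 1000 ng/mL = 1 mg/L
NAMED_UNITS = {"cu": "1000*ng/mL", "mg/L": "mg/L"}

MEM_PEAK = 107.53  # mg/L
MEM_T_HALF = 0.893  # h
TOB_PEAK = 32.79  # mg/L
TOB_T_HALF = 2.75  # h


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: a bolus peak or an infusion segment."""

    time: float
    peak: float | None = None  # bolus: concentration reached at `time`
    css_target: float | None = None  # infusion: plateau concentration
    duration: float | None = None  # infusion length (h)

    def __post_init__(self):
        if self.time < 0:
            raise ConfigurationError("dose time must be >= 0")
        if self.peak is not None and self.peak <= 0:
            raise ConfigurationError("bolus peak must be > 0")
        if self.css_target is not None:
            if self.css_target <= 0:
                raise ConfigurationError("css_target must be > 0")
            if self.duration is None or self.duration <= 0:
                raise ConfigurationError("infusion requires duration > 0")
        if self.peak is None and self.css_target is None:
            raise ConfigurationError("dose event needs peak or css_target")


@dataclass(frozen=True)
class PKProfile:
    """Concentration-time function of one agent."""

    agent_name: str
    mode: str
    events: tuple[DoseEvent, ...] = ()
    t_half: float | None = None
    points: tuple[tuple[float, float], ...] | None = None
    unit: str = "mg/L"

    def __post_init__(self):
        if self.mode not in PK_MODES:
            raise ConfigurationError(f"unknown PK mode {self.mode!r}")
        object.__setattr__(self, "events", tuple(self.events))
        if self.mode in ("bolus", "infusion"):
            if self.t_half is None or self.t_half <= 0:
                raise ConfigurationError(f"{self.mode} mode requires t_half > 0")
            if not self.events:
                raise ConfigurationError(f"{self.mode} mode requires >= 1 dose event")
            want = "peak" if self.mode == "bolus" else "css_target"
            for ev in self.events:
                if getattr(ev, want) is None:
                    raise ConfigurationError(f"{self.mode} events require {want}")
        else:
            pts = tuple(tuple(map(float, p)) for p in (self.points or ()))
            if len(pts) < 2:
                raise ConfigurationError("interpolated mode requires >= 2 points")
            t = np.array([p[0] for p in pts])
            c = np.array([p[1] for p in pts])
            if np.any(np.diff(t) <= 0) or np.any(t < 0) or np.any(c < 0):
                raise ConfigurationError(
                    "interpolated points must be time-sorted and nonnegative"
                )
            object.__setattr__(self, "points", pts)

    @property
    def k_elim(self) -> float:
        return math.log(2.0) / self.t_half

    def breakpoints(self) -> np.ndarray:
        """Times where C(t) is not smooth: dose times and infusion stops.

        The dynamics layer restarts integration at these points.
        """
        bps: list[float] = []
        if self.mode == "bolus":
            bps = [ev.time for ev in self.events]
        elif self.mode == "infusion":
            for ev in self.events:
                bps += [ev.time, ev.time + ev.duration]
        else:
            bps = [p[0] for p in self.points]
        return np.unique(np.asarray(bps, dtype=float))


def concentration(profile: PKProfile, t) -> np.ndarray | float:
    """Evaluate C(t) for a profile; vectorised over ``t``.

    Times before any dose (or before the first measured point) give 0.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    if profile.mode == "interpolated":
        pt = np.array([p[0] for p in profile.points])
        pc = np.array([p[1] for p in profile.points])
        if np.any(t_arr < pt[0]) or np.any(t_arr > pt[-1]):
            warnings.warn(
                f"{profile.agent_name}: query outside the measured window; "
                "using 0 before the first point and holding the last value",
                stacklevel=2,
            )
        out = np.interp(t_arr, pt, pc, left=0.0, right=pc[-1])
    else:
        k = profile.k_elim
        out = np.zeros_like(t_arr)
        for ev in profile.events:
            if profile.mode == "bolus":
                dt = t_arr - ev.time
                out += np.where(dt >= 0, ev.peak * np.exp(-k * np.maximum(dt, 0.0)), 0.0)
            else:
                t0, dur, css = ev.time, ev.duration, ev.css_target
                dt = t_arr - t0
                during = css * (1.0 - np.exp(-k * np.clip(dt, 0.0, dur)))
                c_end = css * (1.0 - math.exp(-k * dur))
                after = c_end * np.exp(-k * np.maximum(dt - dur, 0.0))
                out += np.where(dt < 0, 0.0, np.where(dt <= dur, during, after))
    return out if np.ndim(t) else float(out[0])


def mem_bolus(dose_times=(24.0,), peak: float = MEM_PEAK) -> PKProfile:
    """Meropenem intermittent-bolus preset (monoexponential washout)."""
    return PKProfile(
        agent_name="MEM",
        mode="bolus",
        events=tuple(DoseEvent(time=t, peak=peak) for t in dose_times),
        t_half=MEM_T_HALF,
    )


def tob_bolus(dose_times=(24.0,), peak: float = TOB_PEAK) -> PKProfile:
    """Tobramycin intermittent-bolus preset (monoexponential washout)."""
    return PKProfile(
        agent_name="TOB",
        mode="bolus",
        events=tuple(DoseEvent(time=t, peak=peak) for t in dose_times),
        t_half=TOB_T_HALF,
    )


def mem_infusion(start: float = 72.0, duration: float = 3.0,
                 css_target: float = MEM_PEAK) -> PKProfile:
    """Meropenem single-infusion preset (first-order elimination)."""
    return PKProfile(
        agent_name="MEM",
        mode="infusion",
        events=(DoseEvent(time=start, css_target=css_target, duration=duration),),
        t_half=MEM_T_HALF,
    )
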