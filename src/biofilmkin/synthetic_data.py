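"""COMSTAT-like synthetic datasets with hierarchical variability.

The generator emulates flow-cell experiments quantified by confocal
microscopy: several experiments, each with a small number of independently
inoculated channels, measured longitudinally (biomass in μm³/μm² or average
thickness in μm).  Channels inherit the population ("fixed-effect")
parameters perturbed by lognormal inter-channel random effects specified as
CV%, trajectories are integrated through :mod:`biofilmkin.dynamics`, and
additive (or proportional) Gaussian residual noise is added.  Negative
noisy measurements are truncated at 0 (they are physical quantities); the
truncation count is recorded in the truth sidecar.

Presets reproduce the worked study designs:

``fig1``
    Logistic growth, B0=0.001, kb=6, Bmax=1, noise-free (model display).
``fig2a`` / ``fig2b``
    Logistic / Gompertz data with additive noise sd 0.1, 25 points on [0, 2]
    (the model-indistinguishability experiment).
``fig3a`` / ``fig3b``
    Bertalanffy data, kb=4, kd=2, δ=1 with λ=0.25 / λ=0.1, noise sd 0.1
    (the model-discrimination experiment).
``table1``
    The population design: logistic growth (Bmax 39.5 μm³/μm², kb 0.0425
    1/h) with two-drug linear-interaction kill (k1 0.00301, k2 0.00352 1/h/cu,
    k12 0.000473 1/h/cu²; cu = 1000 ng/mL = mg/L), MEM/TOB PK presets,
    inter-channel CV% (21.8, 11.1, 14.8, 20.9, 7.1), residual σ 8.02, and the
    four dosing arms: control, single dose of both drugs at 24 h, triple dose
    (q8h) of both at 74 h, and MEM infusion + TOB bolus at 72 h; 7
    experiments × 2 channels sampled every 12 h over 0–168 h.
``example1_thickness``
    Logistic average-thickness control growth, Bmax 52.1 μm, kb 0.051 1/h,
    15 points over 0–168 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .agent_kinetics import PKProfile, mem_bolus, mem_infusion, tob_bolus
from .agent_models import TwoAgentParams
from .dynamics import ModelSpec, simulate_trajectory
from .errors import ConfigurationError
from .estimation import SeriesData, update_spec
from .growth_models import GrowthParams
from .population import cv_to_omega

PRESET_NAMES = ("fig1", "fig2a", "fig2b", "fig3a", "fig3b", "table1",
                "example1_thickness")


@dataclass(frozen=True)
class Arm:
    """A dosing arm: the PK profiles shared by every channel in the arm."""

    name: str
    pk: tuple = ()

    def apply(self, spec: ModelSpec) -> ModelSpec:
        """Attach this arm's PK to a template spec.

        A control arm (no PK) removes the agent effect entirely; a dosed arm
        must carry as many profiles as the template's effect model expects
        (mismatches raise a configuration error).
        """
        if not self.pk:
            return replace(spec, agent_effect=None, pk=())
        return replace(spec, pk=tuple(self.pk))


@dataclass(frozen=True)
class PopulationDesign:
    """A complete multi-experiment study design."""

    name: str
    spec: ModelSpec  # template with the generating fixed effects
    sampling_times: np.ndarray
    n_experiments: int = 1
    channels_per_experiment: int = 1
    cv_percent: dict = field(default_factory=dict)
    sigma: float = 0.0
    residual_model: str = "additive"
    arms: tuple = ()
    include_dead: bool = False
    variable: str = "biomass"
    unit: str = ""
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ConfigurationError("sampling_times must be increasing and nonnegative")
        object.__setattr__(self, "sampling_times", t)
        if any(cv < 0 for cv in self.cv_percent.values()):
            raise ConfigurationError("CV% values must be >= 0")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.residual_model not in ("additive", "proportional"):
            raise ConfigurationError("residual_model must be additive or proportional")
        object.__setattr__(self, "arms", tuple(self.arms))

    def arm_for_experiment(self, e: int) -> Arm:
        """Arms are cycled across experiments (control arm if none given)."""
        if not self.arms:
            return Arm("control", ())
        return self.arms[e % len(self.arms)]


def channel_specs(design: PopulationDesign) -> dict:
    """Per-channel ModelSpec mapping (experiment, channel) → spec.

    Deterministic: depends only on the design's arm structure, not on the
    random draws, so it can be handed to the estimation layer as the model
    to fit.
    """
    out = {}
    for e in range(design.n_experiments):
        arm = design.arm_for_experiment(e)
        spec_e = arm.apply(design.spec)
        for c in range(design.channels_per_experiment):
            out[(f"E{e + 1}", f"C{c + 1}")] = spec_e
    return out


def generate_dataset(design: PopulationDesign, seed: int | None = None):
    """Generate a dataset from a design; returns (series, truth sidecar).

    Per channel: lognormal parameter perturbations are drawn from the CV%
    map, live (and optionally dead) trajectories are integrated with the
    general ODE machinery, residual noise is added, and negative values are
    truncated at 0.  Fully reproducible from the seed (argument overrides
    the design's own seed).

    The truth sidecar is a JSON-serialisable dict holding the generating
    fixed effects, each channel's true parameters and arm, and the count of
    truncated observations.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    times = design.sampling_times
    grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    idx = np.searchsorted(grid, times)
    param_names = sorted(design.cv_percent)
    omegas = {p: cv_to_omega(cv) for p, cv in design.cv_percent.items()}

    series: list[SeriesData] = []
    truth_channels: dict = {}
    n_truncated = 0
    for e in range(design.n_experiments):
        arm = design.arm_for_experiment(e)
        spec_e = arm.apply(design.spec)
        for c in range(design.channels_per_experiment):
            exp_id, ch_id = f"E{e + 1}", f"C{c + 1}"
            draws = {}
            for p in param_names:
                om = omegas[p]
                if om > 0:
                    draws[p] = math.exp(rng.normal(0.0, om))
            base = _base_params(design.spec, param_names)
            true_params = {p: base[p] * draws.get(p, 1.0) for p in param_names}
            # control channels carry no agent effect: drop agent parameters
            applicable = true_params
            if spec_e.agent_effect is None:
                from .estimation import PARAM_ALIASES, _GROWTH_FIELDS

                applicable = {
                    p: v for p, v in true_params.items()
                    if PARAM_ALIASES.get(p, p) in _GROWTH_FIELDS
                }
            spec_j = update_spec(spec_e, applicable) if applicable else spec_e
            traj = simulate_trajectory(spec_j, grid)
            paths = {"live": traj.B[idx]}
            if design.include_dead:
                paths["dead"] = traj.D[idx]
            for compartment, clean in paths.items():
                if design.sigma > 0:
                    noise = rng.normal(0.0, design.sigma, size=len(times))
                    if design.residual_model == "additive":
                        vals = clean + noise
                    else:
                        vals = clean * (1.0 + noise)
                else:
                    vals = clean.copy()
                n_truncated += int(np.sum(vals < 0))
                vals = np.maximum(vals, 0.0)
                series.append(
                    SeriesData(
                        experiment_id=exp_id,
                        channel_id=ch_id,
                        variable=design.variable,
                        compartment=compartment,
                        times=times.copy(),
                        values=vals,
                        unit=design.unit,
                    )
                )
            truth_channels[f"{exp_id}/{ch_id}"] = {
                "experiment_id": exp_id,
                "channel_id": ch_id,
                "arm": arm.name,
                "params": true_params,
            }
    truth = {
        "design": design.name,
        "fixed_effects": _base_params(design.spec, param_names),
        "cv_percent": dict(design.cv_percent),
        "sigma": design.sigma,
        "residual_model": design.residual_model,
        "seed": design.seed if seed is None else seed,
        "n_truncated": n_truncated,
        "channels": truth_channels,
    }
    return series, truth


def _base_params(spec: ModelSpec, names) -> dict:
    """Fixed-effect values of the named parameters from a template spec."""
    from .estimation import PARAM_ALIASES

    out = {}
    for name in names:
        canon = PARAM_ALIASES.get(name, name)
        val = getattr(spec.growth, canon, None)
        if val is None and spec.agent_effect is not None:
            val = getattr(spec.agent_effect, canon, None)
        if val is None:
            raise ConfigurationError(f"parameter {name!r} not present in the design spec")
        out[name] = float(val)
    return out


# ---------------------------------------------------------------------------
# presets


def _fig_design(name: str, growth: GrowthParams, sigma: float) -> PopulationDesign:
    return PopulationDesign(
        name=name,
        spec=ModelSpec(growth=growth),
        sampling_times=np.linspace(0.0, 2.0, 25),
        sigma=sigma,
        variable="biomass",
        unit="arbitrary",
    )


def table1_spec() -> ModelSpec:
    """Template spec of the population design (single-dose arm PK attached)."""
    return ModelSpec(
        growth=GrowthParams(family="logistic", B0=1.0, kb=0.0425, Bmax=39.5),
        agent_effect=TwoAgentParams(
            model="linear_interaction",
            theta1=0.00301,  # MEM kill rate, 1/h per cu
            theta2=0.00352,  # TOB kill rate, 1/h per cu
            theta3=0.000473,  # interaction kill rate, 1/h per cu²
        ),
        effect_sign="inhibit",
        pk=(mem_bolus((24.0,)), tob_bolus((24.0,))),
    )


def zero_profile(agent_name: str, t_end: float = 168.0) -> PKProfile:
    """An identically-zero concentration profile (agent not administered).

    Lets a single-drug arm reuse a two-agent effect model: the absent drug's
    terms vanish with C ≡ 0.
    """
    return PKProfile(agent_name=agent_name, mode="interpolated",
                     points=((0.0, 0.0), (t_end, 0.0)))


def table1_arms() -> tuple:
    """The five dosing arms of the population experiment.

    Single-drug arms are included so the per-drug kill rates k1 and k2 are
    separately identifiable: if both drugs were always co-administered at a
    fixed concentration ratio, k1, k2 and the interaction k12 would lie on a
    likelihood ridge, incompatible with the few-percent standard errors the
    population analysis reports for them.
    """
    return (
        Arm("control", ()),
        Arm("mem_single_24h", (mem_bolus((24.0,)), zero_profile("TOB"))),
        Arm("tob_single_24h", (zero_profile("MEM"), tob_bolus((24.0,)))),
        Arm("triple_dose_74h",
            (mem_bolus((74.0, 82.0, 90.0)), tob_bolus((74.0, 82.0, 90.0)))),
        Arm("combined_infusion_72h", (mem_infusion(72.0, 3.0), tob_bolus((72.0,)))),
    )


def preset(name: str) -> PopulationDesign:
    """Return a named study design with the published generating parameters."""
    if name == "fig1":
        return _fig_design(
            "fig1", GrowthParams(family="logistic", B0=0.001, kb=6.0, Bmax=1.0), 0.0
        )
    if name == "fig2a":
        return _fig_design(
            "fig2a", GrowthParams(family="logistic", B0=0.001, kb=6.0, Bmax=1.0), 0.1
        )
    if name == "fig2b":
        return _fig_design(
            "fig2b", GrowthParams(family="gompertz", B0=0.001, kb=6.0, Bmax=1.0), 0.1
        )
    if name == "fig3a":
        return _fig_design(
            "fig3a",
            GrowthParams(family="bertalanffy", B0=0.001, kb=4.0, kd=2.0, lam=0.25, delta=1.0),
            0.1,
        )
    if name == "fig3b":
        return _fig_design(
            "fig3b",
            GrowthParams(family="bertalanffy", B0=0.001, kb=4.0, kd=2.0, lam=0.1, delta=1.0),
            0.1,
        )
    if name == "table1":
        return PopulationDesign(
            name="table1",
            spec=table1_spec(),
            sampling_times=np.arange(0.0, 169.0, 12.0),
            n_experiments=7,
            channels_per_experiment=2,
            cv_percent={"Bmax": 21.8, "kb": 11.1, "k1": 14.8, "k2": 20.9, "k12": 7.1},
            sigma=8.02,
            arms=table1_arms(),
            variable="biomass",
            unit="um^3/um^2",
        )
    if name == "example1_thickness":
        return PopulationDesign(
            name="example1_thickness",
            spec=ModelSpec(
                growth=GrowthParams(family="logistic", B0=1.0, kb=0.051, Bmax=52.1)
            ),
            sampling_times=np.linspace(0.0, 168.0, 15),
            sigma=8.02,
            variable="avg_thickness",
            unit="um",
        )
    raise ConfigurationError(
        f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
    )
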