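"""Readers and writers: COMSTAT text exports, tidy CSV, PK CSV, configs.

The canonical in-memory exchange format is the tidy table with seven columns

    experiment_id, channel_id, time_h, variable, compartment, value, unit

sorted by (experiment, channel, time); (experiment, channel, time, variable,
compartment) keys must be unique and units consistent within a variable.
Time is stored in hours, 0-based at inoculation.

COMSTAT exports are tab- or multi-space-delimited tables with a header row,
one file per (channel, time point); the files carry no timestamps, so an
external manifest (CSV with columns ``filename, experiment_id, channel_id,
time_h, compartment``) supplies the metadata.  When a file holds several
rows (several random image positions), the feature is averaged across rows.

Model configurations are YAML documents validated into
:class:`~biofilmkin.dynamics.ModelSpec`; see ``docs/methods.md`` for the
schema.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import yaml

from .agent_kinetics import DoseEvent, PKProfile
from .agent_models import AgentParams, TwoAgentParams
from .dynamics import ModelSpec, PostPlateau
from .errors import ConfigurationError, ParseError
from .estimation import SeriesData
from .growth_models import GrowthParams

TIDY_COLUMNS = (
    "experiment_id",
    "channel_id",
    "time_h",
    "variable",
    "compartment",
    "value",
    "unit",
)

TIDY_KEY = ("experiment_id", "channel_id", "time_h", "variable", "compartment")

COMSTAT_FEATURES = ("biomass", "avg_thickness", "max_thickness", "area", "colony_volume")

_FEATURE_ALIASES = {
    "biomass": ("biomass", "bio_volume", "biovolume"),
    "avg_thickness": ("avg_thickness", "average_thickness", "mean_thickness"),
    "max_thickness": ("max_thickness", "maximum_thickness"),
    "area": ("area", "substratum_coverage"),
    "colony_volume": ("colony_volume", "microcolony_volume", "volume_of_microcolonies"),
}

_FEATURE_UNITS = {
    "biomass": "um^3/um^2",
    "avg_thickness": "um",
    "max_thickness": "um",
    "area": "um^2",
    "colony_volume": "um^3",
}


def _normalise_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


# ---------------------------------------------------------------------------
# tidy format


def series_to_tidy(series_list) -> pd.DataFrame:
    """Convert SeriesData objects to the canonical tidy table."""
    rows = []
    for s in series_list:
        for t, v in zip(s.times, s.values):
            rows.append((s.experiment_id, s.channel_id, float(t), s.variable,
                         s.compartment, float(v), s.unit))
    df = pd.DataFrame(rows, columns=list(TIDY_COLUMNS))
    return df.sort_values(list(TIDY_KEY)).reset_index(drop=True)


def tidy_to_series(df: pd.DataFrame) -> list[SeriesData]:
    """Group a tidy table back into per-channel SeriesData objects."""
    _validate_tidy(df)
    out = []
    keys = ["experiment_id", "channel_id", "variable", "compartment"]
    for (exp, ch, var, comp), g in df.groupby(keys, sort=True):
        g = g.sort_values("time_h")
        units = g["unit"].fillna("").unique()
        if len(units) > 1:
            raise ParseError(f"inconsistent units for {var}: {sorted(units)}")
        out.append(
            SeriesData(
                experiment_id=str(exp), channel_id=str(ch), variable=str(var),
                compartment=str(comp),
                times=g["time_h"].to_numpy(dtype=float),
                values=g["value"].to_numpy(dtype=float),
                unit=str(units[0]) if len(units) else "",
            )
        )
    return out


def _validate_tidy(df: pd.DataFrame) -> None:
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"tidy table missing columns: {missing}")
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ParseError(f"non-numeric value cells at file rows {rows[:10]}")
    dup = df.duplicated(subset=list(TIDY_KEY), keep=False)
    if dup.any():
        offenders = df.loc[dup, list(TIDY_KEY)].drop_duplicates().head(10)
        raise ParseError(
            "duplicate (experiment, channel, time, variable, compartment) keys:\n"
            f"{offenders.to_string(index=False)}"
        )


def write_tidy(data, path) -> None:
    """Write SeriesData objects or a tidy DataFrame to CSV (canonical order)."""
    df = data if isinstance(data, pd.DataFrame) else series_to_tidy(data)
    _validate_tidy(df)
    df = df.sort_values(list(TIDY_KEY)).reset_index(drop=True)
    df.to_csv(path, index=False)


def read_tidy(path) -> pd.DataFrame:
    """Read and validate a tidy CSV; rows come back in canonical order."""
    try:
        df = pd.read_csv(path, dtype={"experiment_id": str, "channel_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    _validate_tidy(df)
    df["value"] = pd.to_numeric(df["value"])
    df["time_h"] = pd.to_numeric(df["time_h"])
    df["unit"] = df["unit"].fillna("")
    return df.sort_values(list(TIDY_KEY)).reset_index(drop=True)


# ---------------------------------------------------------------------------
# COMSTAT exports


def _read_comstat_table(path) -> pd.DataFrame:
    text = Path(path).read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty COMSTAT file")
    try:
        df = pd.read_csv(path, sep=r"\t|\s{2,}", engine="python")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: cannot parse as delimited text ({exc})") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    df.columns = [_normalise_header(c) for c in df.columns]
    return df


def read_comstat(paths, feature: str, mapping) -> pd.DataFrame:
    """Read COMSTAT text exports into a tidy table.

    ``mapping`` is a manifest DataFrame (or CSV path) with columns
    ``filename, experiment_id, channel_id, time_h, compartment`` supplying
    the metadata the export files lack.  One tidy row per file: the requested
    feature averaged over the file's image rows.
    """
    if feature not in COMSTAT_FEATURES:
        raise ConfigurationError(
            f"unknown feature {feature!r}; choose from {COMSTAT_FEATURES}"
        )
    if not isinstance(mapping, pd.DataFrame):
        mapping = pd.read_csv(mapping, dtype={"experiment_id": str, "channel_id": str})
    need = {"filename", "experiment_id", "channel_id", "time_h", "compartment"}
    if not need <= set(mapping.columns):
        raise ParseError(f"manifest must have columns {sorted(need)}")
    by_name = {Path(f).name: row for f, row in
               zip(mapping["filename"], mapping.to_dict("records"))}
    aliases = _FEATURE_ALIASES[feature]
    rows = []
    for path in paths:
        name = Path(path).name
        if name not in by_name:
            raise ParseError(f"{name}: not present in the manifest")
        meta = by_name[name]
        table = _read_comstat_table(path)
        col = next((c for c in table.columns if c in aliases), None)
        if col is None:
            raise ParseError(
                f"{name}: feature {feature!r} not found; available columns: "
                f"{list(table.columns)}"
            )
        value = float(pd.to_numeric(table[col], errors="raise").mean())
        rows.append(
            (str(meta["experiment_id"]), str(meta["channel_id"]),
             float(meta["time_h"]), feature, str(meta["compartment"]), value,
             _FEATURE_UNITS[feature])
        )
    df = pd.DataFrame(rows, columns=list(TIDY_COLUMNS))
    _validate_tidy(df)
    return df.sort_values(list(TIDY_KEY)).reset_index(drop=True)


def read_pk_csv(path) -> dict[str, PKProfile]:
    """Read measured concentration profiles (columns time_h, conc, agent)."""
    df = pd.read_csv(path)
    need = {"time_h", "conc", "agent"}
    if not need <= set(df.columns):
        raise ParseError(f"PK CSV must have columns {sorted(need)}")
    out = {}
    for agent, g in df.groupby("agent"):
        g = g.sort_values("time_h")
        out[str(agent)] = PKProfile(
            agent_name=str(agent), mode="interpolated",
            points=tuple(zip(g["time_h"].astype(float), g["conc"].astype(float))),
        )
    return out


# ---------------------------------------------------------------------------
# config schema


def build_model_spec(cfg: dict) -> ModelSpec:
    """Build a ModelSpec from a config dict (see docs for the schema)."""
    if "growth" not in cfg:
        raise ConfigurationError("config requires a 'growth' section")
    growth = GrowthParams(**cfg["growth"])
    effect_cfg = cfg.get("agent_effect")
    effect = None
    if effect_cfg:
        effect_cfg = dict(effect_cfg)
        kind = effect_cfg.pop("type", "single")
        if kind == "single":
            effect = AgentParams(**effect_cfg)
        elif kind == "two_agent":
            effect = TwoAgentParams(**effect_cfg)
        else:
            raise ConfigurationError("agent_effect.type must be 'single' or 'two_agent'")
    pk = tuple(_build_pk(p) for p in cfg.get("pk", []))
    pp_cfg = cfg.get("post_plateau")
    pp = PostPlateau(**pp_cfg) if pp_cfg else None
    return ModelSpec(
        growth=growth,
        agent_effect=effect,
        effect_sign=cfg.get("effect_sign", "inhibit"),
        pk=pk,
        dead_model=cfg.get("dead_model", "none"),
        post_plateau=pp,
    )


def _build_pk(p: dict) -> PKProfile:
    p = dict(p)
    events = tuple(DoseEvent(**e) for e in p.pop("events", []))
    points = p.pop("points", None)
    return PKProfile(
        agent_name=p.pop("agent", p.pop("agent_name", "agent")),
        mode=p.pop("mode"),
        events=events,
        t_half=p.pop("t_half", None),
        points=tuple(tuple(pt) for pt in points) if points else None,
        **p,
    )


def spec_to_config(spec: ModelSpec) -> dict:
    """Serialise a ModelSpec back to the config-dict form (for report echo)."""
    g = spec.growth
    cfg: dict = {
        "growth": {
            k: v
            for k, v in {
                "family": g.family, "B0": g.B0, "kb": g.kb, "Bmax": g.Bmax,
                "kd": g.kd, "lam": g.lam, "delta": g.delta, "t_lag": g.t_lag,
            }.items()
            if v is not None
        }
    }
    eff = spec.agent_effect
    if isinstance(eff, AgentParams):
        cfg["agent_effect"] = {
            k: v for k, v in {
                "type": "single", "model": eff.model, "theta1": eff.theta1,
                "theta2": eff.theta2,
            }.items() if v is not None
        }
    elif isinstance(eff, TwoAgentParams):
        cfg["agent_effect"] = {
            k: v for k, v in {
                "type": "two_agent", "model": eff.model, "theta1": eff.theta1,
                "theta2": eff.theta2, "theta3": eff.theta3, "c1_50": eff.c1_50,
                "c2_50": eff.c2_50, "alpha": eff.alpha, "scale": eff.scale,
            }.items() if v is not None
        }
    cfg["effect_sign"] = spec.effect_sign
    cfg["dead_model"] = spec.dead_model
    if spec.post_plateau is not None:
        pp = spec.post_plateau
        cfg["post_plateau"] = {
            k: v for k, v in {"variant": pp.variant, "kl": pp.kl,
                              "kp": pp.kp, "kq": pp.kq}.items() if v is not None
        }
    pk_cfgs = []
    for prof in spec.pk:
        pc: dict = {"agent": prof.agent_name, "mode": prof.mode}
        if prof.mode == "interpolated":
            pc["points"] = [list(pt) for pt in prof.points]
        else:
            pc["t_half"] = prof.t_half
            pc["events"] = [
                {k: v for k, v in {"time": ev.time, "peak": ev.peak,
                                   "css_target": ev.css_target,
                                   "duration": ev.duration}.items() if v is not None}
                for ev in prof.events
            ]
        pk_cfgs.append(pc)
    if pk_cfgs:
        cfg["pk"] = pk_cfgs
    return cfg


def load_config(path) -> dict:
    """Load a YAML config document."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a YAML mapping")
    return cfg


def dump_config(cfg: dict) -> str:
    """YAML text of a resolved config (echoed by every CLI run)."""
    return yaml.safe_dump(cfg, sort_keys=True)
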