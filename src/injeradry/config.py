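"""Run configuration, file I/O and the end-to-end pipeline.

The run configuration is a TOML file with sections [composition],
[geometry], [air], [conditions], [solver], [kinetics] and [synthetic].
Keys carry unit suffixes (_K, _m, _m_s, _min, _pct, ...) and are validated
against a closed schema: unknown keys are rejected with the expected unit
named in the message.  Every key is optional; missing entries fall back to
the reference tunnel-dryer defaults (air at 333.15 K, 0.5 m/s, RH 11 %,
porosity 0.74, 3 cm x 30 cm sample).
"""
from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import kinetics as kin
from .curve import DryingCurve
from .properties import Composition, INJERA_COMPOSITION
from .simulator import DryingConditions, SampleGeometry, SolverSettings, simulate
from .transfer import AirState

__all__ = ["RunConfig", "load_config", "dump_config", "pipeline_run",
           "SCHEMA_VERSION"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

# section -> key -> (dataclass field, unit note)
_SCHEMA = {
    "composition": {
        "water": ("water", "mass fraction (kg/kg)"),
        "carbohydrate": ("carbohydrate", "mass fraction (kg/kg)"),
        "protein": ("protein", "mass fraction (kg/kg)"),
        "fat": ("fat", "mass fraction (kg/kg)"),
        "fiber": ("fiber", "mass fraction (kg/kg)"),
        "ash": ("ash", "mass fraction (kg/kg)"),
    },
    "geometry": {
        "thickness_m": ("thickness", "m"),
        "diameter_m": ("diameter", "m"),
        "mode": ("mode", "1d | axisym2d"),
        "n_z": ("n_z", "node count"),
        "n_r": ("n_r", "node count"),
    },
    "air": {
        "temperature_K": ("T_air", "K"),
        "velocity_m_s": ("u_air", "m/s"),
        "humidity_pct": ("RH", "%"),
        "pressure_Pa": ("p_atm", "Pa"),
    },
    "conditions": {
        "K_vap_per_s": ("K_vap", "1/s"),
        "vent_rate_per_s": ("vent_rate", "1/s"),
        "area_factor": ("area_factor", "dimensionless"),
        "capillary_diffusivity_m2_s": ("capillary_diffusivity", "m^2/s"),
        "MR_stop": ("MR_stop", "dimensionless"),
        "t_max_min": ("t_max", "min"),
        "c0_mol_m3": ("c0", "mol/m^3"),
        "T0_K": ("T0", "K"),
        "porosity": ("eps", "dimensionless"),
    },
    "solver": {
        "dt_s": ("dt", "s"),
        "picard_tol": ("picard_tol", "relative"),
        "picard_max": ("picard_max", "count"),
        "mixture_rule": ("mixture_rule", "as_printed | corrected"),
        "darcy": ("darcy", "off | on"),
        "bottom": ("bottom", "insulated | convective"),
    },
    "kinetics": {
        "half_thickness_m": (None, "m"),
        "models": (None, "list of model names"),
    },
    "synthetic": {
        "sample_mass_g": (None, "g"),
        "mass_interval_min": (None, "min"),
        "temp_interval_min": (None, "min"),
        "mass_noise_sd_g": (None, "g"),
        "temp_noise_sd_K": (None, "K"),
        "mr_noise_sd": (None, "dimensionless"),
        "seed": (None, "integer"),
    },
}


@dataclass(frozen=True)
class RunConfig:
    composition: Composition = INJERA_COMPOSITION
    geometry: SampleGeometry = field(default_factory=SampleGeometry)
    conditions: DryingConditions = field(default_factory=DryingConditions)
    solver: SolverSettings = field(default_factory=SolverSettings)
    kinetics: dict = field(default_factory=lambda: {
        "half_thickness_m": 0.015,
        "models": ["henderson_pabis", "two_term", "page"],
    })
    synthetic: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def config_hash(self) -> str:
        return hashlib.sha256(dump_config(self).encode()).hexdigest()[:16]


def _check_keys(section: str, entries: dict) -> None:
    known = _SCHEMA.get(section)
    if known is None:
        raise ValueError(f"unknown config section [{section}]; expected one "
                         f"of {sorted(_SCHEMA)}")
    for key in entries:
        if key not in known:
            hints = ", ".join(f"{k} ({u})" for k, (_, u) in known.items())
            raise ValueError(
                f"unknown key '{key}' in [{section}]; valid keys: {hints}")


def load_config(path: str | Path | None = None,
                text: str | None = None) -> RunConfig:
    """Read and validate a TOML run configuration.

    An empty file (or ``path=None``) yields the full default
    configuration.
    """
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    raw = tomllib.loads(text)
    version = str(raw.pop("schema_version", SCHEMA_VERSION))
    for section, entries in raw.items():
        _check_keys(section, entries)

    comp = INJERA_COMPOSITION
    if "composition" in raw:
        base = comp.as_dict()
        base.update(raw["composition"])
        comp = Composition(**base)

    geometry = SampleGeometry(**{
        _SCHEMA["geometry"][k][0]: v for k, v in raw.get("geometry", {}).items()
    })

    air_kwargs = {_SCHEMA["air"][k][0]: v for k, v in raw.get("air", {}).items()}
    air = AirState(**air_kwargs)

    cond_kwargs = {}
    for k, v in raw.get("conditions", {}).items():
        name = _SCHEMA["conditions"][k][0]
        if k == "t_max_min":
            v = float(v) * 60.0
        cond_kwargs[name] = v
    conditions = DryingConditions(air=air, **cond_kwargs)

    solver = SolverSettings(**{
        _SCHEMA["solver"][k][0]: v for k, v in raw.get("solver", {}).items()
    })

    cfg = RunConfig(composition=comp, geometry=geometry,
                    conditions=conditions, solver=solver,
                    schema_version=version)
    if raw.get("kinetics"):
        merged = dict(cfg.kinetics)
        merged.update(raw["kinetics"])
        cfg = replace(cfg, kinetics=merged)
    if raw.get("synthetic"):
        cfg = replace(cfg, synthetic=dict(raw["synthetic"]))
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)}")


def dump_config(cfg: RunConfig) -> str:
    """Serialise a configuration back to canonical TOML."""
    c, g, d, s = cfg.composition, cfg.geometry, cfg.conditions, cfg.solver
    sections = {
        "composition": c.as_dict(),
        "geometry": {"thickness_m": g.thickness, "diameter_m": g.diameter,
                     "mode": g.mode, "n_z": g.n_z, "n_r": g.n_r},
        "air": {"temperature_K": d.air.T_air, "velocity_m_s": d.air.u_air,
                "humidity_pct": d.air.RH, "pressure_Pa": d.air.p_atm},
        "conditions": {"K_vap_per_s": d.K_vap, "vent_rate_per_s": d.vent_rate,
                       "area_factor": d.area_factor,
                       "capillary_diffusivity_m2_s": d.capillary_diffusivity,
                       "MR_stop": d.MR_stop, "t_max_min": d.t_max / 60.0,
                       "c0_mol_m3": d.c0, "T0_K": d.T0, "porosity": d.eps},
        "solver": {"dt_s": s.dt, "picard_tol": s.picard_tol,
                   "picard_max": s.picard_max, "mixture_rule": s.mixture_rule,
                   "darcy": s.darcy, "bottom": s.bottom},
        "kinetics": cfg.kinetics,
        "synthetic": cfg.synthetic,
    }
    lines = [f'schema_version = "{cfg.schema_version}"']
    for name, entries in sections.items():
        if not entries:
            continue
        lines.append("")
        lines.append(f"[{name}]")
        for k, v in entries.items():
            lines.append(f"{k} = {_toml_value(v)}")
    return "\n".join(lines) + "\n"


def pipeline_run(cfg: RunConfig, outdir: str | Path) -> dict:
    """simulate -> fit kinetics -> effective diffusivity -> report.

    Writes curve.csv, fits.json, report.json and run.log into ``outdir``
    and returns the report dictionary.  Outputs are deterministic for a
    given configuration and carry its hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("injeradry")
    root.addHandler(handler)
    try:
        log.info("pipeline start, config %s", cfg_hash)
        log.info("mixture_rule=%s darcy=%s bottom=%s",
                 cfg.solver.mixture_rule, cfg.solver.darcy, cfg.solver.bottom)
        curve = simulate(cfg.composition, cfg.geometry, cfg.conditions,
                         cfg.solver)
        curve.meta["config_hash"] = cfg_hash
        curve.to_csv(outdir / "curve.csv")

        fits = kin.rank_models(curve, tuple(cfg.kinetics["models"]))
        deff = kin.effective_diffusivity_slope(
            curve, cfg.kinetics["half_thickness_m"])
        fits_payload = {
            "config_hash": cfg_hash,
            "ranked_models": [
                {"model": f.model, "constants": f.params, "R2": f.r2,
                 "RMSE": f.rmse, "n_obs": f.n_obs} for f in fits
            ],
            "effective_diffusivity_m2_s": deff,
        }
        (outdir / "fits.json").write_text(json.dumps(fits_payload, indent=2))

        report = {
            "config_hash": cfg_hash,
            "schema_version": cfg.schema_version,
            "drying_time_min": (curve.drying_time(cfg.conditions.MR_stop)
                                if not curve.meta["truncated"] else None),
            "truncated": curve.meta["truncated"],
            "balance": curve.meta["balance"],
            "picard": curve.meta["picard"],
            "transfer": curve.meta["transfer"],
            "best_model": fits[0].model,
            "effective_diffusivity_m2_s": deff,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        log.info("pipeline done: %s", report["drying_time_min"])
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
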