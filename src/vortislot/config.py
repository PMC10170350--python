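"""Run configuration: a single YAML file with SI-unit-suffixed keys.

Unit suffixes are part of the key names (``*_m``, ``*_pa_s``, ...) because
the quantities involved span micrometres to metres and two water-viscosity
conventions; explicit suffixes prevent silent unit errors.  Unknown keys are
rejected.  Defaults are filled and their provenance recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .geometry import CrossStepParams
from .porous import (
    CALIBRATION_FLUID,
    FluidProperties,
    PorousLayerSpec,
    calibrate_porous_parameters,
    read_samples_csv,
)
from .solver import SolverConfig


class ConfigError(ValueError):
    pass


_GEOMETRY_KEYS = {
    "n_slots": ("n_slots", int),
    "filter_length_m": ("filter_length", float),
    "mouth_diameter_m": ("mouth_diameter", float),
    "step_height_m": ("step_height", float),
    "slot_width_m": ("slot_width", float),
    "rib_width_m": ("rib_width", float),
    "porous_thickness_m": ("dm", float),
    "back_inner_radius_m": ("back_inner_radius", float),
    "domain_length_m": ("domain_length", float),
    "domain_half_width_m": ("domain_half_width", float),
    "mouth_position_m": ("mouth_position", float),
    "inlet_speed_m_per_s": ("inlet_speed", float),
    "cells_per_step": ("cells_per_step", int),
    "mode": ("mode", str),
}

_FLUID_KEYS = {
    "density_kg_per_m3": ("density", float),
    "viscosity_pa_s": ("viscosity", float),
}

_POROUS_KEYS = {
    "samples_csv": None,
    "calibration_viscosity_pa_s": None,
    "alpha_n_m2": ("alpha_n", float),
    "alpha_t_m2": ("alpha_t", float),
    "c2_per_m": ("c2", float),
    "thickness_m": ("dm", float),
}

_SOLVER_KEYS = {
    "relax_velocity": ("relax_velocity", float),
    "relax_pressure": ("relax_pressure", float),
    "max_iterations": ("max_iterations", int),
    "tolerance": ("tolerance", float),
    "scheme": ("scheme", str),
    "thicken_porous_layer": ("thicken_porous_layer", bool),
}

_TOP_KEYS = {"geometry", "fluid", "porous", "scenario", "solver", "output_dir", "seed"}


@dataclass
class RunConfig:
    """Fully validated run configuration with defaults filled."""

    geometry: CrossStepParams
    fluid: FluidProperties
    porous: PorousLayerSpec
    scenario: str = "original"
    solver: SolverConfig = field(default_factory=SolverConfig)
    output_dir: Path = Path("runs")
    seed: int = 0
    defaulted: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in ("original", "half", "none"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")


def _build(section: dict, keymap: dict, cls, where: str, defaulted: list[str]):
    kwargs = {}
    for key, val in section.items():
        if key not in keymap:
            raise ConfigError(f"unknown key {where}.{key!r}; known: {sorted(keymap)}")
        target = keymap[key]
        if target is None:
            continue
        name, typ = target
        try:
            kwargs[name] = typ(val)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad value for {where}.{key}: {val!r} ({exc})") from exc
    obj = cls(**kwargs)
    for key, target in keymap.items():
        if target is not None and key not in section:
            defaulted.append(f"{where}.{key}")
    return obj


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    A ``porous.samples_csv`` entry triggers calibration from the referenced
    pressure-drop table (the CSV must exist at load time); otherwise explicit
    coefficients (or their defaults) are used.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not raw:
        raise ConfigError(
            "empty config; required sections: geometry, fluid, porous "
            "(all optional individually, but the file must be a mapping)"
        )
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}; known: {sorted(_TOP_KEYS)}")

    defaulted: list[str] = []
    geometry = _build(raw.get("geometry", {}) or {}, _GEOMETRY_KEYS, CrossStepParams,
                      "geometry", defaulted)
    fluid = _build(raw.get("fluid", {}) or {}, _FLUID_KEYS, FluidProperties,
                   "fluid", defaulted)

    psec = dict(raw.get("porous", {}) or {})
    for key in psec:
        if key not in _POROUS_KEYS:
            raise ConfigError(f"unknown key porous.{key!r}; known: {sorted(_POROUS_KEYS)}")
    if "samples_csv" in psec:
        csv = (path.parent / psec["samples_csv"]).resolve() \
            if not Path(psec["samples_csv"]).is_absolute() else Path(psec["samples_csv"])
        if not csv.exists():
            raise ConfigError(f"porous.samples_csv not found: {csv}")
        cal_mu = float(psec.get("calibration_viscosity_pa_s", CALIBRATION_FLUID.viscosity))
        cal_fluid = FluidProperties(density=fluid.density, viscosity=cal_mu)
        porous = calibrate_porous_parameters(
            read_samples_csv(csv), cal_fluid,
            dm=float(psec.get("thickness_m", 50e-6)),
            alpha_t=float(psec.get("alpha_t_m2", 1e-10)),
        )
    else:
        porous = _build(psec, {k: v for k, v in _POROUS_KEYS.items() if v is not None},
                        PorousLayerSpec, "porous", defaulted)

    solver = _build(raw.get("solver", {}) or {}, _SOLVER_KEYS, SolverConfig,
                    "solver", defaulted)
    return RunConfig(
        geometry=geometry,
        fluid=fluid,
        porous=porous,
        scenario=str(raw.get("scenario", "original")),
        solver=solver,
        output_dir=Path(raw.get("output_dir", "runs")),
        seed=int(raw.get("seed", 0)),
        defaulted=tuple(defaulted),
    )
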