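"""Porous-layer resistance model (Darcy + inertial loss).

A thin porous layer (e.g. a gill-raker mesh or nylon screen) is treated as a
continuum momentum sink instead of resolving individual pores.  The pressure
drop across a layer of thickness ``dm`` for flow normal to it at approach
velocity ``v`` is

    dp = -(mu/alpha * v + C2 * rho/2 * v**2) * dm

where ``alpha`` is the face permeability (m^2) and ``C2`` the pressure-jump
coefficient (1/m).  Given pressure-drop samples at two or more velocities the
two coefficients follow from a linear solve (or least squares) in
``x = mu/alpha`` and ``y = C2*rho/2``.

The layer is anisotropic in its viscous term: a *main* (through-layer)
permeability ``alpha_n`` and a lower tangential (in-plane) permeability
``alpha_t``.  The inertial term is isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd


class CalibrationError(ValueError):
    """Raised when pressure-drop samples cannot yield a physical fit."""


@dataclass(frozen=True)
class FluidProperties:
    """Incompressible Newtonian fluid.

    density : kg m^-3
    viscosity : dynamic viscosity, Pa s
    """

    density: float = 998.2
    viscosity: float = 1.003e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


#: fluid used for the pore-scale resistance calibration (20 C water as used
#: in the micro-scale pressure-drop computations)
CALIBRATION_FLUID = FluidProperties(density=998.2, viscosity=1.03e-3)

#: fluid used in the bulk flow solves (20 C water; this viscosity makes the
#: mouth-aperture Reynolds number come out at 4420 for 0.111 m/s and 40 mm)
WATER_20C = FluidProperties(density=998.2, viscosity=1.003e-3)


@dataclass(frozen=True)
class PressureDropSample:
    """One (approach velocity, pressure-drop magnitude) observation.

    velocity : approach velocity normal to the layer, m/s (> 0)
    delta_p : magnitude of the pressure drop across the layer, Pa (> 0).
        Stored positive (upstream minus downstream); the signed "pressure
        jump" convention is negative and is what :func:`predict_pressure_jump`
        returns.
    """

    velocity: float
    delta_p: float

    def __post_init__(self) -> None:
        if self.velocity <= 0:
            raise ValueError("sample velocity must be > 0")
        if self.delta_p <= 0:
            raise ValueError("sample pressure drop must be > 0 (store the magnitude)")


@dataclass(frozen=True)
class PorousLayerSpec:
    """Calibrated resistance parameters of one porous layer.

    alpha_n : face (through-layer) permeability, m^2
    alpha_t : tangential (in-plane) permeability, m^2
    c2 : pressure-jump (inertial loss) coefficient, 1/m, isotropic
    dm : layer thickness, m
    """

    alpha_n: float = 2.3468e-10
    alpha_t: float = 1.0e-10
    c2: float = 29473.0
    dm: float = 50e-6

    def __post_init__(self) -> None:
        if self.alpha_n <= 0 or self.alpha_t <= 0:
            raise ValueError("permeabilities must be positive")
        if self.c2 < 0:
            raise ValueError("pressure-jump coefficient must be >= 0")
        if self.dm <= 0:
            raise ValueError("layer thickness must be positive")

    @property
    def viscous_resistance_n(self) -> float:
        """Main-direction viscous resistance coefficient 1/alpha_n (m^-2)."""
        return 1.0 / self.alpha_n

    @property
    def viscous_resistance_t(self) -> float:
        """In-plane viscous resistance coefficient 1/alpha_t (m^-2)."""
        return 1.0 / self.alpha_t

    def thickened(self, thickness: float) -> "PorousLayerSpec":
        """Equivalent layer of a different thickness.

        Rescales the resistance coefficients so the integrated pressure jump
        at equal normal velocity is preserved: (1/alpha)*dm and c2*dm are
        invariants.  Used by the solver to thicken a micrometre layer to one
        grid cell without changing its total resistance.
        """
        if thickness <= 0:
            raise ValueError("thickness must be positive")
        k = self.dm / thickness
        return PorousLayerSpec(
            alpha_n=self.alpha_n / k,
            alpha_t=self.alpha_t / k,
            c2=self.c2 * k,
            dm=thickness,
        )


class FreeFluid:
    """Marker: the layer carries no resistance (treated as ordinary fluid)."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "FreeFluid()"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FreeFluid)

    def __hash__(self) -> int:
        return hash("FreeFluid")


FREE_FLUID = FreeFluid()

LayerOrFree = Union[PorousLayerSpec, FreeFluid]


@dataclass(frozen=True)
class ResistanceScenario:
    """Named multiplier applied to all resistance coefficients."""

    name: str
    multiplier: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.multiplier <= 1.0:
            raise ValueError("multiplier must lie in [0, 1]")


ORIGINAL = ResistanceScenario("original", 1.0)
HALF = ResistanceScenario("half", 0.5)
NONE = ResistanceScenario("none", 0.0)

SCENARIOS = {s.name: s for s in (ORIGINAL, HALF, NONE)}


def calibrate_porous_parameters(
    samples: Sequence[PressureDropSample],
    fluid: FluidProperties = CALIBRATION_FLUID,
    dm: float = 50e-6,
    alpha_t: float = 1.0e-10,
) -> PorousLayerSpec:
    """Fit (alpha_n, C2) from pressure-drop samples.

    With exactly two samples the 2x2 linear system in x = mu/alpha and
    y = C2*rho/2 is solved exactly; with more, ordinary least squares on the
    same linearization dp/dm = x*v + y*v**2.  ``alpha_t`` is not identifiable
    from normal-incidence drops and is passed through.

    Raises
    ------
    CalibrationError
        If fewer than two distinct velocities are supplied, or the fitted
        permeability/inertial coefficient is non-physical.
    """
    if len(samples) < 2:
        raise CalibrationError("need at least two pressure-drop samples")
    v = np.array([s.velocity for s in samples], dtype=float)
    dp = np.array([s.delta_p for s in samples], dtype=float)
    if np.unique(v).size < 2:
        raise CalibrationError(
            "samples must span at least two distinct velocities "
            "(duplicate velocities make the system singular)"
        )
    A = np.column_stack([v, v**2])
    rhs = dp / dm
    if len(samples) == 2:
        x, y = np.linalg.solve(A, rhs)
    else:
        (x, y), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    alpha_n = fluid.viscosity / x if x != 0 else np.inf
    c2 = 2.0 * y / fluid.density
    if x <= 0 or c2 < -1e-12 * abs(x):
        raise CalibrationError(
            f"non-physical fit: mu/alpha = {x:.6g} Pa s m^-2, C2 = {c2:.6g} m^-1"
        )
    return PorousLayerSpec(alpha_n=alpha_n, alpha_t=alpha_t, c2=max(c2, 0.0), dm=dm)


def predict_pressure_jump(
    v: float,
    spec: PorousLayerSpec,
    fluid: FluidProperties = CALIBRATION_FLUID,
) -> float:
    """Signed pressure jump (Pa) across the layer at normal approach velocity v.

    Negative: pressure falls across the layer in the flow direction.
    """
    if v < 0:
        raise ValueError("approach velocity must be >= 0")
    return -(
        fluid.viscosity / spec.alpha_n * v + spec.c2 * 0.5 * fluid.density * v**2
    ) * spec.dm


def scale_resistance(spec: PorousLayerSpec, scenario: ResistanceScenario) -> LayerOrFree:
    """Apply a scenario multiplier m to all resistance coefficients.

    m scales 1/alpha_n, 1/alpha_t and C2; m = 0 returns the free-fluid
    marker telling the solver to treat the layer as ordinary water.
    """
    m = scenario.multiplier
    if m == 0.0:
        return FREE_FLUID
    return replace(spec, alpha_n=spec.alpha_n / m, alpha_t=spec.alpha_t / m, c2=spec.c2 * m)


def momentum_sink(
    velocity: np.ndarray,
    n: np.ndarray,
    spec: PorousLayerSpec,
    fluid: FluidProperties = CALIBRATION_FLUID,
) -> np.ndarray:
    """Force density (N m^-3) exerted on the fluid inside the porous layer.

    S = -[ mu * ( (1/alpha_n) n n^T + (1/alpha_t) (I - n n^T) ) v
           + C2 * rho/2 * |v| v ]

    ``n`` is the unit main-permeability direction.  Integrating S over the
    layer thickness for uniform normal flow reproduces
    :func:`predict_pressure_jump`.
    """
    n = np.asarray(n, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("main-permeability direction must be a unit vector")
    v_n = np.dot(velocity, n) * n
    v_t = velocity - v_n
    viscous = fluid.viscosity * (v_n / spec.alpha_n + v_t / spec.alpha_t)
    inertial = spec.c2 * 0.5 * fluid.density * np.linalg.norm(velocity) * velocity
    return -(viscous + inertial)


# ---------------------------------------------------------------------------
# sample-table I/O

_SAMPLE_COLUMNS = ("velocity_m_per_s", "delta_p_Pa")


def read_samples_csv(path: Union[str, Path]) -> list[PressureDropSample]:
    """Read pressure-drop samples from a two-column CSV table."""
    df = pd.read_csv(path)
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} lacks required columns: {missing}")
    return [
        PressureDropSample(velocity=float(r.velocity_m_per_s), delta_p=abs(float(r.delta_p_Pa)))
        for r in df.itertuples()
    ]


def write_samples_csv(samples: Sequence[PressureDropSample], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "velocity_m_per_s": [s.velocity for s in samples],
            "delta_p_Pa": [s.delta_p for s in samples],
        }
    ).to_csv(path, index=False)


#: the printed micro-scale calibration table: pressure-drop magnitudes across
#: a 50 um pore layer at two approach velocities
DEFAULT_CALIBRATION_SAMPLES = (
    PressureDropSample(velocity=0.1, delta_p=29.3),
    PressureDropSample(velocity=0.5, delta_p=293.6),
)
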