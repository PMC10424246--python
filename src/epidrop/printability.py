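"""Dimensionless-number printability analysis for droplet-based bioprinting.

A valve-driven nozzle expels a low-viscosity cell suspension as discrete
droplets. Whether a given bioink/jet configuration prints stably is governed
by a small set of dimensionless groups built from the fluid properties
(viscosity η, surface tension γ, density ρ), the nozzle orifice diameter L
and the droplet velocity U:

* Ohnesorge number  Oh = η / √(γρL)  (equivalently √We / Re); its reciprocal
  Z = 1/Oh is the classical jettability number.
* Weber number      We = ρU²L / γ     (inertia vs. surface tension)
* Reynolds number   Re = ρUL / η      (inertia vs. viscosity)
* Froude number     Fr = U / √(gL)    (inertia vs. gravity)
* Bond number       Bo = ρgL² / γ     (gravity vs. surface tension);
  Bo < 1 means gravity is negligible during droplet spreading.
* Splashing number  K_sp = √(We·√Re); impacts with K_sp below 57.7 do not
  splash significantly.

All quantities are SI internally; :func:`load_fluid_spec` converts common
lab units (mPa·s, mN/m, g/ml, µm) on input.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from os import PathLike
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SPLASHING_THRESHOLD",
    "BOND_GRAVITY_THRESHOLD",
    "InvalidSpecError",
    "FluidJetSpec",
    "DimensionlessProfile",
    "GravimetricCalibration",
    "ohnesorge",
    "weber",
    "reynolds",
    "froude",
    "bond",
    "splashing_parameter",
    "profile",
    "droplet_volume",
    "droplet_velocity",
    "load_fluid_spec",
]

#: Droplet impacts with K_sp at or above this value splash significantly.
SPLASHING_THRESHOLD = 57.7

#: Gravity is negligible during droplet spreading when Bo is below this.
BOND_GRAVITY_THRESHOLD = 1.0


class InvalidSpecError(ValueError):
    """A fluid/jet specification violates a physical positivity constraint."""


@dataclass(frozen=True)
class FluidJetSpec:
    """Physical properties of a bioink and its jetting configuration (SI).

    Parameters
    ----------
    viscosity : float
        Dynamic viscosity η in Pa·s.
    surface_tension : float
        Surface tension γ in N/m.
    density : float
        Fluid density ρ in kg/m³.
    orifice_diameter : float
        Nozzle orifice inner diameter L in m.
    droplet_velocity : float, optional
        Droplet velocity U in m/s. May be zero (Oh, Z and Bo are
        velocity-independent).
    gravity : float, optional
        Gravitational acceleration g in m/s². Default 9.81.
    """

    viscosity: float
    surface_tension: float
    density: float
    orifice_diameter: float
    droplet_velocity: float = 0.0
    gravity: float = 9.81

    def __post_init__(self) -> None:
        for name in ("viscosity", "surface_tension", "density",
                     "orifice_diameter", "gravity"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise InvalidSpecError(f"{name} must be positive, got {value!r}")
        if not (np.isfinite(self.droplet_velocity) and self.droplet_velocity >= 0):
            raise InvalidSpecError(
                f"droplet_velocity must be >= 0, got {self.droplet_velocity!r}"
            )


@dataclass(frozen=True)
class DimensionlessProfile:
    """The full dimensionless-number report for one jet configuration."""

    oh: float
    we: float
    re: float
    fr: float
    bo: float
    z: float
    k_sp: float
    gravity_negligible: bool
    splashing: bool

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class GravimetricCalibration:
    """Droplet volume calibration: weigh a counted burst of droplets.

    The mean per-droplet volume is ``total_mass / (density · droplet_count)``.
    """

    total_mass: float
    droplet_count: int
    density: float

    def __post_init__(self) -> None:
        if self.droplet_count < 1:
            raise InvalidSpecError("droplet_count must be >= 1")
        if not (np.isfinite(self.total_mass) and self.total_mass > 0):
            raise InvalidSpecError("total_mass must be positive")
        if not (np.isfinite(self.density) and self.density > 0):
            raise InvalidSpecError("density must be positive")

    @property
    def per_droplet_volume(self) -> float:
        return self.total_mass / (self.density * self.droplet_count)


def ohnesorge(spec: FluidJetSpec) -> float:
    """Oh = η / √(γρL). Velocity-independent."""
    return spec.viscosity / math.sqrt(
        spec.surface_tension * spec.density * spec.orifice_diameter
    )


def weber(spec: FluidJetSpec) -> float:
    """We = ρU²L / γ."""
    return (
        spec.density * spec.droplet_velocity**2 * spec.orifice_diameter
        / spec.surface_tension
    )


def reynolds(spec: FluidJetSpec) -> float:
    """Re = ρUL / η."""
    return (
        spec.density * spec.droplet_velocity * spec.orifice_diameter
        / spec.viscosity
    )


def froude(spec: FluidJetSpec) -> float:
    """Fr = U / √(gL)."""
    return spec.droplet_velocity / math.sqrt(spec.gravity * spec.orifice_diameter)


def bond(spec: FluidJetSpec) -> float:
    """Bo = ρgL² / γ. Independent of U and η."""
    return (
        spec.density * spec.gravity * spec.orifice_diameter**2
        / spec.surface_tension
    )


def splashing_parameter(spec: FluidJetSpec) -> float:
    """K_sp = √(We·√Re); zero for a resting droplet (U = 0)."""
    return math.sqrt(weber(spec) * math.sqrt(reynolds(spec)))


def profile(spec: FluidJetSpec) -> DimensionlessProfile:
    """Aggregate all printability numbers and classification flags.

    ``gravity_negligible`` is ``Bo < 1``; ``splashing`` is ``K_sp >= 57.7``,
    with the boundary assigned to the splashing side.
    """
    oh = ohnesorge(spec)
    bo = bond(spec)
    k_sp = splashing_parameter(spec)
    return DimensionlessProfile(
        oh=oh,
        we=weber(spec),
        re=reynolds(spec),
        fr=froude(spec),
        bo=bo,
        z=1.0 / oh,
        k_sp=k_sp,
        gravity_negligible=bool(bo < BOND_GRAVITY_THRESHOLD),
        splashing=bool(k_sp >= SPLASHING_THRESHOLD),
    )


def droplet_volume(cal: GravimetricCalibration) -> tuple[float, float]:
    """Per-droplet volume (m³) and equivalent-sphere diameter (m)."""
    volume = cal.per_droplet_volume
    diameter = (6.0 * volume / math.pi) ** (1.0 / 3.0)
    return volume, diameter


def droplet_velocity(
    positions: Sequence[float], frame_interval: float
) -> float:
    """Droplet velocity (m/s) from frame-by-frame displacements.

    Fits a least-squares line to displacement vs. time; the slope is robust
    to per-frame jitter, unlike a two-point difference.

    Parameters
    ----------
    positions : sequence of float
        Displacement of the droplet front in metres, one value per frame.
    frame_interval : float
        Time between consecutive frames in seconds.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 1 or pos.size < 2:
        raise ValueError("need at least two positions to estimate velocity")
    if not frame_interval > 0:
        raise ValueError("frame_interval must be positive")
    t = np.arange(pos.size) * frame_interval
    slope, _ = np.polyfit(t, pos, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# Unit-aware config loading

_UNIT_TABLES: dict[str, dict[str, float]] = {
    "viscosity": {
        "pa·s": 1.0, "pa.s": 1.0, "pa s": 1.0, "pas": 1.0,
        "mpa·s": 1e-3, "mpa.s": 1e-3, "mpa s": 1e-3, "mpas": 1e-3,
        "cp": 1e-3,
    },
    "surface_tension": {
        "n/m": 1.0, "mn/m": 1e-3, "dyn/cm": 1e-3,
    },
    "density": {
        "kg/m^3": 1.0, "kg/m3": 1.0, "kg/m³": 1.0,
        "g/ml": 1e3, "g/cm^3": 1e3, "g/cm3": 1e3, "g/cm³": 1e3,
    },
    "orifice_diameter": {
        "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "μm": 1e-6,
    },
    "droplet_velocity": {
        "m/s": 1.0, "mm/s": 1e-3, "cm/s": 1e-2,
    },
    "gravity": {
        "m/s^2": 1.0, "m/s2": 1.0, "m/s²": 1.0,
    },
}


def _to_si(field: str, raw: Any) -> float:
    """Convert a config entry (bare number, "value unit" string, or
    {"value": v, "units": u} mapping) to SI."""
    if isinstance(raw, (int, float)):
        return float(raw)
    if isinstance(raw, Mapping):
        value, unit = raw.get("value"), raw.get("units")
    elif isinstance(raw, str):
        parts = raw.split(None, 1)
        if len(parts) != 2:
            raise InvalidSpecError(
                f"{field}: cannot parse {raw!r}; expected 'value unit'"
            )
        value, unit = float(parts[0]), parts[1]
    else:
        raise InvalidSpecError(f"{field}: unsupported value {raw!r}")
    table = _UNIT_TABLES[field]
    key = str(unit).strip().lower()
    if key not in table:
        raise InvalidSpecError(
            f"{field}: unknown unit {unit!r}; accepted: {sorted(table)}"
        )
    return float(value) * table[key]


def load_fluid_spec(source: str | PathLike | Mapping[str, Any]) -> FluidJetSpec:
    """Read a :class:`FluidJetSpec` from a YAML/JSON file or mapping.

    Values may be bare numbers (interpreted as SI) or carry lab units, e.g.::

        viscosity: 1.0 mPa.s
        surface_tension: 72.8 mN/m
        density: 0.998 g/ml
        orifice_diameter: 250 um
        droplet_velocity: 2.0 m/s
    """
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(data, Mapping):
            raise InvalidSpecError(f"spec file {source!s} is not a mapping")
    kwargs: dict[str, float] = {}
    for field in ("viscosity", "surface_tension", "density", "orifice_diameter"):
        if field not in data:
            raise InvalidSpecError(f"missing required field {field!r}")
        kwargs[field] = _to_si(field, data[field])
    for field in ("droplet_velocity", "gravity"):
        if field in data:
            kwargs[field] = _to_si(field, data[field])
    return FluidJetSpec(**kwargs)
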