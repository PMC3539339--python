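"""Interface mass-transfer coefficients and D-value (conductance) assembly.

Air-water exchange uses the Southworth empirical two-film formulation: an
air-side coefficient K12 driven by wind and surface flow, and a water-side
coefficient K21 with an exponential wind enhancement above 1.9 m/s.  The
two films combine in series (resistances add).  Sediment resuspension uses
a wind/depth velocity law.  All conductances (D values, mol/(Pa h)) follow
the standard Mackay process definitions: ``D = k * A * Z`` for interfacial
transport, ``D = km * V * Z`` for degradation and ``D = Q * Z`` for
advection; each process flux is then ``D * f`` of the source compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from math import exp, sqrt
from typing import Mapping

from .core import (
    ChemicalProperties,
    LakeEnvironment,
    ZValueSet,
    compartment_volumes,
)

__all__ = [
    "InputError",
    "AssemblyError",
    "TransferConstants",
    "TransferParameters",
    "DValueSet",
    "k12_air_side",
    "k21_water_side",
    "k42r_resuspension",
    "assemble_d_values",
]


class InputError(ValueError):
    """A kinematic input (wind, flow, depth) is outside its valid range."""


class AssemblyError(ValueError):
    """A D-value term came out negative during assembly."""


def k12_air_side(wind_speed: float, surface_flow: float, molar_mass: float) -> float:
    """Air-side air-water mass transfer coefficient, m/h.

    ``K12 = 11.375 * (WS + RS) * (18 / MW) ** 0.5`` with WS, RS in m/s and
    MW in g/mol (the square root rescales water's diffusivity to the
    chemical's by molar mass).
    """
    if wind_speed < 0 or surface_flow < 0:
        raise InputError("wind speed and surface flow must be >= 0")
    if molar_mass <= 0:
        raise InputError("molar mass must be > 0")
    return 11.375 * (wind_speed + surface_flow) * sqrt(18.0 / molar_mass)


def k21_water_side(
    wind_speed: float, surface_flow: float, molar_mass: float, water_depth: float
) -> float:
    """Water-side air-water mass transfer coefficient, m/h.

    ``K21 = 0.2351 * RS**0.969 * (32 / MW)**0.5 * a / hW**0.673`` where the
    wind enhancement is ``a = 1`` for WS <= 1.9 m/s and
    ``a = exp(0.529 * (WS - 1.9))`` above; the two branches meet
    continuously at WS = 1.9 m/s.
    """
    if wind_speed < 0 or surface_flow < 0:
        raise InputError("wind speed and surface flow must be >= 0")
    if molar_mass <= 0:
        raise InputError("molar mass must be > 0")
    if water_depth <= 0:
        raise InputError(f"water depth must be > 0, got {water_depth}")
    enhancement = 1.0 if wind_speed <= 1.9 else exp(0.529 * (wind_speed - 1.9))
    return (
        0.2351
        * surface_flow**0.969
        * sqrt(32.0 / molar_mass)
        * enhancement
        / water_depth**0.673
    )


def k42r_resuspension(wind_speed: float, water_depth: float) -> float:
    """Sediment resuspension velocity ``K42r = 3e-8 * WS / hW``, m/h."""
    if wind_speed < 0:
        raise InputError("wind speed must be >= 0")
    if water_depth <= 0:
        raise InputError(f"water depth must be > 0, got {water_depth}")
    return 3e-8 * wind_speed / water_depth


@dataclass(frozen=True)
class TransferConstants:
    """Static kinetic constants of the interface processes.

    Velocities in m/h.  ``sediment_diffusion_mtc`` may be given directly;
    when ``None`` it is derived as molecular diffusivity over the sediment
    diffusion path length with a porosity correction
    (``Dmol / L4 * porosity**1.5``).
    """

    dry_dep_velocity: float = 10.8
    sedimentation_velocity: float = 0.05
    surface_flow: float = 0.05  # RS, m/s
    molecular_diffusivity: float = 1.8e-6  # m2/h, aqueous
    sediment_diffusion_mtc: float | None = None

    def sediment_mtc(self, env: LakeEnvironment) -> float:
        if self.sediment_diffusion_mtc is not None:
            return self.sediment_diffusion_mtc
        porosity = env.sediment_porewater_fraction
        return self.molecular_diffusivity / env.diffusion_path_length * porosity**1.5


@dataclass(frozen=True)
class TransferParameters:
    """Snapshot of every kinetic coefficient entering the D values at one time.

    ``k12``/``k21``/``k42r`` are the (dynamic) interface coefficients in
    m/h; the deposition/sedimentation velocities and the rain rate are in
    m/h; ``surface_flow`` and ``wind_speed`` are in m/s.
    """

    k12: float
    k21: float
    k42r: float
    dry_dep_velocity: float
    rain_rate: float
    sedimentation_velocity: float
    sediment_diffusion_mtc: float
    surface_flow: float = 0.0
    wind_speed: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise InputError(f"{f.name} must be >= 0, got {getattr(self, f.name)}")

    @classmethod
    def from_conditions(
        cls,
        constants: TransferConstants,
        chem: ChemicalProperties,
        env: LakeEnvironment,
        wind_speed: float,
        water_depth: float,
        rain_rate: float,
        k12: float | None = None,
        k21: float | None = None,
        k42r: float | None = None,
    ) -> "TransferParameters":
        """Build a snapshot, deriving K12/K21/K42r from wind and depth unless supplied."""
        rs = constants.surface_flow
        return cls(
            k12=k12 if k12 is not None else k12_air_side(wind_speed, rs, chem.molar_mass),
            k21=k21
            if k21 is not None
            else k21_water_side(wind_speed, rs, chem.molar_mass, water_depth),
            k42r=k42r if k42r is not None else k42r_resuspension(wind_speed, water_depth),
            dry_dep_velocity=constants.dry_dep_velocity,
            rain_rate=rain_rate,
            sedimentation_velocity=constants.sedimentation_velocity,
            sediment_diffusion_mtc=constants.sediment_mtc(env),
            surface_flow=rs,
            wind_speed=wind_speed,
        )


@dataclass(frozen=True)
class DValueSet:
    """All transport/transformation conductances (mol/(Pa h)) and advective inputs (mol/h).

    Naming: first index = source compartment, second = destination
    (0 = outside, 1 = air, 2 = water, 4 = sediment); the trailing letter is
    the process (d diffusion, p dry deposition, w wet particle scavenging,
    r rain dissolution / resuspension, s sedimentation, m degradation,
    t advection, h wastewater / withdrawal).
    """

    d12d: float
    d12p: float
    d12w: float
    d12r: float
    d21d: float
    d24d: float
    d24s: float
    d42d: float
    d42r: float
    d10m: float
    d20m: float
    d40m: float
    d10t: float
    d20t: float
    d23h: float
    t01t: float = 0.0
    t02t: float = 0.0
    t02h: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value < 0:
                raise AssemblyError(f"term {f.name} is negative: {value}")

    @property
    def air_loss_total(self) -> float:
        """Sum of all first-order losses from air, mol/(Pa h)."""
        return self.d12d + self.d12p + self.d12w + self.d12r + self.d10m + self.d10t

    @property
    def water_loss_total(self) -> float:
        return self.d21d + self.d24d + self.d24s + self.d20m + self.d20t + self.d23h

    @property
    def sediment_loss_total(self) -> float:
        return self.d42d + self.d42r + self.d40m


def _two_film(k_air: float, z_air: float, k_water: float, z_water: float, area: float) -> float:
    """Series-resistance diffusion conductance across the air-water interface."""
    g_air = k_air * z_air
    g_water = k_water * z_water
    if g_air <= 0.0 or g_water <= 0.0:
        return 0.0
    return area / (1.0 / g_air + 1.0 / g_water)


def assemble_d_values(
    chem: ChemicalProperties,
    env: LakeEnvironment,
    z: ZValueSet,
    tp: TransferParameters,
    snapshot: Mapping[str, float] | None = None,
) -> DValueSet:
    """Assemble every conductance and advective input of the balance equations.

    ``env`` must already reflect the dynamic state (water depth, aerosol and
    suspended fractions) for the time point; ``snapshot`` supplies the
    advection volumes ``q01t``/``q10t``/``q02t``/``q20t``/``q23h``/``q02h``
    (m3/h) and carried concentrations ``c_air_in``/``c_water_in``/
    ``c_wastewater`` (mol/m3), all defaulting to zero.
    """
    snap = dict(snapshot or {})

    def q(key: str) -> float:
        value = snap.get(key, 0.0)
        if value < 0:
            raise AssemblyError(f"term {key} is negative: {value}")
        return value

    area = env.area
    vol = compartment_volumes(env)
    d_diff_aw = _two_film(tp.k12, z.z_air, tp.k21, z.z_water, area)
    d_diff_ws = tp.sediment_diffusion_mtc * area * z.z_water

    return DValueSet(
        d12d=d_diff_aw,
        d12p=tp.dry_dep_velocity * area * env.aerosol_fraction * z.z_aerosol,
        d12w=tp.rain_rate * env.scavenging_ratio * env.aerosol_fraction * area * z.z_aerosol,
        d12r=tp.rain_rate * area * z.z_water,
        d21d=d_diff_aw,
        d24d=d_diff_ws,
        d24s=tp.sedimentation_velocity * area * env.suspended_fraction * z.z_suspended,
        d42d=d_diff_ws,
        d42r=tp.k42r * area * z.z_sediment_solid,
        d10m=chem.km_air * vol.air * z.z_bulk_air,
        d20m=chem.km_water * vol.water * z.z_bulk_water,
        d40m=chem.km_sediment * vol.sediment * z.z_bulk_sediment,
        d10t=q("q10t") * z.z_bulk_air,
        d20t=q("q20t") * z.z_bulk_water,
        d23h=q("q23h") * z.z_water,
        t01t=q("q01t") * q("c_air_in"),
        t02t=q("q02t") * q("c_water_in"),
        t02h=q("q02h") * q("c_wastewater"),
    )
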