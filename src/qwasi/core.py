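"""Domain types, temperature correction and fugacity capacities (Z values).

The fugacity framework expresses the concentration of a chemical in any
phase as ``C = f * Z`` where ``f`` (Pa) is the escaping tendency and ``Z``
(mol/(m3 Pa)) the phase's fugacity capacity.  Z values follow the standard
Mackay conventions:

* air (gaseous):         ``Z = 1 / (R * T_K)``
* water (dissolved):     ``Z = 1 / H(T)``
* organic-carbon solids: ``Z = Koc * oc * rho / 1000 / H(T)``
* aerosol:               ``Z = 6e6 / (Ps_L(T) * R * T_K)`` (Junge-type,
  vapor-pressure based)

Bulk compartment capacities are the volume-fraction weighted sums of their
sub-phase capacities.  Temperature dependence of Henry's constant and the
(subcooled liquid) vapor pressure is handled with a log-linear correction
anchored at 25 degC.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "R_GAS",
    "InvalidPropertyError",
    "ChemicalProperties",
    "LakeEnvironment",
    "ZValueSet",
    "Volumes",
    "correct_for_temperature",
    "compute_z_values",
    "compartment_volumes",
]

#: Ideal gas constant, Pa m3 / (mol K)
R_GAS = 8.314


class InvalidPropertyError(ValueError):
    """A physicochemical property is outside its physically valid range."""


@dataclass(frozen=True)
class ChemicalProperties:
    """Physicochemical constants of the pollutant.

    Parameters
    ----------
    molar_mass:
        Molar mass MW, g/mol.
    henry_25:
        Henry's law constant H at 25 degC, Pa m3/mol.
    vapor_pressure_25:
        Subcooled-liquid saturation vapor pressure Ps at 25 degC, Pa.
    koc:
        Organic-carbon partition coefficient Koc, L/kg.
    km_air, km_water, km_sediment:
        First-order degradation rate constants (k_m1, k_m2, k_m4), 1/h.
    temp_coeff_henry:
        Log-linear temperature-correction slope A for H, K.
    temp_coeff_vp:
        Log-linear temperature-correction slope A for Ps, K.
    temp_coeff_fugacity_ratio:
        Optional third correction slope (fugacity ratio); defaults to 0 and
        is folded into the H(T) dependence when left at 0.
    """

    molar_mass: float
    henry_25: float
    vapor_pressure_25: float
    koc: float
    km_air: float = 0.0
    km_water: float = 0.0
    km_sediment: float = 0.0
    temp_coeff_henry: float = 0.0
    temp_coeff_vp: float = 0.0
    temp_coeff_fugacity_ratio: float = 0.0

    def __post_init__(self) -> None:
        for name in ("molar_mass", "henry_25", "vapor_pressure_25", "koc"):
            if getattr(self, name) <= 0:
                raise InvalidPropertyError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("km_air", "km_water", "km_sediment"):
            if getattr(self, name) < 0:
                raise InvalidPropertyError(f"{name} must be >= 0, got {getattr(self, name)}")

    def henry_at(self, temperature_c: float) -> float:
        """Henry's constant at ``temperature_c`` (degC), Pa m3/mol."""
        return correct_for_temperature(self.henry_25, self.temp_coeff_henry, temperature_c)

    def vapor_pressure_at(self, temperature_c: float) -> float:
        """Subcooled-liquid vapor pressure at ``temperature_c`` (degC), Pa."""
        return correct_for_temperature(self.vapor_pressure_25, self.temp_coeff_vp, temperature_c)


@dataclass(frozen=True)
class LakeEnvironment:
    """Static lake geometry and sub-phase composition.

    Areas in m2, depths/heights in m, densities in kg/m3; the fractions are
    dimensionless volume (X) or mass (oc) fractions.  ``water_depth`` holds
    the static default; the dynamic hourly depth comes from the forcing set.
    """

    area: float
    air_height: float
    water_depth: float
    sediment_depth: float
    aerosol_fraction: float  # X13, v/v in air
    suspended_fraction: float  # X23, v/v in water
    sediment_solid_fraction: float  # X43, v/v in sediment
    oc_suspended: float  # O23, g OC / g solid
    oc_sediment: float  # O43
    solid_density_suspended: float  # r23
    solid_density_sediment: float  # r43
    diffusion_path_length: float  # L4, m
    scavenging_ratio: float  # Sc
    solid_density_aerosol: float = 1500.0  # r13, used only for mass-based reporting

    def __post_init__(self) -> None:
        positive = (
            "area",
            "air_height",
            "water_depth",
            "sediment_depth",
            "solid_density_suspended",
            "solid_density_sediment",
            "solid_density_aerosol",
            "diffusion_path_length",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidPropertyError(f"{name} must be > 0, got {getattr(self, name)}")
        fractions = (
            "aerosol_fraction",
            "suspended_fraction",
            "sediment_solid_fraction",
            "oc_suspended",
            "oc_sediment",
        )
        for name in fractions:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidPropertyError(f"{name} must lie in [0, 1], got {value}")
        if self.scavenging_ratio < 0:
            raise InvalidPropertyError("scavenging_ratio must be >= 0")

    @property
    def sediment_porewater_fraction(self) -> float:
        """Porewater volume fraction; complements the solid fraction to 1."""
        return 1.0 - self.sediment_solid_fraction


@dataclass(frozen=True)
class ZValueSet:
    """Fugacity capacities, mol/(m3 Pa), for sub-phases and bulk compartments."""

    z_air: float
    z_water: float
    z_aerosol: float
    z_suspended: float
    z_sediment_solid: float
    z_bulk_air: float
    z_bulk_water: float
    z_bulk_sediment: float

    def __post_init__(self) -> None:
        for name in (
            "z_air",
            "z_water",
            "z_aerosol",
            "z_suspended",
            "z_sediment_solid",
            "z_bulk_air",
            "z_bulk_water",
            "z_bulk_sediment",
        ):
            if getattr(self, name) <= 0:
                raise InvalidPropertyError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class Volumes:
    """Compartment and sub-phase volumes, m3."""

    air: float
    water: float
    sediment: float
    aerosol: float
    suspended: float
    sediment_solid: float
    porewater: float


def correct_for_temperature(p25: float, slope_k: float, temperature_c: float) -> float:
    """Correct a property from 25 degC to ``temperature_c``.

    Implements the log-linear van't Hoff / Clausius-Clapeyron style form

        log10 P(T) = log10 P(25) + A * (1/298 - 1/(T + 273))

    where ``A`` (``slope_k``, in K) is the property-specific slope.  The
    reference temperatures use the 273/298 offsets of the published
    empirical form (not 273.15/298.15); the discrepancy is below 0.06 %.
    """
    if p25 <= 0:
        raise InvalidPropertyError(f"property value at 25 degC must be > 0, got {p25}")
    if temperature_c <= -273:
        raise InvalidPropertyError(f"temperature must exceed -273 degC, got {temperature_c}")
    return p25 * 10.0 ** (slope_k * (1.0 / 298.0 - 1.0 / (temperature_c + 273.0)))


def compute_z_values(
    chem: ChemicalProperties, env: LakeEnvironment, temperature_c: float
) -> ZValueSet:
    """Fugacity capacities of every sub-phase and bulk compartment at T (degC).

    Henry's constant and the vapor pressure are first corrected to the given
    temperature.  Koc is in L/kg and densities in kg/m3, so the sorbed-phase
    capacity carries a 1e-3 m3/L conversion:
    ``Z_solid = Koc * oc * rho * 1e-3 / H(T)``.
    """
    t_kelvin = temperature_c + 273.15
    henry = chem.henry_at(temperature_c)
    vp = chem.vapor_pressure_at(temperature_c)
    if henry <= 0 or vp <= 0:
        raise InvalidPropertyError("temperature-corrected H and Ps must be > 0")

    z_air = 1.0 / (R_GAS * t_kelvin)
    z_water = 1.0 / henry
    z_suspended = chem.koc * env.oc_suspended * env.solid_density_suspended * 1e-3 / henry
    z_sediment_solid = chem.koc * env.oc_sediment * env.solid_density_sediment * 1e-3 / henry
    z_aerosol = 6e6 / (vp * R_GAS * t_kelvin)

    x13 = env.aerosol_fraction
    x23 = env.suspended_fraction
    x43 = env.sediment_solid_fraction
    return ZValueSet(
        z_air=z_air,
        z_water=z_water,
        z_aerosol=z_aerosol,
        z_suspended=z_suspended,
        z_sediment_solid=z_sediment_solid,
        z_bulk_air=(1.0 - x13) * z_air + x13 * z_aerosol,
        z_bulk_water=(1.0 - x23) * z_water + x23 * z_suspended,
        z_bulk_sediment=(1.0 - x43) * z_water + x43 * z_sediment_solid,
    )


def compartment_volumes(env: LakeEnvironment, water_depth: float | None = None) -> Volumes:
    """Bulk and sub-phase volumes; ``water_depth`` overrides the static default."""
    h2 = env.water_depth if water_depth is None else water_depth
    if h2 <= 0:
        raise InvalidPropertyError(f"water depth must be > 0, got {h2}")
    v_air = env.area * env.air_height
    v_water = env.area * h2
    v_sediment = env.area * env.sediment_depth
    return Volumes(
        air=v_air,
        water=v_water,
        sediment=v_sediment,
        aerosol=v_air * env.aerosol_fraction,
        suspended=v_water * env.suspended_fraction,
        sediment_solid=v_sediment * env.sediment_solid_fraction,
        porewater=v_sediment * env.sediment_porewater_fraction,
    )
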