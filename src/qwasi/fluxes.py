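"""Concentrations, process fluxes, and monthly/annual budget aggregation.

Concentrations follow the fugacity identity ``C = f * Z`` (mol/m3),
converted to the field's customary reporting units: pg/m3 for gaseous and
aerosol-bound air, pg/L for dissolved water, and ng/g (dry mass, via the
solid density) for the particulate phases.  Process fluxes are ``D * f`` of
the source compartment (mol/h); advective inputs pass through.  The ledger
aggregates per-step fluxes to time-weighted monthly means plus an annual
row, with t/a conversions based on an 8760-hour year.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ChemicalProperties, LakeEnvironment, ZValueSet
from .solver import FLUX_NAMES, FugacityState, Trajectory
from .transfer import DValueSet

__all__ = [
    "ConcentrationRecord",
    "FluxLedger",
    "concentrations_from_fugacity",
    "instantaneous_fluxes",
    "aggregate_fluxes",
    "mol_per_hour_to_tonnes_per_year",
    "interface_net_flux",
    "concentration_series",
    "monthly_mean_concentrations",
]

HOURS_PER_YEAR = 8760.0

#: Gains minus losses per interface, by flux name.
_INTERFACES = {
    "air-water": (("t12d", "t12p", "t12w", "t12r"), ("t21d",)),
    "water-sediment": (("t24d", "t24s"), ("t42d", "t42r")),
}


@dataclass(frozen=True)
class ConcentrationRecord:
    """Sub-phase concentrations derived from one fugacity state."""

    air_gaseous_pg_m3: float
    air_aerosol_pg_m3: float  # per m3 of air
    air_aerosol_ng_g: float  # per g of particle
    water_dissolved_pg_L: float
    suspended_ng_g: float
    sediment_solid_ng_g: float
    t: int = 0


def concentrations_from_fugacity(
    state: FugacityState,
    z: ZValueSet,
    chem: ChemicalProperties,
    env: LakeEnvironment,
) -> ConcentrationRecord:
    """Convert a fugacity state to reporting-unit concentrations.

    ``f * z`` gives mol per m3 of the sub-phase; multiplying by the molar
    mass gives g/m3, then unit factors (1e12 pg/g; 1e9 pg per g per 1000 L;
    division by solid density for dry-mass basis) produce the customary
    units.  Aerosol content is reported both per air volume (via X13) and
    per particle mass.
    """
    mw = chem.molar_mass
    g_m3_gas = state.f1 * z.z_air * mw
    g_m3_aerosol = state.f1 * z.z_aerosol * mw  # per m3 of aerosol
    g_m3_dissolved = state.f2 * z.z_water * mw
    g_m3_suspended = state.f2 * z.z_suspended * mw
    g_m3_sediment = state.f4 * z.z_sediment_solid * mw
    return ConcentrationRecord(
        air_gaseous_pg_m3=g_m3_gas * 1e12,
        air_aerosol_pg_m3=g_m3_aerosol * env.aerosol_fraction * 1e12,
        air_aerosol_ng_g=g_m3_aerosol / env.solid_density_aerosol * 1e6,
        water_dissolved_pg_L=g_m3_dissolved * 1e9,
        suspended_ng_g=g_m3_suspended / env.solid_density_suspended * 1e6,
        sediment_solid_ng_g=g_m3_sediment / env.solid_density_sediment * 1e6,
        t=state.t,
    )


def instantaneous_fluxes(state: FugacityState, d: DValueSet) -> dict[str, float]:
    """All process fluxes (mol/h) at one instant: ``D * f`` of the source."""
    return {
        "t01t": d.t01t,
        "t02t": d.t02t,
        "t02h": d.t02h,
        "t10t": d.d10t * state.f1,
        "t12d": d.d12d * state.f1,
        "t12p": d.d12p * state.f1,
        "t12w": d.d12w * state.f1,
        "t12r": d.d12r * state.f1,
        "t10m": d.d10m * state.f1,
        "t21d": d.d21d * state.f2,
        "t24d": d.d24d * state.f2,
        "t24s": d.d24s * state.f2,
        "t20m": d.d20m * state.f2,
        "t20t": d.d20t * state.f2,
        "t23h": d.d23h * state.f2,
        "t42d": d.d42d * state.f4,
        "t42r": d.d42r * state.f4,
        "t40m": d.d40m * state.f4,
    }


def mol_per_hour_to_tonnes_per_year(x: float, molar_mass: float) -> float:
    """Convert a flux from mol/h to t/a: ``x * 8760 * MW / 1e6``."""
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be > 0, got {molar_mass}")
    return x * HOURS_PER_YEAR * molar_mass / 1e6


@dataclass(frozen=True)
class FluxLedger:
    """Per-period process-flux budget.

    ``table`` holds time-weighted mean fluxes in mol/h, one row per month
    of the simulation window plus an ``"annual"`` row (the mean over the
    whole window), one column per flux name.
    """

    table: pd.DataFrame
    molar_mass: float

    def __post_init__(self) -> None:
        if (self.table[list(FLUX_NAMES)] < 0).any().any():
            raise ValueError("flux magnitudes must be >= 0")

    def to_tonnes_per_year(self) -> pd.DataFrame:
        """The same budget expressed as t/a rates (8760 h year)."""
        return self.table * HOURS_PER_YEAR * self.molar_mass / 1e6

    def net_input(self, period: str = "annual") -> float:
        """Total external input rate, mol/h (advection + wastewater)."""
        row = self.table.loc[period]
        return float(row["t01t"] + row["t02t"] + row["t02h"])

    def net_output(self, period: str = "annual") -> float:
        """Total external output rate, mol/h (advection, withdrawal, degradation)."""
        row = self.table.loc[period]
        return float(
            row["t10t"] + row["t20t"] + row["t23h"] + row["t10m"] + row["t20m"] + row["t40m"]
        )


def aggregate_fluxes(traj: Trajectory, molar_mass: float) -> FluxLedger:
    """Aggregate per-step fluxes into monthly means plus an annual row."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    frame = pd.DataFrame(
        {name: traj.fluxes[name] for name in FLUX_NAMES}, index=traj.hours
    )
    frame["_month"] = traj.month_of_hour
    monthly = frame.groupby("_month").mean()
    monthly.index = pd.Index(traj.month_labels, name="period")
    annual = frame.drop(columns="_month").mean().to_frame().T
    annual.index = pd.Index(["annual"], name="period")
    return FluxLedger(table=pd.concat([monthly, annual]), molar_mass=molar_mass)


def interface_net_flux(ledger: FluxLedger, interface: str) -> pd.Series:
    """Signed monthly net flux across an interface, mol/h.

    Positive values mean net transfer from air to water (``"air-water"``)
    or from water to sediment (``"water-sediment"``).
    """
    if interface not in _INTERFACES:
        raise ValueError(
            f"unknown interface {interface!r}; expected one of {sorted(_INTERFACES)}"
        )
    gains, losses = _INTERFACES[interface]
    table = ledger.table.drop(index="annual")
    net = table[list(gains)].sum(axis=1) - table[list(losses)].sum(axis=1)
    net.name = interface
    return net


def concentration_series(
    traj: Trajectory, chem: ChemicalProperties, env: LakeEnvironment
) -> pd.DataFrame:
    """Hourly sub-phase concentrations along a trajectory (reporting units)."""
    mw = chem.molar_mass
    z = traj.z
    data = {
        "air_gaseous_pg_m3": traj.f1 * z["z_air"] * mw * 1e12,
        "air_aerosol_ng_g": traj.f1 * z["z_aerosol"] * mw / env.solid_density_aerosol * 1e6,
        "water_dissolved_pg_L": traj.f2 * z["z_water"] * mw * 1e9,
        "suspended_ng_g": traj.f2 * z["z_suspended"] * mw / env.solid_density_suspended * 1e6,
        "sediment_solid_ng_g": traj.f4
        * z["z_sediment_solid"]
        * mw
        / env.solid_density_sediment
        * 1e6,
    }
    return pd.DataFrame(data, index=traj.hours)


def monthly_mean_concentrations(
    traj: Trajectory, chem: ChemicalProperties, env: LakeEnvironment
) -> pd.DataFrame:
    """Monthly mean concentrations of the three main phases.

    Columns: ``air`` (gaseous, pg/m3), ``water`` (dissolved, pg/L),
    ``sediment`` (solids, ng/g) — the outputs subjected to sensitivity and
    uncertainty analysis.
    """
    series = concentration_series(traj, chem, env)
    frame = pd.DataFrame(
        {
            "air": series["air_gaseous_pg_m3"],
            "water": series["water_dissolved_pg_L"],
            "sediment": series["sediment_solid_ng_g"],
            "_month": traj.month_of_hour,
        },
        index=traj.hours,
    )
    out = frame.groupby("_month").mean()
    out.index = pd.Index(traj.month_labels, name="month")
    return out
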