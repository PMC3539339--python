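"""Level IV (unsteady-state) solver for the three-compartment fugacity balance.

The coupled balance equations for the air (1), water (2) and sediment (4)
fugacities are

    V1*Z1 * df1/dt = T01t - (D12d+D12p+D12r+D12w+D10m+D10t)*f1 + D21d*f2
    V2*Z2 * df2/dt = T02t + T02h + (D12d+D12p+D12w+D12r)*f1
                     - (D21d+D24d+D24s+D20m+D20t+D23h)*f2 + (D42d+D42r)*f4
    V4*Z4 * df4/dt = (D24d+D24s)*f2 - (D42d+D42r+D40m)*f4

and are advanced with the classical fourth-order Runge-Kutta scheme at a
one-hour step.  Within each hour all forcings are constant (zero-order
hold), so the system is linear with constant coefficients over the step;
Z and D values are refreshed from the held forcings every step.  Process
fluxes are recorded against the RK4 stage-averaged fugacity, which makes
the discrete ledger close the compartment mass balances to rounding error.

A steady-state linear solver (the Level III balance for frozen forcings)
provides the default initial condition and serves as an independent oracle
for long constant-forcing runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    ChemicalProperties,
    LakeEnvironment,
    Volumes,
    ZValueSet,
    compute_z_values,
    compartment_volumes,
)
from .forcing import ForcingSet
from .transfer import (
    DValueSet,
    TransferConstants,
    TransferParameters,
    assemble_d_values,
)

__all__ = [
    "NumericalError",
    "SingularSystemError",
    "FugacityState",
    "Trajectory",
    "rhs",
    "rk4_step",
    "steady_state",
    "simulate",
    "FLUX_NAMES",
]


class NumericalError(RuntimeError):
    """The integration produced a non-finite state."""


class SingularSystemError(ValueError):
    """The steady-state loss matrix is singular (a compartment has no losses)."""


#: Every process flux tracked by the ledger, mol/h.
FLUX_NAMES = (
    "t01t",
    "t10t",
    "t12d",
    "t12p",
    "t12w",
    "t12r",
    "t21d",
    "t24d",
    "t24s",
    "t42d",
    "t42r",
    "t02t",
    "t20t",
    "t02h",
    "t23h",
    "t10m",
    "t20m",
    "t40m",
)


@dataclass(frozen=True)
class FugacityState:
    """Compartment fugacities (Pa) at hour index ``t``."""

    f1: float
    f2: float
    f4: float
    t: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f4])


@dataclass(frozen=True)
class Trajectory:
    """Hourly solution of the dynamic balance plus per-step ledger inputs.

    ``f1``/``f2``/``f4`` hold the state at the *end* of each hourly step
    (one entry per forcing hour).  ``fluxes`` maps each process flux name to
    its per-step value in mol/h, evaluated at the RK4 stage-averaged
    fugacity so that per-compartment budgets close exactly.  ``vz`` holds
    the V*Z products (mol/Pa) used during each step, and ``z`` the
    sub-phase fugacity capacities, for concentration conversion.
    """

    hours: pd.DatetimeIndex
    initial: FugacityState
    f1: np.ndarray
    f2: np.ndarray
    f4: np.ndarray
    fluxes: dict[str, np.ndarray]
    vz: dict[str, np.ndarray]  # keys: air, water, sediment
    z: dict[str, np.ndarray]  # per-step sub-phase capacities
    temperature: np.ndarray
    month_of_hour: np.ndarray
    month_labels: list[str]

    def __len__(self) -> int:
        return len(self.hours)

    @property
    def states(self) -> list[FugacityState]:
        return [
            FugacityState(a, b, c, t)
            for t, (a, b, c) in enumerate(zip(self.f1, self.f2, self.f4))
        ]

    def inventory_change(self) -> float:
        """Total chemical inventory change over the window, mol.

        Computed as the per-step sum of ``V*Z*df`` with that step's V*Z —
        the quantity the discrete balance equations actually conserve.
        """
        prev1, prev2, prev4 = self.initial.f1, self.initial.f2, self.initial.f4
        total = 0.0
        for k in range(len(self)):
            total += self.vz["air"][k] * (self.f1[k] - prev1)
            total += self.vz["water"][k] * (self.f2[k] - prev2)
            total += self.vz["sediment"][k] * (self.f4[k] - prev4)
            prev1, prev2, prev4 = self.f1[k], self.f2[k], self.f4[k]
        return total

    def to_frame(self) -> pd.DataFrame:
        """Fugacities and fluxes on the hourly axis."""
        data = {"f1": self.f1, "f2": self.f2, "f4": self.f4}
        data.update(self.fluxes)
        return pd.DataFrame(data, index=self.hours)


def rhs(
    state: FugacityState, d: DValueSet, z: ZValueSet, volumes: Volumes
) -> tuple[float, float, float]:
    """Time derivatives (df1/dt, df2/dt, df4/dt) in Pa/h.

    Advection out of the air (``D10t * f1``) is treated as a loss alongside
    the other air-side D terms.
    """
    vz1 = volumes.air * z.z_bulk_air
    vz2 = volumes.water * z.z_bulk_water
    vz4 = volumes.sediment * z.z_bulk_sediment
    if vz1 <= 0 or vz2 <= 0 or vz4 <= 0:
        raise SingularSystemError("every compartment needs a positive V*Z product")
    df1 = (d.t01t - d.air_loss_total * state.f1 + d.d21d * state.f2) / vz1
    df2 = (
        d.t02t
        + d.t02h
        + (d.d12d + d.d12p + d.d12w + d.d12r) * state.f1
        - d.water_loss_total * state.f2
        + (d.d42d + d.d42r) * state.f4
    ) / vz2
    df4 = ((d.d24d + d.d24s) * state.f2 - d.sediment_loss_total * state.f4) / vz4
    return df1, df2, df4


def rk4_step(
    state: FugacityState,
    dt: float,
    rhs_fn: Callable[[FugacityState], Sequence[float]],
) -> FugacityState:
    """One classical fourth-order Runge-Kutta step of size ``dt`` hours.

    Tiny negative results (possible for stiff steps) are clipped to zero
    with a warning; non-finite derivatives abort with the time stamp.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    y = np.asarray([state.f1, state.f2, state.f4], dtype=float)
    k1 = np.asarray(rhs_fn(replace(state, f1=y[0], f2=y[1], f4=y[2])), dtype=float)
    s2 = y + 0.5 * dt * k1
    k2 = np.asarray(rhs_fn(replace(state, f1=s2[0], f2=s2[1], f4=s2[2])), dtype=float)
    s3 = y + 0.5 * dt * k2
    k3 = np.asarray(rhs_fn(replace(state, f1=s3[0], f2=s3[1], f4=s3[2])), dtype=float)
    s4 = y + dt * k3
    k4 = np.asarray(rhs_fn(replace(state, f1=s4[0], f2=s4[1], f4=s4[2])), dtype=float)
    if not np.all(np.isfinite([k1, k2, k3, k4])):
        raise NumericalError(f"non-finite derivative at hour {state.t}")
    y_next = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if np.any(y_next < 0.0):
        warnings.warn(
            f"negative fugacity clipped to zero at hour {state.t}",
            RuntimeWarning,
            stacklevel=2,
        )
        y_next = np.maximum(y_next, 0.0)
    return FugacityState(float(y_next[0]), float(y_next[1]), float(y_next[2]), state.t + 1)


def steady_state(
    d: DValueSet,
    z: ZValueSet,
    volumes: Volumes,
    t01t: float | None = None,
    t02t: float | None = None,
) -> FugacityState:
    """Fugacities solving the frozen-forcing balance (all derivatives zero).

    The advective inputs default to the ones carried by ``d``; ``z`` and
    ``volumes`` are accepted for interface symmetry with :func:`rhs` (the
    V*Z products cancel at steady state).
    """
    del z, volumes  # V*Z divides out when the derivatives vanish
    in1 = d.t01t if t01t is None else t01t
    in2 = (d.t02t if t02t is None else t02t) + d.t02h
    matrix = np.array(
        [
            [d.air_loss_total, -d.d21d, 0.0],
            [-(d.d12d + d.d12p + d.d12w + d.d12r), d.water_loss_total, -(d.d42d + d.d42r)],
            [0.0, -(d.d24d + d.d24s), d.sediment_loss_total],
        ]
    )
    b = np.array([in1, in2, 0.0])
    try:
        f = np.linalg.solve(matrix, b)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(
            "steady-state loss matrix is singular (an isolated compartment has no losses)"
        ) from exc
    return FugacityState(float(f[0]), float(f[1]), float(f[2]), t=0)


def _coefficients_for_hour(
    chem: ChemicalProperties,
    env: LakeEnvironment,
    constants: TransferConstants,
    snap: dict[str, float],
) -> tuple[ZValueSet, DValueSet, Volumes]:
    """Z values, D values and volumes under one zero-order-held snapshot."""
    env_t = replace(
        env,
        water_depth=snap["h2"],
        aerosol_fraction=snap["aerosol_fraction"],
        suspended_fraction=snap["suspended_fraction"],
    )
    z = compute_z_values(chem, env_t, snap["temperature"])
    tp = TransferParameters.from_conditions(
        constants,
        chem,
        env_t,
        wind_speed=snap["wind_speed"],
        water_depth=snap["h2"],
        rain_rate=snap["rain_rate"],
        k12=snap["k12"],
        k21=snap["k21"],
        k42r=snap["k42r"],
    )
    d = assemble_d_values(chem, env_t, z, tp, snap)
    return z, d, compartment_volumes(env_t)


def simulate(
    chem: ChemicalProperties,
    env: LakeEnvironment,
    forcing: ForcingSet,
    constants: TransferConstants | None = None,
    init: FugacityState | str = "steady",
    step_hours: float = 1.0,
) -> Trajectory:
    """Integrate the dynamic balance over the forcing window.

    Each hour the forcings are sampled (zero-order hold), the
    temperature-corrected Z values and the D values are rebuilt, and the
    state advances by RK4 (``step_hours`` must divide one hour; sub-hourly
    steps reuse the held coefficients).  ``init`` is either an explicit
    :class:`FugacityState` or ``"steady"`` for the steady state under the
    first hour's forcings.
    """
    constants = constants or TransferConstants()
    n_sub = max(1, round(1.0 / step_hours))
    if abs(n_sub * step_hours - 1.0) > 1e-9:
        raise ValueError(f"step_hours must divide one hour exactly, got {step_hours}")
    dt = 1.0 / n_sub

    n = forcing.n_hours
    day_of_hour = np.arange(n) // 24
    expand = forcing.expand_hourly()
    cols = {name: expand[name].to_numpy() for name in expand.columns}

    f1 = np.empty(n)
    f2 = np.empty(n)
    f4 = np.empty(n)
    fluxes = {name: np.empty(n) for name in FLUX_NAMES}
    vz = {"air": np.empty(n), "water": np.empty(n), "sediment": np.empty(n)}
    z_track = {
        name: np.empty(n)
        for name in ("z_air", "z_water", "z_aerosol", "z_suspended", "z_sediment_solid")
    }

    # initial condition from the first hour's coefficients
    snap0 = {name: cols[name][0] for name in cols}
    z0, d0, vol0 = _coefficients_for_hour(chem, env, constants, snap0)
    if isinstance(init, str):
        if init != "steady":
            raise ValueError(f"unknown init mode {init!r}")
        state = steady_state(d0, z0, vol0)
    else:
        state = replace(init, t=0)
    initial = state

    y1, y2, y4 = state.f1, state.f2, state.f4
    clipped = 0
    prev_key: tuple[int, float] | None = None
    z = d = vol = None
    for k in range(n):
        # coefficients change only when the day changes or h2 moves (hourly)
        key = (int(day_of_hour[k]), cols["h2"][k])
        if key != prev_key:
            snap = {name: cols[name][k] for name in cols}
            z, d, vol = _coefficients_for_hour(chem, env, constants, snap)
            vz1 = vol.air * z.z_bulk_air
            vz2 = vol.water * z.z_bulk_water
            vz4 = vol.sediment * z.z_bulk_sediment
            la = d.air_loss_total
            lw = d.water_loss_total
            ls = d.sediment_loss_total
            g21 = d.d12d + d.d12p + d.d12w + d.d12r  # air -> water gains
            g24 = d.d24d + d.d24s
            g42 = d.d42d + d.d42r
            b1 = d.t01t
            b2 = d.t02t + d.t02h
            prev_key = key

        # RK4 on the hour's (constant-coefficient) linear system; the
        # stage-average fugacities make the recorded fluxes close exactly.
        a1sum = a2sum = a4sum = 0.0
        for _ in range(n_sub):
            k1_1 = (b1 - la * y1 + d.d21d * y2) / vz1
            k1_2 = (b2 + g21 * y1 - lw * y2 + g42 * y4) / vz2
            k1_4 = (g24 * y2 - ls * y4) / vz4
            s1, s2_, s4 = y1 + 0.5 * dt * k1_1, y2 + 0.5 * dt * k1_2, y4 + 0.5 * dt * k1_4
            k2_1 = (b1 - la * s1 + d.d21d * s2_) / vz1
            k2_2 = (b2 + g21 * s1 - lw * s2_ + g42 * s4) / vz2
            k2_4 = (g24 * s2_ - ls * s4) / vz4
            u1, u2, u4 = y1 + 0.5 * dt * k2_1, y2 + 0.5 * dt * k2_2, y4 + 0.5 * dt * k2_4
            k3_1 = (b1 - la * u1 + d.d21d * u2) / vz1
            k3_2 = (b2 + g21 * u1 - lw * u2 + g42 * u4) / vz2
            k3_4 = (g24 * u2 - ls * u4) / vz4
            w1, w2, w4 = y1 + dt * k3_1, y2 + dt * k3_2, y4 + dt * k3_4
            k4_1 = (b1 - la * w1 + d.d21d * w2) / vz1
            k4_2 = (b2 + g21 * w1 - lw * w2 + g42 * w4) / vz2
            k4_4 = (g24 * w2 - ls * w4) / vz4
            # stage averages (weights 1,2,2,1)/6 applied to the stage states
            a1sum += (y1 + 2.0 * s1 + 2.0 * u1 + w1) / 6.0
            a2sum += (y2 + 2.0 * s2_ + 2.0 * u2 + w2) / 6.0
            a4sum += (y4 + 2.0 * s4 + 2.0 * u4 + w4) / 6.0
            y1 += dt / 6.0 * (k1_1 + 2.0 * k2_1 + 2.0 * k3_1 + k4_1)
            y2 += dt / 6.0 * (k1_2 + 2.0 * k2_2 + 2.0 * k3_2 + k4_2)
            y4 += dt / 6.0 * (k1_4 + 2.0 * k2_4 + 2.0 * k3_4 + k4_4)

        if not (np.isfinite(y1) and np.isfinite(y2) and np.isfinite(y4)):
            raise NumericalError(f"non-finite state at {forcing.hours[k]}")
        if y1 < 0.0 or y2 < 0.0 or y4 < 0.0:
            clipped += 1
            y1, y2, y4 = max(y1, 0.0), max(y2, 0.0), max(y4, 0.0)

        fa1 = a1sum / n_sub
        fa2 = a2sum / n_sub
        fa4 = a4sum / n_sub
        f1[k], f2[k], f4[k] = y1, y2, y4
        vz["air"][k], vz["water"][k], vz["sediment"][k] = vz1, vz2, vz4
        for name in z_track:
            z_track[name][k] = getattr(z, name)
        fluxes["t01t"][k] = d.t01t
        fluxes["t02t"][k] = d.t02t
        fluxes["t02h"][k] = d.t02h
        fluxes["t10t"][k] = d.d10t * fa1
        fluxes["t12d"][k] = d.d12d * fa1
        fluxes["t12p"][k] = d.d12p * fa1
        fluxes["t12w"][k] = d.d12w * fa1
        fluxes["t12r"][k] = d.d12r * fa1
        fluxes["t10m"][k] = d.d10m * fa1
        fluxes["t21d"][k] = d.d21d * fa2
        fluxes["t24d"][k] = d.d24d * fa2
        fluxes["t24s"][k] = d.d24s * fa2
        fluxes["t20m"][k] = d.d20m * fa2
        fluxes["t20t"][k] = d.d20t * fa2
        fluxes["t23h"][k] = d.d23h * fa2
        fluxes["t42d"][k] = d.d42d * fa4
        fluxes["t42r"][k] = d.d42r * fa4
        fluxes["t40m"][k] = d.d40m * fa4

    if clipped:
        warnings.warn(
            f"{clipped} step(s) produced a negative fugacity and were clipped to zero",
            RuntimeWarning,
            stacklevel=2,
        )

    return Trajectory(
        hours=forcing.hours,
        initial=initial,
        f1=f1,
        f2=f2,
        f4=f4,
        fluxes=fluxes,
        vz=vz,
        z=z_track,
        temperature=cols["temperature"].copy(),
        month_of_hour=forcing.month_of_hour(),
        month_labels=forcing.month_labels(),
    )
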