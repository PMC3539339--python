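"""Local (static) and dynamic sensitivity analysis.

Static parameters are screened with one-at-a-time elementary effects:

* Morris coefficient ``S`` — the mean relative slope over a fixed-step
  perturbation ladder,
  ``S = mean_i [ (Y_{i+1}-Y_i)/Y_0 / ((P_{i+1}-P_i)/100) ]``;
* perturbation coefficient ``Cs = |Y(1.1 p0) - Y(0.9 p0)| / (0.2 Y(p0))``;
* CV-normalised coefficient ``Cn = Cs * CV``, which weights a parameter's
  local slope by its real-world variability.

For linear models S and Cs are exactly 1 regardless of the step size; for
smooth nonlinear models they agree to first order in the step.

Dynamic forcing series get a dynamic sensitivity coefficient ``SCV``: the
series' deviations about its mean are rescaled (mean-preserving) so its
coefficient of variation changes by a known relative amount, the model is
re-run, and SCV is the relative change of the output CV over the relative
change of the input CV.  An output that simply tracks the input gives
SCV = 1; an insensitive output gives 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_STATIC_CV,
    DYNAMIC_PARAMETERS,
    ModelSetup,
    STATIC_PARAMETERS,
)
from .fluxes import monthly_mean_concentrations
from .forcing import DAILY_SERIES, HOURLY_SERIES, MONTHLY_SERIES, ForcingSet
from .solver import simulate

__all__ = [
    "SensitivityResult",
    "morris_index",
    "perturbation_cs",
    "cv_normalized_cn",
    "dynamic_scv",
    "perturb_series_cv",
    "static_sensitivity_table",
    "dynamic_sensitivity_table",
    "compartment_cn_averages",
]

COMPARTMENTS = ("air", "water", "sediment")


@dataclass(frozen=True)
class SensitivityResult:
    """Sensitivity of one output to one parameter."""

    parameter: str
    output: str
    s: float | None = None
    cs: float | None = None
    cv: float | None = None
    cn: float | None = None
    scv: float | None = None

    def __post_init__(self) -> None:
        if self.cs is not None and self.cs < 0:
            raise ValueError("Cs is an absolute value and must be >= 0")
        if self.cn is not None and self.cs is not None and self.cv is not None:
            if self.cn != self.cs * self.cv:
                raise ValueError("Cn must equal Cs * CV exactly")


def morris_index(
    model: Callable[[float], float],
    p0: float,
    n: int = 2,
    step_pct: float = 10.0,
    percents: Sequence[float] | None = None,
) -> float:
    """Morris elementary-effect coefficient over a fixed-step ladder.

    The ladder of parameter values is ``p0 * (1 + P_i/100)`` with
    ``P_i = i * step_pct`` for ``i = 0..n-1`` (or an explicit ``percents``
    sequence).  The baseline ``Y_0 = model(p0)`` normalises every effect.
    """
    if percents is None:
        if n < 2:
            raise ValueError(f"need n >= 2 ladder points, got {n}")
        percents = [i * step_pct for i in range(n)]
    if len(percents) < 2:
        raise ValueError("need at least two ladder points")
    y0 = model(p0)
    if y0 == 0:
        raise ZeroDivisionError("baseline output Y0 is zero; Morris index undefined")
    ys = [model(p0 * (1.0 + p / 100.0)) for p in percents]
    effects = []
    for i in range(len(percents) - 1):
        dp = (percents[i + 1] - percents[i]) / 100.0
        if dp == 0:
            raise ValueError("ladder contains a zero-width step")
        effects.append((ys[i + 1] - ys[i]) / y0 / dp)
    return float(np.mean(effects))


def perturbation_cs(model: Callable[[float], float], p0: float) -> float:
    """Symmetric +/-10 % perturbation coefficient ``|Y1.1 - Y0.9| / (0.2 Y0)``."""
    y0 = model(p0)
    if y0 == 0:
        raise ZeroDivisionError("baseline output Y0 is zero; Cs undefined")
    return abs(model(1.1 * p0) - model(0.9 * p0)) / (0.2 * y0)


def cv_normalized_cn(cs: float, cv: float) -> float:
    """CV-normalised sensitivity ``Cn = Cs * CV``."""
    if cv < 0:
        raise ValueError(f"CV must be >= 0, got {cv}")
    return cs * cv


def perturb_series_cv(
    series: np.ndarray, delta: float, floor: float | None = 0.0
) -> np.ndarray:
    """Mean-preserving rescaling of a series' deviations by ``1 + delta``.

    Increases (or decreases) the coefficient of variation by approximately
    ``delta`` relative; values are clipped at ``floor`` if given, so the
    realised CV change should be measured on the returned series.
    """
    x = np.asarray(series, dtype=float)
    mean = x.mean()
    out = mean + (1.0 + delta) * (x - mean)
    if floor is not None:
        out = np.maximum(out, floor)
    return out


def _cv(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ZeroDivisionError("series mean is zero; CV undefined")
    return float(x.std(ddof=0) / abs(mean))


def dynamic_scv(
    model: Callable[[np.ndarray], np.ndarray],
    base_series: np.ndarray,
    delta: float = 0.1,
    floor: float | None = 0.0,
) -> float:
    """Dynamic sensitivity coefficient of an output series to an input series.

    ``model`` maps the input series to the output series.  The input CV is
    changed by ~``delta`` relative via mean-preserving deviation scaling and
    SCV = (relative change of output CV) / (realised relative change of
    input CV).
    """
    base = np.asarray(base_series, dtype=float)
    cv_x = _cv(base)
    if cv_x == 0:
        raise ZeroDivisionError("input series has zero CV; SCV undefined")
    perturbed = perturb_series_cv(base, delta, floor)
    cv_x_new = _cv(perturbed)
    rel_dx = (cv_x_new - cv_x) / cv_x
    if rel_dx == 0:
        raise ZeroDivisionError("perturbation left the input CV unchanged")
    y_base = np.asarray(model(base), dtype=float)
    y_pert = np.asarray(model(perturbed), dtype=float)
    cv_y = _cv(y_base)
    if cv_y == 0:
        return 0.0
    return float(((_cv(y_pert) - cv_y) / cv_y) / rel_dx)


# ---------------------------------------------------------------------------
# model-level sweeps


def _annual_outputs(setup: ModelSetup, forcing: ForcingSet) -> dict[str, float]:
    """Annual mean concentration of the three main phases."""
    traj = simulate(setup.chem, setup.env, forcing, setup.constants)
    monthly = monthly_mean_concentrations(traj, setup.chem, setup.env)
    return {c: float(monthly[c].mean()) for c in COMPARTMENTS}


def _monthly_outputs(setup: ModelSetup, forcing: ForcingSet) -> pd.DataFrame:
    traj = simulate(setup.chem, setup.env, forcing, setup.constants)
    return monthly_mean_concentrations(traj, setup.chem, setup.env)


def _replace_series(forcing: ForcingSet, series: str, values: np.ndarray) -> ForcingSet:
    if series in HOURLY_SERIES:
        return replace(forcing, h2=np.asarray(values, dtype=float))
    if series in DAILY_SERIES:
        daily = forcing.daily.copy()
        daily[series] = values
        return replace(forcing, daily=daily)
    if series in MONTHLY_SERIES:
        monthly = forcing.monthly.copy()
        monthly[series] = values
        return replace(forcing, monthly=monthly)
    raise KeyError(f"unknown forcing series {series!r}")


def static_sensitivity_table(
    setup: ModelSetup,
    forcing: ForcingSet,
    parameters: Iterable[str] | None = None,
    cvs: dict[str, float] | None = None,
    step_pct: float = 10.0,
) -> pd.DataFrame:
    """One-at-a-time screening of the static parameters.

    Every registered parameter (plus ``C02t``, the river-inflow
    concentration, scaled as a whole series) is perturbed by
    +/- ``step_pct`` % and the Morris ``S``, ``Cs``, assigned ``CV`` and
    ``Cn = Cs * CV`` are reported against the annual mean concentration of
    each main phase.
    """
    cvs = {**DEFAULT_STATIC_CV, **(cvs or {})}
    names = list(parameters) if parameters is not None else [*STATIC_PARAMETERS, "C02t"]
    base_outputs = _annual_outputs(setup, forcing)
    rows = []
    for name in names:
        if name in STATIC_PARAMETERS:
            p0 = setup.get_parameter(name)

            def run(value: float, _name: str = name) -> dict[str, float]:
                return _annual_outputs(setup.with_parameter(_name, value), forcing)

        elif name == "C02t":
            base_series = forcing.monthly["c_water_in"].to_numpy()
            p0 = 1.0  # multiplicative scale of the series

            def run(value: float, _s=base_series) -> dict[str, float]:
                return _annual_outputs(
                    setup, _replace_series(forcing, "c_water_in", _s * value)
                )

        else:
            raise KeyError(f"unknown static parameter {name!r}")

        if p0 == 0:
            continue  # no relative perturbation possible
        step = step_pct / 100.0
        y_up = run(p0 * (1.0 + step))
        y_down = run(p0 * (1.0 - step))
        for compartment in COMPARTMENTS:
            y0 = base_outputs[compartment]
            up, down = y_up[compartment], y_down[compartment]
            # two-point ladder (-step, +step): mean elementary effect
            s = (up - down) / y0 / (2.0 * step)
            cs = abs(up - down) / (2.0 * step * y0)
            cv = cvs.get(name, 0.0)
            rows.append(
                {
                    "parameter": name,
                    "output": compartment,
                    "S": s,
                    "Cs": cs,
                    "CV": cv,
                    "Cn": cs * cv,
                }
            )
    return pd.DataFrame(rows)


def dynamic_sensitivity_table(
    setup: ModelSetup,
    forcing: ForcingSet,
    series: Iterable[str] | None = None,
    delta: float = 0.1,
) -> pd.DataFrame:
    """SCV of the monthly output series to each dynamic forcing series."""
    symbols = dict(DYNAMIC_PARAMETERS)
    if series is not None:
        wanted = set(series)
        symbols = {k: v for k, v in symbols.items() if k in wanted or v in wanted}
    base_monthly = _monthly_outputs(setup, forcing)
    rows = []
    for symbol, name in symbols.items():
        if name in HOURLY_SERIES:
            base = np.asarray(forcing.h2, dtype=float)
            floor = 0.1
        elif name in DAILY_SERIES:
            base = forcing.daily[name].to_numpy(dtype=float)
            floor = None if name == "temperature" else 0.0
        else:
            base = forcing.monthly[name].to_numpy(dtype=float)
            floor = 0.0
        if base.mean() == 0 or base.std(ddof=0) == 0:
            continue  # degenerate series (e.g. all-zero wastewater)
        cv_x = _cv(base)
        perturbed_series = perturb_series_cv(base, delta, floor)
        cv_x_new = _cv(perturbed_series)
        rel_dx = (cv_x_new - cv_x) / cv_x
        if rel_dx == 0:
            continue
        pert_monthly = _monthly_outputs(
            setup, _replace_series(forcing, name, perturbed_series)
        )
        for compartment in COMPARTMENTS:
            cv_y = _cv(base_monthly[compartment].to_numpy())
            if cv_y == 0:
                scv = 0.0
            else:
                cv_y_new = _cv(pert_monthly[compartment].to_numpy())
                scv = ((cv_y_new - cv_y) / cv_y) / rel_dx
            rows.append({"parameter": symbol, "output": compartment, "SCV": scv})
    return pd.DataFrame(rows)


def compartment_cn_averages(table: pd.DataFrame) -> pd.Series:
    """Mean Cn per output compartment (the per-phase summary statistic)."""
    return table.groupby("output")["Cn"].mean()
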