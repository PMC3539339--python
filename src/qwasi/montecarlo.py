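"""Monte Carlo uncertainty propagation with truncated parameter sampling.

Each uncertain parameter carries a distribution: lognormal for every
quantity except temperature, which is normal.  Draws are
rejection-sampled inside a one-dispersion truncation band on the sampling
scale (geometric mean times/divided by the geometric SD for lognormal;
mean +/- SD for normal).  Static parameters get one draw per run; dynamic
(monthly-scoped) parameters get an independent draw per month, applied as
multiplicative factors (additive offsets for temperature) on the base
forcing series.  The ensemble of monthly mean concentrations per
compartment is summarised by the median and the semi-interquartile range
``(Q3 - Q1) / 2`` with linear-interpolation quartiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_STATIC_CV, DYNAMIC_PARAMETERS, ModelSetup, STATIC_PARAMETERS
from .fluxes import monthly_mean_concentrations
from .forcing import DAILY_SERIES, HOURLY_SERIES, ForcingSet
from .sensitivity import COMPARTMENTS
from .solver import simulate

__all__ = [
    "ParameterDistribution",
    "MonteCarloSummary",
    "sample_parameters",
    "apply_draw",
    "run_monte_carlo",
    "summarize_semi_iqr",
    "default_distributions",
    "select_sensitive",
    "recover_km_sediment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution of one uncertain parameter.

    ``central`` is the geometric mean (lognormal) or mean (normal); for
    ``scope="monthly"`` it is interpreted as a multiplicative factor around
    the base series (so 1.0 leaves the series unchanged) or an additive
    offset for normal distributions.  ``dispersion`` is the geometric SD
    (> 1) or the SD (> 0); draws are truncated to central x/ gsd (lognormal)
    or central +/- sd (normal).
    """

    name: str
    kind: str = "lognormal"  # "lognormal" | "normal"
    central: float = 1.0
    dispersion: float = 1.2
    scope: str = "static"  # "static" | "monthly"

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "normal"):
            raise ValueError(f"kind must be 'lognormal' or 'normal', got {self.kind!r}")
        if self.scope not in ("static", "monthly"):
            raise ValueError(f"scope must be 'static' or 'monthly', got {self.scope!r}")
        if self.kind == "lognormal":
            if self.central <= 0:
                raise ValueError(f"{self.name}: lognormal central must be > 0")
            if self.dispersion < 1.0:
                raise ValueError(f"{self.name}: geometric SD must be >= 1")
        elif self.dispersion < 0:
            raise ValueError(f"{self.name}: SD must be >= 0")

    def draw(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Truncated draws (rejection-sampled inside the one-dispersion band)."""
        if self.kind == "lognormal":
            if self.dispersion == 1.0:
                return np.full(size, self.central)
            mu, sigma = np.log(self.central), np.log(self.dispersion)
            lo, hi = mu - sigma, mu + sigma
            out = np.empty(size)
            for i in range(size):
                while True:
                    x = rng.normal(mu, sigma)
                    if lo <= x <= hi:
                        out[i] = np.exp(x)
                        break
            return out
        if self.dispersion == 0.0:
            return np.full(size, self.central)
        lo, hi = self.central - self.dispersion, self.central + self.dispersion
        out = np.empty(size)
        for i in range(size):
            while True:
                x = rng.normal(self.central, self.dispersion)
                if lo <= x <= hi:
                    out[i] = x
                    break
        return out


@dataclass(frozen=True)
class MonteCarloSummary:
    """Monthly median and quartile summaries of the MC ensemble.

    Each attribute is a DataFrame indexed by month with one column per
    compartment; ``semi_iqr = (q3 - q1) / 2``.
    """

    median: pd.DataFrame
    q1: pd.DataFrame
    q3: pd.DataFrame
    semi_iqr: pd.DataFrame
    n_runs: int

    def __post_init__(self) -> None:
        if (self.semi_iqr < -1e-15).any().any():
            raise ValueError("semi-interquartile range must be >= 0")
        if (self.q3 < self.q1 - 1e-15).any().any():
            raise ValueError("quartiles must be ordered (Q1 <= Q3)")


def sample_parameters(
    dists: Sequence[ParameterDistribution], rng: np.random.Generator, n_months: int = 1
) -> dict[str, np.ndarray]:
    """One Monte Carlo draw: scalar per static, one value per month otherwise."""
    draw: dict[str, np.ndarray] = {}
    for dist in dists:
        size = n_months if dist.scope == "monthly" else 1
        draw[dist.name] = dist.draw(rng, size)
    return draw


def apply_draw(
    setup: ModelSetup, forcing: ForcingSet, draw: dict[str, np.ndarray],
    dists: Sequence[ParameterDistribution],
) -> tuple[ModelSetup, ForcingSet]:
    """Realise one parameter draw as a perturbed setup and forcing set."""
    kinds = {d.name: d for d in dists}
    daily = forcing.daily.copy()
    monthly = forcing.monthly.copy()
    h2 = np.asarray(forcing.h2, dtype=float).copy()
    month_of_hour = forcing.month_of_hour()
    month_of_day = month_of_hour[::24]
    touched_daily = touched_monthly = touched_h2 = False

    for name, values in draw.items():
        dist = kinds[name]
        if dist.scope == "static":
            if name in STATIC_PARAMETERS:
                setup = setup.with_parameter(name, float(values[0]))
            else:
                raise KeyError(f"unknown static parameter {name!r}")
            continue
        series = DYNAMIC_PARAMETERS.get(name, name)
        additive = dist.kind == "normal"
        if series in HOURLY_SERIES:
            factors = values[month_of_hour]
            h2 = h2 + factors if additive else h2 * factors
            touched_h2 = True
        elif series in DAILY_SERIES:
            factors = values[month_of_day]
            col = daily[series].to_numpy(dtype=float)
            daily[series] = col + factors if additive else col * factors
            touched_daily = True
        elif series in forcing.monthly.columns:
            col = monthly[series].to_numpy(dtype=float)
            monthly[series] = col + values if additive else col * values
            touched_monthly = True
        else:
            raise KeyError(f"unknown dynamic parameter {name!r}")

    if touched_h2:
        forcing = replace(forcing, h2=h2)
    if touched_daily:
        forcing = replace(forcing, daily=daily)
    if touched_monthly:
        forcing = replace(forcing, monthly=monthly)
    return setup, forcing


def summarize_semi_iqr(
    ensemble: np.ndarray, month_labels: Sequence[str],
    compartments: Sequence[str] = COMPARTMENTS,
) -> MonteCarloSummary:
    """Summarise an ensemble array of shape (runs, months, compartments).

    Quartiles use the linear-interpolation convention between order
    statistics (the numpy default).
    """
    ensemble = np.asarray(ensemble, dtype=float)
    if ensemble.ndim != 3 or ensemble.shape[0] < 2:
        raise ValueError("need an ensemble of shape (runs >= 2, months, compartments)")

    def frame(values: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(values, index=list(month_labels), columns=list(compartments))

    q1 = np.quantile(ensemble, 0.25, axis=0)
    q3 = np.quantile(ensemble, 0.75, axis=0)
    return MonteCarloSummary(
        median=frame(np.median(ensemble, axis=0)),
        q1=frame(q1),
        q3=frame(q3),
        semi_iqr=frame((q3 - q1) / 2.0),
        n_runs=ensemble.shape[0],
    )


def run_monte_carlo(
    setup: ModelSetup,
    forcing: ForcingSet,
    dists: Sequence[ParameterDistribution],
    n_runs: int = 2200,
    seed: int = 1,
    return_ensemble: bool = False,
):
    """Propagate parameter uncertainty through ``n_runs`` full simulations.

    Only the parameters listed in ``dists`` (the sensitive subset) are
    varied; everything else stays at its base value.  Failed runs are
    logged and excluded; more than 5 % failures aborts.
    """
    if n_runs < 2:
        raise ValueError(f"need n_runs >= 2, got {n_runs}")
    rng = np.random.default_rng(seed)
    n_months = len(forcing.monthly)
    outputs = []
    failures = 0
    for run in range(n_runs):
        draw = sample_parameters(dists, rng, n_months)
        try:
            setup_i, forcing_i = apply_draw(setup, forcing, draw, dists)
            traj = simulate(setup_i.chem, setup_i.env, forcing_i, setup_i.constants)
            monthly = monthly_mean_concentrations(traj, setup_i.chem, setup_i.env)
            outputs.append(monthly[list(COMPARTMENTS)].to_numpy())
        except Exception as exc:  # noqa: BLE001 - any failed run is excluded
            failures += 1
            logger.warning("Monte Carlo run %d failed: %s", run, exc)
            if failures > 0.05 * n_runs:
                raise RuntimeError(
                    f"more than 5% of Monte Carlo runs failed ({failures}/{run + 1})"
                ) from exc
    ensemble = np.stack(outputs)
    summary = summarize_semi_iqr(ensemble, forcing.month_labels())
    if return_ensemble:
        return summary, ensemble
    return summary


def _cv_to_gsd(cv: float) -> float:
    """Geometric SD of a lognormal with the given coefficient of variation."""
    return float(np.exp(np.sqrt(np.log(1.0 + cv**2))))


def select_sensitive(
    static_table: pd.DataFrame,
    dynamic_table: pd.DataFrame | None = None,
    quantile: float = 0.75,
) -> tuple[list[str], list[str]]:
    """Parameters in the top quantile of Cn (static) and |SCV| (dynamic)."""
    cn = static_table.groupby("parameter")["Cn"].mean()
    static = sorted(cn[cn >= cn.quantile(quantile)].index)
    dynamic: list[str] = []
    if dynamic_table is not None and len(dynamic_table):
        scv = dynamic_table.assign(a=dynamic_table["SCV"].abs()).groupby("parameter")["a"].mean()
        dynamic = sorted(scv[scv >= scv.quantile(quantile)].index)
    return static, dynamic


def default_distributions(
    setup: ModelSetup,
    static_names: Iterable[str] = ("km4", "km2", "h4", "L4", "H25", "Ps25", "O43"),
    dynamic_names: Iterable[str] = ("T", "C1", "Q01t", "K12", "K21", "Kw", "h2"),
    dynamic_gsd: float = 1.2,
    temperature_sd: float = 2.0,
) -> list[ParameterDistribution]:
    """Distributions for a default sensitive-parameter subset.

    Static parameters are lognormal around their base value with a
    geometric SD matched to their assigned CV; dynamic parameters vary as
    monthly lognormal factors (normal additive offsets for temperature).
    """
    dists = [
        ParameterDistribution(
            name=name,
            kind="lognormal",
            central=setup.get_parameter(name),
            dispersion=_cv_to_gsd(DEFAULT_STATIC_CV.get(name, 0.2)),
            scope="static",
        )
        for name in static_names
    ]
    for name in dynamic_names:
        if name == "T":
            dists.append(
                ParameterDistribution(
                    name=name, kind="normal", central=0.0,
                    dispersion=temperature_sd, scope="monthly",
                )
            )
        else:
            dists.append(
                ParameterDistribution(
                    name=name, kind="lognormal", central=1.0,
                    dispersion=dynamic_gsd, scope="monthly",
                )
            )
    return dists


def recover_km_sediment(
    setup: ModelSetup,
    forcing: ForcingSet,
    observed_monthly_sediment: np.ndarray,
    grid_factors: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Recover the sediment degradation rate from monthly observations.

    Grid search over ``km4`` candidates (base value times ``grid_factors``)
    minimising the squared log-concentration error against the observed
    monthly mean sediment concentrations.  Returns the best-fit rate and
    the objective table.
    """
    if grid_factors is None:
        grid_factors = np.exp(np.linspace(np.log(0.4), np.log(2.5), 31))
    obs = np.log(np.asarray(observed_monthly_sediment, dtype=float))
    base = setup.get_parameter("km4")
    rows = []
    for factor in grid_factors:
        candidate = base * float(factor)
        setup_i = setup.with_parameter("km4", candidate)
        traj = simulate(setup_i.chem, setup_i.env, forcing, setup_i.constants)
        monthly = monthly_mean_concentrations(traj, setup_i.chem, setup_i.env)
        pred = np.log(monthly["sediment"].to_numpy())
        rows.append({"km4": candidate, "sse": float(np.sum((pred - obs) ** 2))})
    table = pd.DataFrame(rows)
    best = table.loc[table["sse"].idxmin(), "km4"]
    return float(best), table
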