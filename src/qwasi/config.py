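"""Run configuration: defaults, YAML parsing/validation and the parameter registry.

The default parameterisation targets alpha-hexachlorocyclohexane (alpha-HCH)
in a large shallow lake (Lake Chaohu geometry).  Geometry and sub-phase
fractions are the lake's published morphometry; the physicochemical and
kinetic defaults are generic literature-range values for alpha-HCH, not
site-calibrated measurements, and every one of them can be overridden from
the YAML config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .core import ChemicalProperties, LakeEnvironment
from .forcing import GeneratorConfig
from .transfer import TransferConstants

__all__ = [
    "ConfigError",
    "ModelSetup",
    "RunConfig",
    "default_chemical",
    "default_environment",
    "default_constants",
    "default_config",
    "parse_config",
    "serialize_config",
    "STATIC_PARAMETERS",
    "DEFAULT_STATIC_CV",
    "DYNAMIC_PARAMETERS",
]


class ConfigError(ValueError):
    """The configuration file violates the schema; lists every offending key."""


def default_chemical() -> ChemicalProperties:
    """Generic alpha-HCH physicochemical defaults (literature-range, not site-fitted)."""
    return ChemicalProperties(
        molar_mass=290.83,  # g/mol
        henry_25=0.735,  # Pa m3/mol
        vapor_pressure_25=0.06,  # Pa, subcooled liquid
        koc=1000.0,  # L/kg (log Koc ~ 3)
        km_air=4.8e-4,  # 1/h (~60 d half-life, OH-radical)
        km_water=4.1e-5,  # 1/h (~2 a, hydrolysis + aerobic biodegradation)
        km_sediment=2.9e-4,  # 1/h (~100 d, anaerobic degradation is faster)
        temp_coeff_henry=2600.0,  # K
        temp_coeff_vp=3700.0,  # K
    )


def default_environment() -> LakeEnvironment:
    """Lake Chaohu geometry and sub-phase composition."""
    return LakeEnvironment(
        area=7.5810e8,  # m2
        air_height=100.0,  # m
        water_depth=3.0124,  # m, annual mean
        sediment_depth=0.1,  # m
        aerosol_fraction=7.6278e-11,
        suspended_fraction=1.2631e-5,
        sediment_solid_fraction=0.3,
        oc_suspended=0.167,
        oc_sediment=4.6077e-3,
        solid_density_suspended=2400.0,  # kg/m3
        solid_density_sediment=2400.0,
        diffusion_path_length=5e-3,  # m
        scavenging_ratio=2e5,
    )


def default_constants() -> TransferConstants:
    return TransferConstants()


@dataclass(frozen=True)
class ModelSetup:
    """The static half of a model run: chemical, environment and kinetics."""

    chem: ChemicalProperties = field(default_factory=default_chemical)
    env: LakeEnvironment = field(default_factory=default_environment)
    constants: TransferConstants = field(default_factory=default_constants)

    def get_parameter(self, name: str) -> float:
        block, attr = _resolve(name)
        return getattr(getattr(self, block), attr)

    def with_parameter(self, name: str, value: float) -> "ModelSetup":
        """A copy with one registered static parameter replaced."""
        block, attr = _resolve(name)
        return replace(self, **{block: replace(getattr(self, block), **{attr: value})})


#: Registered static parameters: symbol -> (block, attribute).
STATIC_PARAMETERS: dict[str, tuple[str, str]] = {
    "H25": ("chem", "henry_25"),
    "Ps25": ("chem", "vapor_pressure_25"),
    "Koc": ("chem", "koc"),
    "km1": ("chem", "km_air"),
    "km2": ("chem", "km_water"),
    "km4": ("chem", "km_sediment"),
    "B_H": ("chem", "temp_coeff_henry"),
    "B_ps": ("chem", "temp_coeff_vp"),
    "A2": ("env", "area"),
    "h1": ("env", "air_height"),
    "h4": ("env", "sediment_depth"),
    "X43": ("env", "sediment_solid_fraction"),
    "O23": ("env", "oc_suspended"),
    "O43": ("env", "oc_sediment"),
    "r23": ("env", "solid_density_suspended"),
    "r43": ("env", "solid_density_sediment"),
    "L4": ("env", "diffusion_path_length"),
    "Sc": ("env", "scavenging_ratio"),
    "Ud": ("constants", "dry_dep_velocity"),
    "Us": ("constants", "sedimentation_velocity"),
    "RS": ("constants", "surface_flow"),
}

#: Assigned coefficients of variation for the static parameters (used to
#: normalise sensitivities, Cn = Cs * CV).  Degradation rates, sediment
#: geometry and the diffusion path length carry the largest spread across
#: literature sources; geometry and densities the smallest.
DEFAULT_STATIC_CV: dict[str, float] = {
    "H25": 0.10,
    "Ps25": 0.10,
    "Koc": 0.20,
    "km1": 0.50,
    "km2": 0.80,
    "km4": 0.90,
    "B_H": 0.05,
    "B_ps": 0.05,
    "A2": 0.01,
    "h1": 0.10,
    "h4": 0.50,
    "X43": 0.20,
    "O23": 0.30,
    "O43": 0.30,
    "r23": 0.05,
    "r43": 0.05,
    "L4": 0.60,
    "Sc": 0.10,
    "Ud": 0.30,
    "Us": 0.40,
    "RS": 0.30,
    "C02t": 0.40,
}

#: The fifteen dynamic forcing series (plus the river-inflow concentration)
#: keyed by symbol -> internal series name.
DYNAMIC_PARAMETERS: dict[str, str] = {
    "h2": "h2",
    "T": "temperature",
    "WS": "wind_speed",
    "Kw": "rain_rate",
    "K12": "k12",
    "K21": "k21",
    "K42r": "k42r",
    "X13": "aerosol_fraction",
    "X23": "suspended_fraction",
    "Q01t": "q01t",
    "Q10t": "q10t",
    "Q02t": "q02t",
    "Q20t": "q20t",
    "Q23h": "q23h",
    "Q02h": "q02h",
    "C1": "c_air_in",
    "C02t": "c_water_in",
}


def _resolve(name: str) -> tuple[str, str]:
    if name not in STATIC_PARAMETERS:
        raise KeyError(
            f"unknown static parameter {name!r}; registered: {sorted(STATIC_PARAMETERS)}"
        )
    return STATIC_PARAMETERS[name]


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration of a pipeline run."""

    setup: ModelSetup
    forcing_source: str = "synthetic"  # "synthetic" | "csv"
    forcing_paths: str | None = None  # directory of per-series CSVs
    seed: int = 0
    start: str = "2010-05-01"
    end: str = "2011-02-28"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    step_hours: float = 1.0
    init: str = "steady"
    sensitivity_step_pct: float = 10.0
    mc_runs: int = 2200
    mc_seed: int = 1
    output_dir: str = "qwasi_out"

    def __post_init__(self) -> None:
        problems = []
        if self.forcing_source not in ("synthetic", "csv"):
            problems.append(f"forcing.source must be 'synthetic' or 'csv', got {self.forcing_source!r}")
        if self.forcing_source == "csv":
            if not self.forcing_paths:
                problems.append("forcing.paths is required when forcing.source is 'csv'")
            elif not Path(self.forcing_paths).exists():
                problems.append(f"forcing.paths does not exist: {self.forcing_paths}")
        if self.step_hours <= 0:
            problems.append(f"simulation.step_hours must be > 0, got {self.step_hours}")
        if self.mc_runs < 2:
            problems.append(f"montecarlo.runs must be >= 2, got {self.mc_runs}")
        if problems:
            raise ConfigError("; ".join(problems))


_SECTION_TYPES = {
    "chemical": (ChemicalProperties, "chem"),
    "environment": (LakeEnvironment, "env"),
    "transfer": (TransferConstants, "constants"),
}


def _build_section(cls: type, defaults: Any, data: Mapping[str, Any], section: str, problems: list[str]):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    for key in sorted(unknown):
        problems.append(f"{section}.{key}: unknown key")
    merged = {k: v for k, v in data.items() if k in valid}
    try:
        return replace(defaults, **merged)
    except (ValueError, TypeError) as exc:
        problems.append(f"{section}: {exc}")
        return defaults


def default_config() -> dict[str, Any]:
    """The full default configuration as a plain (YAML-serialisable) mapping."""
    return {
        "chemical": dataclasses.asdict(default_chemical()),
        "environment": dataclasses.asdict(default_environment()),
        "transfer": dataclasses.asdict(default_constants()),
        "forcing": {
            "source": "synthetic",
            "seed": 0,
            "start": "2010-05-01",
            "end": "2011-02-28",
        },
        "simulation": {"step_hours": 1.0, "init": "steady"},
        "sensitivity": {"step_pct": 10.0},
        "montecarlo": {"runs": 2200, "seed": 1},
        "output_dir": "qwasi_out",
    }


def parse_config(source: str | Path | Mapping[str, Any] | None = None) -> RunConfig:
    """Parse and validate a YAML config (path, mapping or ``None`` for defaults).

    Unknown keys, invalid values and missing referenced files are collected
    and reported together in one :class:`ConfigError`.
    """
    if source is None:
        data: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        data = source
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}

    problems: list[str] = []
    known_sections = {
        "chemical",
        "environment",
        "transfer",
        "forcing",
        "generator",
        "simulation",
        "sensitivity",
        "montecarlo",
        "output_dir",
    }
    for key in sorted(set(data) - known_sections):
        problems.append(f"{key}: unknown top-level section")

    chem = _build_section(
        ChemicalProperties, default_chemical(), data.get("chemical", {}) or {}, "chemical", problems
    )
    env = _build_section(
        LakeEnvironment, default_environment(), data.get("environment", {}) or {}, "environment", problems
    )
    constants = _build_section(
        TransferConstants, default_constants(), data.get("transfer", {}) or {}, "transfer", problems
    )
    generator = _build_section(
        GeneratorConfig, GeneratorConfig(), data.get("generator", {}) or {}, "generator", problems
    )

    forcing = data.get("forcing", {}) or {}
    sim = data.get("simulation", {}) or {}
    sens = data.get("sensitivity", {}) or {}
    mc = data.get("montecarlo", {}) or {}
    if problems:
        raise ConfigError("; ".join(problems))

    try:
        return RunConfig(
            setup=ModelSetup(chem=chem, env=env, constants=constants),
            forcing_source=forcing.get("source", "synthetic"),
            forcing_paths=forcing.get("paths"),
            seed=int(forcing.get("seed", 0)),
            start=str(forcing.get("start", "2010-05-01")),
            end=str(forcing.get("end", "2011-02-28")),
            generator=generator,
            step_hours=float(sim.get("step_hours", 1.0)),
            init=str(sim.get("init", "steady")),
            sensitivity_step_pct=float(sens.get("step_pct", 10.0)),
            mc_runs=int(mc.get("runs", 2200)),
            mc_seed=int(mc.get("seed", 1)),
            output_dir=str(data.get("output_dir", "qwasi_out")),
        )
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def serialize_config(config: RunConfig) -> dict[str, Any]:
    """Round-trippable plain mapping for a :class:`RunConfig`."""
    return {
        "chemical": dataclasses.asdict(config.setup.chem),
        "environment": dataclasses.asdict(config.setup.env),
        "transfer": dataclasses.asdict(config.setup.constants),
        "generator": {
            **{
                k: v
                for k, v in dataclasses.asdict(config.generator).items()
                if k not in ("monthly_medians", "monthly_gsd")
            },
            "monthly_medians": dict(config.generator.monthly_medians),
            "monthly_gsd": dict(config.generator.monthly_gsd),
        },
        "forcing": {
            "source": config.forcing_source,
            "paths": config.forcing_paths,
            "seed": config.seed,
            "start": config.start,
            "end": config.end,
        },
        "simulation": {"step_hours": config.step_hours, "init": config.init},
        "sensitivity": {"step_pct": config.sensitivity_step_pct},
        "montecarlo": {"runs": config.mc_runs, "seed": config.mc_seed},
        "output_dir": config.output_dir,
    }
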