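"""Structured-text (YAML) configuration parsing and serialization.

A configuration file holds everything needed for one comparison: the two
strategies, the shared disease/utility/cost parameters, run settings, the
willingness-to-pay thresholds and the PSA distributions.  The bundled
``base_case.yaml`` encodes the shipped sinonasal-cancer comparison (proton
IMPT vs photon IMRT, 47-year-old, 30 one-year cycles, 3% discounting).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import lifetable as lt
from .params import (
    DEFAULT_ENDPOINT_AGE,
    DiseaseParams,
    ModelSpec,
    RelapseInterval,
    RunSettings,
    StrategyParams,
)
from .sensitivity import ParameterDistribution

DEFAULT_WTP = 30828.0  # US$/QALY, 3x 2019 Chinese GDP per capita
DEFAULT_PSA_ITERATIONS = 50_000


class _StrategySchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    p_eradicate: float = Field(ge=0.0, le=1.0)
    cost_radiotherapy: float = Field(ge=0.0)
    cost_chemo: float = Field(default=0.0, ge=0.0)


class _UtilitiesSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    no_cancer: float = Field(ge=0.0, le=1.0)
    with_cancer: float = Field(ge=0.0, le=1.0)
    death: float = 0.0
    first_year: Optional[float] = Field(default=None, ge=0.0, le=1.0)


class _CostsSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    followup_per_year: float = Field(ge=0.0)
    palliative_per_year: float = Field(ge=0.0)


class _DiseaseSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    relapse_schedule: list[RelapseInterval]
    p_cancer_death: float = Field(ge=0.0, le=1.0)
    utilities: _UtilitiesSchema
    costs: _CostsSchema


class _SettingsSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start_age: int = Field(ge=0)
    horizon: int | str = "auto"
    discount_rate: float = Field(default=0.03, ge=0.0, lt=1.0)
    life_expectancy_endpoint: int = DEFAULT_ENDPOINT_AGE

    @field_validator("horizon")
    @classmethod
    def _auto_or_positive(cls, v):
        if isinstance(v, str):
            if v != "auto":
                raise ValueError("horizon must be a positive integer or 'auto'")
            return v
        if v < 1:
            raise ValueError("horizon must be >= 1")
        return v


class _DistributionSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    path: str
    kind: str
    mean: float
    ci90: tuple[float, float]


class _PsaSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_iterations: int = Field(default=DEFAULT_PSA_ITERATIONS, ge=1)
    distributions: list[_DistributionSchema] = []


class _ConfigSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    strategies: list[_StrategySchema] = Field(min_length=2, max_length=2)
    disease: _DiseaseSchema
    settings: _SettingsSchema
    lifetable: Optional[str] = None
    wtp: list[float] = [DEFAULT_WTP]
    psa: _PsaSchema = _PsaSchema()


@dataclass(frozen=True)
class AnalysisConfig:
    """Parsed configuration: spec + PSA distributions + WTP thresholds."""

    spec: ModelSpec
    distributions: tuple[ParameterDistribution, ...]
    wtp: tuple[float, ...]
    psa_iterations: int
    source: str = "<buffer>"
    raw: dict = field(default_factory=dict, repr=False)


def parse_config(source, life_table: lt.LifeTable | None = None) -> AnalysisConfig:
    """Parse and validate a YAML configuration.

    ``source`` is a path or readable buffer.  ``life_table`` overrides the
    table named in the file; when neither is given the vendored synthetic
    US-2016 reconstruction is used.  Schema violations raise pydantic
    validation errors naming the offending key.
    """
    if hasattr(source, "read"):
        text = source.read()
        origin = "<buffer>"
        base_dir = Path.cwd()
    else:
        text = Path(source).read_text()
        origin = str(source)
        base_dir = Path(source).parent
    raw = yaml.safe_load(text)
    cfg = _ConfigSchema.model_validate(raw)

    if life_table is None:
        if cfg.lifetable is not None:
            p = Path(cfg.lifetable)
            life_table = lt.load_life_table(p if p.is_absolute() else base_dir / p)
        else:
            life_table = lt.us2016()

    sa, sb = cfg.strategies
    horizon = None if cfg.settings.horizon == "auto" else int(cfg.settings.horizon)
    spec = ModelSpec(
        strategy_a=StrategyParams(
            name=sa.name,
            p_eradicate=sa.p_eradicate,
            c_radiotherapy=sa.cost_radiotherapy,
            c_chemo=sa.cost_chemo,
        ),
        strategy_b=StrategyParams(
            name=sb.name,
            p_eradicate=sb.p_eradicate,
            c_radiotherapy=sb.cost_radiotherapy,
            c_chemo=sb.cost_chemo,
        ),
        disease=DiseaseParams(
            relapse_schedule=tuple(cfg.disease.relapse_schedule),
            p_cancer_death=cfg.disease.p_cancer_death,
            u_no_cancer=cfg.disease.utilities.no_cancer,
            u_with_cancer=cfg.disease.utilities.with_cancer,
            u_death=cfg.disease.utilities.death,
            u_first_year=cfg.disease.utilities.first_year,
            c_followup=cfg.disease.costs.followup_per_year,
            c_palliative=cfg.disease.costs.palliative_per_year,
        ),
        settings=RunSettings(
            start_age=cfg.settings.start_age,
            horizon=horizon,
            discount_rate=cfg.settings.discount_rate,
            endpoint_age=cfg.settings.life_expectancy_endpoint,
        ),
        life_table=life_table,
    )
    dists = tuple(
        ParameterDistribution(d.path, d.kind, d.mean, tuple(d.ci90))
        for d in cfg.psa.distributions
    )
    return AnalysisConfig(
        spec=spec,
        distributions=dists,
        wtp=tuple(cfg.wtp),
        psa_iterations=cfg.psa.n_iterations,
        source=origin,
        raw=raw,
    )


def serialize_config(config: AnalysisConfig) -> str:
    """Render a configuration back to YAML (parse → serialize is idempotent)."""
    spec = config.spec
    doc = {
        "strategies": [
            {
                "name": s.name,
                "p_eradicate": s.p_eradicate,
                "cost_radiotherapy": s.c_radiotherapy,
                "cost_chemo": s.c_chemo,
            }
            for s in (spec.strategy_a, spec.strategy_b)
        ],
        "disease": {
            "relapse_schedule": [
                {"from_year": iv.from_year, "to_year": iv.to_year, "prob": iv.prob}
                for iv in spec.disease.relapse_schedule
            ],
            "p_cancer_death": spec.disease.p_cancer_death,
            "utilities": {
                "no_cancer": spec.disease.u_no_cancer,
                "with_cancer": spec.disease.u_with_cancer,
                "death": spec.disease.u_death,
                **(
                    {"first_year": spec.disease.u_first_year}
                    if spec.disease.u_first_year is not None
                    else {}
                ),
            },
            "costs": {
                "followup_per_year": spec.disease.c_followup,
                "palliative_per_year": spec.disease.c_palliative,
            },
        },
        "settings": {
            "start_age": spec.settings.start_age,
            "horizon": "auto" if spec.settings.horizon is None else spec.settings.horizon,
            "discount_rate": spec.settings.discount_rate,
            "life_expectancy_endpoint": spec.settings.endpoint_age,
        },
        "wtp": list(config.wtp),
        "psa": {
            "n_iterations": config.psa_iterations,
            "distributions": [
                {
                    "path": d.path,
                    "kind": d.kind,
                    "mean": d.mean,
                    "ci90": list(d.ci90),
                }
                for d in config.distributions
            ],
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_base_case(life_table: lt.LifeTable | None = None) -> AnalysisConfig:
    """Parse the bundled base-case configuration."""
    ref = resources.files("sinocea.data").joinpath("base_case.yaml")
    with ref.open("r") as fh:
        cfg = parse_config(io.StringIO(fh.read()), life_table=life_table)
    return cfg
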