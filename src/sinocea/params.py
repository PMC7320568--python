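"""Parameter containers for the 3-state radiotherapy decision model.

The model compares two radiotherapy strategies (proton IMPT vs photon IMRT in
the shipped base case) that differ only in the one-time treatment cost and in
the probability of eradicating the tumour, which fixes the initial Markov
state.  Disease progression, utilities, recurring costs, run settings and the
background-mortality life table are shared between the arms.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InvalidSpecError
from .lifetable import LifeTable

#: Life-expectancy endpoint (years of age) used when the horizon is derived.
DEFAULT_ENDPOINT_AGE = 77


class StrategyParams(BaseModel):
    """One treatment arm: label, tumour-eradication probability, one-time costs.

    ``p_eradicate`` is the probability that radiotherapy achieves a complete
    response, placing the patient in the "no cancer" state at cycle 0 (and in
    "alive with cancer" otherwise).  ``c_radiotherapy`` and ``c_chemo`` are
    charged once, undiscounted, at cycle 0.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    p_eradicate: float = Field(ge=0.0, le=1.0)
    c_radiotherapy: float = Field(ge=0.0)
    c_chemo: float = Field(default=0.0, ge=0.0)


class RelapseInterval(BaseModel):
    """Annual relapse probability applying from ``from_year`` to ``to_year`` inclusive."""

    model_config = ConfigDict(frozen=True)

    from_year: int = Field(ge=1)
    to_year: int = Field(ge=1)
    prob: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.to_year < self.from_year:
            raise ValueError("to_year must be >= from_year")
        return self


class DiseaseParams(BaseModel):
    """Shared natural-history, utility and recurring-cost parameters.

    The relapse schedule gives the annual "no cancer" → "alive with cancer"
    probability by year since radiotherapy; years not covered by any interval
    have probability 0.  ``u_first_year=None`` means the first-year utility
    tracks ``u_with_cancer`` (treatment disutility makes the first year after
    radiotherapy as burdensome as living with progressive disease), so a
    sensitivity draw on ``u_with_cancer`` moves both coherently.
    """

    model_config = ConfigDict(frozen=True)

    relapse_schedule: tuple[RelapseInterval, ...]
    p_cancer_death: float = Field(ge=0.0, le=1.0)
    u_no_cancer: float = Field(ge=0.0, le=1.0)
    u_with_cancer: float = Field(ge=0.0, le=1.0)
    u_death: float = 0.0
    u_first_year: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    c_followup: float = Field(ge=0.0)
    c_palliative: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _disjoint_schedule(self):
        ivs = sorted(self.relapse_schedule, key=lambda iv: iv.from_year)
        for a, b in zip(ivs, ivs[1:]):
            if b.from_year <= a.to_year:
                raise ValueError(
                    f"relapse intervals overlap: years {a.from_year}-{a.to_year} "
                    f"and {b.from_year}-{b.to_year}"
                )
        if self.u_death != 0.0:
            raise ValueError("the death-state utility is fixed at 0")
        return self

    @property
    def first_year_utility(self) -> float:
        return self.u_with_cancer if self.u_first_year is None else self.u_first_year

    def relapse_prob(self, cycle_index: int) -> float:
        """Annual relapse probability during cycle ``cycle_index`` (1-based)."""
        for iv in self.relapse_schedule:
            if iv.from_year <= cycle_index <= iv.to_year:
                return iv.prob
        return 0.0


class RunSettings(BaseModel):
    """Cohort-run settings: start age, horizon in annual cycles, discounting.

    ``horizon=None`` derives ``endpoint_age − start_age`` cycles (at least 1),
    following the convention of running the model to the life-expectancy
    endpoint.  The cycle length is fixed at one year.
    """

    model_config = ConfigDict(frozen=True)

    start_age: int = Field(ge=0)
    horizon: Optional[int] = Field(default=None, ge=1)
    cycle_length: float = 1.0
    discount_rate: float = Field(default=0.03, ge=0.0, lt=1.0)
    endpoint_age: int = DEFAULT_ENDPOINT_AGE

    @model_validator(mode="after")
    def _fixed_cycle(self):
        if self.cycle_length != 1.0:
            raise ValueError("only 1-year cycles are supported")
        return self

    @property
    def n_cycles(self) -> int:
        if self.horizon is not None:
            return self.horizon
        return max(1, self.endpoint_age - self.start_age)


class ModelSpec(BaseModel):
    """Complete parameterization of one two-strategy comparison."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    strategy_a: StrategyParams
    strategy_b: StrategyParams
    disease: DiseaseParams
    settings: RunSettings
    life_table: LifeTable

    @model_validator(mode="after")
    def _finite(self):
        for strat in (self.strategy_a, self.strategy_b):
            for v in (strat.p_eradicate, strat.c_radiotherapy, strat.c_chemo):
                if not math.isfinite(v):
                    raise InvalidSpecError(f"non-finite parameter in {strat.name}")
        for v in (
            self.disease.p_cancer_death,
            self.disease.u_no_cancer,
            self.disease.u_with_cancer,
            self.disease.first_year_utility,
            self.disease.c_followup,
            self.disease.c_palliative,
        ):
            if not math.isfinite(v):
                raise InvalidSpecError("non-finite disease parameter")
        return self

    # -- parameter paths -----------------------------------------------------
    # Dotted paths name scalar leaves for sensitivity analyses, e.g.
    # "strategy_a.p_eradicate" or "disease.u_no_cancer".  The bare alias
    # "c_chemo" sets the chemotherapy cost of BOTH arms from one value
    # (the regimen is identical in the two strategies, so it must co-vary).

    def get_value(self, path: str) -> float:
        if path == "c_chemo":
            return self.strategy_a.c_chemo
        section, _, leaf = path.partition(".")
        if not leaf:
            raise KeyError(f"unknown parameter path {path!r}")
        return float(getattr(getattr(self, section), leaf))

    def with_value(self, path: str, value: float) -> "ModelSpec":
        """Return a copy of the spec with one scalar parameter replaced."""
        if path == "c_chemo":
            return self.model_copy(
                update={
                    "strategy_a": self.strategy_a.model_copy(update={"c_chemo": value}),
                    "strategy_b": self.strategy_b.model_copy(update={"c_chemo": value}),
                }
            )
        section, _, leaf = path.partition(".")
        if section not in {"strategy_a", "strategy_b", "disease", "settings"} or not leaf:
            raise KeyError(f"unknown parameter path {path!r}")
        obj = getattr(self, section)
        if not hasattr(obj, leaf):
            raise KeyError(f"unknown parameter path {path!r}")
        return self.model_copy(update={section: obj.model_copy(update={leaf: value})})

    def swap_strategies(self) -> "ModelSpec":
        return self.model_copy(
            update={"strategy_a": self.strategy_b, "strategy_b": self.strategy_a}
        )
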