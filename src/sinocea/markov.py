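"""Deterministic 3-state Markov cohort engine.

States are ``NO_CANCER``, ``WITH_CANCER`` and ``DEAD`` (absorbing).  Each
annual cycle combines three competing events:

* background (non-cancer) death at the life-table probability ``q(age)``,
  which takes precedence in the split;
* relapse out of "no cancer" at the schedule probability ``r(t)``, applied to
  the survivors of background death, giving ``r(t)·(1 − q)``;
* cancer death out of "alive with cancer" at probability ``d`` per year,
  combined multiplicatively with background death (independence), giving a
  total death probability ``1 − (1 − d)·(1 − q)``.

Reward conventions (deliberately simple, no half-cycle correction): one-time
treatment costs are charged at cycle 0 undiscounted; every later cycle ``t``
applies the transition matrix first and then accrues state rewards on the
end-of-cycle occupancy, discounted by ``(1 + ρ)^−t``.  During cycle 1 both
alive states earn the first-year utility (treatment disutility); from cycle 2
utilities are state-specific.  The dead state accrues nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AgeRangeError
from .lifetable import LifeTable
from .params import DiseaseParams, ModelSpec, StrategyParams

NO_CANCER, WITH_CANCER, DEAD = 0, 1, 2
STATE_NAMES = ("NO_CANCER", "WITH_CANCER", "DEAD")

#: Column order of the cohort-trace CSV (contractual, do not reorder).
TRACE_COLUMNS = [
    "cycle",
    "age",
    "p_no_cancer",
    "p_with_cancer",
    "p_dead",
    "cost_cycle",
    "qaly_cycle",
    "disc_cost_cum",
    "disc_qaly_cum",
]


def transition_matrix(
    cycle_index: int,
    current_age: int,
    disease: DiseaseParams,
    life_table: LifeTable,
) -> np.ndarray:
    """Row-stochastic 3×3 transition matrix for one annual cycle.

    ``cycle_index`` is 1-based (the first transition after radiotherapy is
    cycle 1) and selects the relapse probability from the schedule;
    ``current_age`` selects the background mortality ``q``.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based; got {cycle_index}")
    q = life_table.lookup(current_age)  # AgeRangeError below table minimum
    r = disease.relapse_prob(cycle_index)
    d = disease.p_cancer_death
    p_wc_death = 1.0 - (1.0 - d) * (1.0 - q)
    return np.array(
        [
            [(1.0 - r) * (1.0 - q), r * (1.0 - q), q],
            [0.0, (1.0 - d) * (1.0 - q), p_wc_death],
            [0.0, 0.0, 1.0],
        ]
    )


@dataclass(frozen=True, eq=False)
class CohortTrace:
    """Per-cycle state occupancy and reward accruals for one strategy.

    Row ``t`` of ``occupancy`` is the state distribution at the end of cycle
    ``t`` (row 0 is the initial distribution).  ``cost_cycle``/``qaly_cycle``
    are undiscounted per-cycle accruals; ``disc_*_cum`` their discounted
    running totals.
    """

    start_age: int
    occupancy: np.ndarray  # (horizon+1, 3)
    cost_cycle: np.ndarray
    qaly_cycle: np.ndarray
    disc_cost_cum: np.ndarray
    disc_qaly_cum: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def p_dead(self) -> np.ndarray:
        return self.occupancy[:, DEAD]

    def to_frame(self) -> pd.DataFrame:
        cycles = np.arange(self.horizon + 1)
        ages = self.start_age + np.maximum(cycles, 1) - 1
        return pd.DataFrame(
            {
                "cycle": cycles,
                "age": ages,
                "p_no_cancer": self.occupancy[:, NO_CANCER],
                "p_with_cancer": self.occupancy[:, WITH_CANCER],
                "p_dead": self.occupancy[:, DEAD],
                "cost_cycle": self.cost_cycle,
                "qaly_cycle": self.qaly_cycle,
                "disc_cost_cum": self.disc_cost_cum,
                "disc_qaly_cum": self.disc_qaly_cum,
            }
        )[TRACE_COLUMNS]

    def write_csv(self, destination) -> None:
        self.to_frame().to_csv(Path(destination), index=False)


@dataclass(frozen=True, eq=False)
class RunResult:
    """Discounted totals and survival curve for one strategy."""

    strategy_name: str
    total_cost: float
    total_qaly: float
    os_curve: np.ndarray  # OS(t) = 1 − p_dead(t), t = 0..horizon
    trace: CohortTrace


def run_cohort(strategy: StrategyParams, spec: ModelSpec) -> RunResult:
    """Propagate the cohort for one strategy and accrue discounted rewards."""
    settings = spec.settings
    disease = spec.disease
    horizon = settings.n_cycles
    rho = settings.discount_rate

    occ = np.zeros((horizon + 1, 3))
    occ[0] = (strategy.p_eradicate, 1.0 - strategy.p_eradicate, 0.0)
    cost_cycle = np.zeros(horizon + 1)
    qaly_cycle = np.zeros(horizon + 1)
    disc_cost = np.zeros(horizon + 1)
    disc_qaly = np.zeros(horizon + 1)
    cost_cycle[0] = strategy.c_radiotherapy + strategy.c_chemo
    disc_cost[0] = cost_cycle[0]  # cycle-0 charge is not discounted

    u_first = disease.first_year_utility
    for t in range(1, horizon + 1):
        age = settings.start_age + t - 1
        P = transition_matrix(t, age, disease, spec.life_table)
        occ[t] = occ[t - 1] @ P
        disc = (1.0 + rho) ** (-t)
        u_nc, u_wc = (u_first, u_first) if t == 1 else (
            disease.u_no_cancer,
            disease.u_with_cancer,
        )
        qaly_cycle[t] = occ[t, NO_CANCER] * u_nc + occ[t, WITH_CANCER] * u_wc
        cost_cycle[t] = occ[t, NO_CANCER] * disease.c_followup + occ[
            t, WITH_CANCER
        ] * (disease.c_followup + disease.c_palliative)
        disc_cost[t] = disc * cost_cycle[t]
        disc_qaly[t] = disc * qaly_cycle[t]

    trace = CohortTrace(
        start_age=settings.start_age,
        occupancy=occ,
        cost_cycle=cost_cycle,
        qaly_cycle=qaly_cycle,
        disc_cost_cum=np.cumsum(disc_cost),
        disc_qaly_cum=np.cumsum(disc_qaly),
    )
    total_cost, total_qaly = expected_outcomes(trace)
    return RunResult(
        strategy_name=strategy.name,
        total_cost=total_cost,
        total_qaly=total_qaly,
        os_curve=1.0 - occ[:, DEAD],
        trace=trace,
    )


def expected_outcomes(trace: CohortTrace) -> tuple[float, float]:
    """Total discounted (cost, QALY) of a cohort trace."""
    return float(trace.disc_cost_cum[-1]), float(trace.disc_qaly_cum[-1])


def overall_survival(result: RunResult, year: int) -> float:
    """OS(year) = 1 − p_dead(year); ``year`` must lie within the horizon."""
    if not 0 <= year < len(result.os_curve):
        raise AgeRangeError(
            f"year {year} outside 0..{len(result.os_curve) - 1}"
        )
    return float(result.os_curve[year])


# ---------------------------------------------------------------------------
# Vectorized kernel: many parameter draws at once (used by the PSA fast path
# and the probabilistic machinery).  Semantically identical to run_cohort;
# equivalence is enforced by the test suite at 1e-12.


def cohort_outcomes_vectorized(
    *,
    p_eradicate,
    c_radiotherapy,
    c_chemo,
    p_cancer_death,
    u_no_cancer,
    u_with_cancer,
    u_first_year,
    c_followup,
    c_palliative,
    settings,
    relapse_prob,
    life_table: LifeTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Discounted (cost, qaly) totals for broadcastable parameter arrays.

    ``relapse_prob`` is a callable ``t -> float`` (shared schedule); all other
    arguments may be scalars or equal-length 1-D arrays of draws.
    """
    (p_er, c_rt, c_ch, d, u_nc_, u_wc_, u_y1, c_fu, c_pall) = np.broadcast_arrays(
        *np.atleast_1d(
            p_eradicate, c_radiotherapy, c_chemo, p_cancer_death, u_no_cancer,
            u_with_cancer, u_first_year, c_followup, c_palliative,
        )
    )
    nc = p_er.astype(float).copy()
    wc = 1.0 - nc
    cost = (c_rt + c_ch).astype(float).copy()
    qaly = np.zeros_like(cost)
    rho = settings.discount_rate
    for t in range(1, settings.n_cycles + 1):
        q = life_table.lookup(settings.start_age + t - 1)
        r = relapse_prob(t)
        nc_next = nc * (1.0 - r) * (1.0 - q)
        wc_next = nc * r * (1.0 - q) + wc * (1.0 - d) * (1.0 - q)
        nc, wc = nc_next, wc_next
        disc = (1.0 + rho) ** (-t)
        if t == 1:
            qaly += disc * (nc + wc) * u_y1
        else:
            qaly += disc * (nc * u_nc_ + wc * u_wc_)
        cost += disc * (nc * c_fu + wc * (c_fu + c_pall))
    return cost, qaly
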