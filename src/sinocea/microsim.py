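"""Patient-level Monte Carlo simulator (first-order uncertainty).

Walks individual patients through the same transition rules, reward timing
and discounting as the deterministic cohort engine, which makes it the
brute-force oracle for that engine: for ``n`` trajectories the empirical
mean cost, mean QALY and survival curve converge to the cohort trace at the
usual ``O(1/sqrt(n))`` rate.

It also provides the paired-trial strategy-selection fraction: two strategies
simulated on the *same* uniform draws (common random numbers), with each
trial voting for the strategy with the higher net monetary benefit.  This is
the patient-level "Monte Carlo simulation" convention of decision-modelling
software, distinct from the parameter PSA in :mod:`sinocea.sensitivity`.

All randomness comes from one ``numpy`` PCG64 stream per run.  Draw order:
one block of ``n`` uniforms for the initial states, then one block of ``n``
uniforms per cycle for the transitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import DEAD, NO_CANCER, STATE_NAMES, WITH_CANCER
from .params import ModelSpec, StrategyParams


@dataclass(frozen=True, eq=False)
class TrajectorySet:
    """States and realized rewards for ``n`` simulated patients.

    ``states`` has shape ``(n, horizon + 1)``; column ``t`` is the state at
    the end of cycle ``t``.  Costs and QALYs are per-patient realized totals.
    """

    strategy_name: str
    one_time_cost: float
    start_age: int
    states: np.ndarray
    cost: np.ndarray
    disc_cost: np.ndarray
    qaly: np.ndarray
    disc_qaly: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1] - 1


@dataclass(frozen=True, eq=False)
class MicrosimEstimate:
    """Sample summary of a trajectory set; SEs are sample sd / sqrt(n)."""

    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    os_curve: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "seed": self.seed,
                "mean_cost": self.mean_cost,
                "se_cost": self.se_cost,
                "mean_qaly": self.mean_qaly,
                "se_qaly": self.se_qaly,
                "os_curve": self.os_curve.tolist(),
                "rng": "numpy.random.default_rng (PCG64)",
            },
            indent=2,
        )


def _walk(
    strategy: StrategyParams, spec: ModelSpec, u: np.ndarray, seed: int = -1
) -> TrajectorySet:
    """Drive patients through the model using pre-drawn uniforms ``u``.

    ``u`` has shape ``(n, horizon + 1)``: column 0 decides the initial state
    (eradicated vs residual disease), column ``t >= 1`` the cycle-``t``
    transition.  Sharing ``u`` across strategies yields common random numbers.
    """
    settings, disease = spec.settings, spec.disease
    n, horizon = u.shape[0], settings.n_cycles
    rho = settings.discount_rate
    u_first = disease.first_year_utility

    states = np.empty((n, horizon + 1), dtype=np.int8)
    states[:, 0] = np.where(u[:, 0] < strategy.p_eradicate, NO_CANCER, WITH_CANCER)
    cost = np.full(n, strategy.c_radiotherapy + strategy.c_chemo)
    disc_cost = cost.copy()
    qaly = np.zeros(n)
    disc_qaly = np.zeros(n)

    for t in range(1, horizon + 1):
        q = spec.life_table.lookup(settings.start_age + t - 1)
        r = disease.relapse_prob(t)
        d = disease.p_cancer_death
        prev, ut = states[:, t - 1], u[:, t]
        new = prev.copy()
        nc = prev == NO_CANCER
        # split of the NC row: [0, q) death, [q, q + r(1-q)) relapse, else stay
        new[nc & (ut < q)] = DEAD
        new[nc & (ut >= q) & (ut < q + r * (1.0 - q))] = WITH_CANCER
        wc = prev == WITH_CANCER
        new[wc & (ut < 1.0 - (1.0 - d) * (1.0 - q))] = DEAD
        states[:, t] = new

        disc = (1.0 + rho) ** (-t)
        u_nc, u_wc = (u_first, u_first) if t == 1 else (
            disease.u_no_cancer,
            disease.u_with_cancer,
        )
        util = np.where(new == NO_CANCER, u_nc, np.where(new == WITH_CANCER, u_wc, 0.0))
        c = np.where(
            new == NO_CANCER,
            disease.c_followup,
            np.where(new == WITH_CANCER, disease.c_followup + disease.c_palliative, 0.0),
        )
        qaly += util
        cost += c
        disc_qaly += disc * util
        disc_cost += disc * c

    return TrajectorySet(
        strategy.name,
        float(strategy.c_radiotherapy + strategy.c_chemo),
        settings.start_age,
        states,
        cost,
        disc_cost,
        qaly,
        disc_qaly,
        seed,
    )


def simulate_patients(
    strategy: StrategyParams,
    spec: ModelSpec,
    n: int,
    seed: int,
    return_trajectories: bool = False,
):
    """Simulate ``n`` patients; returns a :class:`MicrosimEstimate`.

    With ``return_trajectories=True`` returns ``(estimate, TrajectorySet)``.
    Fixed seeds give identical trajectory sets.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, spec.settings.n_cycles + 1))
    traj = _walk(strategy, spec, u, seed=seed)
    est = MicrosimEstimate(
        n=n,
        seed=seed,
        mean_cost=float(traj.disc_cost.mean()),
        se_cost=float(traj.disc_cost.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        mean_qaly=float(traj.disc_qaly.mean()),
        se_qaly=float(traj.disc_qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        os_curve=(traj.states != DEAD).mean(axis=0),
    )
    return (est, traj) if return_trajectories else est


def selection_fraction(
    spec: ModelSpec,
    wtp: float,
    n: int,
    seed: int,
    common_random_numbers: bool = True,
) -> float:
    """Fraction of paired patient-level trials in which strategy A wins.

    Each trial simulates one patient under each strategy and compares the
    realized net monetary benefits ``λ·E − C``; A "wins" when its NMB is
    strictly higher (ties count against A).  With common random numbers
    (default) both arms consume the same uniforms, so trials only diverge
    where the strategies genuinely differ — the convention under which
    comparative patient-level Monte Carlo is usually run.
    """
    rng = np.random.default_rng(seed)
    u_a = rng.random((n, spec.settings.n_cycles + 1))
    u_b = u_a if common_random_numbers else rng.random((n, spec.settings.n_cycles + 1))
    ta = _walk(spec.strategy_a, spec, u_a)
    tb = _walk(spec.strategy_b, spec, u_b)
    nmb_a = wtp * ta.disc_qaly - ta.disc_cost
    nmb_b = wtp * tb.disc_qaly - tb.disc_cost
    return float(np.mean(nmb_a > nmb_b))


def export_trajectories(traj: TrajectorySet, spec: ModelSpec, destination) -> None:
    """Write patient-year records as CSV.

    Columns: ``patient_id, year, age, state, cost_accrued, qaly_accrued``
    (undiscounted per-cycle accruals; states encoded by name).  Rows stop at
    the cycle in which a patient enters DEAD.
    """
    disease = spec.disease
    u_first = disease.first_year_utility
    records = []
    for pid in range(traj.n):
        for t in range(traj.horizon + 1):
            state = int(traj.states[pid, t])
            age = traj.start_age + max(t, 1) - 1
            if t == 0:
                c = traj.one_time_cost
                uu = 0.0
            else:
                u_nc, u_wc = (u_first, u_first) if t == 1 else (
                    disease.u_no_cancer,
                    disease.u_with_cancer,
                )
                uu = {NO_CANCER: u_nc, WITH_CANCER: u_wc, DEAD: 0.0}[state]
                c = {
                    NO_CANCER: disease.c_followup,
                    WITH_CANCER: disease.c_followup + disease.c_palliative,
                    DEAD: 0.0,
                }[state]
            records.append(
                (pid, t, age, STATE_NAMES[state], c, uu)
            )
            if state == DEAD:
                break
    frame = pd.DataFrame(
        records,
        columns=["patient_id", "year", "age", "state", "cost_accrued", "qaly_accrued"],
    )
    frame.to_csv(Path(destination), index=False)


def load_trajectories(source) -> pd.DataFrame:
    """Read a trajectory CSV back into a DataFrame (round-trip of export)."""
    return pd.read_csv(Path(source))
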