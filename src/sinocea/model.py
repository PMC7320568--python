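"""Model / Results surface over the cohort engine and sensitivity machinery.

:class:`MarkovCEA` packages one two-strategy comparison the way statistical
modelling libraries package an estimator: the model object holds the inputs
(parameter spec, PSA distributions, willingness-to-pay thresholds),
``fit()`` evaluates the deterministic cohort model and returns a
:class:`CEAResults` carrying totals, increments and a ``summary()`` table,
and the probabilistic analyses (PSA, patient-level simulation), tornado,
threshold and age-stratified analyses hang off the results object.  Because
the model is a mechanistic decision model parameterized from the literature,
``fit()`` involves no estimation — it is a deterministic evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import config as _config
from .lifetable import LifeTable
from .markov import RunResult, run_cohort
from .microsim import MicrosimEstimate, selection_fraction, simulate_patients
from .params import ModelSpec
from .sensitivity import (
    ComparisonResult,
    ParameterDistribution,
    PSAResult,
    TornadoEntry,
    age_stratified_icer,
    age_threshold,
    compare,
    net_monetary_benefit,
    one_way_threshold,
    run_psa,
    tornado,
)


class MarkovCEA:
    """Two-strategy, 3-state Markov cohort cost-effectiveness model."""

    def __init__(
        self,
        spec: ModelSpec,
        distributions: Sequence[ParameterDistribution] = (),
        wtp: Sequence[float] = (_config.DEFAULT_WTP,),
        psa_iterations: int = _config.DEFAULT_PSA_ITERATIONS,
    ):
        self.spec = spec
        self.distributions = tuple(distributions)
        self.wtp = tuple(wtp)
        self.psa_iterations = int(psa_iterations)

    @classmethod
    def from_config(cls, source, life_table: LifeTable | None = None) -> "MarkovCEA":
        cfg = _config.parse_config(source, life_table=life_table)
        return cls(cfg.spec, cfg.distributions, cfg.wtp, cfg.psa_iterations)

    @classmethod
    def base_case(cls, life_table: LifeTable | None = None) -> "MarkovCEA":
        """The bundled proton-vs-photon sinonasal cancer comparison."""
        cfg = _config.load_base_case(life_table=life_table)
        return cls(cfg.spec, cfg.distributions, cfg.wtp, cfg.psa_iterations)

    def fit(self) -> "CEAResults":
        """Evaluate both strategies deterministically."""
        res_a = run_cohort(self.spec.strategy_a, self.spec)
        res_b = run_cohort(self.spec.strategy_b, self.spec)
        return CEAResults(self, res_a, res_b, compare(res_a, res_b))

    def at(self, path: str, value: float) -> "MarkovCEA":
        """Copy of the model with one scalar parameter replaced."""
        return MarkovCEA(
            self.spec.with_value(path, value),
            self.distributions,
            self.wtp,
            self.psa_iterations,
        )


@dataclass(frozen=True)
class CEAResults:
    """Deterministic evaluation of a :class:`MarkovCEA` model."""

    model: MarkovCEA
    result_a: RunResult
    result_b: RunResult
    comparison: ComparisonResult

    # -- scalar accessors ---------------------------------------------------

    @property
    def icer(self) -> float | None:
        return self.comparison.icer

    @property
    def delta_cost(self) -> float:
        return self.comparison.delta_cost

    @property
    def delta_effect(self) -> float:
        return self.comparison.delta_effect

    def nmb(self, wtp: float) -> float:
        return net_monetary_benefit(self.comparison, wtp)

    def os_table(self, years: Sequence[int] = (2, 5, 10)) -> pd.DataFrame:
        rows = {}
        for res in (self.result_a, self.result_b):
            rows[res.strategy_name] = {
                f"os_{y}y": float(res.os_curve[y]) for y in years
            }
        return pd.DataFrame(rows).T

    # -- downstream analyses ------------------------------------------------

    def psa(self, n: int | None = None, seed: int = 0, wtp: float | None = None) -> PSAResult:
        """Parameter (second-order) probabilistic sensitivity analysis."""
        if not self.model.distributions:
            raise ValueError("model carries no parameter distributions")
        return run_psa(
            self.model.spec,
            self.model.distributions,
            n_iterations=n or self.model.psa_iterations,
            seed=seed,
            wtp=self._wtp(wtp),
        )

    def tornado(self) -> list[TornadoEntry]:
        return tornado(self.model.spec, self.model.distributions)

    def one_way_threshold(
        self,
        path: str,
        wtp: float | None = None,
        bounds: tuple[float, float] | None = None,
    ) -> float:
        return one_way_threshold(
            self.model.spec,
            path,
            self._wtp(wtp),
            bounds or default_threshold_bounds(self.model.spec, path),
        )

    def age_stratified(
        self, ages: Sequence[int] = range(0, 80, 10)
    ) -> pd.DataFrame:
        rows = [
            {
                "age": age,
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_effect,
                "icer": res.icer,
            }
            for age, res in age_stratified_icer(self.model.spec, ages)
        ]
        return pd.DataFrame(rows)

    def age_threshold(self, wtp: float | None = None) -> int:
        return age_threshold(self.model.spec, self._wtp(wtp))

    def microsim(
        self, strategy: str = "a", n: int = 100_000, seed: int = 0
    ) -> MicrosimEstimate:
        strat = getattr(self.model.spec, f"strategy_{strategy}")
        return simulate_patients(strat, self.model.spec, n=n, seed=seed)

    def selection_fraction(
        self, wtp: float | None = None, n: int = 50_000, seed: int = 0
    ) -> float:
        """Paired patient-level trial fraction favoring strategy A (CRN)."""
        return selection_fraction(self.model.spec, self._wtp(wtp), n=n, seed=seed)

    def _wtp(self, wtp: float | None) -> float:
        return float(wtp) if wtp is not None else float(self.model.wtp[0])

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table (1-decimal display for $ and QALY values)."""
        a, b, cmp_ = self.result_a, self.result_b, self.comparison
        spec = self.model.spec
        lines = [
            "Markov cohort cost-effectiveness analysis",
            "=" * 57,
            f"cohort start age {spec.settings.start_age}, "
            f"{spec.settings.n_cycles} annual cycles, "
            f"discount {spec.settings.discount_rate:.1%}",
            f"life table: {spec.life_table.provenance}",
            "-" * 57,
            f"{'strategy':<12}{'cost ($)':>14}{'QALYs':>10}",
            f"{a.strategy_name:<12}{a.total_cost:>14,.1f}{a.total_qaly:>10.2f}",
            f"{b.strategy_name:<12}{b.total_cost:>14,.1f}{b.total_qaly:>10.2f}",
            "-" * 57,
            f"incremental cost   {cmp_.delta_cost:>14,.1f}",
            f"incremental QALYs  {cmp_.delta_effect:>14.2f}",
        ]
        if cmp_.icer is not None:
            lines.append(f"ICER ($/QALY)      {cmp_.icer:>14,.1f}")
        else:
            lines.append(f"ICER               {'undefined':>14} ({cmp_.dominance})")
        for wtp in self.model.wtp:
            nmb = self.nmb(wtp)
            verdict = "cost-effective" if nmb > 0 else "not cost-effective"
            lines.append(
                f"NMB at λ={wtp:>9,.0f}  {nmb:>14,.1f}  ({a.strategy_name} {verdict})"
            )
        lines.append("=" * 57)
        return "\n".join(lines)

    # -- plotting (optional extra) -----------------------------------------

    def plot_survival(self, ax=None):
        """Overall-survival curves for both strategies."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        for res in (self.result_a, self.result_b):
            ax.step(
                np.arange(len(res.os_curve)), res.os_curve, where="post",
                label=res.strategy_name,
            )
        ax.set_xlabel("years since radiotherapy")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax

    def plot_tornado(self, ax=None):
        """Horizontal-bar tornado diagram of one-way ICER ranges."""
        import matplotlib.pyplot as plt

        entries = self.tornado()
        ax = ax or plt.gca()
        base = self.icer
        names = [e.path for e in entries][::-1]
        for i, e in enumerate(entries[::-1]):
            lo, hi = sorted((e.icer_at_low, e.icer_at_high))
            ax.barh(i, hi - lo, left=lo, height=0.6)
        ax.axvline(base, color="k", lw=1, ls="--", label="base ICER")
        ax.set_yticks(range(len(names)), names)
        ax.set_xlabel("ICER ($/QALY)")
        ax.legend()
        return ax

    def plot_ce_scatter(self, psa_result: PSAResult, ax=None):
        """Incremental cost vs incremental effect cloud from a PSA."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.scatter(psa_result.delta_effect, psa_result.delta_cost, s=2, alpha=0.2)
        lam = psa_result.wtp
        xs = np.linspace(*ax.get_xlim(), 10)
        ax.plot(xs, lam * xs, "k--", lw=1, label=f"λ = {lam:,.0f} $/QALY")
        ax.set_xlabel("incremental QALYs")
        ax.set_ylabel("incremental cost ($)")
        ax.legend()
        return ax


def default_threshold_bounds(spec: ModelSpec, path: str) -> tuple[float, float]:
    """Heuristic search bounds for a one-way threshold on ``path``.

    Eradication probabilities are bounded away from the point where the
    incremental effect vanishes (the ICER diverges there); costs get a wide
    non-negative range; other [0, 1] parameters span almost the unit interval.
    """
    eps = 1e-3
    if path == "strategy_a.p_eradicate":
        return (spec.strategy_b.p_eradicate + eps, 1.0)
    if path == "strategy_b.p_eradicate":
        return (0.0, spec.strategy_a.p_eradicate - eps)
    base = spec.get_value(path)
    if path.endswith(("c_radiotherapy", "c_chemo", "c_followup", "c_palliative")) or path == "c_chemo":
        return (0.0, max(10.0 * base, base + 1e6))
    return (eps, 1.0 - eps)
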