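"""Cost-effectiveness comparison and sensitivity machinery.

Implements the incremental cost-effectiveness ratio (ICER) and net monetary
benefit (NMB), probabilistic sensitivity analysis (PSA) with beta /
truncated-normal parameter distributions moment-matched to 90% confidence
intervals, tornado diagrams, deterministic one-way threshold searches by
bisection, and age-stratified analyses run to the life-expectancy endpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AgeRangeError,
    InfeasibleMomentsError,
    NoCrossingError,
    NoThresholdInRangeError,
)
from .markov import RunResult, cohort_outcomes_vectorized, run_cohort
from .params import ModelSpec

#: z such that P(|Z| < z) = 0.90 for a standard normal; converts a 90% CI
#: half-width into a standard deviation.
Z_90 = 1.6448536269514722


# ---------------------------------------------------------------------------
# ICER / NMB


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental outcome of strategy A versus strategy B (deltas are A − B)."""

    delta_cost: float
    delta_effect: float
    icer: Optional[float]
    dominance: str  # none | a_dominates | b_dominates | tie


def compare(result_a: RunResult, result_b: RunResult) -> ComparisonResult:
    dc = result_a.total_cost - result_b.total_cost
    de = result_a.total_qaly - result_b.total_qaly
    icer = dc / de if de != 0.0 else None
    if dc == 0.0 and de == 0.0:
        dominance = "tie"
    elif dc <= 0.0 and de >= 0.0:
        dominance = "a_dominates"
    elif dc >= 0.0 and de <= 0.0:
        dominance = "b_dominates"
    else:
        dominance = "none"
    return ComparisonResult(dc, de, icer, dominance)


def net_monetary_benefit(comparison: ComparisonResult, wtp: float) -> float:
    """λ·ΔE − ΔC; positive means A is cost-effective versus B at λ."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    return wtp * comparison.delta_effect - comparison.delta_cost


def compare_spec(spec: ModelSpec) -> ComparisonResult:
    """Run both strategies of a spec and compare them (A vs B)."""
    return compare(run_cohort(spec.strategy_a, spec), run_cohort(spec.strategy_b, spec))


def _icer(spec: ModelSpec) -> float:
    res = compare_spec(spec)
    if res.icer is None:
        raise ZeroDivisionError("undefined ICER: zero incremental effect")
    return res.icer


# ---------------------------------------------------------------------------
# Parameter distributions


@dataclass(frozen=True)
class ParameterDistribution:
    """PSA sampling spec for one scalar parameter.

    ``kind`` is ``"beta"`` (moment-matched; for probabilities and utilities)
    or ``"normal"`` (truncated at 0 by resampling; for costs).  The standard
    deviation is recovered from the 90% CI as ``(high − low) / (2·1.645)``.
    A degenerate CI (low = high = mean) yields a point mass.
    """

    path: str
    kind: str
    mean: float
    ci90: tuple[float, float]

    def __post_init__(self):
        low, high = self.ci90
        if self.kind not in {"beta", "normal"}:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if not (low <= self.mean <= high):
            raise ValueError(
                f"{self.path}: need low <= mean <= high, got {low}, {self.mean}, {high}"
            )
        if self.kind == "beta" and not (0.0 <= low and high <= 1.0):
            raise ValueError(f"{self.path}: beta support must lie in [0, 1]")

    @property
    def sd(self) -> float:
        low, high = self.ci90
        return (high - low) / (2.0 * Z_90)


@dataclass(frozen=True)
class Sampler:
    """Reproducible sampler for one ParameterDistribution."""

    dist: ParameterDistribution
    _draw: Callable = field(repr=False)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self._draw(rng, n)


def fit_distribution(dist: ParameterDistribution) -> Sampler:
    """Build a sampler; beta by moment matching, normal truncated at 0."""
    m, sd = dist.mean, dist.sd
    if sd == 0.0:
        return Sampler(dist, lambda rng, n: np.full(n, m))
    if dist.kind == "beta":
        v = sd * sd
        if v >= m * (1.0 - m):
            raise InfeasibleMomentsError(
                f"{dist.path}: implied variance {v:.3g} >= m(1-m) = {m * (1 - m):.3g}"
            )
        alpha = m * (m * (1.0 - m) / v - 1.0)
        beta = alpha * (1.0 - m) / m
        return Sampler(dist, lambda rng, n: rng.beta(alpha, beta, n))

    def draw_truncnorm(rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.normal(m, sd, n)
        while True:  # resample negatives from the same stream
            bad = x < 0.0
            if not bad.any():
                return x
            x[bad] = rng.normal(m, sd, int(bad.sum()))

    return Sampler(dist, draw_truncnorm)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis

# Scalar leaves the vectorized kernel understands; anything else forces the
# per-iteration fallback through run_cohort.
_FAST_PATHS = frozenset(
    ["c_chemo"]
    + [f"strategy_{s}.{f}" for s in "ab" for f in ("p_eradicate", "c_radiotherapy", "c_chemo")]
    + [
        f"disease.{f}"
        for f in (
            "p_cancer_death",
            "u_no_cancer",
            "u_with_cancer",
            "u_first_year",
            "c_followup",
            "c_palliative",
        )
    ]
)


@dataclass(frozen=True, eq=False)
class PSAResult:
    """Joint parameter-uncertainty analysis output.

    ``fraction_favoring_a`` is the share of iterations with positive
    incremental NMB at ``wtp`` (ties count against A) — the acceptability of
    strategy A under second-order (parameter) uncertainty.
    """

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    n_iterations: int
    seed: int
    wtp: float
    samples: dict[str, np.ndarray]

    @property
    def nmb(self) -> np.ndarray:
        return self.wtp * self.delta_effect - self.delta_cost

    @property
    def fraction_favoring_a(self) -> float:
        return float(np.mean(self.nmb > 0.0))

    def acceptability(self, wtp: float) -> float:
        """Fraction of iterations favoring A at an arbitrary λ."""
        return float(np.mean(wtp * self.delta_effect - self.delta_cost > 0.0))

    def parameter_summary(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": path,
                "mean": float(np.mean(x)),
                "p5": float(np.percentile(x, 5)),
                "p95": float(np.percentile(x, 95)),
            }
            for path, x in self.samples.items()
        ]
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_effect,
                "nmb": self.nmb,
            }
        )

    def write(self, csv_path, json_path) -> None:
        self.to_frame().to_csv(Path(csv_path), index=False)
        summary = {
            "fraction_favoring": self.fraction_favoring_a,
            "n": self.n_iterations,
            "seed": self.seed,
            "wtp": self.wtp,
            "rng": "numpy.random.default_rng (PCG64)",
        }
        Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


def run_psa(
    spec: ModelSpec,
    distributions: Sequence[ParameterDistribution],
    n_iterations: int,
    seed: int,
    wtp: float,
) -> PSAResult:
    """Sample all distributed parameters jointly-independently and rerun both arms.

    Draw order is the order of ``distributions``, one block of ``n_iterations``
    values each, from a single PCG64 stream seeded with ``seed`` — identical
    seeds give bit-identical results.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    samplers = [fit_distribution(d) for d in distributions]
    samples = {s.dist.path: s.draw(rng, n_iterations) for s in samplers}

    if set(samples) <= _FAST_PATHS:
        cost, qaly = {}, {}
        for arm in ("a", "b"):
            strat = getattr(spec, f"strategy_{arm}")

            def pick(path: str, default: float) -> np.ndarray | float:
                return samples.get(path, default)

            u_wc = pick("disease.u_with_cancer", spec.disease.u_with_cancer)
            if "disease.u_first_year" in samples:
                u_y1 = samples["disease.u_first_year"]
            elif spec.disease.u_first_year is None:
                u_y1 = u_wc  # first-year utility tracks the with-cancer draw
            else:
                u_y1 = spec.disease.u_first_year
            cost[arm], qaly[arm] = cohort_outcomes_vectorized(
                p_eradicate=pick(f"strategy_{arm}.p_eradicate", strat.p_eradicate),
                c_radiotherapy=pick(
                    f"strategy_{arm}.c_radiotherapy", strat.c_radiotherapy
                ),
                c_chemo=pick(
                    f"strategy_{arm}.c_chemo", pick("c_chemo", strat.c_chemo)
                ),
                p_cancer_death=pick(
                    "disease.p_cancer_death", spec.disease.p_cancer_death
                ),
                u_no_cancer=pick("disease.u_no_cancer", spec.disease.u_no_cancer),
                u_with_cancer=u_wc,
                u_first_year=u_y1,
                c_followup=pick("disease.c_followup", spec.disease.c_followup),
                c_palliative=pick("disease.c_palliative", spec.disease.c_palliative),
                settings=spec.settings,
                relapse_prob=spec.disease.relapse_prob,
                life_table=spec.life_table,
            )
        delta_cost = cost["a"] - cost["b"]
        delta_effect = qaly["a"] - qaly["b"]
    else:  # general fallback: rebuild the spec per iteration
        delta_cost = np.empty(n_iterations)
        delta_effect = np.empty(n_iterations)
        for i in range(n_iterations):
            spec_i = spec
            for path, draws in samples.items():
                spec_i = spec_i.with_value(path, float(draws[i]))
            res = compare_spec(spec_i)
            delta_cost[i], delta_effect[i] = res.delta_cost, res.delta_effect

    return PSAResult(
        delta_cost=np.broadcast_to(delta_cost, (n_iterations,)).astype(float),
        delta_effect=np.broadcast_to(delta_effect, (n_iterations,)).astype(float),
        n_iterations=n_iterations,
        seed=seed,
        wtp=wtp,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Tornado diagram


@dataclass(frozen=True)
class TornadoEntry:
    path: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def tornado(
    spec: ModelSpec,
    distributions: Sequence[ParameterDistribution],
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """One-at-a-time ICER ranges over each parameter's 90% CI endpoints.

    Every other parameter stays at its base value; entries come back sorted
    by descending spread.  ``wtp`` is accepted for interface symmetry but the
    ranking uses the ICER itself.
    """
    if not distributions:
        raise ValueError("tornado requires at least one distribution")
    entries = []
    for dist in distributions:
        low, high = dist.ci90
        entries.append(
            TornadoEntry(
                path=dist.path,
                low=low,
                high=high,
                icer_at_low=_icer(spec.with_value(dist.path, low)),
                icer_at_high=_icer(spec.with_value(dist.path, high)),
            )
        )
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.path,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# One-way threshold search


def one_way_threshold(
    spec: ModelSpec,
    path: str,
    wtp: float,
    bounds: tuple[float, float],
    rtol: float = 1e-6,
) -> float:
    """Parameter value at which the ICER equals ``wtp``, by bisection.

    The ICER must be monotone in the parameter over ``bounds`` (checked by
    endpoint evaluation); absence of a sign change raises
    :class:`NoThresholdInRangeError`.  The returned value re-evaluates to
    ``|ICER − λ|/λ < 1e-4``.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")

    def f(x: float) -> float:
        return _icer(spec.with_value(path, x)) - wtp

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoThresholdInRangeError(
            f"ICER - wtp has no sign change for {path} over [{lo}, {hi}] "
            f"(endpoints {f_lo:+.4g}, {f_hi:+.4g})"
        )
    while hi - lo > rtol * max(1.0, abs(hi)):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid == 0.0:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Age stratification


def age_stratified_icer(
    spec: ModelSpec, ages: Sequence[int]
) -> list[tuple[int, ComparisonResult]]:
    """Comparisons for cohorts starting at each age, run to the endpoint age.

    The horizon is ``endpoint_age − age`` cycles; all other parameters keep
    their base-case values.
    """
    out = []
    for age in ages:
        out.append((int(age), compare_spec(_spec_at_age(spec, int(age)))))
    return out


def _spec_at_age(spec: ModelSpec, age: int) -> ModelSpec:
    endpoint = spec.settings.endpoint_age
    if age >= endpoint:
        raise AgeRangeError(f"start age {age} must be below the endpoint {endpoint}")
    settings = spec.settings.model_copy(update={"start_age": age, "horizon": None})
    return spec.model_copy(update={"settings": settings})


def age_threshold(spec: ModelSpec, wtp: float) -> int:
    """Largest integer start age at which strategy A is cost-effective at λ.

    Scans every age below the endpoint; "cost-effective" means A dominates or
    ICER ≤ λ with positive incremental effect.  Raises
    :class:`NoCrossingError` if the answer is no age or every age.
    """
    ages = range(0, spec.settings.endpoint_age)
    ce = []
    for age in ages:
        res = compare_spec(_spec_at_age(spec, age))
        ce.append(
            res.dominance == "a_dominates"
            or (res.delta_effect > 0 and res.icer is not None and res.icer <= wtp)
        )
    if all(ce):
        raise NoCrossingError("cost-effective at every age", direction="all")
    if not any(ce):
        raise NoCrossingError("cost-effective at no age", direction="none")
    return max(age for age, ok in zip(ages, ce) if ok)
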