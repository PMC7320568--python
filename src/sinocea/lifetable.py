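"""Period life tables for background (non-cancer) mortality.

A :class:`LifeTable` maps integer age to the annual probability ``q(age)`` of
dying within the year from causes other than the modelled cancer.  The cohort
engine looks ages up one cycle at a time, so only integer ages are supported
and no interpolation is performed.  Ages above the tabulated maximum clamp to
the last row, and ``q`` is forced to 1 from age 120 onward.

Two sources of tables ship with the package:

* :func:`us2016` — a vendored *synthetic reconstruction* of the sex-combined
  (unweighted mean of male and female) United States 2016 period life table,
  used for base-case reproduction.
* :func:`synthesize_life_table` — a Gompertz–Makeham generator used by the
  test suite so that no external data are ever required.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AgeRangeError, InvalidLifeTableError

#: Age at and above which the annual death probability is forced to 1.
MAX_HUMAN_AGE = 120


@dataclass(frozen=True, eq=False)
class LifeTable:
    """Age-indexed annual probabilities of background death.

    Parameters
    ----------
    ages
        Strictly increasing, contiguous integer ages.
    q
        Annual death probabilities in [0, 1], one per age.
    provenance
        Free-text label describing where the table came from; preserved on
        round-trips through :meth:`write` / :func:`load_life_table`.
    """

    ages: np.ndarray
    q: np.ndarray
    provenance: str = "unspecified"
    _qmap: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        if ages.size == 0:
            raise InvalidLifeTableError("life table must contain at least one record")
        if ages.size != q.size:
            raise InvalidLifeTableError("ages and q must have equal length")
        if np.any(np.diff(ages) != 1):
            raise InvalidLifeTableError(
                "ages must be strictly increasing and contiguous (step of 1 year)"
            )
        if np.any(~np.isfinite(q)) or np.any((q < 0) | (q > 1)):
            raise InvalidLifeTableError("q values must be probabilities in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        # dense lookup from min_age to MAX_HUMAN_AGE, clamped at the top row
        pad = np.full(max(0, MAX_HUMAN_AGE - int(ages[-1])), q[-1])
        object.__setattr__(self, "_qmap", np.concatenate([q, pad]))

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def __len__(self) -> int:
        return len(self.ages)

    def lookup(self, age) -> float | np.ndarray:
        """Return ``q(age)`` with top clamping and the age-120 hard cap.

        Accepts a scalar or an integer array.  Raises :class:`AgeRangeError`
        for any age below the tabulated minimum — there is no extrapolation
        downward because the engine should never ask for one.
        """
        a = np.asarray(age, dtype=int)
        if np.any(a < self.min_age):
            raise AgeRangeError(
                f"age {np.min(a)} below life-table minimum {self.min_age}"
            )
        idx = np.minimum(a, MAX_HUMAN_AGE - 1) - self.min_age
        out = np.where(a >= MAX_HUMAN_AGE, 1.0, self._qmap[idx])
        return float(out) if np.isscalar(age) or a.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self.q})

    def write(self, destination) -> None:
        """Write the table as CSV with headers ``age,q``.

        The provenance is stored as a leading ``# provenance:`` comment line
        so that write → load round-trips are lossless.
        """
        buf = io.StringIO()
        buf.write(f"# provenance: {self.provenance}\n")
        self.to_frame().to_csv(buf, index=False)
        Path(destination).write_text(buf.getvalue())


def load_life_table(source) -> LifeTable:
    """Load and validate a life table from 2-column CSV (headers ``age,q``).

    ``source`` may be a path or any readable text buffer.  An optional
    ``# provenance: ...`` comment line is honoured; other ``#`` lines are
    skipped.  Duplicate, gapped or non-monotone ages and q outside [0, 1]
    raise :class:`InvalidLifeTableError`.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    provenance = "unspecified"
    for line in text.splitlines():
        if line.startswith("# provenance:"):
            provenance = line.split(":", 1)[1].strip()
            break
    try:
        frame = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise InvalidLifeTableError(f"unparseable life-table CSV: {exc}") from exc
    if list(frame.columns) != ["age", "q"]:
        raise InvalidLifeTableError(
            f"expected headers 'age,q', found {list(frame.columns)!r}"
        )
    return LifeTable(frame["age"].to_numpy(), frame["q"].to_numpy(), provenance)


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Parameters of a Gompertz–Makeham hazard ``λ(a) = c + s·exp(g·a)``.

    ``makeham`` (c) is the age-independent baseline hazard per year,
    ``gompertz_scale`` (s) the senescent hazard at age 0 and
    ``gompertz_rate`` (g) its exponential growth rate per year of age.
    The defaults are roughly human-plausible and exist purely so the test
    suite is self-contained; they are not calibrated to any population.
    """

    makeham: float = 5e-4
    gompertz_scale: float = 3e-5
    gompertz_rate: float = 0.09

    def __post_init__(self):
        if min(self.makeham, self.gompertz_scale, self.gompertz_rate) < 0:
            raise ValueError("Gompertz–Makeham parameters must be non-negative")

    def hazard(self, age) -> np.ndarray:
        a = np.asarray(age, dtype=float)
        return self.makeham + self.gompertz_scale * np.exp(self.gompertz_rate * a)


def synthesize_life_table(
    params: GompertzMakehamParams | None = None, max_age: int = 110
) -> LifeTable:
    """Generate a synthetic life table with ``q(a) = 1 − exp(−λ(a))``.

    The conversion from hazard to annual probability assumes the hazard is
    constant within each year of age.  ``q`` is monotone non-decreasing in
    age whenever ``gompertz_rate > 0``.
    """
    if max_age < 1:
        raise ValueError("max_age must be at least 1")
    params = params or GompertzMakehamParams()
    ages = np.arange(0, max_age + 1)
    q = np.minimum(1.0, 1.0 - np.exp(-params.hazard(ages)))
    label = (
        f"synthetic Gompertz-Makeham (makeham={params.makeham}, "
        f"scale={params.gompertz_scale}, rate={params.gompertz_rate})"
    )
    return LifeTable(ages, q, label)


def us2016() -> LifeTable:
    """Vendored synthetic reconstruction of the US 2016 period life table.

    This is *not* the published table: the offline build cannot fetch the
    Social Security Administration file, so the fixture interpolates
    (log-linearly in ``q``) between recalled anchor values of the unweighted
    male/female mean annual death probability.  It tracks the published
    sex-combined table closely enough for the few-per-mille background
    hazards that matter over the model's age range, and its provenance label
    marks it as synthetic.
    """
    ref = resources.files("sinocea.data").joinpath("us2016_synthetic.csv")
    with ref.open("r") as fh:
        return load_life_table(fh)
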