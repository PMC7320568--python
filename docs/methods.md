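# Methods

## Model structure

The model is a pair of 3-state Markov cohort models — one per radiotherapy
strategy — fed by a one-shot decision node. States are *no cancer* (NC),
*alive with cancer* (WC) and *dead* (absorbing). Radiotherapy eradicates the
tumour with probability `p_eradicate` (IMPT 0.9, IMRT 0.73); eradicated
patients start in NC, the rest in WC. Cycles are one year; the base case runs
a 47-year-old cohort for 30 cycles, i.e. to the 77-year life-expectancy
endpoint (`horizon = endpoint_age − start_age` whenever the horizon is left
as `auto`).

Per cycle `t` (1-based), three competing events combine:

* background (non-cancer) death at the life-table probability `q(age)`, with
  `age = start_age + t − 1`; background death takes precedence in the split;
* relapse NC → WC at the schedule rate `r(t)` applied to background
  survivors: `r(t)·(1 − q)`. The schedule is 0.10/year in years 1–3,
  0.05 in years 4–5, 0.01 in years 6–10 and 0 afterwards;
* cancer death WC → dead at `d = 0.3`/year, combined with background death
  under independence: total `1 − (1 − d)(1 − q)`.

The NC row of the transition matrix is therefore
`[(1−r)(1−q), r(1−q), q]` and the WC row `[0, (1−d)(1−q), 1−(1−d)(1−q)]`.
Independence is a modelling choice — the source material for the rates does
not say how cancer and background risks interact — and is the standard
convention when a disease-specific rate must be overlaid on an all-cause
life table.

## Rewards, discounting, conventions

* One-time costs (radiotherapy $50,000 IMPT / $12,000 IMRT, plus $5,000 of
  concurrent chemotherapy in both arms) are charged at cycle 0, undiscounted.
  Chemotherapy is identical across arms and cancels exactly in ΔC.
* Each cycle `t ≥ 1` applies the transition matrix first and then accrues
  state rewards on the end-of-cycle occupancy, discounted by `(1+ρ)^−t`,
  ρ = 0.03/year. There is **no half-cycle correction**; the flag is reserved
  but unimplemented in v1.
* Utilities: NC 0.94, WC 0.47, dead 0. The first post-radiotherapy year uses
  0.47 for *both* alive states (treatment disutility). Internally
  `u_first_year = None` means "track `u_with_cancer`", so a sensitivity draw
  on the WC utility moves the first-year utility coherently; an explicit
  value decouples them.
* Recurring costs: NC pays $1,000/year follow-up; WC pays follow-up plus
  $5,000/year palliative therapy; the dead state accrues nothing, and there
  is no terminal-care cost.
* Overall survival is `OS(t) = 1 − p_dead(t)`; cycle 0 has OS = 1.

## Life tables

`q(age)` comes from a period life table with integer-age lookup (no
interpolation; cycles are annual). Ages above the tabulated maximum clamp to
the last row and `q` is forced to 1 from age 120.

The bundled fixture `us2016_synthetic.csv` is a **synthetic reconstruction**
of the sex-combined United States 2016 period life table, built as the
unweighted mean of male and female annual death probabilities at ~27 anchor
ages with log-linear interpolation in between. It is *not* the published
table — the build environment has no access to it — and the anchors are
approximate; its provenance line says so. Background mortality enters the
model only as small per-cycle corrections (≈0.003–0.03 over the base-case
age range), so few-percent anchor errors perturb the ICER by at most a few
percent (see "Known discrepancies"). For fully self-contained testing a
Gompertz–Makeham generator (`q(a) = 1 − exp(−(c + s·e^{g·a}))`, defaults
c = 5·10⁻⁴, s = 3·10⁻⁵, g = 0.09 — roughly human-plausible, calibrated to
nothing) replaces the fixture.

## Sensitivity machinery

**Parameter distributions.** Each Table-style 90% CI is converted to a
standard deviation as `(high − low)/(2·1.645)`. Probabilities and utilities
get moment-matched beta distributions (`α = m(m(1−m)/σ² − 1)`,
`β = α(1−m)/m`; infeasible moments are rejected); costs get normal
distributions truncated at 0 by resampling. A degenerate CI yields a point
mass. The source material is contradictory about the cost family (a column
says normal, a footnote says uniform); the normal reading is used.

**PSA.** `run_psa` samples all distributed parameters jointly-independently
(no correlation structure is given anywhere), reruns both arms per draw and
records (ΔC, ΔE). The acceptability `fraction_favoring_a` is the share of
draws with positive incremental NMB at λ (ties count against A). Sampling
uses one PCG64 stream; draw order is the order of the distribution list, one
block per parameter, so a fixed seed gives bit-identical reruns. When every
sampled path is a recognized scalar leaf the engine runs a vectorized kernel
over all draws at once (50,000 iterations in well under a second); otherwise
it falls back to per-iteration cohort runs. Kernel and engine are asserted
equivalent to 1e-12 in the tests.

**Tornado.** Each parameter is set to its CI endpoints one at a time (others
at base), the ICER recomputed, and entries ranked by spread. The three
dominant parameters are the two eradication probabilities and the proton
treatment cost.

**One-way thresholds.** Deterministic bisection on `ICER(x) − λ` to a
relative bracket of 1e-6, after an endpoint sign-change check (absence
raises a no-threshold error). Re-evaluating the model at the returned value
reproduces λ to better than 1e-4 relative. Eradication-probability searches
must stay on the side where ΔE > 0; the default bounds do.

**Age stratification.** Each stratum restarts the cohort at the given age
with horizon `77 − age`, all other parameters at base. The age threshold is
the largest integer start age whose ICER is at or below λ, found by scanning
all ages below the endpoint (77 cohort evaluations; cheap enough that
bisection would be pointless).

## Patient-level simulator

The microsimulator walks individual patients through exactly the cohort
engine's transition rows and reward conventions, using one PCG64 stream per
run (a block of `n` uniforms for initial states, then a block per cycle).
It serves two purposes:

1. **Oracle.** For `n` patients the empirical mean cost, mean QALY and
   survival curve must agree with the cohort trace within Monte Carlo error;
   the suite enforces 3-standard-error agreement at n up to 10⁶.
2. **Strategy selection.** `selection_fraction` pairs one patient per
   strategy per trial and votes on realized net benefit `λ·E − C`. By
   default the two arms consume **common random numbers**, the convention of
   comparative patient-level Monte Carlo in decision-modelling software:
   paths diverge only where the strategies genuinely differ (mainly the
   eradication draw, discordant with probability ≈ 0.17), so the winning
   fraction is far below the parameter-PSA acceptability. At the Chinese WTP
   it computes to ≈ 0.14 with n = 50,000. With independent pairing the
   fraction is ≈ 0.43; both are exposed.

The simulator shares all parameters with the cohort (no individual
heterogeneity) and uses no variance reduction. What passing oracle tests
show is internal consistency of the two implementations — not calibration
of the model to real patients, which no synthetic data can establish.

## Known discrepancies with the originally published figures

The package reproduces the original base case closely (ICER within ~5%, ΔC
within 0.1%, QALY totals within 0.1–0.3, all nine one-way thresholds and all
four age thresholds within their printed precision ±1, Monte Carlo selection
within 0.7 points), with two deliberate, documented exceptions:

* **Survival rows.** The originally printed 5/10-year OS values are mutually
  inconsistent: they imply a higher years-5→10 death hazard for the proton
  arm than the photon arm, impossible in any shared-parameter 3-state model,
  and the printed disease-free survival exceeds printed OS at 2 years, which
  no definition permits. The printed *DFS* rows in fact match this model's
  computed OS within ~1.6 percentage points, suggesting mislabelled curves
  at the source. This package reports OS as `1 − p_dead(t)` and makes no
  attempt to chase the printed OS row; 2-year values and the proton 5-year
  value agree with print anyway.
* **Young-age strata.** Age-stratified ICERs for start ages 0–20 sit ~6%
  below the printed sequence (older strata agree within 2–5%). The deficit
  grows with horizon length, consistent with residual life-table
  reconstruction error and/or an undocumented late-relapse tail in the
  original implementation; a ~0.005/year relapse rate beyond year 10 would
  reconcile the sequence but has no textual basis and degrades the absolute
  QALY totals, so the documented schedule (zero after year 10) is kept.

## Numerical and degenerate-input choices

* Occupancy conservation holds to 1e-12 per cycle; `p_dead` is monotone.
* Zero incremental effect makes the ICER undefined (`None`), never a
  division error, with dominance reported as `tie`/`none`.
* A start age at or above the endpoint age is rejected for stratified
  analyses; a spec whose derived horizon would be ≤ 0 is forced to one cycle.
* Life-table lookups below the tabulated minimum raise rather than
  extrapolate.
* All CLI randomness is seeded via `--seed` and recorded in the manifest;
  thresholds, traces and deterministic results carry no randomness at all.

## Problem sizes

Defaults were chosen so the whole pipeline is interactive on a laptop: the
deterministic run is ~1 ms; the 50,000-iteration PSA and the 50,000-trial
paired simulation each run in well under a second via the vectorized
kernels; the 10⁶-patient oracle check takes a few seconds. The test suite
uses 2·10⁵-patient simulations for routine oracle checks and reserves 10⁶
for the final consistency battery.
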