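# Methods

## The problem

A laboratory HbA1c measurement summarises roughly three months of glycaemia
in a single number, because glucose binds haemoglobin non-enzymatically over
the ~120-day life of a red blood cell. Clinically it is usually translated
to an "estimated average glucose" through a population regression, which
treats every day of the preceding window as equally informative. It is not:
recent glucose is seen by every circulating cell, the earliest glucose only
by the oldest cells. Two patients with the same three-month mean — one
improving, one newly out of control — therefore deserve different HbA1c
interpretations, and an unweighted mean masks the difference.

`glycalc` implements a chronologically weighted estimator on top of the
published relations, and a first-principles erythrocyte-cohort engine that
both validates the kinetic closed form and quantifies how much each
backward-looking month really contributes.

## Models

All glucose values are mg/dl unless stated; 1 mmol/l = 18.0156 mg/dl
(glucose molar mass 180.156 g/mol).

**ADAG regression** (`eag_from_hba1c` / `hba1c_from_eag_adag`):
`eAG = 28.7·HbA1c − 46.7`, invertible, kept as a distinct named model and
never silently substituted for the one below.

**Simulated-ADAG linear model** (`hba1c_linear`):
`HbA1c(%) = 0.0296·eAG + 2.419`.

**Kinetic closed form** (`hba1c_kinetic`): with exposure
`x = k·LS·eAG` (k = 1.296×10⁻⁹ l/(mmol·s), LS = 120 d = 10 368 000 s,
eAG in mmol/l),

    HbA1c(%) = 91.5 · (1 − (1 − e^(−x))/x) + 2.15.

The units must be made self-consistent by the implementer: k is per
mmol·s, so LS goes in as seconds and eAG in mmol/l. A pre-build check
confirmed that the conversion factor 18.0156 reproduces every reference
kinetic value at two-decimal rounding, while the common shortcut 18.0 does
not (it shifts 7.71 → 7.72 and 8.80 → 8.81); the exact molar-mass factor is
therefore the default and lives in the overridable constants table.
For `x < 10⁻⁶` the bracket is evaluated by its series `x/2 − x²/6`
(error < 10⁻¹² there), so the function is continuous with limit 2.15% as
glucose → 0.

**Weighted average glucose** (`weighted_ag` / `weighted_hba1c`):
`wAG = Σ wₘ·AGMₘ` over backward-looking 30-day monthly means, earliest
first. Presets: `default3` = (0.20, 0.30, 0.50), `fourmonth` =
(0.10, 0.15, 0.25, 0.50), `tahara3` = (0.25, 0.25, 0.50); in all of them
the most recent month carries half the weight. Profiles and schemes both
carry chronological labels (AGM-3 … AGM-1) and are paired by label, because
mixing earliest-first with most-recent-first ordering is the most likely
usage bug. Schemes that do not sum to 1 (within 10⁻¹²) are rejected, not
renormalised: the masking behaviour the weighting is meant to expose
depends on exact normalisation.

## The cohort engine

The kinetic closed form assumes constant glucose. The engine in
`kinetic_core` drops that assumption. A single cell's non-glycated fraction
h obeys dh/dt = −k·h·AG(t) with h(0) = 1, so a cell of age `a` carries the
glycated fraction

    g(a) = 1 − exp(−k · ∫ AG over the most recent a seconds).

(The decaying quantity must be the *non-glycated* fraction: that is the
only reading under which the age-average reproduces the closed form's
`1 − (1 − e^(−x))/x`.) Blood HbA1c averages g over cell ages uniform on
[0, LS] and maps through scale/offset. For piecewise-constant trajectories
the exposure is linear in age within each segment, so the age-average has a
closed form per segment and is evaluated exactly; midpoint quadrature over
ages is available as the independent numerical route and converges
monotonically to it. At constant glucose the exact route matches
`hba1c_kinetic` to better than 10⁻⁹ percent — the engine is the oracle for
the closed form, derived by a different path.

Trajectories shorter than the life span are rejected; extending the
earliest level backward is available only through an explicit
`pad_to_days` argument, because silent padding changes results.

`implied_month_weights` perturbs each backward 30-day window by ±1% of a
constant baseline (central differences; small enough for linearity, large
enough for stable floating-point differences) and normalises the
sensitivities. At a 170 mg/dl baseline with three 30-day windows it yields
≈ (0.196, 0.332, 0.472) — the 20/30/50 preset is, to a few points, what the
kinetics itself implies; with four windows the most recent one carries
≈ 0.44, close to the folk figure of one half.

## Scenarios and the comparison table

Three built-in archetypes share the plain 3-month mean 170 mg/dl:
steady-state control ISSC (180, 170, 160), improving control IIC
(250, 160, 100), newly diagnosed IND (100, 100, 310). The comparison table
computes, per archetype, the plain-mean eAG, wAG, and HbA1c under the
linear and kinetic maps applied to each. The unweighted column is constant
across archetypes (7.45% linear, 7.71% kinetic) while the weighted column
separates them (7.36 / 6.80 / 8.49% linear; 7.62 / 7.02 / 8.80% kinetic).

The relative difference between the kinetic and weighted-linear estimates
uses the kinetic (larger) value as denominator — the ratio is not uniquely
defined by the claim it quantifies, so the choice is documented here and
exposed as an argument. Per archetype it is 3.37%, 3.13% and 3.58%
(mean 3.36%, i.e. ≈3% and nearly the same for all three); note 3.58 rounds
to 4 at the nearest integer, so "≈3%" is asserted in tests as "in [3, 4)
with mutual spread < 0.5 points", with the nearest-integer claim reserved
for the mean.

## Rounding and display

Internal computation is never rounded. Human-facing renderings round half
away from zero — 2 decimals for percent, integers for mg/dl — matching how
such tables are conventionally printed (Python's built-in banker's rounding
would print 8.485 as 8.48). Machine-readable outputs carry full-precision
`_raw` columns alongside.

## Aggregation of raw readings

A "month" is a backward 30-day window from the test date, not a calendar
month: deterministic across locales and consistent with equal-month
weighting. Windows are half-open `[start, end)`; the most recent window
excludes the test instant itself (a reading at exactly that instant belongs
to no window and triggers a warning). The window mean is a plain arithmetic
mean of whatever readings fall inside — no weighting by time of day or
fasting state, a deliberate simplification. `min_readings` defaults to 1;
sparse self-monitoring data is surfaced via per-window reading counts in
the report rather than imputed.

## Synthetic generator

`generate_readings` emulates a patient taking K finger-stick readings per
day at fixed clock times ((j + 0.5)·24/K hours), each equal to the window's
target mean plus independent N(0, σ) noise truncated below at 1 mg/dl. One
`numpy` generator seeded from a single integer drives all randomness; the
same seed gives a byte-identical CSV. Defaults are noiseless with one
reading per day — the archetype scenarios are defined by exact monthly
means, so the generator's job is to reconstruct them through the I/O and
aggregation path. The noisy parameter-recovery check uses σ = 20 mg/dl,
4 readings/day and 200 replicate seeds, for a per-window standard error of
about 0.13 mg/dl.

What the generator does *not* emulate: meal excursions, dawn phenomenon,
hypoglycaemic episodes, autocorrelation, measurement-device bias. Passing
tests therefore demonstrate the correctness of the aggregation and
estimation pipeline, not that weighted HbA1c is accurate on real
self-monitoring data.

## Numerical choices and degenerate inputs

* Small-exposure series switch at x = 10⁻⁶ (see above); the per-segment
  exact integral has an analogous guard for near-zero glucose segments.
* Unit conversion is one multiplicative constant; round-trips are exact to
  10⁻¹² relative.
* Negative glucose, HbA1c below the ADAG zero-crossing (46.7/28.7 ≈
  1.63%), cell ages outside trajectory coverage, empty aggregation windows
  and unnormalised weight schemes all raise typed errors rather than
  propagating NaNs.
* `relative_variation` refuses a zero denominator.

## Limitations

Uniform cell-age distribution and a fixed 120-day life span (anaemias and
haemoglobinopathies violate both); a single rate constant k taken from the
literature, not fitted; monthly-resolution glucose only (intra-day dynamics
out of scope); the linear models are population regressions and inherit
their calibration ranges. The weighted estimator is a heuristic
re-weighting of a population formula, not a patient-specific kinetic fit.
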