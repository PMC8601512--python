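# Methods

## Severity-adjusted performance metrics

**Risk model.** Expected mortality comes from the SAPS-3 logistic
equation `logit(p) = intercept + slope · ln(score + offset)` with the
published global admission coefficients (−32.6659, 7.3068, 20.5958) as
the default (`Saps3Coefficients` is a value object, so recalibrated
regional equations drop in without code changes).  The equation predicts
*hospital* mortality; the SMR outcome is therefore `hospital` by default,
with an `icu` option for analyses that count ICU deaths — both are
supported and neither is privileged beyond the default.

**SMR.** Per unit: observed deaths / Σ predicted risks.  A unit whose
expected deaths are zero gets a missing SMR (never ±∞) and is excluded
from frontier analysis with a warning.

**SRU.** ICU length of stay is the resource surrogate.  The cohort is
cut into SAPS-3 quantile bands (deciles by default; `n_strata`
configurable).  Each band's reference is (total ICU LOS of all cohort
patients in the band) / (cohort survivors in the band); a unit's expected
use is Σ over bands of (its survivors in the band × reference).  Bands
without survivors merge into the adjacent lower band.  Two consequences
worth knowing: the cohort treated as one unit has SRU exactly 1
(standardization closure, tested to 1e−12), and survivorship follows the
same outcome definition as the SMR.

## DEA solver

Envelopment-form BCC (variable returns to scale) problems are solved
with `scipy.optimize.linprog` (HiGHS dual simplex, primal/dual
feasibility tolerances 1e−9) in two phases: the radial LP, then slack
maximisation at the fixed radial optimum.  Design choices:

* **Efficiency tolerance.** `|score − 1| ≤ 1e−6` classifies "efficient";
  scores within tolerance are snapped to exactly 1.  Weak efficiency
  (score 1 with nonzero phase-2 slacks) is reported as a separate flag,
  since a radial score of 1 alone does not imply Pareto efficiency.
* **Peer degeneracy.** Alternative optima can spread λ across equivalent
  peers.  The phase-2 optimum of a fixed deterministic solver
  configuration is reported, and strongly efficient units (score 1, zero
  slacks) are canonically assigned `λ_self = 1`, so reference counts are
  reproducible and an all-efficient dataset yields all-zero counts.
* **Strict positivity.** Zeros and negatives are rejected at ingestion
  with an error naming the unit and variable — no silent ε-substitution.
* **Undesirable variables.** SMR, SRU (and occupancy in the capacity
  model) enter as reciprocals; projection targets are mapped back with
  `1/t`, so reported targets live on the original scale and respect the
  orientation's direction (staffing targets never above current levels in
  model A, SMR/SRU targets never above current values, occupancy targets
  never below).

The test suite checks the solver against two independent routes: a
brute-force grid over the peer-weight simplex at resolution 1/400 (up to
3 units — beyond that the grid is combinatorial) and a from-scratch
two-phase tableau simplex with Bland's rule that shares no code with the
HiGHS path (up to 5 units, exact).

## Efficiency matrix

Median split of SMR and SRU over units with both metrics defined.  The
tie rule at the median is `≤ median → "low"` by default (documented and
configurable to strict `<`): the data do not dictate a convention, so one
is fixed and stated.  Units missing either metric are excluded and
logged.

## Grouped summaries

Non-discretionary groupings: hospital administration (public /
philanthropic / for-profit), hospital size (small < 100 beds, medium
100–200 inclusive, large > 200), specialization (specialized = ICU type
other than mixed or general medical), and ICU-bed proportion
(`icu_beds / hospital_beds`) terciles.  Tercile cut points default to the
fixed reference values 4.70% / 9.57% — exactly 4.70% is "low" and exactly
9.57% is "high" — with a `data` mode that recomputes terciles from the
cohort at hand.  All medians/IQRs use the linear-interpolation quantile
convention.

## Synthetic cohort generator

What it emulates, and the defaults (all overridable in `CohortConfig`):

* **Units (93 by default).** Bed counts drawn from banded weights
  (<10: 0.40, 11–30: 0.48, 31–50: 0.11, >50: 0.01 → median ≈ 13–17
  beds); staffing ratios per 10 beds and weekly hours log-normal around
  the reference medians (physicians 1.67, nurses 1.71, techs 5.0,
  physios 1.0; 372 and 396 h/week) with log-sds matched to the reported
  IQRs; occupancy Beta(13.79, 3.13), quantile-matched to median 0.83,
  IQR [0.75, 0.87]; organisational categories drawn with the reference
  frequencies.  Roughly 0.6 hospitals per ICU, so some hospitals run
  several units; hospital-level fields are shared within a hospital.
* **Patients.** Admissions per unit are Poisson with mean
  beds × occupancy × period / E[LOS] (census identity; 730-day window by
  default, ≈ 130k admissions at 93 units).  SAPS-3 is a zero-truncated
  normal (location 44, scale 15), reproducing the reference IQR 34–54.
  ICU LOS is log-normal with median 3 days, log-sd 1.25 plus a severity
  slope of 0.3 log-days per severity SD — right-skewed, cohort median
  ≈ 3, IQR ≈ 1.2–7.
* **Mortality.** Hospital death probability = SAPS-3 risk × a log-normal
  unit effect (sd `unit_effect_sd`, default 0.3 — chosen to reproduce an
  SMR IQR of roughly 0.8–1.2 across units), clipped to (0,1).  With the
  unit effect at 0 every unit's true hospital SMR is 1, which is what the
  null-model tests exercise.  ICU death is a coupled sub-event of
  hospital death whose marginal rate is calibrated to
  `mortality_calibration` (default 0.12) by a scalar logit shift found by
  root-finding on the drawn cohort — the shape of the risk curve is
  preserved, only its level moves.
* **Planted frontier.** `plant_frontier` rewrites the merged
  unit+performance table: planted units get identical inputs (the column
  medians) and SMR/SRU on a strictly concave trade-off arc — each is
  therefore an extreme, efficient point in *any* model built from these
  variables — while every other unit is made worse than some planted unit
  by at least the dominance margin on every variable, hence provably
  off the frontier.  The rewritten table is a testing device: counts stop
  being integers and the joint distribution is no longer realistic.

**What the generator does not emulate** (so what passing tests do not
show): readmissions and transfers, correlation between staffing,
occupancy and unit size (all drawn independently), within-hospital
correlation of unit effects, case-mix differences between units (every
unit samples severity from the same distribution), and seasonal or
secular trends.  Synthetic results validate the *machinery* —
calibration, standardization closure, frontier recovery — not the
substantive efficiency rankings of any real cohort, and the efficient-unit
counts on synthetic data differ from those of the observed multicenter
cohort the defaults imitate.

## Problem sizes and numerical notes

The test suite runs ~1–2k-patient cohorts for pipeline mechanics, 200
random DEA instances (≤ 5 units) against the oracles, ≥ 10,000
admissions/unit for the null-SMR check and ~50,000 admissions for the
planted-multiplier check; the acceptance script uses the full default
cohort (93 units, ~130k admissions) and completes in seconds.  All
randomness flows through `numpy.random.default_rng` seeded from the
config, and CSV output uses fixed float formatting, so identical
config + seed gives byte-identical files.  The planted-multiplier oracle
accounts for probability clipping at 1 (a ×2 multiplier on an already
high risk cannot double it), comparing the realized SMR against the
clipped expectation rather than against 2 exactly.

## Known limitations

Constant-returns (CCR) frontiers, super-efficiency, weight restrictions,
Malmquist indices and stochastic frontier analysis are out of scope.
Peer sets are reproducible but not unique where the LP has alternative
optima.  DEA treats all variables as continuous and deterministic:
sampling noise in SMR/SRU propagates directly into scores, so small
units sit on or off the frontier partly by chance.
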