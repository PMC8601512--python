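# icudea

Efficiency benchmarking for intensive care units (ICUs) that accounts for
the *resources* a unit consumes, not just its risk-adjusted outcomes.

Classical ICU benchmarking compares two severity-adjusted performance
metrics — the Standardized Mortality Ratio (SMR, observed/expected deaths
under the SAPS-3 risk equation) and the Standardized Resource Use (SRU,
observed/expected ICU bed-days given admission severity) — and splits
units into four quadrants at the cohort medians ("most efficient",
"overachieving", "least efficient", "underachieving").  That view ignores
staffing and structure.  `icudea` adds Data Envelopment Analysis (DEA):
each ICU is a decision-making unit scored against the best convex
combinations of its peers on a variable-returns-to-scale (BCC) frontier,

```
input orientation:   min θ   s.t.  Σⱼ λⱼ xᵢⱼ ≤ θ xᵢ₀,  Σⱼ λⱼ y_rⱼ ≥ y_r₀,  Σⱼ λⱼ = 1, λ ≥ 0
output orientation:  max φ   s.t.  Σⱼ λⱼ xᵢⱼ ≤ xᵢ₀,   Σⱼ λⱼ y_rⱼ ≥ φ y_r₀, Σⱼ λⱼ = 1, λ ≥ 0
```

followed by a slack-maximisation phase at the fixed radial optimum.  A
unit is efficient when its score is 1; for every non-efficient unit the
peer weights λ define concrete improvement targets Σλ·x, Σλ·y.  Because
SMR and SRU are "the lower, the better", they enter the models as
reciprocals (and so does bed occupancy where low occupancy is the easy
condition).

Three built-in models look at the frontier from different angles:

| model | focus     | inputs                                                | outputs  | orientation |
|-------|-----------|-------------------------------------------------------|----------|-------------|
| A     | staffing  | physicians, nurses, nursing techs, physios per 10 beds | SMR, SRU | input       |
| B     | structure | ICU beds, physician hours/week, nurse hours/week       | SMR, SRU | output      |
| C     | capacity  | bed occupancy rate (reciprocal)                        | SMR, SRU | input       |

A synthetic cohort generator (93 ICUs, ~130k admissions by default,
SAPS-3 centred at 44, pooled ICU mortality 12%, ICU LOS median 3 days)
makes the whole pipeline runnable and testable without any patient data,
including a "planted frontier" mode in which the truly efficient units
are known by construction.

## Worked example

```bash
icu-dea simulate --out demo --seed 1          # units.csv + patients.csv
icu-dea metrics --patients demo/patients.csv --out demo/perf.csv
icu-dea run --units demo/units.csv --precomputed-performance demo/perf.csv --out demo/report
```

or in one go from Python:

```python
from icudea import CohortConfig, PipelineConfig, run_pipeline
bundle = run_pipeline(PipelineConfig(simulate=CohortConfig(seed=1), out_dir="demo/report"))
```

On the default seed-1 cohort (93 ICUs, 132,069 admissions) this prints

```
efficient units per model: {"A": 29, "B": 14, "C": 6}
```

and writes, among others, `dea_scores.csv` (per-unit radial score,
efficient flag, peers, reference counts), `dea_targets.csv`
(original-scale input/output targets for every unit),
`efficiency_matrix.csv` (quadrant labels with the medians used, here
SMR median 1.004, SRU median 0.962) and `quadrant_summary.csv`.  Units in
the "most efficient" quadrant average the best DEA scores (0.939 in
model A and 0.884 in model C, where 1 is best from below; 1.277 in the
output-oriented model B, where 1 is best from above) — the frontier view
and the quadrant view largely agree, while DEA additionally tells each
non-efficient unit *which* peers to emulate and by how much to move each
variable.

Patient-level CSVs need columns `unit_id, saps3, icu_los, icu_death,
hospital_death`; unit-level CSVs the staffing/structure columns named in
the table above plus `occupancy` (see `docs/methods.md` for the full
schema).  Observed cohorts drop straight in: point `--patients`/`--units`
at your own files, or supply unit-level SMR/SRU directly via
`--precomputed-performance`.

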