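"""Three-model ICU benchmarking pipeline.

Wires the stages together: severity metrics -> DEA models A/B/C ->
efficiency matrix -> group summaries, with CSV/JSON input and output.

The three built-in model specifications:

========  =========  ================================================  ===========
model     focus      inputs                                            orientation
========  =========  ================================================  ===========
A         staffing   physicians, nurses, nursing technicians and
                     physiotherapists per 10 beds                      input
B         structure  ICU beds, physicians' and nurses' weekly hours    output
C         capacity   bed occupancy rate (reciprocal scale)             input
========  =========  ================================================  ===========

All three use SMR and SRU as outputs on the reciprocal scale, since for
both metrics lower is better.  Occupancy is also entered reciprocally in
model C: low occupancy is the easier condition, so its reciprocal acts
as the resource being consumed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .dea_core import (
    DEADataset,
    DEAResult,
    back_transform_targets,
    evaluate_all,
    reference_counts,
)
from .efficiency_matrix import classify_quadrants, fig1_table, quadrant_dea_summary
from .severity_metrics import SAPS3_GLOBAL, compute_performance
from .synthetic_data import (
    CohortConfig,
    generate_patients,
    generate_units,
    write_patients_csv,
    write_units_csv,
)

__all__ = [
    "DEAModelSpec",
    "ModelReport",
    "PipelineConfig",
    "builtin_model_specs",
    "run_model",
    "efficient_group_comparison",
    "group_efficiency_summary",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: tercile cut points of ICU-bed proportion used by the reference analysis
FIXED_TERCILE_CUTOFFS = (0.047, 0.0957)
#: ICU types regarded as specialized (not mixed, not general medical)
SPECIALIZED_TYPES = {"surgical", "neurological", "other"}


class DEAModelSpec(BaseModel):
    """A named DEA model: variable lists, orientation, reciprocal flags."""

    model_config = ConfigDict(frozen=True)

    name: str
    focus: str = ""
    input_variables: tuple[str, ...]
    output_variables: tuple[str, ...]
    orientation: Literal["input", "output"]
    inverted_variables: frozenset[str] = frozenset()

    @model_validator(mode="after")
    def _check(self):
        if not self.input_variables or not self.output_variables:
            raise ValueError("input and output variable lists must be non-empty")
        overlap = set(self.input_variables) & set(self.output_variables)
        if overlap:
            raise ValueError(f"variables cannot be both input and output: {sorted(overlap)}")
        stray = self.inverted_variables - set(self.input_variables) - set(self.output_variables)
        if stray:
            raise ValueError(f"inverted variables not in the model: {sorted(stray)}")
        return self


def builtin_model_specs() -> list[DEAModelSpec]:
    """The staffing (A), structure (B) and capacity (C) models."""
    return [
        DEAModelSpec(
            name="A",
            focus="staffing",
            input_variables=(
                "physicians_per_10_beds",
                "nurses_per_10_beds",
                "nursing_techs_per_10_beds",
                "physios_per_10_beds",
            ),
            output_variables=("smr", "sru"),
            orientation="input",
            inverted_variables=frozenset({"smr", "sru"}),
        ),
        DEAModelSpec(
            name="B",
            focus="structure",
            input_variables=("icu_beds", "physician_hours_week", "nurse_hours_week"),
            output_variables=("smr", "sru"),
            orientation="output",
            inverted_variables=frozenset({"smr", "sru"}),
        ),
        DEAModelSpec(
            name="C",
            focus="capacity",
            input_variables=("occupancy",),
            output_variables=("smr", "sru"),
            orientation="input",
            inverted_variables=frozenset({"smr", "sru", "occupancy"}),
        ),
    ]


@dataclasses.dataclass
class ModelReport:
    """Everything one DEA model produced for the cohort."""

    spec: DEAModelSpec
    dataset: DEADataset
    results: list[DEAResult]
    reference_counts: dict[str, int]
    excluded_units: list[str]
    data: pd.DataFrame  # original-scale model variables, one row per scored unit

    @property
    def efficient_ids(self) -> set[str]:
        return {r.dmu_id for r in self.results if r.efficient}

    def scores_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            peers = sorted(r.lambdas)
            rows.append(
                {
                    "unit_id": r.dmu_id,
                    "model": self.spec.name,
                    "orientation": r.orientation,
                    "score": r.score,
                    "efficient": r.efficient,
                    "weakly_efficient": r.weakly_efficient,
                    "reference_count": self.reference_counts.get(r.dmu_id, 0),
                    "peers": ";".join(peers),
                }
            )
        return pd.DataFrame(rows)

    def targets_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"unit_id": r.dmu_id, "model": self.spec.name, "efficient": r.efficient}
            for var, val in (r.targets_original_scale or {}).items():
                row[f"target_{var}"] = val
            rows.append(row)
        return pd.DataFrame(rows)


def _merge_unit_data(
    units: pd.DataFrame, performance: pd.DataFrame | None
) -> pd.DataFrame:
    if performance is None:
        if not {"smr", "sru"} <= set(units.columns):
            raise ValueError(
                "unit table has no smr/sru columns and no performance table given"
            )
        return units.copy()
    cols = ["unit_id", "smr", "sru"]
    merged = units.drop(columns=["smr", "sru"], errors="ignore").merge(
        performance[cols], on="unit_id", how="inner", validate="one_to_one"
    )
    return merged


def run_model(
    spec: DEAModelSpec,
    units: pd.DataFrame,
    performance: pd.DataFrame | None = None,
) -> ModelReport:
    """Assemble the model's dataset, score every unit, compute peers,
    reference counts and original-scale targets.

    Units with missing or non-positive values on any model variable are
    excluded with a warning (frontier analysis needs strictly positive
    data); fewer than two usable units is an error.
    """
    merged = _merge_unit_data(units, performance)
    variables = list(spec.input_variables) + list(spec.output_variables)
    missing_cols = [v for v in variables if v not in merged.columns]
    if missing_cols:
        raise ValueError(f"model {spec.name}: unit data lacks columns {missing_cols}")
    vals = merged[variables].apply(pd.to_numeric, errors="coerce")
    usable = (vals.notna() & (vals > 0)).all(axis=1)
    excluded = merged.loc[~usable, "unit_id"].astype(str).tolist()
    if excluded:
        logger.warning(
            "model %s: excluding units with missing/non-positive variables: %s",
            spec.name,
            excluded,
        )
    frame = merged.loc[usable].reset_index(drop=True)
    if len(frame) < 2:
        raise ValueError(f"model {spec.name}: fewer than 2 usable units")
    dataset = DEADataset.from_dataframe(
        frame,
        dmu_column="unit_id",
        input_columns=spec.input_variables,
        output_columns=spec.output_variables,
        inverted=spec.inverted_variables,
    )
    results = [
        back_transform_targets(r, dataset)
        for r in evaluate_all(dataset, spec.orientation)
    ]
    return ModelReport(
        spec=spec,
        dataset=dataset,
        results=results,
        reference_counts=reference_counts(results),
        excluded_units=excluded,
        data=frame[["unit_id", *variables]],
    )


def _median_iqr(series: pd.Series) -> tuple[float, float, float]:
    if len(series) == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.quantile(series.to_numpy(float), [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def efficient_group_comparison(reports: Sequence[ModelReport]) -> pd.DataFrame:
    """Median [IQR] of each model variable, efficient vs non-efficient.

    One row per model x variable; statistics are missing when a group is
    empty (e.g. every unit efficient).
    """
    rows = []
    for rep in reports:
        eff = rep.efficient_ids
        is_eff = rep.data["unit_id"].astype(str).isin(eff)
        for var in (*rep.spec.input_variables, *rep.spec.output_variables):
            e_med, e_q1, e_q3 = _median_iqr(rep.data.loc[is_eff, var])
            n_med, n_q1, n_q3 = _median_iqr(rep.data.loc[~is_eff, var])
            rows.append(
                {
                    "model": rep.spec.name,
                    "variable": var,
                    "efficient_median": e_med,
                    "efficient_q1": e_q1,
                    "efficient_q3": e_q3,
                    "nonefficient_median": n_med,
                    "nonefficient_q1": n_q1,
                    "nonefficient_q3": n_q3,
                    "n_efficient": int(is_eff.sum()),
                    "n_nonefficient": int((~is_eff).sum()),
                }
            )
    return pd.DataFrame(rows)


def _bed_proportion_tercile(
    values: pd.Series, mode: Literal["fixed", "data"], cutoffs=FIXED_TERCILE_CUTOFFS
) -> pd.Series:
    if mode == "data":
        lo, hi = np.quantile(values.to_numpy(float), [1 / 3, 2 / 3])
    else:
        lo, hi = cutoffs
    # boundary rules: exactly `lo` is low, exactly `hi` is high
    return pd.Series(
        np.select([values <= lo, values >= hi], ["low", "high"], default="medium"),
        index=values.index,
    )


def group_efficiency_summary(
    reports: Sequence[ModelReport],
    units: pd.DataFrame,
    performance: pd.DataFrame | None = None,
    tercile_mode: Literal["fixed", "data"] = "fixed",
) -> pd.DataFrame:
    """Mean DEA scores, mean SMR/SRU and efficient counts per category of
    each non-discretionary grouping variable (hospital administration,
    hospital size, specialization, ICU-bed-proportion tercile)."""
    merged = _merge_unit_data(units, performance)
    merged = merged.set_index(merged["unit_id"].astype(str))
    known_admin = {"public", "philanthropic", "for_profit"}
    bad = set(merged["admin"]) - known_admin
    if bad:
        raise ValueError(f"unknown hospital administration value(s): {sorted(bad)}")
    groups = {
        "admin": merged["admin"],
        "hospital_size": merged["hospital_size_category"],
        "specialized": merged["icu_type"].map(
            lambda t: "yes" if t in SPECIALIZED_TYPES else "no"
        ),
        "bed_proportion_tercile": _bed_proportion_tercile(
            merged["bed_proportion"], tercile_mode
        ),
    }
    score_of = {
        rep.spec.name: {r.dmu_id: r.score for r in rep.results} for rep in reports
    }
    eff_of = {rep.spec.name: rep.efficient_ids for rep in reports}
    rows = []
    for gvar, labels in groups.items():
        for cat in sorted(labels.unique()):
            uids = labels.index[labels == cat]
            row = {"grouping_variable": gvar, "category": cat, "n": len(uids)}
            for rep in reports:
                name = rep.spec.name
                svals = [score_of[name][u] for u in uids if u in score_of[name]]
                row[f"mean_score_{name}"] = float(np.mean(svals)) if svals else np.nan
                row[f"n_efficient_{name}"] = sum(u in eff_of[name] for u in uids)
            row["mean_smr"] = float(merged.loc[uids, "smr"].mean())
            row["mean_sru"] = float(merged.loc[uids, "sru"].mean())
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end run


class PipelineConfig(BaseModel):
    """Configuration of a full benchmarking run.

    Exactly one source of unit data must resolve: CSV paths for observed
    data, or ``simulate`` for a synthetic cohort.  ``precomputed_performance``
    skips the patient-level metrics stage and reads unit-level SMR/SRU
    directly (original, non-reciprocal scale).
    """

    model_config = ConfigDict(frozen=True)

    units: Path | None = None
    patients: Path | None = None
    precomputed_performance: Path | None = None
    simulate: CohortConfig | None = None
    models: tuple[str, ...] = ("A", "B", "C")
    outcome: Literal["hospital", "icu"] = "hospital"
    n_strata: int = Field(10, ge=1)
    tercile_mode: Literal["fixed", "data"] = "fixed"
    tie_rule: Literal["le", "lt"] = "le"
    out_dir: Path = Path("icudea_out")
    seed: int | None = None  # overrides simulate.seed when set

    @model_validator(mode="after")
    def _sources(self):
        if self.simulate is None and self.units is None:
            raise ValueError("either 'simulate' or a 'units' CSV is required")
        if (
            self.simulate is None
            and self.patients is None
            and self.precomputed_performance is None
        ):
            raise ValueError(
                "need 'patients' or 'precomputed_performance' (or 'simulate')"
            )
        unknown = set(self.models) - {"A", "B", "C"}
        if unknown:
            raise ValueError(f"unknown model names: {sorted(unknown)}")
        return self


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute metrics -> DEA models -> matrix -> summaries; write CSVs
    and a JSON manifest into ``config.out_dir``.  Returns the bundle of
    in-memory results keyed by artefact name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        patients = None
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            if config.seed is not None:
                sim = sim.model_copy(update={"seed": config.seed})
            units = generate_units(sim)
            patients = generate_patients(units, sim)
            write_units_csv(units, out / "units.csv")
            write_patients_csv(patients, out / "patients.csv")
        else:
            units = pd.read_csv(config.units)
            if config.patients is not None:
                patients = pd.read_csv(config.patients)

        stage = "metrics"
        if config.precomputed_performance is not None:
            performance = pd.read_csv(config.precomputed_performance)
        else:
            performance = compute_performance(
                patients, SAPS3_GLOBAL, config.outcome, config.n_strata
            )
        performance.to_csv(out / "unit_performance.csv", index=False)

        stage = "dea"
        specs = [s for s in builtin_model_specs() if s.name in config.models]
        reports = [run_model(spec, units, performance) for spec in specs]
        scores = pd.concat([r.scores_frame() for r in reports], ignore_index=True)
        targets = pd.concat([r.targets_frame() for r in reports], ignore_index=True)
        scores.to_csv(out / "dea_scores.csv", index=False)
        targets.to_csv(out / "dea_targets.csv", index=False)

        stage = "matrix"
        labels = classify_quadrants(performance, config.tie_rule)
        labels.to_csv(out / "efficiency_matrix.csv", index=False)
        by_model = {r.spec.name: r.results for r in reports}
        refs = {r.spec.name: r.reference_counts for r in reports}
        quad = quadrant_dea_summary(labels, by_model)
        quad.to_csv(out / "quadrant_summary.csv", index=False)
        fig1 = fig1_table(labels, by_model, refs)
        fig1.to_csv(out / "fig1_data.csv", index=False)

        stage = "summaries"
        eff_vs_non = efficient_group_comparison(reports)
        eff_vs_non.to_csv(out / "efficient_vs_nonefficient.csv", index=False)
        group = group_efficiency_summary(
            reports, units, performance, config.tercile_mode
        )
        group.to_csv(out / "group_summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "icudea_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": json.loads(config.model_dump_json()),
        "efficiency_tolerance": 1e-6,
        "excluded_units": {r.spec.name: r.excluded_units for r in reports},
        "n_units_scored": {r.spec.name: len(r.results) for r in reports},
        "outputs": [
            "unit_performance.csv",
            "dea_scores.csv",
            "dea_targets.csv",
            "efficiency_matrix.csv",
            "quadrant_summary.csv",
            "fig1_data.csv",
            "efficient_vs_nonefficient.csv",
            "group_summary.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "units": units,
        "patients": patients,
        "performance": performance,
        "reports": reports,
        "labels": labels,
        "quadrant_summary": quad,
        "fig1": fig1,
        "efficient_vs_nonefficient": eff_vs_non,
        "group_summary": group,
        "manifest": manifest,
    }
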