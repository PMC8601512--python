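"""Synthetic ICU cohort generator.

Emulates a multicenter ICU benchmarking dataset at two levels: a
unit-level table (beds, staffing ratios per 10 beds, weekly staffing
hours, occupancy, organisational categories) and a patient-level table
(admission severity on the SAPS-3 scale, ICU/hospital length of stay and
vital status).  Defaults are calibrated to a Brazilian multicenter
cohort profile: 93 ICUs, SAPS-3 centred at 44 (IQR roughly 34-54),
pooled ICU mortality near 12%, ICU length of stay with median 3 days and
a heavy right tail, occupancy around 0.83.

Hospital death is simulated directly from the SAPS-3 risk equation times
a log-normal unit effect, so with the unit effect switched off every
unit's true hospital SMR is 1.  ICU death is a coupled sub-event whose
marginal rate is calibrated to ``mortality_calibration`` by a scalar
shift of the risk logit (bisection), preserving the shape of the risk
curve.

``plant_frontier`` rewrites a unit-level table so that a chosen subset
is provably DEA-efficient and everything else is strictly dominated — a
testing device that makes the true frontier known.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy import optimize, stats
from scipy.special import expit

from .severity_metrics import SAPS3_GLOBAL, Saps3Coefficients, saps3_logit

__all__ = [
    "CohortConfig",
    "generate_units",
    "generate_patients",
    "plant_frontier",
    "write_units_csv",
    "write_patients_csv",
]

#: bed-count bands of the unit-size distribution and their integer ranges
BED_BANDS: dict[str, tuple[int, int]] = {
    "<10": (4, 9),
    "11-30": (10, 30),
    "31-50": (31, 50),
    ">50": (51, 60),
}
HOSPITAL_SIZE_BANDS: dict[str, tuple[int, int]] = {
    "small": (60, 99),
    "medium": (100, 200),
    "large": (201, 700),
}

UNIT_COLUMNS = [
    "unit_id",
    "hospital_id",
    "icu_beds",
    "hospital_beds",
    "physicians_per_10_beds",
    "nurses_per_10_beds",
    "nursing_techs_per_10_beds",
    "physios_per_10_beds",
    "physician_hours_week",
    "nurse_hours_week",
    "occupancy",
    "admin",
    "icu_type",
    "hospital_size_category",
    "bed_proportion",
]
PATIENT_COLUMNS = [
    "patient_id",
    "unit_id",
    "age",
    "admission_type",
    "saps3",
    "icu_los",
    "hospital_los",
    "icu_death",
    "hospital_death",
]


def _validate_weights(name: str, weights: Mapping[str, float]) -> None:
    vals = np.array(list(weights.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError(f"{name}: weights must be nonnegative")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name}: weights must sum to 1 (got {vals.sum()!r})")


class CohortConfig(BaseModel):
    """Everything the generator needs; identical config + seed gives
    byte-identical CSV output."""

    model_config = ConfigDict(frozen=True)

    n_units: int = Field(93, gt=0)
    seed: int = 0

    # unit level -----------------------------------------------------------
    beds_distribution: dict[str, float] = {
        "<10": 0.40,
        "11-30": 0.48,
        "31-50": 0.11,
        ">50": 0.01,
    }
    # (median, log-scale sd) per profession ratio [professionals x 10/beds]
    staffing_ratio_distributions: dict[str, tuple[float, float]] = {
        "physicians_per_10_beds": (1.67, 0.29),
        "nurses_per_10_beds": (1.71, 0.39),
        "nursing_techs_per_10_beds": (5.0, 0.15),
        "physios_per_10_beds": (1.0, 0.30),
    }
    # (median, log-scale sd) of weekly staffing hours
    hours_distributions: dict[str, tuple[float, float]] = {
        "physician_hours_week": (372.0, 0.45),
        "nurse_hours_week": (396.0, 0.49),
    }
    # Beta(a, b): quantile-matched to median 0.83, IQR [0.75, 0.87]
    occupancy_distribution: tuple[float, float] = (13.79, 3.13)
    admin_weights: dict[str, float] = {
        "public": 17 / 93,
        "philanthropic": 19 / 93,
        "for_profit": 57 / 93,
    }
    icu_type_weights: dict[str, float] = {
        "mixed": 75 / 93,
        "surgical": 8 / 93,
        "medical": 1 / 93,
        "neurological": 5 / 93,
        "other": 4 / 93,
    }
    hospital_size_weights: dict[str, float] = {
        "small": 9 / 93,
        "medium": 33 / 93,
        "large": 51 / 93,
    }

    # patient level --------------------------------------------------------
    saps3_location: float = Field(44.0, gt=0)  # score points
    saps3_scale: float = Field(15.0, gt=0)  # score points
    mortality_calibration: float = Field(0.12, gt=0, lt=1)  # marginal ICU rate
    los_median_days: float = Field(3.0, gt=0)
    los_log_sd: float = Field(1.25, gt=0)
    los_severity_slope: float = 0.3  # log-days per severity SD
    post_icu_los_median_days: float = Field(4.0, gt=0)
    post_icu_los_log_sd: float = Field(0.9, gt=0)
    period_days: float = Field(730.0, gt=0)  # admission window emulated
    unit_effect_sd: float = Field(0.3, ge=0)  # log-scale unit spread

    @field_validator(
        "beds_distribution",
        "admin_weights",
        "icu_type_weights",
        "hospital_size_weights",
    )
    @classmethod
    def _weights_ok(cls, v, info):
        _validate_weights(info.field_name, v)
        return v

    @field_validator("staffing_ratio_distributions", "hours_distributions")
    @classmethod
    def _scales_ok(cls, v, info):
        for key, (loc, sd) in v.items():
            if loc <= 0 or sd <= 0:
                raise ValueError(f"{info.field_name}[{key}]: location and scale must be > 0")
        return v

    @field_validator("occupancy_distribution")
    @classmethod
    def _beta_ok(cls, v):
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("occupancy_distribution: Beta parameters must be > 0")
        return v

    @field_validator("beds_distribution")
    @classmethod
    def _bands_known(cls, v):
        unknown = set(v) - set(BED_BANDS)
        if unknown:
            raise ValueError(f"beds_distribution: unknown bands {sorted(unknown)}")
        return v


def _draw_categorical(rng: np.random.Generator, weights: Mapping[str, float], size: int):
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return np.array(keys)[rng.choice(len(keys), size=size, p=p / p.sum())]


def generate_units(config: CohortConfig) -> pd.DataFrame:
    """Draw the unit-level table: one row per ICU.

    Hospitals are shared (about 0.6 hospitals per unit, so some hospitals
    run several ICUs); hospital-level fields (administration, bed count,
    size category) are drawn once per hospital and copied to its units.
    """
    rng = np.random.default_rng([int(config.seed), 101])
    n = config.n_units
    n_hosp = max(1, round(0.6 * n))

    # hospital-level draws
    h_size = _draw_categorical(rng, config.hospital_size_weights, n_hosp)
    h_beds = np.array(
        [rng.integers(*HOSPITAL_SIZE_BANDS[s]) + 0 for s in h_size]
    )
    h_admin = _draw_categorical(rng, config.admin_weights, n_hosp)

    # every hospital hosts at least one unit; the rest assigned at random
    assign = np.r_[np.arange(n_hosp), rng.integers(0, n_hosp, size=n - n_hosp)]

    bands = _draw_categorical(rng, config.beds_distribution, n)
    icu_beds = np.array([rng.integers(lo, hi + 1) for lo, hi in (BED_BANDS[b] for b in bands)])

    ratios = {
        k: np.exp(rng.normal(math.log(loc), sd, size=n))
        for k, (loc, sd) in config.staffing_ratio_distributions.items()
    }
    hours = {
        k: np.exp(rng.normal(math.log(loc), sd, size=n))
        for k, (loc, sd) in config.hours_distributions.items()
    }
    a, b = config.occupancy_distribution
    occupancy = np.clip(stats.beta.rvs(a, b, size=n, random_state=rng), 1e-6, 1.0)
    icu_type = _draw_categorical(rng, config.icu_type_weights, n)

    # a hospital must hold all its ICUs comfortably (proportion <= ~0.35)
    hosp_beds_unit = h_beds[assign].astype(float)
    per_hosp_icu = np.bincount(assign, weights=icu_beds, minlength=n_hosp)
    floor = np.ceil(per_hosp_icu / 0.35)
    h_beds = np.maximum(h_beds, floor.astype(int))
    hosp_beds_unit = h_beds[assign]

    size_cat = np.where(
        h_beds < 100, "small", np.where(h_beds <= 200, "medium", "large")
    )
    width = max(2, len(str(n)))
    frame = pd.DataFrame(
        {
            "unit_id": [f"ICU_{i + 1:0{width}d}" for i in range(n)],
            "hospital_id": [f"H{assign[i] + 1:0{width}d}" for i in range(n)],
            "icu_beds": icu_beds,
            "hospital_beds": hosp_beds_unit,
            **ratios,
            **hours,
            "occupancy": occupancy,
            "admin": h_admin[assign],
            "icu_type": icu_type,
            "hospital_size_category": size_cat[assign],
            "bed_proportion": icu_beds / hosp_beds_unit,
        }
    )
    return frame[UNIT_COLUMNS]


def _calibrate_logit_shift(
    logits: np.ndarray, multipliers: np.ndarray, target: float
) -> float:
    """Scalar shift delta with mean(clip(expit(logit+delta)*mult)) = target."""

    def gap(delta: float) -> float:
        return float(np.mean(np.clip(expit(logits + delta) * multipliers, 0, 1))) - target

    lo, hi = -20.0, 20.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"mortality_calibration {target} unreachable by a logit shift"
        )
    return optimize.brentq(gap, lo, hi, xtol=1e-10)


def generate_patients(
    units: pd.DataFrame,
    config: CohortConfig,
    coefficients: Saps3Coefficients = SAPS3_GLOBAL,
    unit_mortality_multipliers: Mapping[str, float] | None = None,
    unit_los_multipliers: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw the patient-level table: one row per ICU admission.

    Per-unit admission counts are Poisson with mean proportional to
    beds x occupancy (census identity over ``period_days``).  Hospital
    death probability is the SAPS-3 risk times the unit's multiplicative
    effect; ICU death is coupled below it at the calibrated marginal rate,
    so ``icu_death`` implies ``hospital_death`` row by row.

    ``unit_mortality_multipliers`` / ``unit_los_multipliers`` override the
    random unit effects for the named units ("planted" units with known
    true SMR / LOS inflation).
    """
    if len(units) == 0:
        raise ValueError("unit table is empty")
    rng = np.random.default_rng([int(config.seed), 202])
    n_units = len(units)

    mort_mult = np.exp(rng.normal(0.0, config.unit_effect_sd, size=n_units))
    los_mult = np.exp(rng.normal(0.0, config.unit_effect_sd, size=n_units))
    ids = units["unit_id"].to_numpy()
    if unit_mortality_multipliers:
        for uid, m in unit_mortality_multipliers.items():
            mort_mult[ids == uid] = m
    if unit_los_multipliers:
        for uid, m in unit_los_multipliers.items():
            los_mult[ids == uid] = m

    sigma_tot = math.hypot(config.los_log_sd, config.los_severity_slope)
    mean_los = config.los_median_days * math.exp(sigma_tot**2 / 2)
    expected = (
        units["icu_beds"].to_numpy(float)
        * units["occupancy"].to_numpy(float)
        * config.period_days
        / mean_los
    )
    n_adm = np.maximum(rng.poisson(expected), 2)
    total = int(n_adm.sum())
    unit_idx = np.repeat(np.arange(n_units), n_adm)

    a0 = (0 - config.saps3_location) / config.saps3_scale
    saps3 = np.round(
        stats.truncnorm.rvs(
            a0, np.inf,
            loc=config.saps3_location,
            scale=config.saps3_scale,
            size=total,
            random_state=rng,
        )
    ).astype(int)
    age = np.round(
        stats.truncnorm.rvs(
            (16 - 64) / 18, (100 - 64) / 18, loc=64, scale=18,
            size=total, random_state=rng,
        )
    ).astype(int)
    adm_type = _draw_categorical(
        rng,
        {"medical": 0.684, "scheduled surgery": 0.250, "emergency surgery": 0.066},
        total,
    )

    logits = saps3_logit(saps3, coefficients)
    m_patient = mort_mult[unit_idx]
    p_hosp = np.clip(expit(logits) * m_patient, 0.0, 1.0)
    delta = _calibrate_logit_shift(logits, m_patient, config.mortality_calibration)
    p_icu = np.minimum(np.clip(expit(logits + delta) * m_patient, 0.0, 1.0), p_hosp)
    u = rng.uniform(size=total)
    hospital_death = u < p_hosp
    icu_death = u < p_icu  # coupled: icu_death => hospital_death

    z_sev = (saps3 - config.saps3_location) / config.saps3_scale
    log_mu = (
        math.log(config.los_median_days)
        + config.los_severity_slope * z_sev
        + np.log(los_mult[unit_idx])
    )
    icu_los = np.maximum(
        np.round(np.exp(rng.normal(log_mu, config.los_log_sd)), 2), 0.01
    )
    post = np.maximum(
        np.round(
            np.exp(
                rng.normal(
                    math.log(config.post_icu_los_median_days),
                    config.post_icu_los_log_sd,
                    size=total,
                )
            ),
            2,
        ),
        0.01,
    )
    hospital_los = np.where(icu_death, icu_los, np.round(icu_los + post, 2))

    width = len(str(total))
    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:0{width}d}" for i in range(total)],
            "unit_id": ids[unit_idx],
            "age": age,
            "admission_type": adm_type,
            "saps3": saps3,
            "icu_los": icu_los,
            "hospital_los": hospital_los,
            "icu_death": icu_death,
            "hospital_death": hospital_death,
        }
    )
    return frame[PATIENT_COLUMNS]


# ---------------------------------------------------------------------------
# planted frontier

#: unit-level DEA variables where *more* is worse (regular inputs)
_REGULAR_INPUTS = [
    "physicians_per_10_beds",
    "nurses_per_10_beds",
    "nursing_techs_per_10_beds",
    "physios_per_10_beds",
    "icu_beds",
    "physician_hours_week",
    "nurse_hours_week",
]
#: variables entering models on the reciprocal scale
_INVERTED_INPUT = "occupancy"  # low occupancy is the burden
_UNDESIRABLE_OUTPUTS = ["smr", "sru"]


def plant_frontier(
    units: pd.DataFrame,
    efficient_ids: Iterable[str],
    dominance_margin: float,
) -> pd.DataFrame:
    """Rewrite unit-level variables so the true frontier is known.

    ``units`` must carry the DEA variables including ``smr`` and ``sru``
    (merge the performance table in first).  Planted units receive
    identical inputs (the original column medians) and SMR/SRU values on
    a strictly concave trade-off arc, which makes each of them efficient
    in any model built from these variables.  Every other unit is made
    strictly worse than some planted unit by at least ``dominance_margin``
    on every variable, so it can never reach the frontier.

    Counts and proportions stop being integers/exact after rewriting:
    this is a testing device, not a realistic cohort.
    """
    efficient_ids = list(dict.fromkeys(efficient_ids))
    if not efficient_ids:
        raise ValueError("efficient_ids must be non-empty")
    if not dominance_margin > 0:
        raise ValueError("dominance_margin must be > 0")
    ids = units["unit_id"].astype(str)
    missing = set(efficient_ids) - set(ids)
    if missing:
        raise ValueError(f"efficient_ids not present in unit table: {sorted(missing)}")
    needed = _REGULAR_INPUTS + [_INVERTED_INPUT] + _UNDESIRABLE_OUTPUTS
    absent = [c for c in needed if c not in units.columns]
    if absent:
        raise ValueError(
            f"unit table lacks DEA variables {absent}; merge SMR/SRU in first"
        )

    out = units.copy().reset_index(drop=True)
    out[needed] = out[needed].astype(float)
    base_in = {c: float(out[c].median()) for c in _REGULAR_INPUTS}
    base_occ = float(out[_INVERTED_INPUT].median())
    base_out = {c: float(out[c].median()) for c in _UNDESIRABLE_OUTPUTS}

    planted_pos = {uid: k for k, uid in enumerate(efficient_ids)}
    K = len(efficient_ids)
    # strictly concave arc: combinations of planted units fall strictly
    # inside it, so each planted unit is extreme in every model
    t = np.array([k / max(K - 1, 1) for k in range(K)])
    g_smr = 1.0 + 0.4 * np.sin(0.5 * np.pi * t)  # benefit on 1/SMR
    g_sru = 1.0 + 0.4 * np.cos(0.5 * np.pi * t)  # benefit on 1/SRU

    grow = 1.0 + dominance_margin
    for i in range(len(out)):
        uid = str(out.at[i, "unit_id"])
        if uid in planted_pos:
            k = planted_pos[uid]
            for c in _REGULAR_INPUTS:
                out.at[i, c] = base_in[c]
            out.at[i, _INVERTED_INPUT] = base_occ
            out.at[i, "smr"] = base_out["smr"] / g_smr[k]
            out.at[i, "sru"] = base_out["sru"] / g_sru[k]
        else:
            k = i % K
            jitter = 1.0 + 0.01 * (1 + i % 7)
            for c in _REGULAR_INPUTS:
                out.at[i, c] = base_in[c] * grow * jitter
            out.at[i, _INVERTED_INPUT] = base_occ / (grow * jitter)
            out.at[i, "smr"] = base_out["smr"] / g_smr[k] * grow * jitter
            out.at[i, "sru"] = base_out["sru"] / g_sru[k] * grow * jitter
    if "hospital_beds" in out.columns:
        out["bed_proportion"] = out["icu_beds"] / out["hospital_beds"]
    return out


# ---------------------------------------------------------------------------
# fixed-format CSV output (byte-identical under identical config + seed)

_FLOAT_FORMAT = "%.6g"


def write_units_csv(units: pd.DataFrame, path) -> None:
    units.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_patients_csv(patients: pd.DataFrame, path) -> None:
    patients.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
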