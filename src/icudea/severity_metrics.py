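"""Severity-adjusted ICU performance metrics: SMR and SRU.

The Standardized Mortality Ratio (SMR) of a unit is observed deaths over
deaths expected from admission severity, where the expectation comes
from the SAPS-3 logistic hospital-mortality equation

    logit(p) = intercept + slope * ln(score + offset)

with the published global coefficients as the default.  The Standardized
Resource Use (SRU) treats ICU length of stay as the resource surrogate:
the cohort is cut into severity strata, each stratum contributes a
reference "days per survivor", and a unit's expected use is the sum of
its survivors in each stratum times that reference.  By construction the
whole cohort, treated as a single unit, has SRU exactly 1.

Both metrics return NaN (never +/-inf) where their denominator is
undefined; downstream frontier analysis excludes such units explicitly.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "Saps3Coefficients",
    "SAPS3_GLOBAL",
    "SeverityStratum",
    "saps3_risk",
    "compute_smr",
    "build_severity_strata",
    "compute_sru",
    "compute_performance",
]

logger = logging.getLogger(__name__)

Outcome = Literal["hospital", "icu"]


@dataclasses.dataclass(frozen=True)
class Saps3Coefficients:
    """Parameters of the logistic risk equation on ln(score + offset)."""

    intercept: float
    slope: float
    offset: float
    source_label: str = "custom"

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be > 0: risk increases with severity")


#: Published global SAPS-3 hospital-mortality equation.
SAPS3_GLOBAL = Saps3Coefficients(
    intercept=-32.6659,
    slope=7.3068,
    offset=20.5958,
    source_label="SAPS-3 global admission equation",
)


def saps3_logit(saps3, coefficients: Saps3Coefficients = SAPS3_GLOBAL) -> np.ndarray:
    score = np.asarray(saps3, dtype=float)
    shifted = score + coefficients.offset
    if np.any(shifted <= 0):
        raise ValueError(
            f"saps3 + offset must be > 0 (offset={coefficients.offset}); "
            f"min score {score.min()!r}"
        )
    return coefficients.intercept + coefficients.slope * np.log(shifted)


def saps3_risk(saps3, coefficients: Saps3Coefficients = SAPS3_GLOBAL) -> np.ndarray:
    """Predicted death probability for a SAPS-3 score (vectorised)."""
    return expit(saps3_logit(saps3, coefficients))


def _death_column(outcome: Outcome) -> str:
    if outcome not in ("hospital", "icu"):
        raise ValueError(f"outcome must be 'hospital' or 'icu', got {outcome!r}")
    return f"{outcome}_death"


def compute_smr(
    patients: pd.DataFrame,
    coefficients: Saps3Coefficients = SAPS3_GLOBAL,
    outcome: Outcome = "hospital",
) -> pd.DataFrame:
    """Per-unit SMR: observed deaths over the sum of predicted risks.

    Returns one row per unit with ``n_admissions``, ``observed_deaths``,
    ``expected_deaths`` and ``smr``.  A unit with zero expected deaths
    gets ``smr = NaN`` and a logged warning.
    """
    death = _death_column(outcome)
    df = patients[["unit_id", "saps3", death]].copy()
    df["risk"] = saps3_risk(df["saps3"].to_numpy(), coefficients)
    g = df.groupby("unit_id", sort=True)
    out = pd.DataFrame(
        {
            "n_admissions": g.size(),
            "observed_deaths": g[death].sum().astype(int),
            "expected_deaths": g["risk"].sum(),
        }
    ).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        smr = out["observed_deaths"] / out["expected_deaths"]
    smr = smr.where(out["expected_deaths"] > 0)
    undefined = out.loc[smr.isna(), "unit_id"].tolist()
    if undefined:
        logger.warning("SMR undefined (zero expected deaths) for units: %s", undefined)
    out["smr"] = smr
    return out


@dataclasses.dataclass(frozen=True)
class SeverityStratum:
    """Half-open severity band ``[lower, upper)`` with its cohort reference."""

    lower: float
    upper: float
    reference_use_per_survivor: float


def build_severity_strata(
    patients: pd.DataFrame,
    n_strata: int = 10,
    outcome: Outcome = "hospital",
) -> list[SeverityStratum]:
    """Cut the cohort into SAPS-3 quantile bands and compute references.

    The reference of a band is (total ICU LOS of *all* cohort patients in
    the band) / (number of cohort survivors in the band).  Bands without
    survivors are merged into the adjacent lower band (the first band, if
    survivor-free, merges upward) so every returned reference is finite.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    death = _death_column(outcome)
    scores = patients["saps3"].to_numpy(dtype=float)
    survivors = ~patients[death].to_numpy(dtype=bool)
    if not survivors.any():
        raise ValueError("no survivors in the cohort: SRU reference undefined")
    los = patients["icu_los"].to_numpy(dtype=float)

    qs = np.quantile(scores, np.linspace(0, 1, n_strata + 1)[1:-1])
    inner = np.unique(qs)
    edges = np.r_[-np.inf, inner, np.inf]
    band = np.searchsorted(inner, scores, side="right")
    n_bands = len(inner) + 1
    tot_los = np.bincount(band, weights=los, minlength=n_bands)
    n_surv = np.bincount(band[survivors], minlength=n_bands)

    # merge survivor-free bands downward (first band merges upward)
    lower = list(edges[:-1])
    upper = list(edges[1:])
    tot = list(tot_los)
    surv = list(n_surv)
    i = 0
    while i < len(surv):
        if surv[i] == 0:
            j = i - 1 if i > 0 else i + 1
            if j >= len(surv):  # single survivor-free band cannot happen (checked)
                raise ValueError("no survivors in the cohort")
            k, l = sorted((i, j))
            tot[k] += tot[l]
            surv[k] += surv[l]
            lower[k] = lower[k]
            upper[k] = upper[l]
            del tot[l], surv[l], lower[l], upper[l]
            i = 0  # restart: merging can expose a new survivor-free head
        else:
            i += 1
    return [
        SeverityStratum(lo, up, t / s)
        for lo, up, t, s in zip(lower, upper, tot, surv)
    ]


def _assign_strata(scores: np.ndarray, strata: Sequence[SeverityStratum]) -> np.ndarray:
    uppers = np.array([st.upper for st in strata[:-1]])
    return np.searchsorted(uppers, scores, side="right")


def compute_sru(
    patients: pd.DataFrame,
    strata: Sequence[SeverityStratum],
    outcome: Outcome = "hospital",
) -> pd.DataFrame:
    """Per-unit SRU: observed ICU days over severity-expected ICU days.

    ``observed_resource_use`` sums ICU LOS over all the unit's patients;
    ``expected_resource_use`` sums, over strata, the unit's survivor count
    times the stratum reference.  A unit without survivors has no
    expectation: its SRU is NaN and a warning is logged.
    """
    death = _death_column(outcome)
    df = patients[["unit_id", "saps3", "icu_los", death]].copy()
    df["band"] = _assign_strata(df["saps3"].to_numpy(dtype=float), strata)
    refs = np.array([st.reference_use_per_survivor for st in strata])
    df["expected_contrib"] = np.where(df[death], 0.0, refs[df["band"]])
    g = df.groupby("unit_id", sort=True)
    out = pd.DataFrame(
        {
            "observed_resource_use": g["icu_los"].sum(),
            "expected_resource_use": g["expected_contrib"].sum(),
        }
    ).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        sru = out["observed_resource_use"] / out["expected_resource_use"]
    sru = sru.where(out["expected_resource_use"] > 0)
    undefined = out.loc[sru.isna(), "unit_id"].tolist()
    if undefined:
        logger.warning("SRU undefined (no survivors) for units: %s", undefined)
    out["sru"] = sru
    return out


def compute_performance(
    patients: pd.DataFrame,
    coefficients: Saps3Coefficients = SAPS3_GLOBAL,
    outcome: Outcome = "hospital",
    n_strata: int = 10,
) -> pd.DataFrame:
    """One row per unit with the full SMR and SRU decomposition."""
    smr = compute_smr(patients, coefficients, outcome)
    strata = build_severity_strata(patients, n_strata, outcome)
    sru = compute_sru(patients, strata, outcome)
    return smr.merge(sru, on="unit_id", validate="one_to_one")
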