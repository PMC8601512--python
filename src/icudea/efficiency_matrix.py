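"""Classical SMR x SRU efficiency matrix and its comparison with DEA.

Units are split at the cohort medians of SMR and SRU into four
quadrants: low SMR & low SRU = "most_efficient", low SMR & high SRU =
"overachieving", high SMR & high SRU = "least_efficient", high SMR &
low SRU = "underachieving".  The tie rule at the median is configurable;
the default counts a value equal to the median as "low".
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .dea_core import DEAResult

__all__ = ["QUADRANTS", "classify_quadrants", "quadrant_dea_summary", "fig1_table"]

logger = logging.getLogger(__name__)

QUADRANTS = ("most_efficient", "overachieving", "least_efficient", "underachieving")

TieRule = Literal["le", "lt"]


def classify_quadrants(
    performance: pd.DataFrame, tie_rule: TieRule = "le"
) -> pd.DataFrame:
    """Label every unit with defined SMR and SRU by median split.

    Units missing either metric are excluded (and logged); at least two
    classifiable units are required for the medians to mean anything.
    """
    if tie_rule not in ("le", "lt"):
        raise ValueError(f"tie_rule must be 'le' or 'lt', got {tie_rule!r}")
    df = performance[["unit_id", "smr", "sru"]].copy()
    defined = df.dropna(subset=["smr", "sru"])
    dropped = sorted(set(df["unit_id"]) - set(defined["unit_id"]))
    if dropped:
        logger.warning("excluded from efficiency matrix (missing SMR/SRU): %s", dropped)
    if len(defined) < 2:
        raise ValueError("need >= 2 units with defined SMR and SRU")
    smr_med = float(defined["smr"].median())
    sru_med = float(defined["sru"].median())
    low = (lambda v, m: v <= m) if tie_rule == "le" else (lambda v, m: v < m)
    low_smr = low(defined["smr"], smr_med)
    low_sru = low(defined["sru"], sru_med)
    quadrant = np.select(
        [
            low_smr & low_sru,
            low_smr & ~low_sru,
            ~low_smr & ~low_sru,
            ~low_smr & low_sru,
        ],
        QUADRANTS,
        default="",  # unreachable: the four conditions partition the plane
    )
    out = defined.copy()
    out["quadrant"] = quadrant
    out["smr_median"] = smr_med
    out["sru_median"] = sru_med
    return out.reset_index(drop=True)


def quadrant_dea_summary(
    labels: pd.DataFrame,
    results_by_model: Mapping[str, Sequence[DEAResult]],
) -> pd.DataFrame:
    """Mean/SD of DEA scores and efficient counts per quadrant per model.

    Every quadrant appears for every model, with ``n = 0`` and missing
    statistics when it is empty.
    """
    rows = []
    quad_of = dict(zip(labels["unit_id"].astype(str), labels["quadrant"]))
    for model, results in results_by_model.items():
        scores: dict[str, list] = {q: [] for q in QUADRANTS}
        n_eff: dict[str, int] = {q: 0 for q in QUADRANTS}
        for r in results:
            q = quad_of.get(r.dmu_id)
            if q is None:
                continue
            scores[q].append(r.score)
            n_eff[q] += int(r.efficient)
        for q in QUADRANTS:
            vals = np.array(scores[q], dtype=float)
            rows.append(
                {
                    "model": model,
                    "quadrant": q,
                    "n": len(vals),
                    "mean_score": float(vals.mean()) if len(vals) else np.nan,
                    "sd_score": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "n_efficient": n_eff[q],
                }
            )
    return pd.DataFrame(rows)


def fig1_table(
    labels: pd.DataFrame,
    results_by_model: Mapping[str, Sequence[DEAResult]],
    reference_counts_by_model: Mapping[str, Mapping[str, int]],
) -> pd.DataFrame:
    """Underlying table of the SMR-vs-SRU scatter: one row per unit per
    model with its score, efficient flag and reference count."""
    frames = []
    for model, results in results_by_model.items():
        res_df = pd.DataFrame(
            {
                "unit_id": [r.dmu_id for r in results],
                "score": [r.score for r in results],
                "efficient": [r.efficient for r in results],
            }
        )
        refs = reference_counts_by_model[model]
        res_df["reference_count"] = res_df["unit_id"].map(lambda u: refs.get(u, 0))
        merged = labels[["unit_id", "smr", "sru", "quadrant"]].merge(
            res_df, on="unit_id", how="inner"
        )
        merged.insert(0, "model", model)
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)
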