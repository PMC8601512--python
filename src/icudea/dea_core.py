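"""Variable-returns-to-scale (BCC) data envelopment analysis.

Envelopment-form linear programs in both orientations, solved in two
phases: a radial phase that finds the proportional contraction factor
``theta`` (input orientation) or expansion factor ``phi`` (output
orientation), and a slack-maximisation phase at the fixed radial optimum
that resolves the indeterminacy of the peer weights and yields the
standard (strongly efficient) projection used for improvement targets.

The convexity constraint ``sum(lambda) == 1`` makes the frontier
variable-returns-to-scale: a decision-making unit (DMU) is compared only
against convex combinations of observed peers, never against scaled
copies of them.  All data must be strictly positive; quantities where
*lower is better* (e.g. standardized mortality ratios) are entered on the
reciprocal scale via :func:`invert_variables` and mapped back with
:func:`back_transform_targets`.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "DEAError",
    "DEADataError",
    "DEADataset",
    "DEAResult",
    "invert_variables",
    "solve_input_oriented",
    "solve_output_oriented",
    "evaluate_all",
    "reference_counts",
    "back_transform_targets",
]

#: |score - 1| below this classifies a DMU as (radially) efficient.
EFFICIENCY_TOL = 1e-6
#: lambda weights below this are treated as zero when reporting peers.
PEER_WEIGHT_TOL = 1e-7

_SOLVER_METHOD = "highs-ds"  # dual simplex: deterministic vertex solutions
_SOLVER_OPTIONS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

Orientation = Literal["input", "output"]


class DEAError(RuntimeError):
    """Solver failure or an internally inconsistent DEA problem."""


class DEADataError(ValueError):
    """Invalid data supplied to a DEA routine."""


def invert_variables(
    values: np.ndarray | Sequence[float],
    flag: bool,
    *,
    label: str = "variable",
    dmu_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Return ``1/values`` when ``flag`` is set, else a copy of ``values``.

    Applying the transform twice returns the original vector (involution).
    Zero or negative entries are rejected because the reciprocal scale —
    and DEA itself — requires strictly positive data.
    """
    arr = np.asarray(values, dtype=float)
    bad = ~(arr > 0) | ~np.isfinite(arr)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        who = dmu_ids[idx] if dmu_ids is not None else f"position {idx}"
        raise DEADataError(
            f"non-positive or non-finite value {arr.flat[idx]!r} for "
            f"{label!r} at DMU {who}"
        )
    return 1.0 / arr if flag else arr.copy()


@dataclasses.dataclass(frozen=True)
class DEADataset:
    """Model-scale input/output matrices for a set of DMUs.

    ``X`` is ``m x n`` (inputs by DMUs) and ``Y`` is ``s x n``; both hold
    strictly positive values *after* any reciprocal transform.  The
    ``inverted_*`` flags record which rows were transformed so targets can
    be mapped back to the original scale.
    """

    dmu_ids: tuple[str, ...]
    X: np.ndarray
    Y: np.ndarray
    input_labels: tuple[str, ...]
    output_labels: tuple[str, ...]
    inverted_inputs: tuple[bool, ...]
    inverted_outputs: tuple[bool, ...]

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        n = len(self.dmu_ids)
        if len(set(self.dmu_ids)) != n:
            raise DEADataError("duplicate DMU identifiers")
        if X.shape[1] != n or Y.shape[1] != n:
            raise DEADataError(
                f"matrix shapes {X.shape}/{Y.shape} inconsistent with {n} DMUs"
            )
        if X.shape[0] != len(self.input_labels) or Y.shape[0] != len(self.output_labels):
            raise DEADataError("label count does not match matrix rows")
        if len(self.inverted_inputs) != X.shape[0] or len(self.inverted_outputs) != Y.shape[0]:
            raise DEADataError("inversion flag count does not match matrix rows")
        for mat, labels in ((X, self.input_labels), (Y, self.output_labels)):
            bad = ~(mat > 0) | ~np.isfinite(mat)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise DEADataError(
                    f"non-positive or non-finite value for {labels[i]!r} "
                    f"at DMU {self.dmu_ids[j]!r}: {mat[i, j]!r}"
                )

    @property
    def n_dmus(self) -> int:
        return len(self.dmu_ids)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        *,
        dmu_column: str,
        input_columns: Sequence[str],
        output_columns: Sequence[str],
        inverted: Sequence[str] = (),
    ) -> "DEADataset":
        """Build a dataset from a tidy frame, applying reciprocal transforms.

        Columns named in ``inverted`` (inputs or outputs) are entered as
        ``1/value``; the flags are recorded on the dataset.
        """
        inverted = set(inverted)
        unknown = inverted - set(input_columns) - set(output_columns)
        if unknown:
            raise DEADataError(f"inverted columns not in model: {sorted(unknown)}")
        ids = tuple(str(v) for v in frame[dmu_column])
        inv_in = tuple(c in inverted for c in input_columns)
        inv_out = tuple(c in inverted for c in output_columns)
        X = np.vstack(
            [
                invert_variables(frame[c].to_numpy(), c in inverted, label=c, dmu_ids=ids)
                for c in input_columns
            ]
        )
        Y = np.vstack(
            [
                invert_variables(frame[c].to_numpy(), c in inverted, label=c, dmu_ids=ids)
                for c in output_columns
            ]
        )
        return cls(
            dmu_ids=ids,
            X=X,
            Y=Y,
            input_labels=tuple(input_columns),
            output_labels=tuple(output_columns),
            inverted_inputs=inv_in,
            inverted_outputs=inv_out,
        )


@dataclasses.dataclass(frozen=True)
class DEAResult:
    """Scores, peers, slacks and projection targets for one DMU."""

    dmu_id: str
    orientation: Orientation
    score: float
    lambdas: Mapping[str, float]
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    targets_model_scale: Mapping[str, float]
    targets_original_scale: Mapping[str, float] | None
    efficient: bool
    weakly_efficient: bool


def _run_lp(c, A_ub, b_ub, A_eq, b_eq, bounds, context: str):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method=_SOLVER_METHOD,
        options=_SOLVER_OPTIONS,
    )
    if res.status != 0:
        raise DEAError(f"{context}: solver status {res.status} ({res.message})")
    return res


def _solve(dataset: DEADataset, dmu_index: int, orientation: Orientation) -> DEAResult:
    X, Y = dataset.X, dataset.Y
    m, n = X.shape
    s = Y.shape[0]
    if not 0 <= dmu_index < n:
        raise DEADataError(f"DMU index {dmu_index} out of range for {n} DMUs")
    x0, y0 = X[:, dmu_index], Y[:, dmu_index]

    # --- phase 1: radial factor -------------------------------------------
    # variables: [radial factor, lambda_1..lambda_n]
    if orientation == "input":
        c = np.r_[1.0, np.zeros(n)]
        A_ub = np.block([[-x0[:, None], X], [np.zeros((s, 1)), -Y]])
        b_ub = np.r_[np.zeros(m), -y0]
    elif orientation == "output":
        c = np.r_[-1.0, np.zeros(n)]
        A_ub = np.block([[np.zeros((m, 1)), X], [y0[:, None], -Y]])
        b_ub = np.r_[x0, np.zeros(s)]
    else:  # pragma: no cover - guarded by typing
        raise DEADataError(f"unknown orientation {orientation!r}")
    A_eq = np.r_[0.0, np.ones(n)][None, :]
    res = _run_lp(
        c,
        A_ub,
        b_ub,
        A_eq,
        [1.0],
        [(None, None)] + [(0, None)] * n,
        f"phase 1 ({orientation}) for DMU {dataset.dmu_ids[dmu_index]!r}",
    )
    score = float(res.x[0])
    if abs(score - 1.0) <= EFFICIENCY_TOL:
        score = 1.0

    # --- phase 2: maximise slacks at the fixed radial optimum -------------
    # variables: [lambda (n), input slacks (m), output slacks (s)]
    if orientation == "input":
        rhs_x, rhs_y = score * x0, y0
    else:
        rhs_x, rhs_y = x0, score * y0
    A_eq2 = np.block(
        [
            [X, np.eye(m), np.zeros((m, s))],
            [Y, np.zeros((s, m)), -np.eye(s)],
            [np.ones((1, n)), np.zeros((1, m + s))],
        ]
    )
    c2 = np.r_[np.zeros(n), -np.ones(m + s)]
    b_eq2 = np.r_[rhs_x, rhs_y, 1.0]
    ctx = f"phase 2 ({orientation}) for DMU {dataset.dmu_ids[dmu_index]!r}"
    try:
        res2 = _run_lp(c2, None, None, A_eq2, b_eq2, [(0, None)] * (n + m + s), ctx)
    except DEAError:
        # the fixed radial factor can sit a hair inside the feasible set;
        # nudge it outward by one part in 1e9 and retry once
        bump = 1.0 + 1e-9 if orientation == "input" else 1.0 - 1e-9
        if orientation == "input":
            b_eq2 = np.r_[score * bump * x0, rhs_y, 1.0]
        else:
            b_eq2 = np.r_[rhs_x, score * bump * y0, 1.0]
        res2 = _run_lp(c2, None, None, A_eq2, b_eq2, [(0, None)] * (n + m + s), ctx)

    lam = res2.x[:n]
    s_in = np.maximum(res2.x[n : n + m], 0.0)
    s_out = np.maximum(res2.x[n + m :], 0.0)
    # strongly efficient DMUs (score 1, zero slacks) support themselves;
    # pick the self-solution over any equally optimal degenerate peer mix
    if score == 1.0 and float(s_in.sum() + s_out.sum()) <= 1e-9 * float(
        x0.sum() + y0.sum()
    ):
        lam = np.zeros(n)
        lam[dmu_index] = 1.0
        s_in = np.zeros(m)
        s_out = np.zeros(s)
    lambdas = {
        dataset.dmu_ids[j]: float(lam[j])
        for j in range(n)
        if lam[j] > PEER_WEIGHT_TOL
    }
    targets_in = X @ lam
    targets_out = Y @ lam
    targets = {
        **dict(zip(dataset.input_labels, map(float, targets_in))),
        **dict(zip(dataset.output_labels, map(float, targets_out))),
    }
    efficient = abs(score - 1.0) <= EFFICIENCY_TOL
    rel_slack = max(
        float(np.max(s_in / x0)) if m else 0.0,
        float(np.max(s_out / y0)) if s else 0.0,
    )
    return DEAResult(
        dmu_id=dataset.dmu_ids[dmu_index],
        orientation=orientation,
        score=score,
        lambdas=lambdas,
        input_slacks=s_in,
        output_slacks=s_out,
        targets_model_scale=targets,
        targets_original_scale=None,
        efficient=efficient,
        weakly_efficient=efficient and rel_slack > EFFICIENCY_TOL,
    )


def solve_input_oriented(dataset: DEADataset, dmu_index: int) -> DEAResult:
    """Minimal proportional input contraction holding outputs fixed.

    Solves ``min theta`` subject to ``X lam <= theta x0``, ``Y lam >= y0``,
    ``sum(lam) == 1``, ``lam >= 0``; the score lies in ``(0, 1]``.
    """
    return _solve(dataset, dmu_index, "input")


def solve_output_oriented(dataset: DEADataset, dmu_index: int) -> DEAResult:
    """Maximal proportional output expansion holding inputs fixed.

    Solves ``max phi`` subject to ``X lam <= x0``, ``Y lam >= phi y0``,
    ``sum(lam) == 1``, ``lam >= 0``; the score lies in ``[1, inf)``.
    """
    return _solve(dataset, dmu_index, "output")


def evaluate_all(dataset: DEADataset, orientation: Orientation) -> list[DEAResult]:
    """Score every DMU against the frontier formed by the full dataset."""
    return [_solve(dataset, j, orientation) for j in range(dataset.n_dmus)]


def reference_counts(results: Sequence[DEAResult]) -> dict[str, int]:
    """Number of *other* DMUs for which each DMU appears as a peer.

    Self-references are excluded, so on an all-efficient dataset every
    count is zero.
    """
    counts = {r.dmu_id: 0 for r in results}
    for r in results:
        for peer, w in r.lambdas.items():
            if peer != r.dmu_id and w > PEER_WEIGHT_TOL:
                counts[peer] += 1
    return counts


def back_transform_targets(result: DEAResult, dataset: DEADataset) -> DEAResult:
    """Map model-scale projection targets back to the original scale.

    Variables that entered the model as reciprocals get ``1/target``
    (e.g. a model-scale target on 1/SMR becomes an SMR target); all other
    variables are copied unchanged.
    """
    original: dict[str, float] = {}
    for label, flipped in zip(dataset.input_labels, dataset.inverted_inputs):
        t = result.targets_model_scale[label]
        original[label] = 1.0 / t if flipped else t
    for label, flipped in zip(dataset.output_labels, dataset.inverted_outputs):
        t = result.targets_model_scale[label]
        original[label] = 1.0 / t if flipped else t
    return dataclasses.replace(result, targets_original_scale=original)
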