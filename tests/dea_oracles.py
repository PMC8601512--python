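"""Independent oracles for the DEA solver tests.

Two routes that share no code with the package implementation:

* a brute-force grid over the peer-weight simplex (resolution 1/400),
  feasible for up to 3 DMUs, evaluating the radial factor at every grid
  point;
* a from-scratch two-phase tableau simplex with Bland's rule, used to
  solve the same envelopment LPs exactly on slightly larger instances.
"""

from __future__ import annotations

import numpy as np

_TOL = 1e-9


# ---------------------------------------------------------------------------
# tableau simplex


def _iterate(T, c, basis):
    """Min c x over the tableau T=[B^-1 A | B^-1 b]; Bland's rule."""
    m, width = T.shape
    ntot = width - 1
    while True:
        red = c - c[basis] @ T[:, :ntot]
        ent = -1
        for j in range(ntot):
            if red[j] < -_TOL:
                ent = j
                break
        if ent < 0:
            return
        best, best_ratio = -1, None
        for i in range(m):
            if T[i, ent] > _TOL:
                ratio = T[i, -1] / T[i, ent]
                if (
                    best_ratio is None
                    or ratio < best_ratio - _TOL
                    or (abs(ratio - best_ratio) <= _TOL and basis[i] < basis[best])
                ):
                    best, best_ratio = i, ratio
        if best < 0:
            raise ValueError("LP is unbounded")
        T[best] /= T[best, ent]
        for i in range(m):
            if i != best and abs(T[i, ent]) > 1e-13:
                T[i] -= T[i, ent] * T[best]
        basis[best] = ent


def solve_lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None):
    """Solve min c x s.t. A_ub x <= b_ub, A_eq x = b_eq, x >= 0.

    Returns (x, objective).  Raises ValueError if infeasible/unbounded.
    """
    c = np.asarray(c, float)
    n = c.size
    if A_ub is not None and len(np.atleast_2d(A_ub)):
        A_ub = np.atleast_2d(np.asarray(A_ub, float))
        b_ub = np.atleast_1d(np.asarray(b_ub, float))
        n_ub = A_ub.shape[0]
    else:
        A_ub, b_ub, n_ub = np.zeros((0, n)), np.zeros(0), 0
    if A_eq is not None and len(np.atleast_2d(A_eq)):
        A_eq = np.atleast_2d(np.asarray(A_eq, float))
        b_eq = np.atleast_1d(np.asarray(b_eq, float))
    else:
        A_eq, b_eq = np.zeros((0, n)), np.zeros(0)

    A = np.vstack(
        [
            np.hstack([A_ub, np.eye(n_ub)]),
            np.hstack([A_eq, np.zeros((A_eq.shape[0], n_ub))]),
        ]
    )
    b = np.r_[b_ub, b_eq]
    m = A.shape[0]
    flip = b < 0
    A[flip] *= -1
    b = np.abs(b)
    total = n + n_ub

    # phase 1: artificial basis
    T = np.hstack([A, np.eye(m), b[:, None]])
    basis = list(range(total, total + m))
    c1 = np.r_[np.zeros(total), np.ones(m)]
    _iterate(T, c1, basis)
    if c1[basis] @ T[:, -1] > 1e-7:
        raise ValueError("LP is infeasible")
    # pivot artificials out of the basis (or drop redundant rows)
    keep = []
    for i in range(m):
        if basis[i] >= total:
            piv = next((j for j in range(total) if abs(T[i, j]) > 1e-9), None)
            if piv is None:
                continue  # redundant row
            T[i] /= T[i, piv]
            for r in range(m):
                if r != i and abs(T[r, piv]) > 1e-13:
                    T[r] -= T[r, piv] * T[i]
            basis[i] = piv
        keep.append(i)
    T = np.hstack([T[keep][:, :total], T[keep][:, -1:]])
    basis = [basis[i] for i in keep]

    c2 = np.r_[c, np.zeros(n_ub)]
    _iterate(T, c2, basis)
    x_full = np.zeros(total)
    for i, j in enumerate(basis):
        x_full[j] = T[i, -1]
    x = x_full[:n]
    return x, float(c @ x)


def oracle_radial_score(X, Y, j, orientation):
    """Exact BCC radial score for DMU j via the independent simplex."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    m, n = X.shape
    s = Y.shape[0]
    x0, y0 = X[:, j], Y[:, j]
    if orientation == "input":
        c = np.r_[1.0, np.zeros(n)]
        A_ub = np.block([[-x0[:, None], X], [np.zeros((s, 1)), -Y]])
        b_ub = np.r_[np.zeros(m), -y0]
        sign = 1.0
    else:
        c = np.r_[-1.0, np.zeros(n)]
        A_ub = np.block([[np.zeros((m, 1)), X], [y0[:, None], -Y]])
        b_ub = np.r_[x0, np.zeros(s)]
        sign = -1.0
    A_eq = np.r_[0.0, np.ones(n)][None, :]
    _, obj = solve_lp(c, A_ub, b_ub, A_eq, [1.0])
    return sign * obj


# ---------------------------------------------------------------------------
# simplex-grid brute force (n <= 3)


def _lambda_grid(n, resolution):
    if n == 1:
        return np.ones((1, 1))
    if n == 2:
        k = np.arange(resolution + 1)
        return np.column_stack([k, resolution - k]) / resolution
    if n == 3:
        i, j = np.meshgrid(
            np.arange(resolution + 1), np.arange(resolution + 1), indexing="ij"
        )
        mask = i + j <= resolution
        i, j = i[mask], j[mask]
        return np.column_stack([i, j, resolution - i - j]) / resolution
    raise ValueError("grid oracle supports at most 3 DMUs")


def grid_radial_score(X, Y, j, orientation, resolution=400):
    """Brute-force BCC radial score by scanning the peer-weight simplex."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n = X.shape[1]
    lam = _lambda_grid(n, resolution)  # (G, n)
    in_mix = lam @ X.T  # (G, m)
    out_mix = lam @ Y.T  # (G, s)
    x0, y0 = X[:, j], Y[:, j]
    if orientation == "input":
        feasible = (out_mix >= y0 - 1e-12).all(axis=1)
        theta = (in_mix[feasible] / x0).max(axis=1)
        return float(theta.min())
    feasible = (in_mix <= x0 + 1e-12).all(axis=1)
    phi = (out_mix[feasible] / y0).min(axis=1)
    return float(phi.max())


def random_instance(rng, n, m, s, low=1.0, high=5.0):
    """Random strictly positive DEA data (m x n inputs, s x n outputs)."""
    X = rng.uniform(low, high, size=(m, n))
    Y = rng.uniform(low, high, size=(s, n))
    return X, Y
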