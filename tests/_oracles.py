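"""Independent brute-force oracles for the envelopment programs.

Two oracles, both independent of the HiGHS solver used by the package:

``oracle_farrell_enum``
    Exhaustive enumeration of basic solutions.  The optimum of the
    envelopment program lies at a vertex of the feasible polytope in
    ``(mu, lambda)`` space; every candidate active set of constraints is
    enumerated, the corresponding square linear system solved, feasible
    solutions kept, and the largest feasible ``lambda`` returned.  Exact up
    to linear-algebra round-off; practical for n <= 8.

``oracle_farrell_grid``
    Direct grid search over convex weights.  Writing ``mu = t * w`` with
    ``w`` on the unit simplex, the inner maximisation over the scale ``t``
    is closed form for every returns-to-scale regime, so only ``w`` is
    gridded.  Used for the tiny two-unit textbook cases where a 0.001 grid
    is affordable.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def oracle_farrell_enum(x0, y0, X, Y, rts, tol=1e-7):
    """Exact Farrell output score by enumeration of basic solutions."""
    x0 = np.asarray(x0, float)
    y0 = np.asarray(y0, float)
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n, p = X.shape
    q = Y.shape[1]
    d = n + 1  # variables: mu_1..mu_n, lambda

    rows, rhs = [], []
    for k in range(p):  # sum_j mu_j x_kj <= x_k0
        rows.append(np.append(X[:, k], 0.0))
        rhs.append(x0[k])
    for m in range(q):  # lambda*y_m0 - sum_j mu_j y_mj <= 0
        rows.append(np.append(-Y[:, m], y0[m]))
        rhs.append(0.0)
    for j in range(n):  # mu_j >= 0
        e = np.zeros(d)
        e[j] = -1.0
        rows.append(e)
        rhs.append(0.0)
    e = np.zeros(d)
    e[-1] = -1.0  # lambda >= 0
    rows.append(e)
    rhs.append(0.0)
    if rts == "nirs":
        rows.append(np.append(np.ones(n), 0.0))
        rhs.append(1.0)
    A = np.array(rows)
    b = np.array(rhs)

    eq_rows, eq_rhs = [], []
    if rts == "vrs":
        eq_rows.append(np.append(np.ones(n), 0.0))
        eq_rhs.append(1.0)
    elif rts not in ("crs", "nirs"):
        raise ValueError(rts)

    need = d - len(eq_rows)
    scale = max(1.0, np.abs(b).max())
    best = -np.inf
    for subset in combinations(range(len(rows)), need):
        M = np.vstack([*eq_rows, A[list(subset)]])
        v = np.concatenate([eq_rhs, b[list(subset)]])
        try:
            sol = np.linalg.solve(M, v)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(sol)):
            continue
        resid = A @ sol - b
        if np.max(resid) > tol * scale:
            continue
        if eq_rows and abs(eq_rows[0] @ sol - eq_rhs[0]) > tol:
            continue
        best = max(best, sol[-1])
    return best


def _simplex_grid(n: int, step: float) -> np.ndarray:
    k = round(1.0 / step)
    out: list[list[int]] = []

    def rec(prefix, remaining, slots):
        if slots == 1:
            out.append(prefix + [remaining])
            return
        for v in range(remaining + 1):
            rec(prefix + [v], remaining - v, slots - 1)

    rec([], k, n)
    return np.asarray(out, dtype=float) * step


def oracle_farrell_grid(x0, y0, X, Y, rts, step=0.001):
    """Farrell score by grid search over convex weights (tiny panels only)."""
    x0 = np.asarray(x0, float)
    y0 = np.asarray(y0, float)
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    W = _simplex_grid(X.shape[0], step)
    pos = y0 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ub = np.min(x0 / (W @ X), axis=1)
        ratio = np.min((W @ Y)[:, pos] / y0[pos], axis=1)
    if rts == "crs":
        val = ratio * t_ub
    elif rts == "nirs":
        val = ratio * np.minimum(t_ub, 1.0)
    elif rts == "vrs":
        val = np.where(t_ub >= 1.0 - 1e-12, ratio, -np.inf)
    else:
        raise ValueError(rts)
    val = np.where(np.isfinite(val), val, -np.inf)
    return float(val.max())
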