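"""Sparse linear-programming back end for the output-oriented envelopment models.

Every DEA score in the package comes through :func:`solve_farrell_block`, which
stacks the per-unit envelopment programs for one shared reference technology
into a single block-separable LP and hands it to HiGHS.  Because the blocks are
independent, maximising the sum of the Farrell multipliers solves each unit's
program at its individual optimum; solving one sparse LP instead of ``n`` dense
ones is what keeps the bootstrap loops tractable.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

RTS_VALUES = ("crs", "vrs", "nirs")


class DEASolverError(RuntimeError):
    """Raised when HiGHS fails to solve an envelopment program."""


def _scale_factors(*arrays: np.ndarray) -> np.ndarray:
    """Per-column positive scale (column max across all arrays).

    Normalising each input and output dimension by its largest observed value
    makes the LP data dimensionless, so Farrell scores are invariant (up to a
    float rounding of the ratios) under rescaling any row of the data, and the
    wildly different natural units of hospital variables (expenditure in
    10,000 RMB vs. bed counts) do not degrade the solver's conditioning.
    """
    stacked = np.vstack(arrays)
    scale = stacked.max(axis=0)
    scale[scale <= 0] = 1.0
    return scale


# Simplex time grows superlinearly with the stacked block size, so large
# evaluation sets are solved in chunks of this many units.
_CHUNK = 32


def solve_farrell_block(
    x_eval: np.ndarray,
    y_eval: np.ndarray,
    x_ref: np.ndarray,
    y_ref: np.ndarray,
    rts: str = "crs",
    return_weights: bool = False,
):
    """Output-oriented Farrell scores of ``(x_eval, y_eval)`` units against a
    reference technology spanned by ``(x_ref, y_ref)``.

    For each evaluated unit ``o`` the program is::

        max  lambda
        s.t. sum_j mu_j x_kj <= x_ko           for every input k
             sum_j mu_j y_mj >= lambda * y_mo  for every output m
             mu >= 0
             sum_j mu_j  = 1   (vrs)
             sum_j mu_j <= 1   (nirs)

    Parameters
    ----------
    x_eval, y_eval : (n_eval, p) and (n_eval, q) arrays
    x_ref, y_ref : (n_ref, p) and (n_ref, q) arrays
    rts : {"crs", "vrs", "nirs"}
    return_weights : bool
        If True also return the (n_eval, n_ref) intensity-weight matrix.

    Returns
    -------
    lam : (n_eval,) array of Farrell multipliers (>= 1 when the evaluated
        units belong to the reference set; may dip below 1 in bootstrap
        replications where they do not).
    weights : optional (n_eval, n_ref) array of optimal intensity weights.
    """
    if rts not in RTS_VALUES:
        raise ValueError(f"rts must be one of {RTS_VALUES}, got {rts!r}")
    x_eval = np.atleast_2d(np.asarray(x_eval, dtype=float))
    y_eval = np.atleast_2d(np.asarray(y_eval, dtype=float))
    x_ref = np.atleast_2d(np.asarray(x_ref, dtype=float))
    y_ref = np.atleast_2d(np.asarray(y_ref, dtype=float))
    n_eval, p = x_eval.shape
    n_ref, q = y_ref.shape[0], y_ref.shape[1]
    if y_eval.shape != (n_eval, q) or x_ref.shape != (n_ref, p):
        raise ValueError("inconsistent input/output matrix shapes")

    if n_eval > _CHUNK:
        lam = np.empty(n_eval)
        weights = np.empty((n_eval, n_ref)) if return_weights else None
        n_chunks = int(np.ceil(n_eval / _CHUNK))
        size = int(np.ceil(n_eval / n_chunks))
        for s in range(0, n_eval, size):
            sl = slice(s, min(s + size, n_eval))
            out = solve_farrell_block(
                x_eval[sl], y_eval[sl], x_ref, y_ref, rts, return_weights
            )
            if return_weights:
                lam[sl], weights[sl] = out
            else:
                lam[sl] = out
        return (lam, weights) if return_weights else lam

    xs = _scale_factors(x_eval, x_ref)
    ys = _scale_factors(y_eval, y_ref)
    xe, xr = x_eval / xs, x_ref / xs
    ye, yr = y_eval / ys, y_ref / ys

    # Variable layout: [lambda_0..lambda_{n_eval-1}, mu^(0), mu^(1), ...]
    n_var = n_eval + n_eval * n_ref
    c = np.zeros(n_var)
    c[:n_eval] = -1.0  # maximise sum of lambdas

    rows_per_unit = p + q + (1 if rts == "nirs" else 0)
    n_rows = n_eval * rows_per_unit
    nnz_per_unit = rows_per_unit * n_ref + q
    data = np.empty(n_eval * nnz_per_unit)
    rix = np.empty(n_eval * nnz_per_unit, dtype=np.int64)
    cix = np.empty(n_eval * nnz_per_unit, dtype=np.int64)
    b_ub = np.empty(n_rows)

    ref_cols = np.arange(n_ref)
    pos = 0
    for i in range(n_eval):
        r0 = i * rows_per_unit
        mu0 = n_eval + i * n_ref
        # input rows:  sum_j mu_j x_kj <= x_ki
        for k in range(p):
            data[pos : pos + n_ref] = xr[:, k]
            rix[pos : pos + n_ref] = r0 + k
            cix[pos : pos + n_ref] = mu0 + ref_cols
            pos += n_ref
            b_ub[r0 + k] = xe[i, k]
        # output rows: lambda*y_mi - sum_j mu_j y_mj <= 0
        for m in range(q):
            data[pos : pos + n_ref] = -yr[:, m]
            rix[pos : pos + n_ref] = r0 + p + m
            cix[pos : pos + n_ref] = mu0 + ref_cols
            pos += n_ref
            data[pos] = ye[i, m]
            rix[pos] = r0 + p + m
            cix[pos] = i
            pos += 1
            b_ub[r0 + p + m] = 0.0
        if rts == "nirs":
            data[pos : pos + n_ref] = 1.0
            rix[pos : pos + n_ref] = r0 + p + q
            cix[pos : pos + n_ref] = mu0 + ref_cols
            pos += n_ref
            b_ub[r0 + p + q] = 1.0
    A_ub = sparse.csr_matrix(
        (data[:pos], (rix[:pos], cix[:pos])), shape=(n_rows, n_var)
    )

    A_eq = b_eq = None
    if rts == "vrs":
        eq_data = np.ones(n_eval * n_ref)
        eq_rows = np.repeat(np.arange(n_eval), n_ref)
        eq_cols = n_eval + np.arange(n_eval * n_ref)
        A_eq = sparse.csr_matrix(
            (eq_data, (eq_rows, eq_cols)), shape=(n_eval, n_var)
        )
        b_eq = np.ones(n_eval)

    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=(0, None),
        method="highs",
        options={"presolve": False},
    )
    if not res.success:  # retry once with presolve before giving up
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
            bounds=(0, None), method="highs",
        )
    if not res.success:
        raise DEASolverError(
            f"envelopment LP failed (rts={rts}, status={res.status}): {res.message}"
        )
    lam = res.x[:n_eval].copy()
    if return_weights:
        weights = res.x[n_eval:].reshape(n_eval, n_ref).copy()
        return lam, weights
    return lam
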