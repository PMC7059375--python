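"""Output-oriented envelopment DEA: Farrell scores, TE/PTE/SE, returns to scale.

The Farrell output multiplier :math:`\\lambda \\ge 1` of a unit is the largest
proportional expansion of all its outputs that remains feasible inside the
technology spanned by the observed units.  Technical efficiency is reported on
the Shephard scale, ``TE = 1/lambda_CRS``; pure technical efficiency is
``PTE = 1/lambda_VRS``; and scale efficiency is the ratio ``SE = TE/PTE``, so
the decomposition ``TE = PTE * SE`` holds by construction.  Units are
classified as operating under constant (CRS), increasing (IRS) or decreasing
(DRS) returns to scale from the CRS/VRS/NIRS score triple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from ._lp import RTS_VALUES, solve_farrell_block
from .panel import DMUPanel

__all__ = [
    "DEAScores",
    "EfficiencyDecomposition",
    "EfficiencyResult",
    "solve_dea",
    "efficiency_table",
    "classify_rts",
]

#: scores within this distance of 1 are snapped to exactly 1 for reporting
DEFAULT_SNAP_TOL = 1e-8
#: tolerance used when comparing CRS/VRS/NIRS scores for RTS classification
DEFAULT_RTS_TOL = 1e-6


def _validate_xy(X, Y):
    X = check_array(X, ensure_min_features=1)
    Y = check_array(Y, ensure_min_features=1)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must describe the same units")
    if np.any(X < 0) or np.any(Y < 0):
        raise ValueError("inputs and outputs must be nonnegative")
    if np.any(Y.max(axis=1) <= 0):
        raise ValueError("every unit needs at least one strictly positive output")
    if np.any(X.max(axis=1) <= 0):
        raise ValueError("every unit needs at least one strictly positive input")
    return X, Y


def _snap(lam: np.ndarray, tol: float) -> np.ndarray:
    lam = np.asarray(lam, dtype=float).copy()
    lam[np.abs(lam - 1.0) <= tol] = 1.0
    # the evaluated unit is always feasible at lambda = 1, so anything below
    # is solver noise
    return np.maximum(lam, 1.0)


class DEAScores(BaseEstimator):
    """Output-oriented Farrell scores under a single returns-to-scale regime.

    Parameters
    ----------
    rts : {"crs", "vrs", "nirs"}, default "crs"
        Returns-to-scale assumption of the envelopment program.
    snap_tol : float, default 1e-8
        Scores within ``snap_tol`` of 1 are reported as exactly 1.

    Attributes
    ----------
    farrell_ : (n,) ndarray of Farrell multipliers, all >= 1.
    scores_ : (n,) ndarray of Shephard efficiencies ``1/farrell_`` in (0, 1].
    weights_ : (n, n) ndarray of optimal intensity weights.
    """

    def __init__(self, rts: str = "crs", snap_tol: float = DEFAULT_SNAP_TOL):
        self.rts = rts
        self.snap_tol = snap_tol

    def fit(self, X, Y):
        if self.rts not in RTS_VALUES:
            raise ValueError(f"rts must be one of {RTS_VALUES}")
        X, Y = _validate_xy(X, Y)
        lam, w = solve_farrell_block(X, Y, X, Y, self.rts, return_weights=True)
        self.farrell_ = _snap(lam, self.snap_tol)
        self.scores_ = 1.0 / self.farrell_
        self.weights_ = w
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, Y):
        return self.fit(X, Y).scores_


def classify_rts(
    lam_crs: np.ndarray,
    lam_vrs: np.ndarray,
    lam_nirs: np.ndarray,
    tol: float = DEFAULT_RTS_TOL,
) -> np.ndarray:
    """Classify each unit's returns-to-scale regime from its score triple.

    A unit is scale efficient (CRS) when its VRS and CRS scores agree.  A
    scale-inefficient unit operates below its most productive scale size (IRS)
    exactly when the non-increasing-RS technology still admits the CRS
    projection, i.e. when the NIRS and CRS scores agree; otherwise the NIRS
    program binds at the VRS frontier and the unit is too large (DRS).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lam_crs = np.atleast_1d(np.asarray(lam_crs, dtype=float))
    lam_vrs = np.atleast_1d(np.asarray(lam_vrs, dtype=float))
    lam_nirs = np.atleast_1d(np.asarray(lam_nirs, dtype=float))
    if np.any(lam_crs < 1) or np.any(lam_vrs < 1) or np.any(lam_nirs < 1):
        raise ValueError("Farrell multipliers must be >= 1")
    out = np.where(
        np.abs(lam_crs - lam_vrs) <= tol,
        "CRS",
        np.where(np.abs(lam_nirs - lam_crs) <= tol, "IRS", "DRS"),
    )
    return out


@dataclass
class EfficiencyResult:
    """Per-unit efficiency table (Farrell and Shephard conventions)."""

    ids: np.ndarray
    groups: np.ndarray
    farrell_crs: np.ndarray
    farrell_vrs: np.ndarray
    farrell_nirs: np.ndarray
    te: np.ndarray
    pte: np.ndarray
    se: np.ndarray
    rts_class: np.ndarray
    orientation: str = "output"
    tol: float = DEFAULT_SNAP_TOL

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "group": self.groups,
                "te": self.te,
                "pte": self.pte,
                "se": self.se,
                "rts_class": self.rts_class,
            }
        )


class EfficiencyDecomposition(BaseEstimator):
    """Full TE = PTE x SE decomposition with returns-to-scale labels.

    Solves the CRS, VRS and NIRS envelopment programs for every unit.  The
    mathematically guaranteed nesting ``lambda_VRS <= lambda_NIRS <=
    lambda_CRS`` is enforced on the solver output (any violation is solver
    round-off), which makes ``TE <= PTE`` and ``SE in (0, 1]`` exact.

    Attributes
    ----------
    farrell_crs_, farrell_vrs_, farrell_nirs_ : (n,) Farrell multipliers.
    te_, pte_, se_ : (n,) Shephard-scale efficiencies in (0, 1].
    rts_class_ : (n,) labels in {"CRS", "IRS", "DRS"}.
    """

    def __init__(
        self,
        snap_tol: float = DEFAULT_SNAP_TOL,
        rts_tol: float = DEFAULT_RTS_TOL,
    ):
        self.snap_tol = snap_tol
        self.rts_tol = rts_tol

    def fit(self, X, Y):
        X, Y = _validate_xy(X, Y)
        lam = {
            rts: _snap(solve_farrell_block(X, Y, X, Y, rts), self.snap_tol)
            for rts in RTS_VALUES
        }
        # enforce the theoretical nesting against solver round-off
        lam["vrs"] = np.minimum(lam["vrs"], lam["crs"])
        lam["nirs"] = np.clip(lam["nirs"], lam["vrs"], lam["crs"])
        self.farrell_crs_ = lam["crs"]
        self.farrell_vrs_ = lam["vrs"]
        self.farrell_nirs_ = lam["nirs"]
        self.te_ = 1.0 / lam["crs"]
        self.pte_ = 1.0 / lam["vrs"]
        self.se_ = self.te_ / self.pte_
        self.rts_class_ = classify_rts(
            lam["crs"], lam["vrs"], lam["nirs"], self.rts_tol
        )
        self.n_features_in_ = X.shape[1]
        return self

    def result(self, ids=None, groups=None) -> EfficiencyResult:
        check_is_fitted(self, "te_")
        n = len(self.te_)
        return EfficiencyResult(
            ids=np.asarray(ids) if ids is not None else np.arange(n),
            groups=np.asarray(groups) if groups is not None else np.repeat("all", n),
            farrell_crs=self.farrell_crs_,
            farrell_vrs=self.farrell_vrs_,
            farrell_nirs=self.farrell_nirs_,
            te=self.te_,
            pte=self.pte_,
            se=self.se_,
            rts_class=self.rts_class_,
            tol=self.snap_tol,
        )


def solve_dea(panel: DMUPanel, rts: str, evaluated_unit: int):
    """Farrell score and intensity weights of one unit of a panel.

    Returns ``(lam, mu)`` where ``lam >= 1`` is the output-oriented Farrell
    multiplier and ``mu`` the optimal intensity weights over the panel units.
    """
    if not 0 <= evaluated_unit < panel.n_units:
        raise IndexError(f"evaluated_unit {evaluated_unit} out of range")
    lam, w = solve_farrell_block(
        panel.X[[evaluated_unit]],
        panel.Y[[evaluated_unit]],
        panel.X,
        panel.Y,
        rts,
        return_weights=True,
    )
    return float(_snap(lam, DEFAULT_SNAP_TOL)[0]), w[0]


def efficiency_table(panel: DMUPanel, **kwargs) -> EfficiencyResult:
    """CRS/VRS/NIRS scores, TE/PTE/SE and RTS class for every panel unit."""
    est = EfficiencyDecomposition(**kwargs).fit(panel.X, panel.Y)
    return est.result(ids=panel.ids, groups=panel.groups)
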