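"""Smoothed homogeneous bootstrap for bias-correcting DEA scores.

DEA estimates the production frontier from the inside, so raw efficiency
scores are optimistic: Farrell multipliers are biased toward 1.  The smoothed
homogeneous bootstrap resamples the estimated Farrell scores with kernel
noise, reflects them about the frontier value 1 (scores live on a bounded
support), regenerates pseudo-outputs, and re-solves the DEA against each
pseudo reference set.  The replicate scores mimic, around the estimated
frontier, how the estimated scores behave around the true frontier, which
yields a bias estimate, bias-corrected scores and percentile confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._lp import solve_farrell_block
from .dea import DEAScores, _validate_xy
from .panel import DMUPanel

__all__ = [
    "reflect_and_bandwidth",
    "SmoothedBootstrapDEA",
    "BootstrapResult",
    "smoothed_bootstrap",
]


def reflect_and_bandwidth(farrell: np.ndarray) -> tuple[float, bool]:
    """Silverman bandwidth on the reflected score sample.

    Farrell scores live on ``[1, inf)``; reflecting them about 1 (the sample
    ``{lam_i} U {2 - lam_i}``) removes the boundary bias of the kernel
    estimate.  The robust Silverman rule is applied to the reflected sample
    of size ``2n``::

        h = 0.9 * min(sd, IQR / 1.349) * (2n) ** (-1/5)

    Returns ``(h, degenerate)``; when all scores coincide there is no spread
    to smooth, ``h = 0`` is returned with the degeneracy flag set and the
    bootstrap falls back to naive resampling.
    """
    farrell = np.asarray(farrell, dtype=float)
    if farrell.ndim != 1 or farrell.size < 2:
        raise ValueError("need a 1-d sample of at least two scores")
    if np.any(farrell < 1):
        raise ValueError("Farrell scores must be >= 1")
    if np.allclose(farrell, farrell[0]):
        return 0.0, True
    reflected = np.concatenate([farrell, 2.0 - farrell])
    sd = reflected.std(ddof=1)
    q75, q25 = np.percentile(reflected, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = 0.9 * spread * (2 * farrell.size) ** (-0.2)
    return float(h), False


@dataclass
class BootstrapResult:
    """Per-unit bias correction output of the smoothed bootstrap."""

    ids: np.ndarray
    groups: np.ndarray
    farrell: np.ndarray                 # original lambda-hat
    replicates: np.ndarray              # (n, B) lambda-star
    bias: np.ndarray                    # mean_b(lambda-star) - lambda-hat
    bias_corrected: np.ndarray          # 2*lambda-hat - mean_b(lambda-star), clamped at 1
    shephard_corrected: np.ndarray      # 1 / bias_corrected
    ci_low: np.ndarray                  # Farrell-scale percentile CI
    ci_high: np.ndarray
    clamped: np.ndarray                 # units whose corrected score hit the clamp
    bandwidth: float
    degenerate: bool
    n_replications: int
    alpha: float
    rts: str
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "group": self.groups,
                "farrell_raw": self.farrell,
                "farrell_bc": self.bias_corrected,
                "score_raw": 1.0 / self.farrell,
                "score_bc": self.shephard_corrected,
                "bias": self.bias,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "clamped": self.clamped,
            }
        )


class SmoothedBootstrapDEA(BaseEstimator):
    """Smoothed homogeneous bootstrap around output-oriented DEA scores.

    Parameters
    ----------
    rts : {"crs", "vrs"}, default "crs"
        Technology for both the original scores and every re-solve.  (The
        NIRS model is used only for returns-to-scale classification and is
        not bootstrapped.)
    n_replications : int, default 2000
        Bootstrap replications ``B``.
    alpha : float, default 0.05
        Two-sided confidence level for the percentile intervals.
    random_state : int or numpy Generator, required for reproducible runs.

    Attributes (after ``fit``)
    --------------------------
    farrell_, bias_, bias_corrected_, shephard_corrected_,
    ci_low_, ci_high_ : (n,) arrays; CIs are on the Farrell scale.
    replicates_ : (n, B) replicate Farrell scores.
    bandwidth_ : float, the smoothing bandwidth used.

    Notes
    -----
    One bootstrap replication: resample ``beta*`` with replacement from the
    estimated scores, add kernel noise ``h * xi``, reflect values below 1,
    shrink toward the resample mean to undo the variance inflation of the
    smoothing, re-reflect, deflate every unit's outputs by the drawn
    inefficiency relative to its estimated one (inputs are never perturbed:
    the model is output-oriented), and re-solve the DEA of every original
    unit against the pseudo reference set.
    """

    def __init__(
        self,
        rts: str = "crs",
        n_replications: int = 2000,
        alpha: float = 0.05,
        random_state=None,
    ):
        self.rts = rts
        self.n_replications = n_replications
        self.alpha = alpha
        self.random_state = random_state

    def _rng(self) -> np.random.Generator:
        if isinstance(self.random_state, np.random.Generator):
            return self.random_state
        return np.random.default_rng(self.random_state)

    def fit(self, X, Y):
        if self.rts not in ("crs", "vrs"):
            raise ValueError("bootstrap supports rts in {'crs', 'vrs'}")
        B = int(self.n_replications)
        if B < 1:
            raise ValueError("n_replications must be >= 1")
        X, Y = _validate_xy(X, Y)
        n = X.shape[0]
        rng = self._rng()

        lam = DEAScores(rts=self.rts).fit(X, Y).farrell_
        h, degenerate = reflect_and_bandwidth(lam) if n > 1 else (0.0, True)
        var_lam = lam.var(ddof=1) if n > 1 else 0.0

        replicates = np.empty((n, B))
        for b in range(B):
            beta = rng.choice(lam, size=n, replace=True)
            if degenerate or h == 0.0:
                delta = beta.copy()
            else:
                smoothed = beta + h * rng.standard_normal(n)
                smoothed = np.where(smoothed < 1.0, 2.0 - smoothed, smoothed)
                mean_beta = beta.mean()
                delta = mean_beta + (smoothed - mean_beta) / np.sqrt(
                    1.0 + h * h / var_lam
                )
                delta = np.where(delta < 1.0, 2.0 - delta, delta)
            pseudo_Y = Y * (lam / delta)[:, None]
            replicates[:, b] = solve_farrell_block(X, Y, X, pseudo_Y, self.rts)

        bias = replicates.mean(axis=1) - lam
        corrected = lam - bias  # = 2*lam - mean(replicates)
        clamped = corrected < 1.0
        corrected = np.maximum(corrected, 1.0)
        diffs = replicates - lam[:, None]
        ci_low = lam - np.quantile(diffs, 1.0 - self.alpha / 2.0, axis=1)
        ci_high = lam - np.quantile(diffs, self.alpha / 2.0, axis=1)
        ci_low = np.maximum(ci_low, 1.0)
        ci_high = np.maximum(ci_high, ci_low)

        self.farrell_ = lam
        self.replicates_ = replicates
        self.bias_ = bias
        self.bias_corrected_ = corrected
        self.shephard_corrected_ = 1.0 / corrected
        self.ci_low_ = ci_low
        self.ci_high_ = ci_high
        self.clamped_ = clamped
        self.bandwidth_ = h
        self.degenerate_ = degenerate
        self.n_features_in_ = X.shape[1]
        return self

    def result(self, ids=None, groups=None) -> BootstrapResult:
        n = len(self.farrell_)
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None
        return BootstrapResult(
            ids=np.asarray(ids) if ids is not None else np.arange(n),
            groups=np.asarray(groups) if groups is not None else np.repeat("all", n),
            farrell=self.farrell_,
            replicates=self.replicates_,
            bias=self.bias_,
            bias_corrected=self.bias_corrected_,
            shephard_corrected=self.shephard_corrected_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            clamped=self.clamped_,
            bandwidth=self.bandwidth_,
            degenerate=self.degenerate_,
            n_replications=int(self.n_replications),
            alpha=self.alpha,
            rts=self.rts,
            seed=seed,
        )


def smoothed_bootstrap(
    panel: DMUPanel,
    rts: str = "crs",
    B: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> BootstrapResult:
    """Run the smoothed homogeneous bootstrap on a panel (single frontier)."""
    est = SmoothedBootstrapDEA(
        rts=rts, n_replications=B, alpha=alpha, random_state=seed
    ).fit(panel.X, panel.Y)
    return est.result(ids=panel.ids, groups=panel.groups)
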