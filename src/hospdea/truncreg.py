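"""Truncated-normal regression and the Simar–Wilson double bootstrap.

Stage two of the analysis regresses efficiency scores on environmental
covariates.  Because Farrell multipliers are bounded below by 1 (Shephard
scores bounded in (0, 1]), the error cannot be normal: the response follows a
truncated-normal regression, fitted here by maximum likelihood on
``(beta, log sigma)``.  Inference uses the Simar–Wilson parametric bootstrap:
naive second-stage regressions on raw DEA scores are invalid because the
scores are estimated from a common frontier (their errors are correlated and
biased toward efficiency), so the procedure first bias-corrects the scores
with a regression-based parametric bootstrap and then bootstraps the
truncated regression itself for confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._lp import solve_farrell_block
from .bootstrap import BootstrapResult
from .dea import DEAScores
from .panel import DMUPanel

__all__ = [
    "truncnorm_loglik",
    "TruncatedNormalRegression",
    "TruncRegResult",
    "fit_truncreg",
    "sw_algorithm1",
    "sw_algorithm2",
]


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _log_trunc_mass(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """log(Phi(beta) - Phi(alpha)) computed stably for extreme arguments."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.all(np.isinf(alpha) & (alpha < 0)):
        return special.log_ndtr(beta)
    if np.all(np.isinf(beta) & (beta > 0)):
        return special.log_ndtr(-alpha)
    la = special.log_ndtr(alpha)
    lb = special.log_ndtr(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = lb + np.log1p(-np.exp(la - lb))
    # mirror for deep upper tails where both normal masses are ~1
    hi = (alpha > 0) & np.isfinite(alpha)
    if np.any(hi):
        la2 = special.log_ndtr(-beta[hi])
        lb2 = special.log_ndtr(-alpha[hi])
        out = np.asarray(out, dtype=float)
        out[hi] = lb2 + np.log1p(-np.exp(la2 - lb2))
    return out


def truncnorm_loglik(
    y: np.ndarray,
    Zd: np.ndarray,
    beta: np.ndarray,
    sigma: float,
    lower: float = -np.inf,
    upper: float = np.inf,
) -> float:
    """Log-likelihood of a truncated-normal regression.

    ``y_i ~ N(z_i beta, sigma^2)`` conditioned on ``lower < y_i < upper``::

        sum_i [ log phi((y_i - z_i beta)/sigma) - log sigma
                - log(Phi((upper - z_i beta)/sigma) - Phi((lower - z_i beta)/sigma)) ]

    ``Zd`` is the full design matrix (including any intercept column).
    """
    if not lower < upper:
        raise ValueError("lower bound must be strictly below upper bound")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    Zd = np.atleast_2d(np.asarray(Zd, dtype=float))
    outside = (y <= lower) | (y >= upper)
    if np.any(outside):
        idx = np.flatnonzero(outside)
        raise ValueError(
            f"responses on or outside the truncation bounds at rows {idx.tolist()}"
        )
    mu = Zd @ np.asarray(beta, dtype=float)
    u = (y - mu) / sigma
    log_pdf = -0.5 * u * u - _LOG_SQRT_2PI - np.log(sigma)
    a = np.full_like(y, -np.inf) if np.isinf(lower) else (lower - mu) / sigma
    b = np.full_like(y, np.inf) if np.isinf(upper) else (upper - mu) / sigma
    return float(np.sum(log_pdf - _log_trunc_mass(a, b)))


def _negloglik_and_grad(theta, y, Zd, lower, upper):
    """Negative log-likelihood and gradient in (beta, log sigma)."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    mu = Zd @ beta
    u = (y - mu) / sigma
    ll = -0.5 * u * u - _LOG_SQRT_2PI - log_sigma

    a = None if np.isinf(lower) else (lower - mu) / sigma
    b = None if np.isinf(upper) else (upper - mu) / sigma
    if a is None and b is None:
        dmu = u / sigma
        dls = u * u - 1.0
        return -np.sum(ll), np.concatenate([-(Zd.T @ dmu), [-np.sum(dls)]])

    a_arr = np.full_like(y, -np.inf) if a is None else a
    b_arr = np.full_like(y, np.inf) if b is None else b
    log_mass = _log_trunc_mass(a_arr, b_arr)
    ll = ll - log_mass
    # hazard-type ratios phi(.)/mass computed in log space: the pdf and the
    # truncation mass underflow together in deep tails, their ratio does not
    a_fin, b_fin = np.isfinite(a_arr), np.isfinite(b_arr)
    ratio_a = np.zeros_like(y)
    ratio_b = np.zeros_like(y)
    with np.errstate(over="ignore"):
        ratio_a[a_fin] = np.exp(
            -0.5 * a_arr[a_fin] ** 2 - _LOG_SQRT_2PI - log_mass[a_fin]
        )
        ratio_b[b_fin] = np.exp(
            -0.5 * b_arr[b_fin] ** 2 - _LOG_SQRT_2PI - log_mass[b_fin]
        )
    # d/dmu log mass = -(phi_b - phi_a) / (sigma * mass)
    dmu = u / sigma + (ratio_b - ratio_a) / sigma
    a_term = np.zeros_like(y)
    b_term = np.zeros_like(y)
    a_term[a_fin] = a_arr[a_fin] * ratio_a[a_fin]
    b_term[b_fin] = b_arr[b_fin] * ratio_b[b_fin]
    dls = u * u - 1.0 + b_term - a_term
    return -np.sum(ll), np.concatenate([-(Zd.T @ dmu), [-np.sum(dls)]])


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class TruncatedNormalRegression(BaseEstimator, RegressorMixin):
    """Maximum-likelihood truncated-normal regression.

    Parameters
    ----------
    lower, upper : floats (either may be infinite)
        Known truncation bounds of the response.
    fit_intercept : bool, default True
    max_iter : int, default 500

    Attributes
    ----------
    coef_ : (r,) covariate coefficients; intercept_ : float; sigma_ : float
    loglik_ : float, log-likelihood at the optimum
    wald_ : float, Wald statistic for joint nullity of the covariates
    se_ : (r + 2,) asymptotic standard errors of (intercept, coef, sigma)
        from the observed information (intercept first when fitted).
    """

    def __init__(
        self,
        lower: float = -np.inf,
        upper: float = np.inf,
        fit_intercept: bool = True,
        max_iter: int = 500,
    ):
        self.lower = lower
        self.upper = upper
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter

    def _design(self, Z: np.ndarray) -> np.ndarray:
        if self.fit_intercept:
            return np.column_stack([np.ones(Z.shape[0]), Z])
        return Z

    def fit(self, Z, y, start: np.ndarray | None = None):
        Z = check_array(Z)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != Z.shape[0]:
            raise ValueError("Z and y length mismatch")
        Zd = self._design(Z)
        n, k = Zd.shape
        if n <= k + 1:
            raise ValueError(f"need more than {k + 1} observations, got {n}")

        if start is None:
            beta0, *_ = np.linalg.lstsq(Zd, y, rcond=None)
            resid = y - Zd @ beta0
            sigma0 = max(float(resid.std(ddof=0)), 1e-3)
            start = np.concatenate([beta0, [np.log(sigma0)]])
        else:
            start = np.asarray(start, dtype=float)

        res = optimize.minimize(
            _negloglik_and_grad,
            start,
            args=(y, Zd, self.lower, self.upper),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": 1e-9},
        )
        if not res.success and np.linalg.norm(res.jac) > 1e-3:
            res2 = optimize.minimize(
                _negloglik_and_grad,
                res.x,
                args=(y, Zd, self.lower, self.upper),
                jac=True,
                method="BFGS",
                options={"maxiter": self.max_iter},
            )
            if res2.fun <= res.fun:
                res = res2
        theta = res.x
        sigma = float(np.exp(theta[-1]))
        if sigma < 1e-8:
            raise RuntimeError("sigma collapsed below 1e-8: degenerate fit")
        full_beta = theta[:-1]
        self.converged_ = bool(res.success or np.linalg.norm(res.jac) < 1e-3)
        if not self.converged_:
            raise RuntimeError(
                "truncated regression failed to converge; "
                f"|grad| = {np.linalg.norm(res.jac):.3g}, best loglik = {-res.fun:.6g}"
            )
        if self.fit_intercept:
            self.intercept_ = float(full_beta[0])
            self.coef_ = full_beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = full_beta.copy()
        self.sigma_ = sigma
        self.loglik_ = -float(res.fun)
        self.n_iter_ = int(res.nit)
        self.n_features_in_ = Z.shape[1]

        # observed information -> Wald statistic for the covariate block
        cov = self._parameter_covariance(theta, y, Zd)
        self.covariance_ = cov
        sl = slice(1, k) if self.fit_intercept else slice(0, k)
        bcov = full_beta[sl.start if self.fit_intercept else 0 : k]
        V = cov[sl, sl]
        try:
            self.wald_ = float(bcov @ np.linalg.solve(V, bcov))
        except np.linalg.LinAlgError:
            self.wald_ = np.nan
        # delta method for sigma = exp(log sigma)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se[-1] *= sigma
        self.se_ = se
        return self

    def _parameter_covariance(self, theta, y, Zd):
        def grad(t):
            return _negloglik_and_grad(t, y, Zd, self.lower, self.upper)[1]

        k = theta.size
        eps = 1e-5 * np.maximum(np.abs(theta), 1.0)
        H = np.empty((k, k))
        for j in range(k):
            step = np.zeros(k)
            step[j] = eps[j]
            H[:, j] = (grad(theta + step) - grad(theta - step)) / (2 * eps[j])
        H = 0.5 * (H + H.T)
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full((k, k), np.nan)

    def predict(self, Z):
        check_is_fitted(self, "coef_")
        Z = check_array(Z)
        return self.intercept_ + Z @ self.coef_


# ---------------------------------------------------------------------------
# result container & functional wrappers
# ---------------------------------------------------------------------------


@dataclass
class TruncRegResult:
    """Coefficients, scale and bootstrap CIs of a truncated regression."""

    names: list[str]
    beta: np.ndarray          # intercept first
    sigma: float
    loglik: float
    wald: float
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    alpha: float = 0.05
    L1: int = 0
    L2: int = 0
    convention: str = "farrell_ge1"
    converged: bool = True
    n_used: int = 0
    n_excluded: int = 0
    boot_beta: np.ndarray | None = None   # (L2, k) bootstrap draws
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"variable": self.names, "beta": self.beta})
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
            df["excludes_zero"] = (self.ci_low > 0) | (self.ci_high < 0)
        return df


def fit_truncreg(
    y: np.ndarray,
    Z: np.ndarray,
    lower: float = -np.inf,
    upper: float = np.inf,
    start: np.ndarray | None = None,
    names: list[str] | None = None,
) -> TruncRegResult:
    """Point-estimate truncated-normal regression of ``y`` on ``Z``."""
    est = TruncatedNormalRegression(lower=lower, upper=upper).fit(Z, y, start=start)
    beta = np.concatenate([[est.intercept_], est.coef_])
    if names is None:
        names = ["intercept"] + [f"z{j + 1}" for j in range(Z.shape[1])]
    return TruncRegResult(
        names=list(names),
        beta=beta,
        sigma=est.sigma_,
        loglik=est.loglik_,
        wald=est.wald_,
        converged=est.converged_,
        n_used=len(np.asarray(y)),
    )


# ---------------------------------------------------------------------------
# Simar–Wilson algorithms
# ---------------------------------------------------------------------------


def _draw_truncated_responses(
    mu: np.ndarray, sigma: float, lower: float, upper: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw y_i ~ N(mu_i, sigma^2) truncated to (lower, upper)."""
    a = (lower - mu) / sigma if np.isfinite(lower) else np.full_like(mu, -np.inf)
    b = (upper - mu) / sigma if np.isfinite(upper) else np.full_like(mu, np.inf)
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng)


def _fit_with_retries(y, Z, lower, upper, max_retries=5, redraw=None, rng=None):
    """Fit, redrawing the replicate on non-convergence (bootstrap inner loop)."""
    last_err = None
    for _ in range(max_retries):
        try:
            est = TruncatedNormalRegression(lower=lower, upper=upper).fit(Z, y)
            return est, y
        except RuntimeError as err:  # non-convergence or degenerate sigma
            last_err = err
            if redraw is None:
                break
            y = redraw(rng)
    raise RuntimeError(f"bootstrap replicate failed after retries: {last_err}")


def _convention(convention: str):
    if convention == "farrell_ge1":
        return 1.0, np.inf
    if convention == "shephard01":
        return 0.0, 1.0
    raise ValueError("response_convention must be 'farrell_ge1' or 'shephard01'")


def _response(farrell: np.ndarray, convention: str) -> np.ndarray:
    return farrell if convention == "farrell_ge1" else 1.0 / farrell


def sw_algorithm1(
    panel: DMUPanel,
    Z: np.ndarray | None = None,
    rts: str = "crs",
    L: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
    response_convention: str = "farrell_ge1",
    names: list[str] | None = None,
) -> TruncRegResult:
    """Single-loop Simar–Wilson bootstrap (no bias correction of scores).

    Regresses the raw DEA scores on the covariates by truncated ML, then
    bootstraps the regression parametrically ``L`` times for percentile CIs.
    """
    rng = np.random.default_rng(seed)
    Z = panel.Z if Z is None else np.asarray(Z, dtype=float)
    if Z is None:
        raise ValueError("panel has no covariates")
    lower, upper = _convention(response_convention)
    lam = DEAScores(rts=rts).fit(panel.X, panel.Y).farrell_
    y = _response(lam, response_convention)
    keep = lam > 1.0
    if keep.sum() < Z.shape[1] + 3:
        raise RuntimeError(
            f"only {int(keep.sum())} units strictly inside the frontier; "
            "too few for the truncated regression"
        )
    est = TruncatedNormalRegression(lower=lower, upper=upper).fit(Z[keep], y[keep])
    beta_hat = np.concatenate([[est.intercept_], est.coef_])
    boot = _parametric_ci_loop(
        Z[keep], beta_hat, est.sigma_, lower, upper, L, rng
    )
    return _assemble_result(
        panel, Z, names, beta_hat, est, boot, alpha, 0, L, response_convention,
        n_used=int(keep.sum()), n_excluded=int((~keep).sum()),
    )


def sw_algorithm2(
    panel: DMUPanel,
    Z: np.ndarray | None = None,
    rts: str = "crs",
    L1: int = 100,
    L2: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
    response_convention: str = "farrell_ge1",
    names: list[str] | None = None,
) -> tuple[TruncRegResult, BootstrapResult]:
    """Simar–Wilson double bootstrap: bias-correct scores, then infer.

    Steps: (1) DEA Farrell scores; (2) truncated regression of the scores on
    the covariates using units strictly inside the frontier; (3) ``L1``
    parametric bootstrap loops that redraw each unit's inefficiency from the
    fitted regression, deflate its outputs accordingly, and re-solve the DEA
    to estimate and remove the frontier bias of each score; (4) refit the
    truncated regression on the bias-corrected scores; (5) ``L2`` parametric
    bootstrap loops around that fit; (6) percentile confidence intervals.
    """
    if L1 < 1 or L2 < 1:
        raise ValueError("L1 and L2 must be >= 1")
    rng = np.random.default_rng(seed)
    Z = panel.Z if Z is None else np.asarray(Z, dtype=float)
    if Z is None:
        raise ValueError("panel has no covariates")
    lower, upper = _convention(response_convention)
    X, Y = panel.X, panel.Y
    n = panel.n_units

    # (1) original scores
    lam = DEAScores(rts=rts).fit(X, Y).farrell_

    # (2) first-stage truncated regression on units with lam > 1
    keep = lam > 1.0
    if keep.sum() < Z.shape[1] + 3:
        raise RuntimeError(
            f"only {int(keep.sum())} units strictly inside the frontier; "
            "too few for the truncated regression"
        )
    y1 = _response(lam, response_convention)
    est1 = TruncatedNormalRegression(lower=lower, upper=upper).fit(
        Z[keep], y1[keep]
    )
    mu_all = est1.intercept_ + Z @ est1.coef_

    # (3) regression-based parametric bootstrap of the frontier bias
    replicates = np.empty((n, L1))
    for b in range(L1):
        resp = _draw_truncated_responses(mu_all, est1.sigma_, lower, upper, rng)
        delta = resp if response_convention == "farrell_ge1" else 1.0 / resp
        pseudo_Y = Y * (lam / delta)[:, None]
        replicates[:, b] = solve_farrell_block(X, Y, X, pseudo_Y, rts)
    bias = replicates.mean(axis=1) - lam
    lam_bc = lam - bias
    clamped = lam_bc <= 1.0
    lam_bc = np.maximum(lam_bc, 1.0)

    # (4) second-stage truncated regression on the bias-corrected scores;
    # scores clamped to the frontier carry no inefficiency signal and are
    # excluded (their count is reported)
    keep2 = lam_bc > 1.0
    if keep2.sum() < Z.shape[1] + 3:
        raise RuntimeError("too few bias-corrected scores inside the frontier")
    y2 = _response(lam_bc, response_convention)
    est2 = TruncatedNormalRegression(lower=lower, upper=upper).fit(
        Z[keep2], y2[keep2]
    )
    beta_hat = np.concatenate([[est2.intercept_], est2.coef_])

    # (5)-(6) parametric bootstrap of the regression itself
    boot = _parametric_ci_loop(
        Z[keep2], beta_hat, est2.sigma_, lower, upper, L2, rng
    )
    reg = _assemble_result(
        panel, Z, names, beta_hat, est2, boot, alpha, L1, L2,
        response_convention,
        n_used=int(keep2.sum()), n_excluded=int((~keep2).sum()),
    )
    diffs = replicates - lam[:, None]
    ci_low = np.maximum(lam - np.quantile(diffs, 1 - alpha / 2, axis=1), 1.0)
    ci_high = np.maximum(lam - np.quantile(diffs, alpha / 2, axis=1), ci_low)
    boot_res = BootstrapResult(
        ids=panel.ids,
        groups=panel.groups,
        farrell=lam,
        replicates=replicates,
        bias=bias,
        bias_corrected=lam_bc,
        shephard_corrected=1.0 / lam_bc,
        ci_low=ci_low,
        ci_high=ci_high,
        clamped=clamped,
        bandwidth=np.nan,
        degenerate=False,
        n_replications=L1,
        alpha=alpha,
        rts=rts,
        seed=seed,
        meta={"kind": "sw-algorithm2-regression-bootstrap"},
    )
    return reg, boot_res


def _parametric_ci_loop(Zk, beta_hat, sigma_hat, lower, upper, L, rng):
    """Step-5 loop: refit on responses simulated from the fitted model."""
    k = beta_hat.size
    mu = beta_hat[0] + Zk @ beta_hat[1:]
    draws = np.empty((L, k + 1))
    for l in range(L):
        def redraw(r):
            return _draw_truncated_responses(mu, sigma_hat, lower, upper, r)

        y_star = redraw(rng)
        est, _ = _fit_with_retries(
            y_star, Zk, lower, upper, redraw=lambda r: redraw(r), rng=rng
        )
        draws[l, :-1] = np.concatenate([[est.intercept_], est.coef_])
        draws[l, -1] = est.sigma_
    return draws


def _assemble_result(
    panel, Z, names, beta_hat, est, boot, alpha, L1, L2, convention,
    n_used, n_excluded,
):
    if names is None:
        base = panel.covariate_names or [f"z{j + 1}" for j in range(Z.shape[1])]
        names = ["intercept"] + list(base)
    ci_low = np.quantile(boot[:, :-1], alpha / 2, axis=0)
    ci_high = np.quantile(boot[:, :-1], 1 - alpha / 2, axis=0)
    return TruncRegResult(
        names=list(names),
        beta=beta_hat,
        sigma=est.sigma_,
        loglik=est.loglik_,
        wald=est.wald_,
        ci_low=ci_low,
        ci_high=ci_high,
        alpha=alpha,
        L1=L1,
        L2=L2,
        convention=convention,
        converged=est.converged_,
        n_used=n_used,
        n_excluded=n_excluded,
        boot_beta=boot[:, :-1],
        meta={"boot_sigma_mean": float(boot[:, -1].mean())},
    )
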