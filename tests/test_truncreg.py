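import numpy as np
import pytest
from scipy import integrate, optimize, stats

from hospdea import (
    TruncatedNormalRegression,
    fit_truncreg,
    recovery_benchmark_config,
    simulate_panel,
    standardize_covariates,
    sw_algorithm1,
    sw_algorithm2,
    truncnorm_loglik,
)


def test_loglik_reduces_to_normal_without_truncation():
    rng = np.random.default_rng(0)
    y = rng.normal(2, 1, 40)
    Zd = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
    beta = np.array([2.0, 0.5, -0.3])
    ll = truncnorm_loglik(y, Zd, beta, 1.3)
    assert ll == pytest.approx(stats.norm.logpdf(y, Zd @ beta, 1.3).sum(), rel=1e-12)


def test_loglik_zero_residual_closed_form():
    sigma = 0.7
    ll = truncnorm_loglik(np.array([1.5]), np.array([[1.0]]), np.array([1.5]), sigma)
    assert ll == pytest.approx(-np.log(sigma) - 0.5 * np.log(2 * np.pi), rel=1e-12)


def test_loglik_matches_quadrature_on_doubly_truncated_sample():
    y = np.array([0.2, 0.5, 0.9])
    Zd = np.array([[1.0, 0.5], [1.0, -0.2], [1.0, 1.0]])
    beta = np.array([0.4, 0.3])
    sigma = 0.5
    expected = 0.0
    for yi, zi in zip(y, Zd):
        mu = zi @ beta
        mass, _ = integrate.quad(lambda t: stats.norm.pdf(t, mu, sigma), 0.0, 1.0)
        expected += np.log(stats.norm.pdf(yi, mu, sigma) / mass)
    ll = truncnorm_loglik(y, Zd, beta, sigma, 0.0, 1.0)
    assert ll == pytest.approx(expected, rel=1e-10)


def test_loglik_rejects_out_of_bounds_response():
    with pytest.raises(ValueError, match="rows \\[1\\]"):
        truncnorm_loglik(
            np.array([1.5, 0.9]), np.ones((2, 1)), np.array([1.2]), 0.3, lower=1.0
        )
    with pytest.raises(ValueError, match="sigma"):
        truncnorm_loglik(np.array([1.5]), np.ones((1, 1)), np.array([1.2]), 0.0)


def test_unbounded_fit_matches_least_squares():
    rng = np.random.default_rng(1)
    Z = rng.normal(size=(120, 3))
    y = 1.0 + Z @ [0.5, -0.2, 0.1] + rng.normal(0, 0.4, 120)
    est = TruncatedNormalRegression().fit(Z, y)
    Zd = np.column_stack([np.ones(120), Z])
    beta_ols, *_ = np.linalg.lstsq(Zd, y, rcond=None)
    np.testing.assert_allclose(
        np.r_[est.intercept_, est.coef_], beta_ols, rtol=1e-4
    )
    sigma_ml = (y - Zd @ beta_ols).std(ddof=0)
    assert est.sigma_ == pytest.approx(sigma_ml, rel=1e-4)


def test_left_truncated_fit_recovers_truth_at_large_n():
    rng = np.random.default_rng(7)
    n = 2000
    Z = rng.normal(size=(n, 2))
    beta_true = np.array([1.4, 0.4, -0.3])
    sigma_true = 0.15
    mu = beta_true[0] + Z @ beta_true[1:]
    y = stats.truncnorm.rvs(
        (1.0 - mu) / sigma_true, np.inf, loc=mu, scale=sigma_true, random_state=rng
    )
    est = TruncatedNormalRegression(lower=1.0).fit(Z, y)
    b = np.r_[est.intercept_, est.coef_]
    np.testing.assert_array_less(np.abs(b - beta_true), 3 * est.se_[:3] + 1e-12)
    assert est.sigma_ == pytest.approx(sigma_true, abs=3 * est.se_[3])
    assert est.wald_ > 100  # strong joint effect


def test_intercept_only_matches_scalar_location_mle():
    rng = np.random.default_rng(3)
    y = stats.truncnorm.rvs(-0.5, np.inf, loc=0.1, scale=0.2, size=400, random_state=rng)
    est = TruncatedNormalRegression(lower=0.0).fit(np.zeros((400, 1)), y)

    def nll(theta):
        m, ls = theta
        s = np.exp(ls)
        a = (0.0 - m) / s
        return -np.sum(stats.truncnorm.logpdf(y, a, np.inf, loc=m, scale=s))

    ref = optimize.minimize(nll, [y.mean(), np.log(y.std())], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10})
    assert est.intercept_ == pytest.approx(ref.x[0], abs=2e-4)
    assert est.sigma_ == pytest.approx(np.exp(ref.x[1]), abs=2e-4)
    assert np.allclose(est.coef_, 0.0)


def test_loglik_invariant_to_covariate_rescaling():
    rng = np.random.default_rng(9)
    Z = rng.normal(5, 2, size=(300, 2))
    mu = 1.3 + 0.1 * Z[:, 0] - 0.05 * Z[:, 1]
    y = stats.truncnorm.rvs((1 - mu) / 0.2, np.inf, loc=mu, scale=0.2, random_state=rng)
    est1 = TruncatedNormalRegression(lower=1.0).fit(Z, y)
    Zc = Z * np.array([10.0, 0.5])
    est2 = TruncatedNormalRegression(lower=1.0).fit(Zc, y)
    assert est1.loglik_ == pytest.approx(est2.loglik_, abs=1e-6)
    np.testing.assert_allclose(est2.coef_ * [10.0, 0.5], est1.coef_, rtol=1e-5)


def test_fit_truncreg_wrapper_returns_result():
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(60, 2))
    y = 0.5 + Z @ [1.0, 0.0] + rng.normal(0, 0.3, 60)
    res = fit_truncreg(y, Z, names=["intercept", "a", "b"])
    assert res.names == ["intercept", "a", "b"]
    assert res.converged and np.isfinite(res.loglik) and res.sigma > 0


def _panel_and_Z(n=60, seed=13):
    cfg = recovery_benchmark_config(n_units=n, seed=seed)
    panel = simulate_panel(cfg)
    return panel, standardize_covariates(panel, cfg)


def test_sw_algorithm2_deterministic_and_centred():
    panel, Z = _panel_and_Z()
    reg1, boot1 = sw_algorithm2(panel, Z=Z, rts="crs", L1=15, L2=200, seed=5)
    reg2, _ = sw_algorithm2(panel, Z=Z, rts="crs", L1=15, L2=200, seed=5)
    np.testing.assert_array_equal(reg1.ci_low, reg2.ci_low)
    np.testing.assert_array_equal(reg1.ci_high, reg2.ci_high)
    assert np.all(reg1.ci_low <= reg1.ci_high)
    # step-5 bootstrap distribution centred near the stage-2 estimate
    draws = reg1.boot_beta
    centre_gap = np.abs(draws.mean(axis=0) - reg1.beta)
    tol = 3.0 * draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
    # allow the truncation-induced small-sample skew a little slack
    assert np.all(centre_gap <= np.maximum(3 * tol, 0.05))
    # bias correction pushed Farrell scores away from the frontier
    assert boot1.bias_corrected.mean() >= boot1.farrell.mean()


def test_sw_algorithm1_runs_on_raw_scores():
    panel, Z = _panel_and_Z()
    reg = sw_algorithm1(panel, Z=Z, rts="crs", L=100, seed=8)
    assert reg.beta.shape == (4,)
    assert np.all(reg.ci_low <= reg.ci_high)
    assert reg.L1 == 0 and reg.L2 == 100


def test_sw_algorithm2_shephard_convention():
    panel, Z = _panel_and_Z(n=80, seed=29)
    reg, _ = sw_algorithm2(
        panel, Z=Z, rts="crs", L1=10, L2=50, seed=3, response_convention="shephard01"
    )
    assert reg.convention == "shephard01"
    # on the Shephard scale the inefficiency-increasing covariate flips sign
    assert reg.beta[1] < 0


def test_sw_algorithm2_needs_interior_units():
    """A panel where every unit is on the frontier leaves nothing to regress."""
    from hospdea import DMUPanel

    panel = DMUPanel(
        ids=list(range(6)), groups=["g"] * 6,
        X=np.tile([1.0, 2.0], (6, 1)), Y=np.tile([3.0], (6, 1)),
        Z=np.random.default_rng(0).normal(size=(6, 2)),
    )
    with pytest.raises(RuntimeError, match="too few|inside the frontier"):
        sw_algorithm2(panel, rts="crs", L1=2, L2=2, seed=0)
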