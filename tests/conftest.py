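"""Shared fixtures, including the two expensive Monte-Carlo studies.

The Monte-Carlo studies are session-scoped so the stage-2 recovery tests and
the interval-calibration tests share one computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from hospdea import (
    DEAScores,
    DMUPanel,
    TruncatedNormalRegression,
    coverage_benchmark_config,
    recovery_benchmark_config,
    simulate_panel,
    smoothed_bootstrap,
    standardize_covariates,
    sw_algorithm2,
)

BETA_TRUE = np.array([1.4, 0.4, -0.3, 0.0])  # recovery_benchmark_config effects


@pytest.fixture
def toy_ab_panel() -> DMUPanel:
    """A(x=1, y=2) dominates B(x=1, y=1); CRS score of B is 2."""
    return DMUPanel(ids=["A", "B"], groups=["g", "g"], X=[[1.0], [1.0]], Y=[[2.0], [1.0]])


@pytest.fixture
def toy_ac_panel() -> DMUPanel:
    """A(x=1, y=2) and the small unit C(x=0.5, y=0.5)."""
    return DMUPanel(ids=["A", "C"], groups=["g", "g"], X=[[1.0], [0.5]], Y=[[2.0], [0.5]])


def random_panel(rng, n=None, p=None, q=None) -> DMUPanel:
    n = int(rng.integers(3, 9)) if n is None else n
    p = int(rng.integers(1, 3)) if p is None else p
    q = int(rng.integers(1, 3)) if q is None else q
    return DMUPanel(
        ids=np.arange(n),
        groups=np.repeat("g", n),
        X=rng.uniform(0.5, 2.0, (n, p)),
        Y=rng.uniform(0.5, 2.0, (n, q)),
    )


@pytest.fixture(scope="session")
def recovery_study() -> dict:
    """50 Monte-Carlo repetitions of the double-bootstrap regression.

    Each repetition simulates a fresh 100-unit panel from the known-truth
    generator, runs the double bootstrap (L1=100, L2=500) and, on the same
    panel, a naive truncated regression of the raw DEA scores with Wald
    intervals, recording point estimates and CI coverage of the true
    coefficient vector.
    """
    n_reps = 50
    k = BETA_TRUE.size
    sw_beta = np.empty((n_reps, k))
    sw_cover = np.empty((n_reps, k), dtype=bool)
    naive_cover = np.empty((n_reps, k), dtype=bool)
    for rep in range(n_reps):
        cfg = recovery_benchmark_config(n_units=100, seed=30_000 + rep)
        panel = simulate_panel(cfg)
        Z = standardize_covariates(panel, cfg)
        reg, _ = sw_algorithm2(
            panel, Z=Z, rts="crs", L1=100, L2=500, alpha=0.05, seed=40_000 + rep
        )
        sw_beta[rep] = reg.beta
        sw_cover[rep] = (reg.ci_low <= BETA_TRUE) & (BETA_TRUE <= reg.ci_high)

        lam = DEAScores(rts="crs").fit(panel.X, panel.Y).farrell_
        keep = lam > 1.0
        naive = TruncatedNormalRegression(lower=1.0).fit(Z[keep], lam[keep])
        b = np.concatenate([[naive.intercept_], naive.coef_])
        se = naive.se_[:k]
        lo, hi = b - 1.959964 * se, b + 1.959964 * se
        naive_cover[rep] = (lo <= BETA_TRUE) & (BETA_TRUE <= hi)
    return {
        "beta_true": BETA_TRUE,
        "sw_beta": sw_beta,
        "sw_cover": sw_cover,
        "naive_cover": naive_cover,
    }


@pytest.fixture(scope="session")
def coverage_study() -> dict:
    """100 Monte-Carlo repetitions of bootstrap interval coverage.

    Homogeneous-inefficiency 50-unit panels with a curved frontier; for each
    panel the VRS smoothed bootstrap (B=200) produces nominal 95% intervals
    on the Farrell scale, checked against the stored true scores.
    """
    hits = 0
    total = 0
    per_rep = []
    for rep in range(100):
        panel = simulate_panel(coverage_benchmark_config(n_units=50, seed=1000 + rep))
        res = smoothed_bootstrap(panel, rts="vrs", B=200, alpha=0.05, seed=2000 + rep)
        c = (panel.true_delta >= res.ci_low) & (panel.true_delta <= res.ci_high)
        hits += int(c.sum())
        total += c.size
        per_rep.append(float(c.mean()))
    return {"pooled": hits / total, "per_rep": np.asarray(per_rep)}
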