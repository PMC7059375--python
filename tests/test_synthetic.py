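import logging

import numpy as np
import pytest

from hospdea import (
    DEAScores,
    SyntheticConfig,
    coverage_benchmark_config,
    default_table2_config,
    recovery_benchmark_config,
    simulate_panel,
    standardize_covariates,
)
from hospdea.synthetic import SyntheticConfigError


def test_two_group_panel_has_published_group_sizes():
    panel = simulate_panel(default_table2_config(seed=0))
    assert panel.n_units == 117
    assert int((panel.groups == "district").sum()) == 33
    assert int((panel.groups == "county").sum()) == 84
    assert panel.n_inputs == 5 and panel.n_outputs == 4 and panel.n_covariates == 6


def test_same_seed_bitwise_identical_different_seed_differs():
    cfg = default_table2_config(seed=42)
    a, b = simulate_panel(cfg), simulate_panel(cfg)
    np.testing.assert_array_equal(a.X, b.X)
    np.testing.assert_array_equal(a.Y, b.Y)
    np.testing.assert_array_equal(a.Z, b.Z)
    np.testing.assert_array_equal(a.true_delta, b.true_delta)
    c = simulate_panel(cfg, seed=43)
    assert not np.array_equal(a.X, c.X)


def test_outputs_never_exceed_frontier():
    cfg = recovery_benchmark_config(n_units=200, seed=5)
    panel = simulate_panel(cfg)
    kernel = np.exp(np.log(panel.X) @ cfg.frontier_exponents)
    frontier = kernel[:, None] * cfg.output_multipliers["all"][None, :]
    assert np.all(panel.Y <= frontier + 1e-9)
    np.testing.assert_allclose(panel.Y * panel.true_delta[:, None], frontier, rtol=1e-12)
    assert np.all(panel.true_delta >= 1.0)


def test_zero_noise_unit_intercept_puts_every_unit_on_frontier():
    cfg = recovery_benchmark_config(n_units=25, seed=3, sigma_true=0.0)
    cfg.covariate_effects = np.array([1.0, 0.0, 0.0, 0.0])
    panel = simulate_panel(cfg)
    np.testing.assert_allclose(panel.true_delta, 1.0)
    # a concave constant-returns frontier supports every point from above,
    # so each unit is a vertex of the empirical cone and scores exactly 1
    lam = DEAScores(rts="crs").fit(panel.X, panel.Y).farrell_
    np.testing.assert_allclose(lam, 1.0, atol=1e-6)
    assert (lam == 1.0).sum() >= 1


def test_inefficiency_mean_matches_truncated_normal_moment():
    cfg = coverage_benchmark_config(n_units=5000, seed=11, sigma_true=0.2)
    panel = simulate_panel(cfg)
    # intercept 1.0 truncated at 1: half-normal, mean 1 + sigma*sqrt(2/pi)
    expected = 1.0 + 0.2 * np.sqrt(2 / np.pi)
    se = panel.true_delta.std(ddof=1) / np.sqrt(panel.n_units)
    assert panel.true_delta.mean() == pytest.approx(expected, abs=3 * se)


def test_table2_district_doctor_mean_at_large_n():
    base = default_table2_config(seed=0)
    cfg = SyntheticConfig(
        n_per_group={"district": 1000},
        n_inputs=5, n_outputs=4,
        frontier_exponents=base.frontier_exponents,
        output_multipliers={"district": base.output_multipliers["district"]},
        covariate_effects=base.covariate_effects,
        sigma_true=base.sigma_true,
        input_scales={"district": base.input_scales["district"]},
        covariate_scales={"district": base.covariate_scales["district"]},
        seed=17,
    )
    panel = simulate_panel(cfg)
    doctors = panel.X[:, 1]
    # published scale 18.64 +/- 10.97; flooring negative draws at ~0 shifts
    # the mean up by ~0.2, well inside two Monte-Carlo standard errors
    se = 10.97 / np.sqrt(1000)
    assert doctors.mean() == pytest.approx(18.64, abs=2 * se + 0.25)


def test_table2_county_discharge_frontier_centred_on_published_mean():
    panel = simulate_panel(default_table2_config(seed=23))
    county = panel.by_group("county")
    frontier_discharges = (county.Y * county.true_delta[:, None])[:, 1]
    se = frontier_discharges.std(ddof=1) / np.sqrt(len(frontier_discharges))
    assert frontier_discharges.mean() == pytest.approx(990.03, abs=3 * se)


def test_standardize_covariates_recover_effect_scale():
    cfg = recovery_benchmark_config(n_units=3000, seed=2)
    panel = simulate_panel(cfg)
    Zs = standardize_covariates(panel, cfg)
    assert np.abs(Zs.mean(axis=0)).max() < 0.1
    assert np.abs(Zs.std(axis=0) - 1.0).max() < 0.1


def test_pooled_frontier_flag_averages_group_multipliers():
    cfg = default_table2_config(seed=0, pooled_frontier=True)
    shared = cfg.multipliers_for("district")
    np.testing.assert_allclose(shared, cfg.multipliers_for("county"))


def test_invalid_configurations_rejected():
    good = dict(
        n_per_group={"g": 10}, n_inputs=2, n_outputs=1,
        frontier_exponents=np.array([0.4, 0.5]),
        output_multipliers=np.array([1.0]),
        covariate_effects=np.array([1.2]),
        sigma_true=0.1,
        input_scales=np.array([[10.0, 2.0], [5.0, 1.0]]),
    )
    SyntheticConfig(**good)
    with pytest.raises(SyntheticConfigError, match="sum"):
        SyntheticConfig(**{**good, "frontier_exponents": np.array([0.7, 0.7])})
    with pytest.raises(SyntheticConfigError, match="nonnegative"):
        SyntheticConfig(**{**good, "frontier_exponents": np.array([-0.1, 0.5])})
    with pytest.raises(SyntheticConfigError, match="positive"):
        SyntheticConfig(**{**good, "input_scales": np.array([[10.0, 0.0], [5.0, 1.0]])})
    with pytest.raises(SyntheticConfigError, match="sigma"):
        SyntheticConfig(**{**good, "sigma_true": -0.5})


def test_small_group_warns_about_dimensionality(caplog):
    cfg_kwargs = dict(
        n_per_group={"g": 3}, n_inputs=2, n_outputs=1,
        frontier_exponents=np.array([0.4, 0.5]),
        output_multipliers=np.array([1.0]),
        covariate_effects=np.array([1.2]),
        sigma_true=0.1,
        input_scales=np.array([[10.0, 2.0], [5.0, 1.0]]),
    )
    with caplog.at_level(logging.WARNING, logger="hospdea.synthetic"):
        SyntheticConfig(**cfg_kwargs)
    assert any("dimensionality" in r.message for r in caplog.records)


def test_panel_csv_sidecar_records_config(tmp_path):
    cfg = recovery_benchmark_config(n_units=12, seed=4)
    panel = simulate_panel(cfg)
    panel.to_csv(tmp_path / "p.csv")
    import json

    meta = json.loads((tmp_path / "p.meta.json").read_text())
    assert meta["config"]["sigma_true"] == cfg.sigma_true
    assert meta["config"]["n_per_group"] == {"all": 12}
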