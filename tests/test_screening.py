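import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hospdea import band_distribution, compare_groups, descriptive_table, screen_variables


def _funnel_table(n=60, seed=0):
    """Six candidates: two collinear inputs, a noise input, three outputs."""
    rng = np.random.default_rng(seed)
    base = rng.normal(10, 2, n)
    out1 = base * 2 + rng.normal(0, 0.5, n)
    out2 = base + rng.normal(0, 0.5, n)
    return pd.DataFrame(
        {
            "in_signal": base + rng.normal(0, 0.3, n),
            "in_twin": None,  # filled below: near-duplicate of in_signal
            "in_noise": rng.normal(5, 1, n),
            "out_a": out1,
            "out_b": out2,
            "out_c": out1 * 0.5 + rng.normal(0, 0.2, n),
        }
    ).assign(in_twin=lambda d: d["in_signal"] * 1.5 + 1e-3 * rng.normal(size=n))


def test_collinear_pair_drops_exactly_one():
    df = _funnel_table()
    rep = screen_variables(
        df, ["in_signal", "in_twin", "in_noise"], ["out_a", "out_b", "out_c"]
    )
    corr_drops = [d["variable"] for d in rep.dropped if d["rule"] == "correlation"]
    assert len(set(corr_drops) & {"in_signal", "in_twin"}) == 1


def test_noise_input_fails_regression_screen():
    df = _funnel_table()
    rep = screen_variables(
        df, ["in_signal", "in_noise"], ["out_a", "out_b"]
    )
    assert "in_noise" not in rep.final_inputs
    assert rep.input_r2["in_noise"] < 0.5
    assert "in_signal" in rep.final_inputs
    rules = {d["variable"]: d["rule"] for d in rep.dropped}
    assert rules["in_noise"] == "regression"


def test_planted_cluster_structure_is_recovered():
    rng = np.random.default_rng(4)
    n = 80
    f1 = rng.normal(size=n)
    f2 = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "a1": f1 + 0.05 * rng.normal(size=n),
            "a2": -f1 + 0.05 * rng.normal(size=n),
            "a3": 2 * f1 + 0.05 * rng.normal(size=n),
            "b1": f2 + 0.05 * rng.normal(size=n),
            "b2": f2 * 0.5 + 0.05 * rng.normal(size=n),
            "b3": -f2 + 0.05 * rng.normal(size=n),
        }
    )
    rep = screen_variables(df, ["a1", "a2", "a3"], ["b1", "b2", "b3"], r_threshold=0.5)
    labels = rep.cluster_assignments
    assert labels["a1"] == labels["a2"] == labels["a3"]
    assert labels["b1"] == labels["b2"] == labels["b3"]
    assert labels["a1"] != labels["b1"]


def test_screening_invariant_to_column_order():
    df = _funnel_table()
    rep1 = screen_variables(
        df, ["in_signal", "in_twin", "in_noise"], ["out_a", "out_b", "out_c"]
    )
    shuffled = df[list(df.columns[::-1])]
    rep2 = screen_variables(
        shuffled, ["in_noise", "in_twin", "in_signal"], ["out_c", "out_a", "out_b"]
    )
    assert set(rep1.final_inputs) == set(rep2.final_inputs)
    assert set(rep1.final_outputs) == set(rep2.final_outputs)


def test_constant_column_dropped_with_warning():
    df = _funnel_table().assign(flat=1.0)
    with pytest.warns(UserWarning, match="constant"):
        rep = screen_variables(df, ["in_signal", "flat"], ["out_a", "out_b"])
    assert "flat" not in rep.final_inputs


def test_pooled_t_matches_hand_formula():
    rng = np.random.default_rng(8)
    a = rng.normal(5.0, 1.0, 10)
    b = rng.normal(7.0, 1.0, 10)
    rec = compare_groups(a, b)
    sp = np.sqrt(((9 * a.var(ddof=1)) + (9 * b.var(ddof=1))) / 18)
    t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 10))
    assert rec["t"] == pytest.approx(t_hand, rel=1e-12)
    assert rec["p"] < 0.01


def test_pooled_t_matches_permutation_pvalue():
    rng = np.random.default_rng(15)
    a = rng.normal(0.0, 1.0, 12)
    b = rng.normal(0.8, 1.0, 12)
    rec = compare_groups(a, b)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    perm_rng = np.random.default_rng(99)
    count = 0
    n_perm = 10_000
    for _ in range(n_perm):
        perm = perm_rng.permutation(pooled)
        count += abs(perm[:12].mean() - perm[12:].mean()) >= obs
    assert rec["p"] == pytest.approx(count / n_perm, abs=0.02)


def test_t_test_edge_cases_and_antisymmetry():
    same = np.array([1.0, 1.0, 1.0])
    rec = compare_groups(same, same)
    assert rec["t"] == 0.0 and rec["p"] == 1.0
    with pytest.raises(ValueError, match="zero pooled variance"):
        compare_groups(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=8), rng.normal(1, 1, 8)
    r1, r2 = compare_groups(a, b), compare_groups(b, a)
    assert r1["t"] == pytest.approx(-r2["t"], rel=1e-12)
    assert r1["p"] == pytest.approx(r2["p"], rel=1e-12)


def test_band_distribution_hand_counts():
    df = band_distribution(np.array([0.5, 0.85, 1.0]))
    by_band = dict(zip(df["band"], df["count"]))
    assert by_band["[0, 0.7)"] == 1
    assert by_band["[0.8, 0.9)"] == 1
    assert by_band["= 1"] == 1
    assert df["percent"].sum() == pytest.approx(100.0)


def test_band_distribution_all_efficient():
    df = band_distribution(np.ones(7))
    assert df.loc[df["band"] == "= 1", "percent"].item() == pytest.approx(100.0)
    with pytest.raises(ValueError, match="scores"):
        band_distribution(np.array([0.5, 1.2]))
    with pytest.raises(ValueError, match="edges"):
        band_distribution(np.array([0.5]), band_edges=(0.0, 0.9, 0.5, 1.0))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=1e-6, max_value=1.0, allow_nan=False), min_size=1, max_size=60
    )
)
def test_band_percentages_always_sum_to_100(scores):
    df = band_distribution(np.array(scores))
    assert df["percent"].sum() == pytest.approx(100.0, abs=1e-9)
    assert int(df["count"].sum()) == len(scores)


def test_descriptive_table_shape():
    df = pd.DataFrame(
        {"group": ["a", "a", "b"], "v1": [1.0, 2.0, 3.0], "v2": [4.0, 5.0, 6.0]}
    )
    out = descriptive_table(df, "group", ["v1", "v2"])
    assert len(out) == 4
    row = out[(out["variable"] == "v1") & (out["group"] == "a")].iloc[0]
    assert row["mean"] == pytest.approx(1.5)
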