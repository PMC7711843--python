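import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockquant.junction_stats import (CC_COLUMNS, cc_by_condition, cc_matrix,
                                      simulate_junction_population,
                                      strength_label, summarize)


def brute_force_pearson(x, y):
    """Two-pass covariance oracle, independent of the library path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def random_table(rng, n):
    return pd.DataFrame({
        "class_code": rng.choice([0.0, 0.5, 1.0], n),
        "separation_nm": rng.uniform(0, 27, n),
        "protrusion_flag": rng.integers(0, 2, n).astype(float),
        "n_densities": rng.integers(2, 35, n).astype(float),
    })


def test_cc_matrix_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    for _ in range(50):
        table = random_table(rng, int(rng.integers(5, 100)))
        res = cc_matrix(table)
        for i, a in enumerate(CC_COLUMNS):
            for b in CC_COLUMNS[i + 1:]:
                assert res.r.loc[a, b] == pytest.approx(
                    brute_force_pearson(table[a], table[b]), abs=1e-12)
        assert np.allclose(res.r.values, res.r.values.T, equal_nan=True)
        assert np.allclose(np.diag(res.r.values), 1.0)


def test_perfect_linearity_and_self_correlation():
    table = pd.DataFrame({"class_code": [0.0, 0.5, 1.0],
                          "separation_nm": [0.0, 1.0, 2.0],
                          "protrusion_flag": [0.0, 1.0, 0.0],
                          "n_densities": [3.0, 4.0, 9.0]})
    res = cc_matrix(table)
    assert res.r.loc["class_code", "separation_nm"] == pytest.approx(1.0)
    assert res.p.loc["class_code", "class_code"] == 0.0


def test_zero_variance_column_reported_missing():
    table = random_table(np.random.default_rng(3), 30)
    table["protrusion_flag"] = 1.0
    res = cc_matrix(table)
    assert np.isnan(res.r.loc["protrusion_flag", "separation_nm"])
    assert res.labels.loc["protrusion_flag", "separation_nm"] == "missing"


def test_cc_matrix_needs_three_rows():
    with pytest.raises(ValueError):
        cc_matrix(random_table(np.random.default_rng(0), 2))


def test_class_separation_correlation_analytic_value():
    """Equal class probabilities with the per-class uniform separation
    ranges give r = Cov/sqrt(Var_code*Var_sep) = -2/sqrt((1/6)*41.861)."""
    table = simulate_junction_population(10_000, seed=42)
    r = cc_matrix(table, ["class_code", "separation_nm"]).r.iloc[0, 1]
    analytic = -2.0 / np.sqrt((1 / 6) * 41.861)
    assert analytic == pytest.approx(-0.7572, abs=5e-4)
    assert r == pytest.approx(analytic, abs=0.02)


@pytest.mark.parametrize("r, label", [
    (0.05, "negligible"), (-0.05, "negligible"),
    (0.1, "small"), (0.22, "small"), (-0.29, "small"),
    (0.3, "moderate"), (-0.49, "moderate"),
    (0.5, "strong"), (-0.76, "strong"), (0.9, "strong"), (1.0, "strong"),
    (float("nan"), "missing"),
])
def test_strength_labels(r, label):
    assert strength_label(r) == label


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(-1, 1))
def test_strength_label_total_and_symmetric(r):
    assert strength_label(r) in {"negligible", "small", "moderate", "strong"}
    assert strength_label(r) == strength_label(-r)


def test_summarize_fraction_below_10nm():
    table = pd.DataFrame({"class_code": [0.0, 0.5, 1.0, 0.0],
                          "separation_nm": [2.0, 5.0, 9.0, 12.0],
                          "protrusion_flag": [0, 0, 0, 1],
                          "n_densities": [3, 4, 5, 6]})
    rep = summarize(table)
    assert rep["overall"]["frac_below_10nm"] == pytest.approx(0.75)
    assert rep["overall"]["n_above_20nm"] == 0


def test_summarize_empty_condition_does_not_crash():
    table = pd.DataFrame(columns=["class_code", "separation_nm",
                                  "protrusion_flag", "n_densities",
                                  "condition_label"])
    rep = summarize(table)
    assert rep["overall"]["n_sites"] == 0
    assert rep["overall"]["frac_below_10nm"] is None


def test_summarize_class_ranges_and_histogram():
    table = simulate_junction_population(2000, seed=9)
    table["protrusion_flag"] = 0.0
    table["n_densities"] = 5.0
    rep = summarize(table)["overall"]
    rng_clustered = rep["separation_range_by_class"]["clustered"]
    assert 5.0 <= rng_clustered[0] < rng_clustered[1] <= 26.0
    hist = rep["separation_histogram"]
    total = sum(sum(v) for v in hist["counts_by_class"].values())
    assert total == 2000


def test_cc_by_condition_pools_and_splits():
    rng = np.random.default_rng(8)
    t1 = random_table(rng, 40); t1["condition_label"] = "WT"
    t2 = random_table(rng, 40); t2["condition_label"] = "mutant"
    res = cc_by_condition(pd.concat([t1, t2], ignore_index=True))
    assert set(res) == {"pooled", "WT", "mutant"}
    assert res["pooled"].n == 80
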