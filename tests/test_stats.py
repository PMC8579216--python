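"""Adjusted Spearman, outlier fences, nested F tests, and averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mobilesense.stats import (
    DesignError,
    adjusted_spearman,
    bh_qvalues,
    build_design,
    flag_extreme_outliers,
    nested_f_test,
    participant_averages,
    tukey_fences,
)


# ---------------------------------------------------------------------------
# adjusted Spearman


def test_reduces_to_plain_spearman_without_covariates():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 10, 60).astype(float)  # ties on purpose
    y = x + rng.normal(0, 3, 60)
    res = adjusted_spearman(x, y)
    r0, p0 = sps.spearmanr(x, y)
    assert res.r == pytest.approx(r0, abs=1e-12)
    assert res.p == pytest.approx(p0, rel=1e-9)


def test_constant_covariates_are_a_no_op():
    rng = np.random.default_rng(1)
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    cov = pd.DataFrame({"c1": np.ones(50), "c2": ["a"] * 50})
    res = adjusted_spearman(x, y, cov)
    r0, _ = sps.spearmanr(x, y)
    assert res.r == pytest.approx(r0, abs=1e-12)


def test_monotone_transform_invariance():
    rng = np.random.default_rng(2)
    x = rng.normal(size=80)
    y = rng.normal(size=80) + 0.5 * x
    cov = pd.DataFrame({"z": rng.normal(size=80)})
    base = adjusted_spearman(x, y, cov)
    for fx, fy in [(np.exp, np.cbrt), (lambda v: v**3, np.exp)]:
        res = adjusted_spearman(fx(x), fy(y), cov)
        assert res.r == pytest.approx(base.r, abs=1e-12)
        assert res.p == pytest.approx(base.p, rel=1e-9)


def test_perfectly_monotone_pair_gives_r_one():
    x = np.arange(20.0)
    res = adjusted_spearman(x, np.exp(x / 5))
    assert res.r == pytest.approx(1.0)
    assert res.p == 0.0


def test_adjusting_for_shared_driver_removes_correlation():
    rng = np.random.default_rng(7)
    n = 2000
    z = rng.normal(size=n)
    x = z + rng.normal(size=n)
    y = z + rng.normal(size=n)
    naive = adjusted_spearman(x, y)
    adj = adjusted_spearman(x, y, pd.DataFrame({"z": z}))
    assert naive.r > 0.3
    assert abs(adj.r) < 0.05


def test_matches_independent_rank_residualization_oracle():
    """statsmodels OLS on ranks as the independent recomputation route."""
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    n = 120
    x = rng.normal(size=n)
    y = rng.normal(size=n) + 0.3 * x
    cov = pd.DataFrame({
        "age": rng.uniform(10, 21, n),
        "sex": rng.choice(["f", "m"], n),
        "edu": rng.choice(["hs", "uni", "missing"], n),
    })
    res = adjusted_spearman(x, y, cov)
    cov_ranked = cov.copy()
    cov_ranked["age"] = sps.rankdata(cov["age"])  # numeric covariates ranked too
    X = pd.get_dummies(cov_ranked, drop_first=True, dtype=float)
    X = sm.add_constant(X)
    ex = sm.OLS(sps.rankdata(x), X).fit().resid
    ey = sm.OLS(sps.rankdata(y), X).fit().resid
    r_oracle = np.corrcoef(ex, ey)[0, 1]
    k = X.shape[1] - 1
    df = n - 2 - k
    t = r_oracle * np.sqrt(df / (1 - r_oracle**2))
    p_oracle = 2 * sps.t.sf(abs(t), df)
    assert res.r == pytest.approx(r_oracle, abs=1e-10)
    assert res.p == pytest.approx(p_oracle, abs=1e-10)
    assert res.df == df


def test_matches_pingouin_partial_spearman():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    n = 90
    df = pd.DataFrame({
        "x": rng.normal(size=n),
        "y": rng.normal(size=n),
        "c1": rng.normal(size=n),
        "c2": rng.normal(size=n),
    })
    df["y"] += 0.4 * df["x"] + 0.5 * df["c1"]
    res = adjusted_spearman(df["x"], df["y"], df[["c1", "c2"]])
    pg = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method="spearman")
    assert res.r == pytest.approx(float(pg["r"].iloc[0]), abs=1e-10)
    assert res.p == pytest.approx(float(pg["p_val"].iloc[0]), abs=1e-8)


def test_zero_variance_and_singular_designs_error():
    x = np.ones(30)
    y = np.arange(30.0)
    with pytest.raises(DesignError, match="zero variance"):
        adjusted_spearman(x, y)
    rng = np.random.default_rng(6)
    x = rng.normal(size=30)
    cov = pd.DataFrame({"a": y, "b": 2 * y})
    with pytest.raises(DesignError, match="collinear"):
        adjusted_spearman(x, rng.normal(size=30), cov)


def test_missing_values_dropped_pairwise():
    rng = np.random.default_rng(8)
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    x[:5] = np.nan
    res = adjusted_spearman(x, y)
    assert res.n == 45


# ---------------------------------------------------------------------------
# outlier fences


def test_identical_values_are_never_outliers():
    df = pd.DataFrame({"f": np.ones(10)}, index=[f"p{i}" for i in range(10)])
    assert flag_extreme_outliers(df) == set()


def test_far_value_is_flagged():
    vals = np.array([1, 2, 3, 4, 5, 1000.0])
    df = pd.DataFrame({"f": vals}, index=[f"p{i}" for i in range(6)])
    assert flag_extreme_outliers(df) == {"p5"}
    lo, hi = tukey_fences(vals)
    assert 1000.0 > hi


def test_fences_affine_equivariant():
    rng = np.random.default_rng(3)
    vals = np.append(rng.normal(0, 1, 40), 25.0)
    idx = [f"p{i}" for i in range(41)]
    base = flag_extreme_outliers(pd.DataFrame({"f": vals}, index=idx))
    for a, b in [(3.5, -2.0), (-1.25, 7.0)]:
        scaled = flag_extreme_outliers(pd.DataFrame({"f": a * vals + b}, index=idx))
        assert scaled == base


def test_fences_require_four_values():
    df = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("abc"))
    with pytest.raises(ValueError):
        flag_extreme_outliers(df)


# ---------------------------------------------------------------------------
# participant averaging


def test_identical_days_average_to_day_value():
    daily = pd.DataFrame({"participant_id": ["a"] * 14, "f": [3.5] * 14})
    out = participant_averages(daily, ["f"])
    assert out.loc["a", "f"] == 3.5
    assert out.loc["a", "f__days"] == 14


def test_two_day_average():
    daily = pd.DataFrame({"participant_id": ["a", "a"], "f": [2.0, 4.0]})
    assert participant_averages(daily, ["f"]).loc["a", "f"] == 3.0


def test_averages_match_brute_force_recompute(small_cohort):
    from mobilesense.pipeline import ALL_FEATURES, features_from_cohort

    daily, _ = features_from_cohort(small_cohort)
    means = participant_averages(daily, ALL_FEATURES)
    for pid in list(means.index)[:10]:
        sub = daily[daily["participant_id"] == pid]
        for feat in ALL_FEATURES:
            vals = [v for v in sub[feat] if not np.isnan(v)]
            expected = sum(vals) / len(vals) if vals else np.nan
            got = means.loc[pid, feat]
            assert got == pytest.approx(expected, rel=1e-12) or (
                np.isnan(got) and np.isnan(expected))


def test_all_days_missing_leaves_cell_missing():
    daily = pd.DataFrame({"participant_id": ["a", "a"], "f": [np.nan, np.nan]})
    out = participant_averages(daily, ["f"])
    assert np.isnan(out.loc["a", "f"]) and out.loc["a", "f__days"] == 0


# ---------------------------------------------------------------------------
# nested F test


def _normal_equations_rss(y, X):
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    return float(resid @ resid)


def test_nested_f_matches_normal_equations_oracle():
    rng = np.random.default_rng(10)
    n = 60
    base = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    added = pd.DataFrame({"c": rng.normal(size=n), "d": rng.normal(size=n),
                          "e": rng.normal(size=n)})
    y = 1 + base["a"] - base["b"] + 0.5 * added["c"] + rng.normal(size=n)
    res = nested_f_test(y.to_numpy(), base, added)
    X0 = np.column_stack([np.ones(n), base.to_numpy()])
    X1 = np.column_stack([X0, added.to_numpy()])
    rss0 = _normal_equations_rss(y.to_numpy(), X0)
    rss1 = _normal_equations_rss(y.to_numpy(), X1)
    df1, df2 = 3, n - X1.shape[1]
    f_oracle = ((rss0 - rss1) / df1) / (rss1 / df2)
    p_oracle = sps.f.sf(f_oracle, df1, df2)
    assert res.F == pytest.approx(f_oracle, rel=1e-8)
    assert res.p == pytest.approx(p_oracle, rel=1e-8)
    assert (res.df1, res.df2) == (df1, df2)


def test_duplicated_predictors_raise_rank_error():
    rng = np.random.default_rng(11)
    n = 40
    base = pd.DataFrame({"a": rng.normal(size=n)})
    with pytest.raises(DesignError):
        nested_f_test(rng.normal(size=n), base, base.rename(columns={"a": "a2"}))


def test_noise_free_linear_signal_gives_vanishing_p():
    rng = np.random.default_rng(12)
    n = 50
    base = pd.DataFrame({"a": rng.normal(size=n)})
    added = pd.DataFrame({"c": rng.normal(size=n)})
    y = 2.0 * added["c"].to_numpy() + base["a"].to_numpy()
    res = nested_f_test(y, base, added)
    assert res.p < 1e-12


def test_listwise_complete_cases_only():
    rng = np.random.default_rng(13)
    n = 40
    base = pd.DataFrame({"a": rng.normal(size=n)})
    added = pd.DataFrame({"c": rng.normal(size=n)})
    added.iloc[:4, 0] = np.nan
    res = nested_f_test(rng.normal(size=n), base, added)
    assert res.n == 36


# ---------------------------------------------------------------------------
# multiple testing


def test_bh_qvalues_match_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(14)
    p = rng.uniform(size=25)
    q = bh_qvalues(p)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert q == pytest.approx(q_sm, abs=1e-12)


def test_design_expands_categoricals():
    cov = pd.DataFrame({"age": [10.0, 12.0, 14.0],
                        "edu": ["hs", "uni", "missing"]})
    X, names = build_design(cov)
    assert X.shape == (3, 4)  # intercept + age + 2 dummies
    assert names[0] == "intercept"
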