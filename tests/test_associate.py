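"""Group comparisons, correlation machinery and BH FDR control."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from msinflam.associate import (AssociationError, compare_groups, correlate,
                                fdr_adjust, results_frame)

from conftest import bh_oracle


# ------------------------------------------------------------------- FDR
def test_single_pvalue_unchanged():
    assert fdr_adjust([0.03])[0] == pytest.approx(0.03)


def test_bh_textbook_example():
    # min over j>=i of p(j)*m/j: (0.01,0.02,0.03,0.04)*4/(1..4) -> all 0.04
    np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_bh_equal_pvalues_are_fixed_points():
    for m in (1, 3, 10):
        np.testing.assert_allclose(fdr_adjust([0.2] * m), [0.2] * m, atol=1e-12)


def test_bh_matches_stepup_oracle_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        m = int(rng.integers(1, 21))
        p = rng.random(m)
        got = fdr_adjust(p)
        want = bh_oracle(list(p))
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert (got >= p - 1e-15).all()


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=15))
def test_bh_monotone_and_bounded(p):
    adj = fdr_adjust(p)
    assert ((adj >= np.asarray(p) - 1e-15) & (adj <= 1 + 1e-15)).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_invalid_pvalues_rejected():
    with pytest.raises(AssociationError):
        fdr_adjust([0.2, 1.4])
    with pytest.raises(AssociationError):
        fdr_adjust([-0.1])


# ------------------------------------------------------------ correlation
def test_perfect_dependence():
    x = pd.DataFrame({"a": np.arange(10.0)})
    for method in ("pearson", "spearman"):
        r = correlate(x, x.rename(columns={"a": "b"}), method, "fam")[0]
        assert r.estimate == pytest.approx(1.0)


def test_spearman_invariant_under_monotone_transform(rng):
    x = pd.DataFrame({"a": rng.normal(size=40)})
    y = pd.DataFrame({"b": rng.normal(size=40)})
    r1 = correlate(x, y, "spearman", "f")[0]
    r2 = correlate(x, np.exp(y), "spearman", "f")[0]
    assert r1.estimate == pytest.approx(r2.estimate, abs=1e-12)
    assert r1.p == pytest.approx(r2.p, abs=1e-12)


def test_pairwise_complete_rows_hand_enumerated():
    x = pd.DataFrame({"a": [1, 2, np.nan, 4, 5]})
    y = pd.DataFrame({"b": [2, 4, 6, np.nan, 10]})
    r = correlate(x, y, "pearson", "f")[0]
    assert r.n == 3                      # rows 1, 2, 5
    want, _ = stats.pearsonr([1, 2, 5], [2, 4, 10])
    assert r.estimate == pytest.approx(want)


def test_undefined_pairs_flagged_and_excluded_from_fdr():
    x = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan, 5.0],
                      "c": [1.0, 2.0, 3.0, 4.0, 5.0]})
    y = pd.DataFrame({"b": [np.nan, np.nan, 3.0, 4.0, 1.0]})
    res = correlate(x, y, "pearson", "f")
    by = {(r.var1, r.var2): r for r in res}
    assert by[("a", "b")].undefined and by[("a", "b")].p_adj is None
    assert not by[("c", "b")].undefined and by[("c", "b")].p_adj is not None


def test_small_sample_spearman_exact_p_matches_enumeration():
    # N=5 without ties: compare against scipy's exact kendall-style table via
    # brute-force enumeration embedded here
    import itertools
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 5.0, 3.0])
    res = correlate(pd.DataFrame({"a": x}), pd.DataFrame({"b": y}),
                    "spearman", "f")[0]
    rx = stats.rankdata(x)
    obs = abs(np.corrcoef(rx, stats.rankdata(y))[0, 1])
    hits = total = 0
    for perm in itertools.permutations(stats.rankdata(y)):
        total += 1
        hits += abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
    assert res.p == pytest.approx(hits / total, abs=1e-12)


def test_spearman_exact_handles_ties():
    x = pd.DataFrame({"a": [1.0, 1.0, 2.0, 3.0, 4.0, 4.0]})
    y = pd.DataFrame({"b": [2.0, 3.0, 3.0, 5.0, 6.0, 8.0]})
    r = correlate(x, y, "spearman", "f")[0]
    want, _ = stats.spearmanr(x["a"], y["b"])   # average-rank estimate
    assert r.estimate == pytest.approx(want)
    assert 0.0 <= r.p <= 1.0


def test_pearson_and_spearman_agree_on_bivariate_normal(rng):
    n = 400
    z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
    x = pd.DataFrame({"a": z[:, 0]})
    y = pd.DataFrame({"b": z[:, 1]})
    rp = correlate(x, y, "pearson", "f")[0].estimate
    rs = correlate(x, y, "spearman", "f")[0].estimate
    assert abs(rp - rs) < 0.05


# ---------------------------------------------------------- group tests
def test_identical_groups_give_zero_difference_p_one():
    vals = pd.DataFrame({"m": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
    g = pd.Series(["HD"] * 3 + ["MS"] * 3, index=vals.index)
    for design in ("anova", "ttest"):
        r = compare_groups(vals, g, design, "f")[0]
        assert r.estimate == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0, abs=1e-9)


def test_ttest_matches_textbook_pooled_computation():
    # (1,2,3) vs (4,5,6): diff 3, pooled var 1, se = sqrt(2/3), df 4
    vals = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
    g = pd.Series(["A"] * 3 + ["B"] * 3, index=vals.index)
    r = compare_groups(vals, g, "ttest", "f")[0]
    t = 3.0 / np.sqrt(2.0 / 3.0)
    p = 2 * stats.t.sf(t, df=4)
    assert r.estimate == pytest.approx(3.0)
    assert r.p == pytest.approx(p, rel=1e-12)


def test_anova_f_equals_linear_model_diagnosis_test(rng):
    import statsmodels.formula.api as smf
    df = pd.DataFrame({"m": rng.normal(size=90),
                       "g": np.repeat(["HD", "RRMS", "PMS"], 30)})
    r = compare_groups(df[["m"]], df["g"], "anova", "f")[0]
    fit = smf.ols("m ~ C(g)", df).fit()
    import statsmodels.api as sm
    tab = sm.stats.anova_lm(fit, typ=2)
    assert r.p == pytest.approx(tab.loc["C(g)", "PR(>F)"], rel=1e-10)


def test_two_sample_power_matches_noncentral_t():
    # delta = 0.5 SD at n = (51, 291): closed-form power of the pooled t-test
    n1, n2, delta, alpha = 51, 291, 0.5, 0.05
    df = n1 + n2 - 2
    nc = delta / np.sqrt(1 / n1 + 1 / n2)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    hits = 0
    reps = 500
    rng = np.random.default_rng(4)
    idx = pd.RangeIndex(n1 + n2)
    g = pd.Series(["HD"] * n1 + ["MS"] * n2, index=idx)
    for _ in range(reps):
        v = rng.normal(0, 1, n1 + n2)
        v[n1:] += delta
        r = compare_groups(pd.DataFrame({"m": v}, index=idx), g, "ttest", "f")[0]
        hits += r.p < alpha
    assert hits / reps == pytest.approx(power, abs=0.05)


def test_group_with_too_few_values_is_reported():
    vals = pd.DataFrame({"m": [1.0, 2.0, 3.0, np.nan, np.nan, 4.0]})
    g = pd.Series(["A"] * 3 + ["B"] * 3, index=vals.index)
    with pytest.raises(AssociationError, match="B"):
        compare_groups(vals, g, "ttest", "f")


def test_results_frame_shape():
    vals = pd.DataFrame({"m": [1.0, 2, 3, 4, 5, 6], "k": [2.0, 1, 3, 6, 5, 4]})
    g = pd.Series(["A"] * 3 + ["B"] * 3, index=vals.index)
    df = results_frame(compare_groups(vals, g, "ttest", "fam"))
    assert list(df.columns) == ["family", "var1", "var2", "method", "estimate",
                                "n", "p", "p_adj", "undefined"]
    assert len(df) == 2
    assert (df["p_adj"] >= df["p"] - 1e-15).all()
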