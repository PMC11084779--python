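"""Tests of the statistical cascade: grouping, normality gating, t-tests,
chi-squared, Pearson bands, BH step-up and ICC(A,1)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cephscreen.errors import (
    DegenerateSampleError,
    DegenerateTableError,
    MissingCellError,
    SchemaError,
)
from cephscreen.stats import (
    assign_groups,
    bh_adjust,
    chi_squared_2x2,
    correlation_category,
    describe,
    icc_a1,
    icc_category,
    ks_normality,
    pearson,
    students_t,
)


# --------------------------------------------------------------------------
# grouping
# --------------------------------------------------------------------------

def test_group_assignment_strict_thresholds():
    df = pd.DataFrame({"A_min": [55.9, 80.0, 120.0],
                       "V_PAS": [9.75, 12.0, 20.0]})
    g = assign_groups(df)
    assert list(g.sasn) == [True, False, False]   # 80.0 is NOT narrowed
    assert list(g.rsav) == [True, False, False]   # 12.0 is NOT reduced
    assert g.counts == {"A1": 1, "A2": 2, "B1": 1, "B2": 2}


def test_group_assignment_schema_errors():
    with pytest.raises(SchemaError):
        assign_groups(pd.DataFrame({"A_min": [1.0]}))
    with pytest.raises(SchemaError):
        assign_groups(pd.DataFrame({"A_min": [np.nan], "V_PAS": [1.0]}))


# --------------------------------------------------------------------------
# normality gate and descriptives
# --------------------------------------------------------------------------

def test_ks_normality_calibration():
    """Normal samples rarely rejected; exponential samples almost always."""
    keep, reject = 0, 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        if ks_normality(rng.normal(size=1000)) >= 0.05:
            keep += 1
        if ks_normality(rng.exponential(size=1000)) < 0.05:
            reject += 1
    assert keep >= 36     # >= 90% of normal samples pass
    assert reject == 40   # exponential always rejected at n = 1000


def test_ks_normality_preconditions():
    with pytest.raises(DegenerateSampleError):
        ks_normality([1.0, 2.0, 3.0])
    with pytest.raises(DegenerateSampleError):
        ks_normality([2.0] * 50)


def test_describe_paths():
    d = describe([1.0, 2.0, 3.0], force_normal=True)
    assert (d.center, d.spread, d.kind) == (2.0, 1.0, "mean±SD")
    rng = np.random.default_rng(0)
    skewed = describe(rng.lognormal(0, 1.2, size=800))
    assert skewed.kind == "median±IQR"
    single = describe([7.5])
    assert single.center == 7.5 and single.spread is None
    with pytest.raises(DegenerateSampleError):
        describe([])


# --------------------------------------------------------------------------
# t-test
# --------------------------------------------------------------------------

def test_t_test_trivial_cases():
    x = [1.0, 2.0, 3.0, 4.0]
    res = students_t(x, x)
    assert res.statistic == pytest.approx(0.0)
    assert res.p_raw == pytest.approx(1.0)
    assert res.df == 6
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 500)
    res2 = students_t(a, a + 1.0)
    assert res2.p_raw < 1e-10
    with pytest.raises(DegenerateSampleError):
        students_t([1.0, 1.0], [1.0, 1.0])


def test_t_test_matches_exact_permutation_oracle():
    """Exact permutation over all 12870 splits of 8+8 observations."""
    rng = np.random.default_rng(7)
    x1 = rng.normal(0.0, 1.0, 8)
    x2 = rng.normal(0.8, 1.0, 8)
    res = students_t(x1, x2)
    pooled = np.concatenate([x1, x2])
    obs = abs(res.statistic)

    def tstat(a, b):
        n1, n2 = len(a), len(b)
        sp = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / (n1 + n2 - 2)
        return (np.mean(a) - np.mean(b)) / np.sqrt(sp * (1 / n1 + 1 / n2))

    count = 0
    idx = set(range(16))
    for comb in itertools.combinations(range(16), 8):
        rest = list(idx - set(comb))
        if abs(tstat(pooled[list(comb)], pooled[rest])) >= obs - 1e-12:
            count += 1
    p_perm = count / 12870
    assert abs(res.p_raw - p_perm) < 0.02


# --------------------------------------------------------------------------
# chi-squared
# --------------------------------------------------------------------------

def test_chi_squared_cases():
    chi2, p = chi_squared_2x2([[10, 10], [10, 10]])
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    chi2, p = chi_squared_2x2([[20, 0], [0, 20]])
    assert chi2 == pytest.approx(40.0)
    assert p < 1e-9
    # closed form n(ad-bc)^2 / (row and column products) on the reference
    # gender counts 13/17 vs 34/36
    chi2, p = chi_squared_2x2([[13, 17], [34, 36]])
    assert chi2 == pytest.approx(100 * (13 * 36 - 17 * 34) ** 2
                                 / (30 * 70 * 47 * 53), rel=1e-12)
    assert p == pytest.approx(0.631, abs=0.001)
    with pytest.raises(DegenerateTableError):
        chi_squared_2x2([[0, 0], [5, 5]])


# --------------------------------------------------------------------------
# Pearson correlation
# --------------------------------------------------------------------------

def test_pearson_cases_and_bands():
    x = np.arange(10.0)
    res = pearson(x, x)
    assert res.r == pytest.approx(1.0)
    assert res.category == "strong"
    assert correlation_category(0.706) == "strong"
    assert correlation_category(0.25) == "medium"
    assert correlation_category(0.20) == "medium"   # band is inclusive at 0.20
    assert correlation_category(0.30) == "medium"   # ... and at 0.30
    assert correlation_category(0.199) == "weak"
    assert correlation_category(-0.31) == "strong"
    with pytest.raises(DegenerateSampleError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pearson_pairwise_deletion():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [2.0, 4.1, 6.0, 8.2, np.nan]
    res = pearson(x, y)
    assert res.n == 3


def test_pearson_p_matches_permutation_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    y = 0.6 * x + rng.normal(size=12)
    res = pearson(x, y)
    count = 0
    n_perm = 4000
    prng = np.random.default_rng(99)
    for _ in range(n_perm):
        r = np.corrcoef(x, prng.permutation(y))[0, 1]
        count += abs(r) >= abs(res.r) - 1e-12
    assert abs(res.p_raw - count / n_perm) < 0.03


# --------------------------------------------------------------------------
# Benjamini-Hochberg
# --------------------------------------------------------------------------

def _bh_oracle(p):
    """min over j >= i of m * p(j) / j, capped at 1 (step-up)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_idx, i in enumerate(order, start=1):
        js = order[rank_idx - 1:]
        ranks = np.arange(rank_idx, m + 1)
        adj[i] = min(1.0, np.min(m * p[js] / ranks))
    return adj


def test_bh_hand_computed_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
    assert np.allclose(bh_adjust([0.37]), [0.37])


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10))
def test_bh_matches_step_up_oracle(p):
    adj = bh_adjust(p)
    assert np.allclose(adj, _bh_oracle(p), atol=1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0)
    # monotone: ordering of adjusted values follows ordering of raw values
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_rejects_invalid_input():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

def test_icc_identical_raters_is_one():
    y = np.tile(np.arange(10.0)[:, None], (1, 3))
    res = icc_a1(y)
    assert res.icc == pytest.approx(1.0)
    assert res.category == "very good"
    assert res.ci_low <= res.icc <= res.ci_high


def test_absolute_agreement_penalises_rater_bias():
    rng = np.random.default_rng(2)
    base = rng.normal(50, 10, 20)
    y = np.column_stack([base, base + 15.0])  # strong constant bias
    res = icc_a1(y)
    # consistency ICC ignores the bias entirely
    n, k = y.shape
    grand = y.mean()
    msr = k * np.sum((y.mean(1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((y.mean(0) - grand) ** 2) / (k - 1)
    mse = (np.sum((y - y.mean(1, keepdims=True)
                   - y.mean(0, keepdims=True) + grand) ** 2)
           / ((n - 1) * (k - 1)))
    icc_consistency = (msr - mse) / (msr + (k - 1) * mse)
    assert icc_consistency == pytest.approx(1.0, abs=1e-9)
    assert res.icc < icc_consistency - 0.3


def test_icc_formula_and_one_way_reduction():
    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, (12, 2)) + rng.normal(0, 3, 12)[:, None]
    n, k = y.shape
    grand = y.mean()
    msr = k * np.sum((y.mean(1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((y.mean(0) - grand) ** 2) / (k - 1)
    mse = (np.sum((y - y.mean(1, keepdims=True)
                   - y.mean(0, keepdims=True) + grand) ** 2)
           / ((n - 1) * (k - 1)))
    expected = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    assert icc_a1(y).icc == pytest.approx(expected, rel=1e-12)
    # no rater effect: ICC(A,1) approaches the one-way formula as the
    # rater mean square shrinks to the residual mean square
    one_way = (msr - mse) / (msr + (k - 1) * mse)
    assert abs(icc_a1(y).icc - one_way) <= (k / n) * abs(msc - mse) / (
        msr + (k - 1) * mse)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    for seed in range(3):
        r = np.random.default_rng(seed)
        y = r.normal(0, 3, 15)[:, None] + r.normal(0, 1, (15, 3))
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(15), 3),
            "rater": np.tile(np.arange(3), 15),
            "y": y.ravel(),
        })
        ours = icc_a1(y)
        theirs = pg.intraclass_corr(long, targets="subj", raters="rater",
                                    ratings="y")
        row = theirs[theirs["Type"] == "ICC(A,1)"].iloc[0]
        assert ours.icc == pytest.approx(float(row["ICC"]), abs=1e-6)
        lo, hi = row["CI95"]
        assert ours.ci_low == pytest.approx(float(lo), abs=0.011)
        assert ours.ci_high == pytest.approx(float(hi), abs=0.011)


def test_icc_categories():
    assert icc_category(0.49) == "poor"
    assert icc_category(0.50) == "moderate"
    assert icc_category(0.75) == "good"
    assert icc_category(0.90) == "very good"


def test_icc_incomplete_table_errors():
    y = np.ones((5, 2))
    y[2, 1] = np.nan
    with pytest.raises(MissingCellError):
        icc_a1(y)
    with pytest.raises(DegenerateSampleError):
        icc_a1(np.ones((1, 2)))
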