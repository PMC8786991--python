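"""Agreement, TRT, bias and ICC statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import petparam as pp


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def test_agreement_identity_line():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = pp.agreement(x, x)
    assert res.r_squared == pytest.approx(1.0)
    assert res.slope == pytest.approx(1.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)


def test_agreement_constructed_linear_data():
    x = np.array([0.0, 1.0, 2.0, 5.0, 9.0])
    res = pp.agreement(x, 0.8 * x + 1.0)
    assert res.slope == pytest.approx(0.8)
    assert res.intercept == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)


def test_agreement_matches_closed_form_ols():
    """Noisy pairs against the textbook closed-form OLS to 1e-10."""
    rng = np.random.default_rng(17)
    x = rng.uniform(1, 20, 40)
    y = 0.9 * x + 0.5 + rng.normal(0, 1.0, 40)
    res = pp.agreement(x, y)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    assert res.slope == pytest.approx(sxy / sxx, abs=1e-10)
    assert res.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), abs=1e-10)
    assert res.r_squared == pytest.approx(sxy**2 / (sxx * syy), abs=1e-10)


def test_agreement_through_origin_option():
    x = np.array([1.0, 2.0, 3.0])
    y = 2.0 * x
    res = pp.agreement(x, y, through_origin=True)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == 0.0


def test_agreement_contracts():
    with pytest.raises(ValueError):
        pp.agreement([1.0, 2.0], [1.0, 2.0])  # n < 3
    with pytest.raises(ValueError, match="zero variance"):
        pp.agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_agreement_slope_invariant_to_y_relabelling():
    rng = np.random.default_rng(3)
    x = rng.uniform(1, 10, 20)
    y1 = x + rng.normal(0, 0.5, 20)
    y2 = x + rng.normal(0, 0.5, 20)
    pooled_a = pp.agreement(np.concatenate([x, x]), np.concatenate([y1, y2]))
    pooled_b = pp.agreement(np.concatenate([x, x]), np.concatenate([y2, y1]))
    assert pooled_a.slope == pytest.approx(pooled_b.slope, abs=1e-12)


# ---------------------------------------------------------------------------
# TRT / bias
# ---------------------------------------------------------------------------

def test_trt_zero_for_identical_sessions():
    res = pp.trt([5.0, 7.0], [5.0, 7.0])
    assert res.mean == 0.0 and res.abs_mean == 0.0


def test_trt_direct_arithmetic():
    res = pp.trt([10.0], [8.0])
    assert res.trt[0] == pytest.approx(-2.0 / 18.0 * 200.0)
    assert res.abs_trt[0] == pytest.approx(2.0 / 18.0 * 200.0)


@given(st.lists(st.tuples(st.floats(0.1, 100), st.floats(0.1, 100)),
                min_size=2, max_size=20))
def test_trt_antisymmetry_and_bounds(pairs):
    t = np.array([p[0] for p in pairs])
    r = np.array([p[1] for p in pairs])
    fwd = pp.trt(t, r)
    rev = pp.trt(r, t)
    np.testing.assert_allclose(fwd.trt, -rev.trt, atol=1e-9)
    np.testing.assert_allclose(fwd.abs_trt, rev.abs_trt, atol=1e-9)
    assert np.all(np.abs(fwd.trt) < 200.0)
    np.testing.assert_allclose(fwd.abs_trt, np.abs(fwd.trt), atol=1e-12)


def test_trt_excludes_nonpositive_pairs_with_warning():
    with pytest.warns(UserWarning, match="excluded 1"):
        res = pp.trt([1.0, -2.0], [1.0, 1.0])
    assert res.n_excluded == 1
    assert res.trt.size == 1


@pytest.mark.parametrize("p, c, expected", [(0.9, 1.0, -10.0), (1.0, 1.0, 0.0),
                                            (1.2, 1.0, 20.0)])
def test_bias_percent(p, c, expected):
    assert pp.bias(p, c) == pytest.approx(expected)


def test_bias_zero_denominator_rejected():
    with pytest.raises(ValueError):
        pp.bias(1.0, 0.0)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def _icc_anova_oracle(X):
    """Explicit two-way ANOVA sums of squares, written independently."""
    n, k = X.shape
    grand = X.mean()
    ss_sub = sum(k * (X[i].mean() - grand) ** 2 for i in range(n))
    ss_ses = sum(n * (X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((X[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    mse = (ss_tot - ss_sub - ss_ses) / ((n - 1) * (k - 1))
    msr = ss_sub / (n - 1)
    msc = ss_ses / (k - 1)
    return (msr - mse) / (msr + (msc - mse) / n)


def test_icc_matches_anova_oracle_to_1e10():
    rng = np.random.default_rng(42)
    X = rng.normal(10, 3, (8, 2))
    res = pp.icc_2way(X)
    assert res.icc == pytest.approx(_icc_anova_oracle(X), abs=1e-10)


def test_icc_matches_pingouin_average_absolute_agreement():
    """Independent cross-check against pingouin's ICC2k (two-way,
    absolute-agreement, average measures) including the 95% CI."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    X = rng.normal(10, 2, (8, 2))
    res = pp.icc_2way(X)
    df = pd.DataFrame({
        "subj": np.repeat(np.arange(8), 2),
        "sess": np.tile([0, 1], 8),
        "y": X.ravel(),
    })
    table = pg.intraclass_corr(df, targets="subj", raters="sess", ratings="y")
    row = table[table["Type"] == "ICC(A,k)"]
    if row.empty:
        row = table[table["Type"] == "ICC2k"]
    row = row.iloc[0]
    assert res.icc == pytest.approx(float(row["ICC"]), abs=1e-9)
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    lo, hi = row[ci_col]
    assert res.ci_lower == pytest.approx(float(lo), abs=0.01)
    assert res.ci_upper == pytest.approx(float(hi), abs=0.01)


def test_icc_one_for_perfect_retest():
    X = np.column_stack([np.array([1.0, 5.0, 9.0, 13.0])] * 2)
    res = pp.icc_2way(X)
    assert res.icc == pytest.approx(1.0)


def test_icc_degenerate_session_shift_not_clipped():
    # identical subjects, sessions differ: no subject variance, ICC <= 0
    X = np.column_stack([np.full(5, 1.0), np.full(5, 2.0)])
    res = pp.icc_2way(X)
    assert res.icc <= 0.0


@given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
def test_icc_invariant_to_affine_rescaling(shift, scale):
    rng = np.random.default_rng(11)
    X = rng.normal(10, 2, (6, 2))
    a = pp.icc_2way(X).icc
    b = pp.icc_2way(scale * X + shift).icc
    assert b == pytest.approx(a, abs=1e-8)


def test_icc_contracts():
    with pytest.raises(ValueError):
        pp.icc_2way(np.ones((2, 2)))  # too few subjects
    bad = np.ones((4, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        pp.icc_2way(bad)


# ---------------------------------------------------------------------------
# voxel-wise TRT maps
# ---------------------------------------------------------------------------

def test_trt_map_zero_for_identical_sessions():
    maps = [np.full((4, 4, 2), 3.0), np.full((4, 4, 2), 5.0)]
    mean_map, sd_map = pp.trt_map(maps, [m.copy() for m in maps])
    np.testing.assert_array_equal(mean_map, 0.0)
    np.testing.assert_array_equal(sd_map, 0.0)


def test_trt_map_single_subject_sd_undefined():
    t = [np.full((2, 2, 2), 4.0)]
    r = [np.full((2, 2, 2), 5.0)]
    with pytest.warns(UserWarning, match="single subject"):
        mean_map, sd_map = pp.trt_map(t, r)
    assert np.all(np.isnan(sd_map))
    np.testing.assert_allclose(mean_map, 1.0 / 9.0 * 200.0)


def test_trt_map_null_cohort_matches_folded_normal_expectation():
    """Gaussian session noise, null effect: the in-mask average of the mean
    absolute-TRT map approaches the folded-normal expectation
    E|R-T|/(R+T)*200 ~ sigma*sqrt(2/pi)/mu*sqrt(2)*100."""
    rng = np.random.default_rng(8)
    mu, sigma = 10.0, 0.5
    shape = (12, 12, 6)
    tests = [mu + sigma * rng.standard_normal(shape) for _ in range(20)]
    retests = [mu + sigma * rng.standard_normal(shape) for _ in range(20)]
    mean_map, _ = pp.trt_map(tests, retests)
    # |R-T| ~ folded normal with sd sigma*sqrt(2); R+T ~ 2 mu
    expected = sigma * np.sqrt(2.0) * np.sqrt(2.0 / np.pi) / (2.0 * mu) * 200.0
    assert np.nanmean(mean_map) == pytest.approx(expected, rel=0.05)
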