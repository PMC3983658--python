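import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import repliphase as rp
from repliphase.io import AsyncExpression, ExpressionTimecourse


# ---------------------------------------------------------------------------
# pearson_r / variance_explained
# ---------------------------------------------------------------------------

def test_pearson_hand_example():
    r, n = rp.pearson_r([1, 2, 3], [1, 2, 4])
    assert n == 3
    assert r == pytest.approx(0.9820, abs=5e-5)
    assert rp.variance_explained([1, 2, 3], [1, 2, 4]) == pytest.approx(
        0.9643, abs=5e-5)


def test_pearson_perfect_anticorrelation():
    x = np.arange(10.0)
    r, _ = rp.pearson_r(x, -x + 7)
    assert r == pytest.approx(-1.0)
    assert rp.variance_explained(x, -x + 7) == pytest.approx(1.0)


def test_pearson_constant_vector_flagged_undefined():
    r, n = rp.pearson_r([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
    assert np.isnan(r) and n == 4


def test_pearson_pairwise_complete():
    x = [1.0, np.nan, 2.0, 3.0, np.nan]
    y = [1.0, 5.0, 2.0, 4.0, np.nan]
    r, n = rp.pearson_r(x, y)
    ref = stats.pearsonr([1, 2, 3], [1, 2, 4])[0]
    assert n == 3 and r == pytest.approx(ref)


def test_pearson_matches_scipy_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(3, 50)
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, _ = rp.pearson_r(x, y)
        assert r == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.floats(0.1, 10), st.floats(-5, 5), st.integers(0, 1000))
def test_pearson_affine_invariance(a, b, seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=20), rng.normal(size=20)
    r0, _ = rp.pearson_r(x, y)
    r_pos, _ = rp.pearson_r(a * x + b, y)
    r_neg, _ = rp.pearson_r(-a * x + b, y)
    assert r_pos == pytest.approx(r0, abs=1e-9)
    assert r_neg == pytest.approx(-r0, abs=1e-9)


# ---------------------------------------------------------------------------
# critical_r
# ---------------------------------------------------------------------------

def test_critical_r_reproduces_published_thresholds():
    # the budding-yeast legend threshold: |r| > 0.107 at P < 0.0025
    assert rp.critical_r(800, 0.0025) == pytest.approx(0.107, abs=1e-3)
    # the fission-yeast legend threshold: |r| > 0.177
    assert rp.critical_r(292, 0.0025) == pytest.approx(0.177, abs=1e-3)


def test_critical_r_limits_and_errors():
    assert rp.critical_r(100, 0.999999) < 1e-4  # alpha -> 1 => threshold -> 0
    with pytest.raises(ValueError):
        rp.critical_r(3, 0.05)
    with pytest.raises(ValueError):
        rp.critical_r(100, 0.0)


def test_critical_r_quick_monte_carlo():
    # light version of the full calibration in the acceptance suite
    rng = np.random.default_rng(42)
    n, alpha, trials = 50, 0.05, 20_000
    x = rng.normal(size=(trials, n))
    y = rng.normal(size=(trials, n))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc ** 2).sum(1) * (yc ** 2).sum(1))
    rate = (np.abs(r) > rp.critical_r(n, alpha)).mean()
    se = np.sqrt(alpha * (1 - alpha) / trials)
    assert abs(rate - alpha) < 4 * se


# ---------------------------------------------------------------------------
# oscillation profiles
# ---------------------------------------------------------------------------

def _expr_from_matrix(mat, gene_ids, minutes, phases):
    values = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                          columns=[float(m) for m in minutes])
    return ExpressionTimecourse(values=values, phases=phases)


def test_oscillation_sign_convention_up_regulated_late():
    # identical expression at three timepoints, perfectly ordered with trep
    col = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
    expr = _expr_from_matrix(np.tile(col[:, None], (1, 3)),
                             [f"g{i}" for i in range(5)],
                             [0, 10, 20], ["G1", "S", "G2"])
    gt = pd.DataFrame({"gene_id": [f"g{i}" for i in range(5)],
                       "trep": [10.0, 20, 30, 40, 50]})
    prof = rp.oscillation_profile(expr, gt, alpha=0.05)
    assert np.allclose(prof.r, 1.0)  # up-regulated genes replicate late
    assert prof.significant.all()
    assert (prof.n_pairs == 5).all()


def test_oscillation_all_na_timepoint_flagged():
    mat = np.random.default_rng(1).normal(size=(6, 3))
    mat[:, 1] = np.nan
    expr = _expr_from_matrix(mat, [f"g{i}" for i in range(6)],
                             [0, 10, 20], ["G1", "S", "G2"])
    gt = pd.DataFrame({"gene_id": [f"g{i}" for i in range(6)],
                       "trep": np.arange(6.0)})
    prof = rp.oscillation_profile(expr, gt)
    assert np.isnan(prof.r.iloc[1]) and not prof.significant.iloc[1]
    assert np.isfinite(prof.r.iloc[0]) and np.isfinite(prof.r.iloc[2])


def test_oscillation_significance_matches_critical_r():
    rng = np.random.default_rng(3)
    mat = rng.normal(size=(40, 4))
    expr = _expr_from_matrix(mat, [f"g{i}" for i in range(40)],
                             [0, 10, 20, 30], ["G1", "S", "G2", "M"])
    gt = pd.DataFrame({"gene_id": [f"g{i}" for i in range(40)],
                       "trep": rng.uniform(20, 40, 40)})
    prof = rp.oscillation_profile(expr, gt, alpha=0.2)
    assert (prof.significant == (prof.r.abs() > prof.critical_r)).all()


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r,k,expected", [
    ([0.2, 0.4], 2, [0.3]),
    ([1.0, 0.0, -1.0], 2, [0.5, -0.5]),
    ([0.1, 0.2, 0.3], 1, [0.1, 0.2, 0.3]),  # identity
])
def test_smooth_profile(r, k, expected):
    np.testing.assert_allclose(rp.smooth_profile(r, k), expected)


# ---------------------------------------------------------------------------
# peak expression time / moving average
# ---------------------------------------------------------------------------

def test_peak_expression_time_rules(tiny_expr):
    peak = rp.peak_expression_time(tiny_expr)
    assert peak["g1"] == 20.0          # plain maximum
    assert peak["g2"] == 0.0           # constant row: earliest tie wins
    assert peak["g3"] == 10.0          # NA ignored
    assert peak["g4"] == 10.0          # tie at 10 and 30 -> 10


def test_peak_expression_time_all_missing():
    values = pd.DataFrame([[np.nan] * 3],
                          index=pd.Index(["g"], name="gene_id"),
                          columns=[0.0, 10.0, 20.0])
    expr = ExpressionTimecourse(values=values, phases=["G1", "S", "G2"])
    assert np.isnan(rp.peak_expression_time(expr)["g"])


def test_trep_moving_average_examples():
    gt = pd.DataFrame({"gene_id": ["a", "b", "c"], "trep": [10.0, 20.0, 60.0]})
    ordering = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    ma = rp.trep_moving_average(gt, ordering, window=2)
    np.testing.assert_allclose(ma.mean_trep, [15.0, 40.0])
    np.testing.assert_allclose(
        ma.se_trep, [np.std([10, 20], ddof=1) / np.sqrt(2),
                     np.std([20, 60], ddof=1) / np.sqrt(2)])


def test_trep_moving_average_constant_and_global():
    gt = pd.DataFrame({"gene_id": list("abcd"), "trep": [5.0] * 4})
    ordering = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
    ma = rp.trep_moving_average(gt, ordering, window=3)
    np.testing.assert_allclose(ma.mean_trep, 5.0)
    np.testing.assert_allclose(ma.se_trep, 0.0)
    single = rp.trep_moving_average(gt, ordering, window=4)
    assert len(single) == 1 and single.mean_trep.iloc[0] == 5.0
    with pytest.raises(ValueError):
        rp.trep_moving_average(gt, ordering, window=1)
    with pytest.raises(ValueError):
        rp.trep_moving_average(gt, ordering, window=5)


def test_moving_average_bounded_by_series_range():
    rng = np.random.default_rng(9)
    gt = pd.DataFrame({"gene_id": [f"g{i}" for i in range(200)],
                       "trep": rng.uniform(20, 40, 200)})
    ordering = pd.Series(rng.uniform(0, 100, 200),
                         index=[f"g{i}" for i in range(200)])
    ma = rp.trep_moving_average(gt, ordering, window=25)
    assert (ma.mean_trep >= gt.trep.min()).all()
    assert (ma.mean_trep <= gt.trep.max()).all()
    assert (ma.se_trep >= 0).all()


# ---------------------------------------------------------------------------
# deciles
# ---------------------------------------------------------------------------

def test_decile_bins_partition_and_order():
    rng = np.random.default_rng(17)
    n = 103  # remainder 3: first three bins get one extra gene
    gt = pd.DataFrame({"gene_id": [f"g{i:03d}" for i in range(n)],
                       "trep": rng.uniform(20, 40, n)})
    expr = pd.Series(rng.normal(size=n), index=gt.gene_id)
    table = rp.decile_median_expression(gt, expr)
    assert table.n.tolist() == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]
    assert table.n.sum() == n
    assert table.median_trep.is_monotonic_increasing


def test_decile_20_genes_two_per_bin():
    gt = pd.DataFrame({"gene_id": [f"g{i:02d}" for i in range(20)],
                       "trep": np.arange(20.0)})
    expr = pd.Series(np.ones(20), index=gt.gene_id)
    table = rp.decile_median_expression(gt, expr)
    assert (table.n == 2).all()
    assert table.median_trep.iloc[0] == 0.5  # the two smallest trep
    assert (table.median_expression == 1.0).all()  # identical expression
    with pytest.raises(ValueError):
        rp.decile_median_expression(gt.head(9), expr.head(9))


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def test_decile_extremes_identical_groups():
    gt = pd.DataFrame({"gene_id": [f"g{i:02d}" for i in range(20)],
                       "trep": [25.0] * 20})
    expr = pd.Series(np.arange(20.0), index=gt.gene_id)
    res = rp.decile_extremes_trep(gt, expr)
    assert res.difference.iloc[0] == 0.0
    assert res["p"].iloc[0] == pytest.approx(1.0)
    assert res.n1.iloc[0] == res.n2.iloc[0] == 2


def test_decile_extremes_matches_scipy_student_t():
    rng = np.random.default_rng(21)
    gt = pd.DataFrame({"gene_id": [f"g{i:02d}" for i in range(20)],
                       "trep": rng.uniform(20, 40, 20)})
    expr = pd.Series(rng.normal(size=20), index=gt.gene_id)
    res = rp.decile_extremes_trep(gt, expr)
    df = pd.DataFrame({"trep": gt.set_index("gene_id").trep, "e": expr})
    df = df.sort_values("e")
    top, bottom = df.trep.iloc[-2:], df.trep.iloc[:2]
    t_ref, p_ref = stats.ttest_ind(top, bottom, equal_var=True)
    assert res.t.iloc[0] == pytest.approx(t_ref)
    assert res["p"].iloc[0] == pytest.approx(p_ref)
    assert res.difference.iloc[0] == pytest.approx(top.mean() - bottom.mean())


def test_compare_top_bottom_partitions_and_direction(default_dataset):
    gt = rp.interpolate_trep(default_dataset["profile"],
                             default_dataset["genes"])
    res = rp.compare_top_bottom_expression(default_dataset["async_expr"], gt,
                                           k=100)
    assert res.n1.iloc[0] == res.n2.iloc[0] == 100
    # highly expressed genes replicate earlier (coupled asynchronous levels)
    assert res.difference.iloc[0] < 0


def test_compare_top_bottom_k_half_partitions():
    rng = np.random.default_rng(2)
    n = 40
    levels = pd.Series(rng.uniform(0.1, 5.0, n),
                       index=[f"g{i:02d}" for i in range(n)])
    ax = AsyncExpression(levels=levels)
    gt = pd.DataFrame({"gene_id": levels.index, "trep": rng.uniform(20, 40, n)})
    res = rp.compare_top_bottom_expression(ax, gt, k=n // 2)
    assert res.n1.iloc[0] + res.n2.iloc[0] == n
    with pytest.raises(ValueError):
        rp.compare_top_bottom_expression(ax, gt, k=n)


# ---------------------------------------------------------------------------
# copy-number correction
# ---------------------------------------------------------------------------

def test_copy_number_endpoints():
    levels = pd.Series([2.0, 2.0], index=["early", "at_division"])
    gt = pd.DataFrame({"gene_id": ["early", "at_division"],
                       "trep": [0.0, 100.0]})  # f = 1 and f = 0
    out = rp.copy_number_correction(AsyncExpression(levels=levels), gt,
                                    cycle_length=100.0, kappa=0.5)
    assert out.per_copy_normalized
    assert out.levels["at_division"] == pytest.approx(2.0)      # f=0 unchanged
    assert out.levels["early"] == pytest.approx(1.0)            # 2/(1+1)


def test_copy_number_rejects_double_correction_and_bad_cycle():
    levels = pd.Series([1.0], index=["g"])
    gt = pd.DataFrame({"gene_id": ["g"], "trep": [120.0]})
    with pytest.raises(ValueError, match="cycle_length|fraction"):
        rp.copy_number_correction(AsyncExpression(levels=levels), gt, 100.0)
    done = AsyncExpression(levels=levels, per_copy_normalized=True)
    with pytest.raises(ValueError, match="already"):
        rp.copy_number_correction(done,
                                  pd.DataFrame({"gene_id": ["g"],
                                                "trep": [50.0]}), 100.0)


def test_copy_number_correction_reduces_copy_driven_correlation():
    rng = np.random.default_rng(8)
    n = 400
    trep = rng.uniform(20, 48, n)
    f = (100.0 - trep) / 100.0
    levels = pd.Series(3.0 * (1.0 + f) * np.exp(rng.normal(0, 0.05, n)),
                       index=[f"g{i}" for i in range(n)])
    gt = pd.DataFrame({"gene_id": levels.index, "trep": trep})
    before, _ = rp.pearson_r(levels.to_numpy(), trep)
    out = rp.copy_number_correction(AsyncExpression(levels=levels), gt, 100.0)
    after, _ = rp.pearson_r(out.levels.to_numpy(), trep)
    assert abs(after) < abs(before)
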