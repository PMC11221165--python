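"""Spline smoothers and the nonparametric test battery."""

import numpy as np
import pytest
from scipy import stats

from isobeak.trend_stats import (cohens_d, fit_smoother, fit_smoother_grouped,
                                 kruskal_wallis_dunn, mann_whitney,
                                 skillings_mack_nemenyi, spearman_rho)


# ---------------------------------------------------------------- smoothers

def test_noise_free_linear_limit():
    x = np.linspace(0.0, 1.0, 30)
    fit = fit_smoother(x, x, n_perm=99, seed=0)
    assert fit.deviance_explained >= 0.999
    assert fit.edf == pytest.approx(1.0, abs=0.1)


def test_constant_response():
    fit = fit_smoother(np.arange(10.0), np.full(10, 3.0), n_perm=99, seed=0)
    assert fit.deviance_explained == 0.0
    assert fit.p_smooth == 1.0


def test_dense_sine_recovery(rng):
    x = np.linspace(0.0, 2 * np.pi, 60)
    y = np.sin(x) + rng.normal(0, 0.05, 60)
    fit = fit_smoother(x, y, n_perm=199, seed=0)
    assert fit.deviance_explained > 0.95
    assert fit.p_smooth < 0.05


def test_smoother_preconditions():
    with pytest.raises(ValueError):
        fit_smoother([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_selected_k_within_candidates_and_deterministic(rng):
    x = np.linspace(0, 1, 40)
    y = np.sin(6 * x) + rng.normal(0, 0.2, 40)
    f1 = fit_smoother(x, y, k_candidates=(3, 4, 5, 6), n_perm=99, seed=5)
    f2 = fit_smoother(x, y, k_candidates=(3, 4, 5, 6), n_perm=99, seed=5)
    assert f1.k <= 6
    assert f1.k == f2.k and f1.p_smooth == f2.p_smooth
    assert f1.aicc == f2.aicc


def test_permutation_p_floor():
    x = np.linspace(0, 1, 30)
    fit = fit_smoother(x, x ** 2, n_perm=99, seed=0)
    assert fit.p_smooth >= 1.0 / 100.0


def test_grouped_offsets_recovered(rng):
    x = np.tile(np.linspace(0, 1, 12), 3)
    g = np.repeat(["a", "b", "c"], 12)
    truth = {"a": -1.0, "b": 0.0, "c": 1.0}
    y = np.sin(2 * x) + np.array([truth[k] for k in g]) \
        + rng.normal(0, 0.05, 36)
    fit = fit_smoother_grouped(x, y, g, n_perm=49, seed=0)
    for k, v in truth.items():
        assert fit.group_offsets[k] == pytest.approx(v, abs=0.1)


def test_grouped_single_group_reduces_to_plain(rng):
    x = np.linspace(0, 1, 15)
    y = np.sin(3 * x) + rng.normal(0, 0.1, 15)
    f1 = fit_smoother(x, y, n_perm=9, seed=0)
    f2 = fit_smoother_grouped(x, y, ["only"] * 15, n_perm=9, seed=0)
    assert np.allclose(f1.fitted, f2.fitted, atol=1e-9)
    assert f1.intercept == pytest.approx(f2.intercept, abs=1e-9)


def test_grouped_flat_smooth_pure_offsets(rng):
    x = np.tile(np.linspace(0, 1, 10), 3)
    g = np.repeat(["a", "b", "c"], 10)
    offs = {"a": -2.0, "b": 0.0, "c": 2.0}
    y = np.array([offs[k] for k in g]) + rng.normal(0, 0.05, 30)
    fit = fit_smoother_grouped(x, y, g, n_perm=49, seed=0)
    # GCV leaves at most mild wiggle on a flat truth; offsets carry the signal
    assert fit.edf < 2.5
    for k, v in offs.items():
        assert fit.group_offsets[k] == pytest.approx(v, abs=0.1)


def test_grouped_preconditions():
    with pytest.raises(ValueError):
        fit_smoother_grouped([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6],
                             ["a", "a", "a", "a", "b", "b"])


# ---------------------------------------------------------------- rank tests

def test_mann_whitney_exact_enumeration():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)


def test_mann_whitney_identical_samples():
    assert mann_whitney([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)


def test_mann_whitney_shift_alternative(rng):
    a = rng.normal(0, 1, 50)
    b = rng.normal(2, 1, 50)
    assert mann_whitney(a, b).p_value < 0.001


def test_kruskal_identical_constants():
    res = kruskal_wallis_dunn([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kruskal_hand_rank_oracle():
    # ranks 1..6, rank sums 3/7/11: H = 12/42 * (9+49+121)/2 - 21 = 32/7
    res = kruskal_wallis_dunn([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == pytest.approx(32.0 / 7.0, abs=1e-9)
    assert res.posthoc is not None and len(res.posthoc) == 3
    assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-12).all()


def test_kruskal_type_one_error_calibrated(rng):
    rejections = 0
    n_sim = 400
    for _ in range(n_sim):
        groups = [rng.normal(0, 1, 8) for _ in range(3)]
        if kruskal_wallis_dunn(groups).p_value < 0.05:
            rejections += 1
    assert rejections / n_sim == pytest.approx(0.05, abs=0.03)


def test_skillings_mack_equals_friedman_when_complete(rng):
    data = rng.normal(size=(10, 4))
    sm = skillings_mack_nemenyi(data)
    fr = stats.friedmanchisquare(*data.T)
    assert sm.statistic == pytest.approx(fr.statistic, abs=1e-9)
    assert sm.p_value == pytest.approx(fr.pvalue, abs=1e-9)


def test_skillings_mack_zero_when_identical():
    data = np.tile([1.0, 1.0, 1.0, 1.0], (6, 1))
    res = skillings_mack_nemenyi(data)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_skillings_mack_handles_missing_cells(rng):
    data = rng.normal(size=(8, 4))
    data[0, 1] = np.nan
    data[3, 2] = np.nan
    res = skillings_mack_nemenyi(data)
    assert 0 <= res.p_value <= 1
    assert res.posthoc is not None  # complete blocks remain


def test_skillings_mack_drops_sparse_blocks(rng):
    data = rng.normal(size=(6, 4))
    data[0, :3] = np.nan  # block with a single observation
    with pytest.warns(UserWarning):
        res = skillings_mack_nemenyi(data)
    assert 0 <= res.p_value <= 1


def test_skillings_mack_null_rejection_rate(rng):
    rejections = 0
    n_sim = 400
    for _ in range(n_sim):
        if skillings_mack_nemenyi(rng.normal(size=(10, 4))).p_value < 0.05:
            rejections += 1
    assert rejections / n_sim == pytest.approx(0.05, abs=0.03)


def test_spearman_monotone_extremes():
    assert spearman_rho([1, 2, 3, 4, 5],
                        [2, 4, 8, 16, 32]).statistic == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3, 4, 5],
                        [5, 4, 3, 2, 1]).statistic == pytest.approx(-1.0)


def test_spearman_exact_small_sample():
    # perfect monotone n=5: exact two-tailed p = 2/5! = 1/60
    res = spearman_rho([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert res.p_value == pytest.approx(2.0 / 120.0)


def test_spearman_independent_unbiased(rng):
    rhos = [spearman_rho(rng.normal(size=100),
                         rng.normal(size=100)).statistic
            for _ in range(300)]
    assert np.mean(rhos) == pytest.approx(0.0, abs=0.05)


def test_cohens_d_values():
    assert cohens_d([1.0, 2.0], [1.0, 2.0]) == 0.0
    a = [0.0, 1.0, -1.0, 0.5, -0.5]
    b = [1.0, 2.0, 0.0, 1.5, 0.5]
    assert cohens_d(a, b) == pytest.approx(
        (np.mean(a) - np.mean(b))
        / np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2))
    assert cohens_d([0.0, 2.0], [1.0, 3.0]) == pytest.approx(-1 / np.sqrt(2))


def test_rank_tests_invariant_under_monotone_transform(rng):
    a = rng.uniform(0, 1, 12)
    b = rng.uniform(0, 1, 12)
    p1 = mann_whitney(a, b).p_value
    p2 = mann_whitney(np.exp(a), np.exp(b)).p_value
    assert p1 == pytest.approx(p2)
    x = rng.uniform(0, 1, 20)
    y = rng.uniform(0, 1, 20)
    assert spearman_rho(x, y).statistic == pytest.approx(
        spearman_rho(x ** 3, y).statistic)
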