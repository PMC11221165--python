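"""Niche posteriors, ellipse geometry, overlap and period segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isobeak.niche import (NichePosterior, OverlapCategory, OverlapMatrix,
                           categorize_overlap, classify_periods,
                           fit_niche_posterior, is_significant_overlap,
                           niche_size, niche_size_distribution,
                           overlap_matrix, overlap_probability)


def _cloud(rng, n=200, mean=(0.0, 0.0), cov=((1.0, 0.3), (0.3, 2.0))):
    return rng.multivariate_normal(mean, cov, size=n)


# ---------------------------------------------------------------- posterior

def test_posterior_mean_mu_matches_sample_mean(rng):
    pts = _cloud(rng, n=300)
    post = fit_niche_posterior(pts, n_draws=1000, seed=1)
    se = np.sqrt(np.diag(post.sample_cov) / post.n_points)
    assert np.all(np.abs(post.mu.mean(axis=0) - post.x_bar) < 3 * se)


def test_posterior_deterministic_under_seed(rng):
    pts = _cloud(rng, n=50)
    a = fit_niche_posterior(pts, n_draws=100, seed=42)
    b = fit_niche_posterior(pts, n_draws=100, seed=42)
    assert np.array_equal(a.mu, b.mu)
    assert np.array_equal(a.sigma, b.sigma)


def test_posterior_sigma_mean_approaches_sample_cov(rng):
    pts = _cloud(rng, n=500)
    post = fit_niche_posterior(pts, n_draws=2000, seed=3)
    rel = (np.abs(post.sigma.mean(axis=0) - post.sample_cov)
           / np.abs(post.sample_cov).max())
    assert rel.max() < 0.10


def test_posterior_rejects_degenerate(rng):
    with pytest.raises(ValueError):
        fit_niche_posterior(np.zeros((2, 2)))
    collinear = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
    with pytest.raises(ValueError):
        fit_niche_posterior(collinear)


# ---------------------------------------------------------------- geometry

def test_ellipse_area_identity_covariance():
    q = stats.chi2.ppf(0.95, df=2)
    assert niche_size(np.eye(2), 0.95) == pytest.approx(np.pi * q, abs=1e-6)
    assert niche_size(np.eye(2), 0.95) == pytest.approx(18.8227, abs=1e-3)


def test_ellipse_area_scaling_and_limits():
    cov = np.array([[2.0, 0.5], [0.5, 1.0]])
    assert niche_size(4 * cov, 0.95) == pytest.approx(
        4 * niche_size(cov, 0.95))
    assert niche_size(cov, 1e-9) < 1e-7
    with pytest.raises(ValueError):
        niche_size(np.array([[1.0, 2.0], [2.0, 1.0]]), 0.95)  # not SPD
    with pytest.raises(ValueError):
        niche_size(cov, 1.0)


def test_ellipse_area_rotation_invariant(rng):
    cov = np.array([[3.0, 0.8], [0.8, 0.5]])
    th = 0.7
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    assert niche_size(r @ cov @ r.T, 0.95) == pytest.approx(
        niche_size(cov, 0.95), abs=1e-9)


def test_doubling_sds_quadruples_posterior_area(rng):
    base = _cloud(rng, n=150)
    small = fit_niche_posterior(base, n_draws=500, seed=5)
    big = fit_niche_posterior(base * 2.0, n_draws=500, seed=5)
    ratio = (niche_size_distribution(big)["mean"]
             / niche_size_distribution(small)["mean"])
    assert ratio == pytest.approx(4.0, rel=0.15)


# ---------------------------------------------------------------- overlap

def test_self_overlap_close_to_alpha(rng):
    pts = _cloud(rng, n=250)
    post = fit_niche_posterior(pts, n_draws=100, seed=7)
    p, _ = overlap_probability(post, post, alpha=0.95, n_mc=10_000, seed=8)
    assert p == pytest.approx(0.95, abs=0.02)


def test_separated_niches_no_overlap(rng):
    a = fit_niche_posterior(_cloud(rng, n=100), n_draws=100, seed=1)
    b = fit_niche_posterior(_cloud(rng, n=100, mean=(40.0, 40.0)),
                            n_draws=100, seed=2)
    p_ab, p_ba = overlap_probability(a, b, n_mc=2000, seed=3)
    assert p_ab < 0.01 and p_ba < 0.01


def test_tiny_niche_inside_big_niche_full_overlap(rng):
    big = fit_niche_posterior(_cloud(rng, n=400,
                                     cov=((25.0, 0.0), (0.0, 25.0))),
                              n_draws=100, seed=1)
    tiny = fit_niche_posterior(
        _cloud(rng, n=400, cov=((1e-4, 0.0), (0.0, 1e-4))),
        n_draws=100, seed=2)
    p, _ = overlap_probability(tiny, big, n_mc=2000, seed=3)
    assert p > 0.99


def test_overlap_deterministic(rng):
    a = fit_niche_posterior(_cloud(rng, n=60), n_draws=50, seed=1)
    b = fit_niche_posterior(_cloud(rng, n=60, mean=(1.0, 1.0)),
                            n_draws=50, seed=2)
    assert overlap_probability(a, b, n_mc=500, seed=9) == \
        overlap_probability(a, b, n_mc=500, seed=9)


# ---------------------------------------------------------------- category

@pytest.mark.parametrize("p,cat", [
    (0.0, "none"), (0.29, "none"), (0.294, "none"),
    (0.295, "medium"), (0.30, "medium"), (0.60, "medium"),
    (0.604, "medium"), (0.605, "large"), (0.61, "large"), (1.0, "large"),
])
def test_categorize_printed_thresholds(p, cat):
    assert categorize_overlap(p).value == cat


def test_only_large_is_significant():
    assert not is_significant_overlap(OverlapCategory.NONE)
    assert not is_significant_overlap(OverlapCategory.MEDIUM)
    assert is_significant_overlap(OverlapCategory.LARGE)


@given(st.floats(0.0, 1.0))
@settings(max_examples=200, deadline=None)
def test_categorize_total_on_unit_interval(p):
    assert categorize_overlap(p) in set(OverlapCategory)


def test_categorize_rejects_outside_unit_interval():
    with pytest.raises(ValueError):
        categorize_overlap(-0.01)
    with pytest.raises(ValueError):
        categorize_overlap(1.01)


# ---------------------------------------------------------------- periods

def _matrix_from(p: np.ndarray) -> OverlapMatrix:
    k = p.shape[0]
    cat = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            cat[i, j] = categorize_overlap(p[i, j])
    return OverlapMatrix(labels=list(range(1, k + 1)), p=p, category=cat)


def test_all_large_single_main_stable():
    p = np.full((6, 6), 0.9)
    seg = classify_periods(_matrix_from(p))
    assert seg.labels == ["main_stable"] * 6
    assert seg.boundaries["initial"] is None


def test_block_structure_recovers_four_periods():
    # subsections {1,2} isolated, {3,4,5} mutually large, {6} mixed,
    # {7..12} all-large terminal block
    k = 12
    p = np.full((k, k), 0.1)
    np.fill_diagonal(p, 0.95)
    for blk in ([0, 1], [2, 3, 4], list(range(6, 12))):
        for i in blk:
            for j in blk:
                p[i, j] = 0.9
    p[5, 6] = p[6, 5] = 0.9  # subsection 6 mixes with the terminal block
    seg = classify_periods(_matrix_from(p))
    assert seg.labels == (["initial"] * 2 + ["first_stable"] * 3 + ["change"]
                          + ["main_stable"] * 6)


def test_weak_banded_overlap_change_dominates():
    # all off-diagonal overlaps below the "large" threshold: no stable block
    k = 10
    p = np.full((k, k), 0.4)
    np.fill_diagonal(p, 0.95)
    seg = classify_periods(_matrix_from(p))
    assert seg.labels.count("main_stable") == 1  # no run longer than 1
    assert seg.labels.count("change") >= k - 3


def test_too_few_subsections_rejected():
    p = np.full((3, 3), 0.9)
    with pytest.raises(ValueError):
        classify_periods(_matrix_from(p))


def test_segmentation_order_preserving_and_exhaustive(rng):
    for _ in range(10):
        k = int(rng.integers(4, 12))
        p = rng.uniform(0, 1, size=(k, k))
        seg = classify_periods(_matrix_from(p))
        assert len(seg.labels) == k
        order = {"initial": 0, "first_stable": 1, "change": 2,
                 "main_stable": 3}
        ranks = [order[lb] for lb in seg.labels]
        assert ranks == sorted(ranks)


def test_overlap_matrix_directional_diagonal(rng):
    a = fit_niche_posterior(_cloud(rng, n=120), n_draws=60, seed=1, label="a")
    b = fit_niche_posterior(_cloud(rng, n=120, mean=(0.5, 0.5)),
                            n_draws=60, seed=2, label="b")
    om = overlap_matrix([a, b], n_mc=2000, seed=3)
    assert om.p[0, 0] == pytest.approx(0.95, abs=0.03)
    assert om.p[1, 1] == pytest.approx(0.95, abs=0.03)
    sym = om.symmetrized()
    assert sym[0, 1] == pytest.approx(sym[1, 0])
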