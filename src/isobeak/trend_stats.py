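"""Trend smoothers and nonparametric tests for temporal/ontogenetic analyses.

Temporal trends (a metric at a fixed beak subsection against calendar year)
and ontogenetic trends (a metric against subsection, with individual as a
factor) are fitted with penalized cubic regression splines: a B-spline basis
of dimension ``k`` under a second-difference penalty, smoothing parameter by
generalized cross-validation (GCV), and ``k`` chosen by the lowest
small-sample-corrected Akaike criterion (AICc) over a candidate set.  The
smooth term's significance is assessed by a seeded permutation test on
deviance explained rather than an analytic reference distribution.

The battery of rank tests mirrors standard usage for small unbalanced isotope
samples: Mann–Whitney U (two groups), Kruskal–Wallis H with Dunn's Z post hoc
(more than two groups), the Skillings–Mack test with Nemenyi post hoc for
blocked designs with missing cells (subsections × time series), Spearman rank
correlation, and Cohen's d effect sizes.  All tests are two-tailed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import solve_triangular

__all__ = [
    "SmoothFit",
    "TestResult",
    "fit_smoother",
    "fit_smoother_grouped",
    "mann_whitney",
    "kruskal_wallis_dunn",
    "skillings_mack_nemenyi",
    "spearman_rho",
    "cohens_d",
]

DEFAULT_K_CANDIDATES = tuple(range(3, 11))
_LAMBDA_GRID = 10.0 ** np.linspace(-8.0, 10.0, 91)


@dataclass
class SmoothFit:
    """A selected penalized-spline fit."""

    response: str
    intercept: float
    intercept_se: float
    k: int
    edf: float                    # effective df of the smooth term
    aicc: float
    deviance_explained: float
    p_smooth: float
    fitted: np.ndarray
    lambda_: float
    n: int
    group_offsets: Optional[dict] = None


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n_per_group: tuple
    posthoc: Optional[pd.DataFrame] = None
    effect_size: Optional[float] = None


# --------------------------------------------------------------------------
# penalized regression splines
# --------------------------------------------------------------------------

def _bspline_basis(x: np.ndarray, k: int) -> np.ndarray:
    """B-spline design matrix with basis dimension k (cubic for k >= 4)."""
    degree = 3 if k >= 4 else k - 1
    n_interior = k - (degree + 1)
    lo, hi = float(x.min()), float(x.max())
    if n_interior > 0:
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(x), qs)
    else:
        interior = np.array([])
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    return BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()


def _second_diff_penalty(p: int) -> np.ndarray:
    d = np.diff(np.eye(p), n=2, axis=0)
    return d.T @ d


def _constrained_basis(b: np.ndarray, s: np.ndarray):
    """Apply the sum-to-zero constraint 1'Bβ = 0 (mgcv-style centering)."""
    c = b.sum(axis=0)[None, :]
    from scipy.linalg import null_space
    q = null_space(c)
    return b @ q, q.T @ s @ q


class _SplineEngine:
    """Demmler–Reinsch decomposition of a partially penalized least squares.

    Design X = [X_unpen | B]; only B carries the penalty.  All smoothing
    parameters can then be evaluated in O(p) per λ after one O(n p²) setup.
    """

    def __init__(self, x_unpen: np.ndarray, b_pen: np.ndarray,
                 s_pen: np.ndarray):
        x = np.hstack([x_unpen, b_pen])
        self.n, self.p = x.shape
        self.p0 = x_unpen.shape[1]
        if self.p >= self.n:
            raise ValueError("design has more columns than observations")
        s_full = np.zeros((self.p, self.p))
        s_full[self.p0:, self.p0:] = s_pen
        q, r = np.linalg.qr(x)
        if np.min(np.abs(np.diag(r))) < 1e-10 * np.max(np.abs(np.diag(r))):
            raise np.linalg.LinAlgError("rank-deficient smoother design")
        rinv = solve_triangular(r, np.eye(self.p), lower=False)
        m = rinv.T @ s_full @ rinv
        m = 0.5 * (m + m.T)
        eig, u = np.linalg.eigh(m)
        self.eig = np.clip(eig, 0.0, None)
        self.a = q @ u          # n x p, orthonormal columns
        self.t = rinv @ u       # maps rotated coefs back to β

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.a.T @ y

    def rss_edf(self, y: np.ndarray, z: np.ndarray, lam: float):
        d = 1.0 / (1.0 + lam * self.eig)
        rss = float(y @ y - np.sum((2.0 * d - d * d) * z * z))
        return max(rss, 0.0), float(d.sum())

    def gcv_select(self, y: np.ndarray, z: np.ndarray,
                   grid: np.ndarray = _LAMBDA_GRID) -> float:
        yty = float(y @ y)
        z2 = z * z
        d = 1.0 / (1.0 + np.outer(grid, self.eig))        # (G, p)
        rss = np.maximum(yty - (2.0 * d - d * d) @ z2, 0.0)
        edf = d.sum(axis=1)
        ok = edf < self.n
        gcv = np.where(ok, self.n * rss / (self.n - edf) ** 2, np.inf)
        gmin = gcv.min()
        # near-ties (flat GCV ridge, e.g. noise-free polynomial data):
        # prefer the largest lambda, i.e. the smoothest admissible fit
        tol = gmin * 1e-7 + 1e-12 * (yty + 1.0)
        idx = np.flatnonzero(gcv <= gmin + tol)
        return float(grid[idx[-1]])

    def coefficients(self, z: np.ndarray, lam: float) -> np.ndarray:
        d = 1.0 / (1.0 + lam * self.eig)
        return self.t @ (d * z)

    def fitted(self, z: np.ndarray, lam: float) -> np.ndarray:
        d = 1.0 / (1.0 + lam * self.eig)
        return self.a @ (d * z)

    def coef_cov_unscaled(self, lam: float) -> np.ndarray:
        d = 1.0 / (1.0 + lam * self.eig)
        return (self.t * (d * d)) @ self.t.T


def _aicc(n: int, rss: float, edf_total: float) -> float:
    p = edf_total + 1.0  # + scale parameter
    if n - p - 1.0 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * p + 2.0 * p * (p + 1.0) / (n - p - 1.0)


def _fit_penalized(x: np.ndarray, y: np.ndarray, x_unpen: np.ndarray,
                   k_candidates: Sequence[int], n_perm: int, seed,
                   response: str, group_labels: Optional[list]) -> SmoothFit:
    n = y.size
    tss = float(np.sum((y - y.mean()) ** 2))
    n_unique = np.unique(x).size
    p0 = x_unpen.shape[1]

    if tss <= 0:
        return SmoothFit(response=response, intercept=float(y.mean()),
                         intercept_se=0.0, k=min(k_candidates), edf=1.0,
                         aicc=-np.inf, deviance_explained=0.0, p_smooth=1.0,
                         fitted=np.full(n, y.mean()), lambda_=np.inf, n=n,
                         group_offsets=None)

    candidates = [k for k in sorted(k_candidates)
                  if k <= n_unique and (k - 1) + p0 < n - 2]
    if not candidates:
        raise ValueError("no admissible basis dimension for this sample")

    best = None
    for k in candidates:
        braw = _bspline_basis(x, k)
        s = _second_diff_penalty(braw.shape[1])
        bc, sc = _constrained_basis(braw, s)
        try:
            eng = _SplineEngine(x_unpen, bc, sc)
        except np.linalg.LinAlgError:
            continue
        z = eng.rotate(y)
        lam = eng.gcv_select(y, z)
        rss, edf_total = eng.rss_edf(y, z, lam)
        aicc = _aicc(n, rss, edf_total)
        if best is None or aicc < best[0]:
            best = (aicc, k, eng, z, lam, rss, edf_total)
    if best is None:
        raise ValueError("smoother design rank-deficient for all candidates")

    aicc, k, eng, z, lam, rss, edf_total = best
    dev = 1.0 - rss / tss

    # permutation test on deviance explained, λ re-selected per permutation
    rng = np.random.default_rng(seed)
    exceed = 0
    yty = float(y @ y)
    for _ in range(n_perm):
        yp = rng.permutation(y)
        zp = eng.rotate(yp)
        lam_p = eng.gcv_select(yp, zp)
        rss_p, _ = eng.rss_edf(yp, zp, lam_p)
        if 1.0 - rss_p / tss >= dev - 1e-12:
            exceed += 1
    p_smooth = (1.0 + exceed) / (n_perm + 1.0)

    sigma2 = rss / max(n - edf_total, 1.0)
    cov = sigma2 * eng.coef_cov_unscaled(lam)
    beta = eng.coefficients(z, lam)
    if group_labels is None:
        intercept = float(beta[0])
        intercept_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        offsets = None
    else:
        g = len(group_labels)
        w = np.zeros(eng.p)
        w[:g] = 1.0 / g
        intercept = float(w @ beta)
        intercept_se = float(np.sqrt(max(w @ cov @ w, 0.0)))
        offsets = {lab: float(beta[i] - intercept)
                   for i, lab in enumerate(group_labels)}

    return SmoothFit(response=response, intercept=intercept,
                     intercept_se=intercept_se, k=k,
                     edf=float(edf_total - p0), aicc=float(aicc),
                     deviance_explained=float(dev), p_smooth=float(p_smooth),
                     fitted=eng.fitted(z, lam), lambda_=float(lam), n=n,
                     group_offsets=offsets)


def fit_smoother(x: Sequence[float], y: Sequence[float],
                 k_candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
                 n_perm: int = 999, seed: int = 0,
                 response: str = "y") -> SmoothFit:
    """Penalized-spline smooth of y on x with AICc basis selection."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    return _fit_penalized(x, y, np.ones((x.size, 1)), k_candidates, n_perm,
                          seed, response, None)


def fit_smoother_grouped(x: Sequence[float], y: Sequence[float],
                         group: Sequence,
                         k_candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
                         n_perm: int = 999, seed: int = 0,
                         response: str = "y") -> SmoothFit:
    """Shared smooth of x plus fixed per-group intercepts.

    ``group`` is typically the individual id, absorbing repeated sampling of
    the same beak.  Offsets are reported relative to their mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if not (x.size == y.size == group.size):
        raise ValueError("x, y and group must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    labels = sorted(set(group.tolist()))
    counts = {lab: int(np.sum(group == lab)) for lab in labels}
    if len(labels) >= 2 and min(counts.values()) < 3:
        raise ValueError("each group needs at least 3 points")
    ind = np.column_stack([(group == lab).astype(float) for lab in labels])
    return _fit_penalized(x, y, ind, k_candidates, n_perm, seed, response,
                          labels)


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed Mann–Whitney U.

    Exact enumeration for total n ≤ 16 without ties; otherwise the
    tie-corrected normal approximation (no continuity correction, so that
    identical samples give p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([a, b])
    if not _has_ties(pooled) and pooled.size <= 16:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return TestResult(name="mann_whitney_u", statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      n_per_group=(a.size, b.size),
                      effect_size=cohens_d(a, b))


def _holm(pvals: np.ndarray) -> np.ndarray:
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def kruskal_wallis_dunn(groups: Sequence[Sequence[float]],
                        adjust: str = "holm") -> TestResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn's Z pairwise post hoc."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        # all observations identical: H = 0 by convention, p = 1
        return TestResult(name="kruskal_wallis_h", statistic=0.0, p_value=1.0,
                          n_per_group=tuple(g.size for g in groups))
    h, p = stats.kruskal(*groups)

    # Dunn's pairwise Z on pooled ranks with tie correction
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + [g.size for g in groups])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = (n_total * (n_total + 1) / 12.0
                - tie_term / (12.0 * (n_total - 1)))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append({"group_i": i, "group_j": j, "z": z,
                     "p_raw": 2.0 * stats.norm.sf(abs(z))})
    posthoc = pd.DataFrame(rows)
    if adjust == "holm":
        posthoc["p_adj"] = _holm(posthoc["p_raw"].to_numpy())
    elif adjust == "none":
        posthoc["p_adj"] = posthoc["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return TestResult(name="kruskal_wallis_h", statistic=float(h),
                      p_value=float(p),
                      n_per_group=tuple(g.size for g in groups),
                      posthoc=posthoc)


def skillings_mack_nemenyi(data: np.ndarray) -> TestResult:
    """Skillings–Mack test for blocked data with missing cells.

    ``data`` is blocks × treatments with NaN for missing cells (e.g., beak
    subsection as block, time series as treatment).  Reduces to the Friedman
    χ² for complete designs.  The Nemenyi post hoc is computed on the blocks
    observed for every treatment.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("need a 2-D blocks x treatments array, >= 3 treatments")
    t = x.shape[1]
    observed = ~np.isnan(x)
    usable = observed.sum(axis=1) >= 2
    if not np.all(usable):
        warnings.warn(f"dropping {int(np.sum(~usable))} block(s) with < 2 "
                      "observed treatments", stacklevel=2)
    x = x[usable]
    observed = observed[usable]
    if x.shape[0] == 0:
        raise ValueError("no usable blocks")

    a = np.zeros(t)
    for j in range(x.shape[0]):
        idx = np.flatnonzero(observed[j])
        kj = idx.size
        r = stats.rankdata(x[j, idx])
        a[idx] += np.sqrt(12.0 / (kj + 1.0)) * (r - (kj + 1.0) / 2.0)

    cov = np.zeros((t, t))
    for j in range(x.shape[0]):
        idx = np.flatnonzero(observed[j])
        kj = idx.size
        for i in idx:
            cov[i, i] += kj - 1
        for i1, i2 in itertools.combinations(idx, 2):
            cov[i1, i2] -= 1.0
            cov[i2, i1] -= 1.0
    df = int(np.linalg.matrix_rank(cov))
    sm = float(a @ np.linalg.pinv(cov) @ a)
    sm = max(sm, 0.0)
    p = float(stats.chi2.sf(sm, df)) if df > 0 else 1.0

    # Nemenyi on complete blocks
    complete = np.all(observed, axis=1)
    posthoc = None
    if np.sum(complete) >= 2:
        xc = x[complete]
        b = xc.shape[0]
        rmat = np.vstack([stats.rankdata(row) for row in xc])
        mean_ranks = rmat.mean(axis=0)
        se = np.sqrt(t * (t + 1) / (12.0 * b))
        rows = []
        for i, j in itertools.combinations(range(t), 2):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            pval = float(stats.studentized_range.sf(q * np.sqrt(2.0), t,
                                                    np.inf))
            rows.append({"treatment_i": i, "treatment_j": j, "q": q,
                         "p_value": min(pval, 1.0)})
        posthoc = pd.DataFrame(rows)
    return TestResult(name="skillings_mack", statistic=sm, p_value=min(p, 1.0),
                      n_per_group=tuple(int(c) for c in observed.sum(axis=0)),
                      posthoc=posthoc)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Spearman rank correlation.

    Exact permutation p for n ≤ 9 without ties; t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    n = x.size
    rho, p_approx = stats.spearmanr(x, y)
    if n <= 9 and not _has_ties(x) and not _has_ties(y):
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        denom = np.sum((rx - rx.mean()) ** 2)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.dot(rx - rx.mean(), np.asarray(perm) - ry.mean()) / denom
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = p_approx
    return TestResult(name="spearman_rho", statistic=float(rho),
                      p_value=float(min(p, 1.0)), n_per_group=(n,))


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d = (mean a − mean b) / pooled SD (n−1 pooling)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * np.var(a, ddof=1)
                      + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)
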