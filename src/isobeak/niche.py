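"""Bayesian bivariate isotopic niche regions, overlap and ontogenetic periods.

The isotopic niche of a group is modelled as a bivariate normal in
(corrected δ13C, trophic position) space — TP on the y-axis, never raw δ15N.
Sequential subsections of one beak violate sample independence, so instead of
small-sample ellipse statistics the niche is summarised by the posterior of
(μ, Σ) under the conjugate normal–inverse-Wishart model in its noninformative
limit:

    Σ | data ~ InvWishart(n − 1, (n − 1) S),   μ | Σ, data ~ N(x̄, Σ / n)

with x̄, S the sample mean and covariance.  Niche size is the area of the
α-probability ellipse, π · χ²₂(α) · √det Σ, reported as a posterior
distribution.  The directional overlap of niche a onto niche b is the
probability that a random member of a falls inside b's α-region, estimated by
Monte Carlo over paired posterior draws.  Overlap probabilities are
categorised on the printed thresholds (≤ 0.29 none, 0.30–0.60 medium,
≥ 0.61 large, after half-up rounding to 2 decimals); only "large" is treated
as significant.  Ordered per-subsection niches are segmented into up to four
ontogenetic periods (initial, first stable, change, main stable) from the
categorical overlap structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "NichePosterior",
    "OverlapMatrix",
    "PeriodSegmentation",
    "OverlapCategory",
    "fit_niche_posterior",
    "niche_size",
    "niche_size_distribution",
    "overlap_probability",
    "categorize_overlap",
    "overlap_matrix",
    "classify_periods",
]


class OverlapCategory(str, Enum):
    NONE = "none"
    MEDIUM = "medium"
    LARGE = "large"


@dataclass(frozen=True)
class NichePosterior:
    """Posterior draws of a bivariate-normal niche."""

    label: str
    n_points: int
    mu: np.ndarray      # (n_draws, 2)
    sigma: np.ndarray   # (n_draws, 2, 2)
    alpha: float = 0.95
    x_bar: np.ndarray | None = None
    sample_cov: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class OverlapMatrix:
    """Directional overlap probabilities p[i, j] = P(member of i in region j)."""

    labels: list
    p: np.ndarray                # (k, k)
    category: np.ndarray         # (k, k) of OverlapCategory
    alpha: float = 0.95

    def symmetrized(self) -> np.ndarray:
        return 0.5 * (self.p + self.p.T)


@dataclass(frozen=True)
class PeriodSegmentation:
    """Ontogenetic period label per ordered subsection."""

    indices: list            # ordered subsection labels/indices
    labels: list             # period name per index
    boundaries: dict         # period -> (first, last) positional bounds, or None


def fit_niche_posterior(points: np.ndarray, n_draws: int = 1000,
                        alpha: float = 0.95,
                        seed: int | np.random.Generator | None = None,
                        label: str = "") -> NichePosterior:
    """Draw (μ, Σ) from the noninformative normal–inverse-Wishart posterior."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("insufficient niche data: need n >= 3")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    x_bar = pts.mean(axis=0)
    s = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(s) < 2 or np.linalg.det(s) <= 0:
        raise ValueError("insufficient niche data: singular sample covariance")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    sigma = stats.invwishart.rvs(df=n - 1, scale=(n - 1) * s,
                                 size=n_draws, random_state=rng)
    sigma = sigma.reshape(n_draws, 2, 2)
    chol = np.linalg.cholesky(sigma / n)
    z = rng.standard_normal((n_draws, 2))
    mu = x_bar + np.einsum("dij,dj->di", chol, z)
    return NichePosterior(label=label, n_points=n, mu=mu, sigma=sigma,
                          alpha=alpha, x_bar=x_bar, sample_cov=s)


def niche_size(cov: np.ndarray, alpha: float = 0.95) -> float:
    """Area of the α-probability ellipse of a bivariate normal.

    area = π · χ²₂(α) · √det Σ  (units: ‰ × TP).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    cov = np.asarray(cov, dtype=float)
    det = np.linalg.det(cov)
    if det <= 0 or not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric positive-definite")
    q = stats.chi2.ppf(alpha, df=2)
    return float(np.pi * q * np.sqrt(det))


def niche_size_distribution(posterior: NichePosterior,
                            alpha: float | None = None) -> dict:
    """Posterior mean and central 95% interval of the niche area."""
    alpha = posterior.alpha if alpha is None else alpha
    q = stats.chi2.ppf(alpha, df=2)
    dets = np.linalg.det(posterior.sigma)
    areas = np.pi * q * np.sqrt(dets)
    lo, hi = np.percentile(areas, [2.5, 97.5])
    return {"mean": float(areas.mean()), "q025": float(lo), "q975": float(hi),
            "areas": areas}


def _directional_overlap(a: NichePosterior, b: NichePosterior,
                         alpha: float, n_mc: int,
                         rng: np.random.Generator) -> float:
    """Mean over paired draws of P(x ~ N(μa, Σa) inside b's α-region)."""
    q = stats.chi2.ppf(alpha, df=2)
    n_draws = min(a.n_draws, b.n_draws)
    same = a is b
    total = 0.0
    for d in range(n_draws):
        mu_a, sig_a = a.mu[d], a.sigma[d]
        mu_b, sig_b = (mu_a, sig_a) if same else (b.mu[d], b.sigma[d])
        la = np.linalg.cholesky(sig_a)
        x = mu_a + rng.standard_normal((n_mc, 2)) @ la.T
        diff = x - mu_b
        sol = np.linalg.solve(sig_b, diff.T)
        maha2 = np.einsum("ij,ji->i", diff, sol)
        total += np.mean(maha2 <= q)
    return total / n_draws


def overlap_probability(a: NichePosterior, b: NichePosterior,
                        alpha: float = 0.95, n_mc: int = 1000,
                        seed: int | np.random.Generator | None = None,
                        ) -> tuple[float, float]:
    """Directional overlap probabilities (p(a→b), p(b→a)).

    ``n_mc`` is the number of Monte Carlo points per posterior draw.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    p_ab = _directional_overlap(a, b, alpha, n_mc, rng)
    p_ba = _directional_overlap(b, a, alpha, n_mc, rng)
    return p_ab, p_ba


def categorize_overlap(p: float) -> OverlapCategory:
    """Categorical overlap: ≤0.29 none, 0.30–0.60 medium, ≥0.61 large.

    p is first rounded half-up to 2 decimals (the printed bins leave gaps at
    (0.29, 0.30) and (0.60, 0.61)).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("overlap probability must be in [0, 1]")
    r = float(Decimal(repr(float(p))).quantize(Decimal("0.01"),
                                               rounding=ROUND_HALF_UP))
    if r <= 0.29:
        return OverlapCategory.NONE
    if r <= 0.60:
        return OverlapCategory.MEDIUM
    return OverlapCategory.LARGE


def is_significant_overlap(category: OverlapCategory) -> bool:
    """Only large overlap is treated as significant."""
    return category is OverlapCategory.LARGE


def overlap_matrix(posteriors: Sequence[NichePosterior],
                   alpha: float = 0.95, n_mc: int = 1000,
                   seed: int | np.random.Generator | None = None,
                   ) -> OverlapMatrix:
    """Full directional overlap matrix over a list of niches."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    k = len(posteriors)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            p[i, j] = _directional_overlap(posteriors[i], posteriors[j],
                                           alpha, n_mc, rng)
    cat = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            cat[i, j] = categorize_overlap(p[i, j])
    return OverlapMatrix(labels=[q.label for q in posteriors], p=p,
                         category=cat, alpha=alpha)


def _all_large(large: np.ndarray, members: Sequence[int]) -> bool:
    for ii, i in enumerate(members):
        for j in members[ii + 1:]:
            if not large[i, j]:
                return False
    return True


def classify_periods(overlap: OverlapMatrix) -> PeriodSegmentation:
    """Segment ordered subsections into up to four ontogenetic periods.

    Works on the symmetrized overlap matrix.  Rule: (1) main_stable is the
    longest terminal run whose members all pairwise overlap largely; (2) within
    the remaining prefix, initial is the longest leading internally-large run
    whose members have no large overlap with anything after the run; (3)
    first_stable is the longest internally all-large run (length ≥ 2) starting
    right after initial; (4) change is everything between first_stable and
    main_stable.  Empty periods are permitted and reported as None.
    """
    k = len(overlap.labels)
    if k < 4:
        raise ValueError("too few subsections to segment (need >= 4)")
    psym = overlap.symmetrized()
    large = np.empty((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            large[i, j] = (i == j) or is_significant_overlap(
                categorize_overlap(psym[i, j]))

    # (1) main stable: longest terminal all-large run
    m = 1
    for cand in range(2, k + 1):
        if _all_large(large, list(range(k - cand, k))):
            m = cand
    main_start = k - m
    prefix_end = main_start  # exclusive

    # (2) initial: leading run, internally large, isolated from everything after
    init_end = 0
    for e in range(prefix_end):
        run = list(range(e + 1))
        if not _all_large(large, run):
            break
        if all(not large[i, j] for i in run for j in range(e + 1, k)):
            init_end = e + 1

    # (3) first stable: maximal all-large run from init_end, length >= 2
    fs_start, fs_end = init_end, init_end
    e = init_end
    while e < prefix_end and _all_large(large, list(range(fs_start, e + 1))):
        e += 1
    if e - fs_start >= 2:
        fs_end = e

    labels = ["change"] * k
    for i in range(init_end):
        labels[i] = "initial"
    for i in range(fs_start, fs_end):
        labels[i] = "first_stable"
    for i in range(main_start, k):
        labels[i] = "main_stable"

    def bounds(name: str):
        pos = [i for i, lb in enumerate(labels) if lb == name]
        return (pos[0], pos[-1]) if pos else None

    boundaries = {name: bounds(name)
                  for name in ("initial", "first_stable", "change",
                               "main_stable")}
    return PeriodSegmentation(indices=list(overlap.labels), labels=labels,
                              boundaries=boundaries)
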