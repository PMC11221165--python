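"""Seeded generator of synthetic squid populations with known ground truth.

The generator emulates the structure of beak increment-profile isotope
datasets: two species sampled in a handful of time series spanning
1844–2023, a few to a dozen individuals per series, 8–23 crest subsections
per beak.  Each individual's true corrected δ13C and trophic-position (TP)
profiles follow a piecewise-linear ontogenetic trend (a main increase over the
anterior subsections, a much slower rate after) plus a per-individual offset
(between-individual heterogeneity, controlling the specialization index) and
within-individual noise.  Raw measurements then *embed* the baseline fields
with the exact sign convention the corrections module removes:

    raw δ15N = baseline_δ15N(loc, year) − 4.8 + TEF · (TP_true − 1)
    raw δ13C = δ13C_true − d13c_correction(loc, year)

so the correction pipeline inverts the embedding exactly, making
baseline-correction correctness testable to machine precision.  C:N ratios
are drawn inside the acceptance window with a configurable outlier fraction
falling outside it.  A fixed seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .beak_geometry import (AllometryCoefficients, PowerLaw, ml_at_crest,
                            mass_from_ml, subsection_layout)
from .corrections import CHITIN_OFFSET, DEFAULT_TEF_POLICY
from .isoscape import IsoscapeConfig, d13c_correction, snap_to_grid

__all__ = [
    "PiecewiseTrend",
    "PopulationParams",
    "SyntheticDataset",
    "SYNTHETIC_ALLOMETRY",
    "generate_population",
    "generate_scenario",
    "default_scenario",
    "true_specialization",
]

#: Self-consistent synthetic allometries (ML in mm, W in g).  These are *not*
#: published coefficients; they are chosen so back-calculated sizes fall in
#: realistic ranges (ML ~7 mm at subsection 1, ~60 mm at subsection 8).
SYNTHETIC_ALLOMETRY = AllometryCoefficients(
    ml_from_url={sp: PowerLaw(16.0, 1.05)
                 for sp in ("G_fabricii", "T_sagittatus")},
    ml_from_ucl={sp: PowerLaw(7.0, 1.05)
                 for sp in ("G_fabricii", "T_sagittatus")},
    w_from_ml={sp: PowerLaw(2e-5, 3.0)
               for sp in ("G_fabricii", "T_sagittatus")},
)


@dataclass(frozen=True)
class PiecewiseTrend:
    """Two-rate piecewise-linear ontogenetic trend over subsection index.

    value(t) = start + rate_main · (clip(t, main_from, main_to) − main_from)
                     + rate_after · max(0, t − main_to)
    """

    start_value: float
    rate_main: float       # per subsection, over [main_from, main_to]
    main_from: int = 1
    main_to: int = 4
    rate_after: float = 0.0

    def value(self, index) -> np.ndarray:
        t = np.asarray(index, dtype=float)
        main = np.clip(t, self.main_from, self.main_to) - self.main_from
        after = np.maximum(0.0, t - self.main_to)
        return self.start_value + self.rate_main * main + self.rate_after * after


@dataclass(frozen=True)
class PopulationParams:
    """Ground-truth parameters of one synthetic time series."""

    species: str = "G_fabricii"
    time_series: str = "2010s"
    year: int = 2014
    lat_range: tuple[float, float] = (62.0, 74.0)
    lon_range: tuple[float, float] = (-60.0, -5.0)
    n_individuals: int = 10
    n_subsections_range: tuple[int, int] = (8, 23)
    d13c_trend: PiecewiseTrend = PiecewiseTrend(
        start_value=-18.3, rate_main=0.33, main_from=1, main_to=4,
        rate_after=-0.05)
    tp_trend: PiecewiseTrend = PiecewiseTrend(
        start_value=3.3, rate_main=0.25, main_from=1, main_to=5,
        rate_after=0.04)
    sigma_between_d13c: float = 0.37
    sigma_within_d13c: float = 0.30
    sigma_between_tp: float = 0.06
    sigma_within_tp: float = 0.25
    cn_mean: float = 3.45
    cn_sd: float = 0.12
    p_cn_outlier: float = 0.05
    allometry: AllometryCoefficients = SYNTHETIC_ALLOMETRY

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        lo, hi = self.n_subsections_range
        if lo < 8 or hi < lo:
            raise ValueError("n_subsections_range must be within [8, inf)")
        for name in ("sigma_between_d13c", "sigma_within_d13c",
                     "sigma_between_tp", "sigma_within_tp", "cn_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.p_cn_outlier <= 1.0):
            raise ValueError("p_cn_outlier must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """Generated tables: specimens, raw subsections and per-row ground truth."""

    beaks: pd.DataFrame
    subsections: pd.DataFrame
    truth: pd.DataFrame


def true_specialization(sigma_between: float, sigma_within: float) -> float:
    """Closed-form detrended specialization index σw² / (σb² + σw²)."""
    total = sigma_between ** 2 + sigma_within ** 2
    if total <= 0:
        raise ValueError("at least one variance component must be positive")
    return sigma_within ** 2 / total


def _draw_cn(rng: np.random.Generator, params: PopulationParams) -> float:
    if rng.uniform() < params.p_cn_outlier:
        if rng.uniform() < 0.5:
            return float(rng.uniform(2.60, 2.89))
        return float(rng.uniform(4.00, 4.40))
    while True:  # truncated normal inside the acceptance window
        v = rng.normal(params.cn_mean, params.cn_sd)
        if 2.90 <= v <= 3.99:
            return float(v)


def generate_population(params: PopulationParams,
                        isoscape_config: IsoscapeConfig | None = None,
                        seed: int | np.random.Generator | None = None,
                        ) -> SyntheticDataset:
    """Generate one time series of beaks with raw measurements and truth."""
    config = isoscape_config or IsoscapeConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    tef = DEFAULT_TEF_POLICY[params.species]

    beak_rows, sub_rows, truth_rows = [], [], []
    nmin, nmax = params.n_subsections_range

    def _s_true(sb, sw):
        # undefined (NaN) when both variance components vanish
        return true_specialization(sb, sw) if sb + sw > 0 else float("nan")

    s_true_d13c = _s_true(params.sigma_between_d13c, params.sigma_within_d13c)
    s_true_tp = _s_true(params.sigma_between_tp, params.sigma_within_tp)

    for i in range(params.n_individuals):
        iid = f"{params.species}_{params.time_series}_{i + 1:02d}"
        lat = float(rng.uniform(*params.lat_range))
        lon = float(rng.uniform(*params.lon_range))
        n_target = int(rng.integers(nmin, nmax + 1))
        crest = 4.0 * n_target / 3.0
        bins = subsection_layout(crest)
        n_sub = len(bins)
        latc, lonc = snap_to_grid(lat, lon, config)
        iso = d13c_correction(latc, lonc, params.year, config)

        off_c = float(rng.normal(0.0, params.sigma_between_d13c))
        off_tp = float(rng.normal(0.0, params.sigma_between_tp))
        idx = np.arange(1, n_sub + 1)
        d13c_true = (params.d13c_trend.value(idx) + off_c
                     + rng.normal(0.0, params.sigma_within_d13c, n_sub))
        tp_true = (params.tp_trend.value(idx) + off_tp
                   + rng.normal(0.0, params.sigma_within_tp, n_sub))

        ml = ml_at_crest(crest, params.species, params.allometry)
        beak_rows.append({
            "individual_id": iid, "species": params.species,
            "time_series": params.time_series, "year": params.year,
            "lat": lat, "lon": lon, "source": "trawl",
            "url_mm": crest / 2.5, "ucl_mm": crest, "ml_mm": ml,
            "w_g": mass_from_ml(ml, params.species, params.allometry),
        })
        for t, (start, end) in enumerate(bins, start=1):
            d15n_raw = (iso.d15n_baseline - CHITIN_OFFSET
                        + tef * (tp_true[t - 1] - 1.0))
            d13c_raw = d13c_true[t - 1] - iso.d13c_correction
            sub_rows.append({
                "individual_id": iid, "index": t,
                "start_mm": start, "end_mm": end,
                "d13c_raw": d13c_raw, "d15n_raw": d15n_raw,
                "cn_ratio": _draw_cn(rng, params),
                "mass_mg": float(rng.uniform(0.3, 0.5)),
            })
            truth_rows.append({
                "individual_id": iid, "index": t,
                "d13c_true": d13c_true[t - 1], "tp_true": tp_true[t - 1],
                "offset_d13c": off_c, "offset_tp": off_tp,
                "s_true_d13c": s_true_d13c, "s_true_tp": s_true_tp,
            })
    return SyntheticDataset(beaks=pd.DataFrame(beak_rows),
                            subsections=pd.DataFrame(sub_rows),
                            truth=pd.DataFrame(truth_rows))


def default_scenario() -> list[PopulationParams]:
    """Scenario pack mirroring the study design: two species, 1844–2018."""
    base = PopulationParams()
    gf = [("1900s", 1900, 9, (8, 10)), ("1930s", 1933, 7, (9, 12)),
          ("1970s", 1977, 9, (10, 12)), ("2000s", 2004, 10, (11, 14)),
          ("2010s", 2014, 10, (15, 17)), ("contemporary", 2017, 13, (11, 17))]
    ts = [("1840s", 1844, 4, (12, 15)), ("1880s", 1881, 10, (12, 15)),
          ("1890s", 1897, 10, (15, 20)), ("contemporary", 2018, 7, (10, 23))]
    pops = [replace(base, species="G_fabricii", time_series=label, year=year,
                    n_individuals=n, n_subsections_range=rng)
            for label, year, n, rng in gf]
    pops += [replace(base, species="T_sagittatus", time_series=label,
                     year=year, n_individuals=n, n_subsections_range=rng,
                     lat_range=(60.0, 65.0), lon_range=(-25.0, -6.0),
                     d13c_trend=replace(base.d13c_trend, start_value=-18.8),
                     tp_trend=replace(base.tp_trend, start_value=3.0))
             for label, year, n, rng in ts]
    return pops


def generate_scenario(populations: Sequence[PopulationParams] | None = None,
                      isoscape_config: IsoscapeConfig | None = None,
                      seed: int | None = 0) -> SyntheticDataset:
    """Generate and concatenate a list of populations under one seed."""
    populations = populations if populations is not None else default_scenario()
    rng = np.random.default_rng(seed)
    parts = [generate_population(p, isoscape_config, rng) for p in populations]
    return SyntheticDataset(
        beaks=pd.concat([d.beaks for d in parts], ignore_index=True),
        subsections=pd.concat([d.subsections for d in parts],
                              ignore_index=True),
        truth=pd.concat([d.truth for d in parts], ignore_index=True),
    )
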