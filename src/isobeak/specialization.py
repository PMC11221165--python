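"""Individual specialization index from within- vs among-individual variance.

For each individual in a time series and each metric (corrected δ13C or
trophic position) the index is

    s = Var_within / (Var_among + Var_within)

where Var_within is the sample variance of the focal individual's values along
its beak crest and Var_among is the variance among individuals of the same
time series.  s = 1 means the individual spans the population's full breadth
(extreme generalist); s → 0 means an extreme specialist.  This is the
WIC/(BIC + WIC) structure of classical individual-specialization theory
computed per individual rather than population-averaged.

"Among individuals" defaults to the variance of per-individual means (the
between-individual component); the pooled variance of all subsection values is
available via ``among="pooled"``.  Sample variances use the n−1 denominator
throughout (time series hold as few as 2 individuals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SpecializationResult", "specialization_index",
           "specialization_table"]


@dataclass(frozen=True)
class SpecializationResult:
    individual_id: str
    metric: str
    s: float
    within_var: float
    among_var: float
    n_subsections: int
    n_individuals: int


def _sample_var(values: np.ndarray) -> float:
    return float(np.var(values, ddof=1))


def specialization_index(individual_id: str,
                         population_series: Mapping[str, Sequence[float]],
                         metric: str = "d13C",
                         among: str = "means") -> SpecializationResult:
    """Specialization index of one individual within its time series.

    Parameters
    ----------
    individual_id
        Focal individual; must be a key of ``population_series``.
    population_series
        Mapping individual id → ordered metric values along the crest, for
        every individual of the time series (corrected values only).
    among
        "means": variance of per-individual means (default);
        "pooled": variance of all subsection values pooled.
    """
    if among not in ("means", "pooled"):
        raise ValueError("among must be 'means' or 'pooled'")
    if individual_id not in population_series:
        raise KeyError(f"{individual_id!r} not in population series")
    if len(population_series) < 2:
        raise ValueError("specialization undefined with < 2 individuals")
    focal = np.asarray(population_series[individual_id], dtype=float)
    if focal.size < 2:
        raise ValueError("specialization undefined with < 2 subsections")
    within = _sample_var(focal)
    if among == "means":
        means = np.array([np.mean(np.asarray(v, dtype=float))
                          for v in population_series.values()])
        among_var = _sample_var(means)
    else:
        pooled = np.concatenate(
            [np.asarray(v, dtype=float) for v in population_series.values()])
        among_var = _sample_var(pooled)
    denom = among_var + within
    if denom <= 0:
        raise ValueError("degenerate population: zero total variance")
    return SpecializationResult(
        individual_id=individual_id,
        metric=metric,
        s=within / denom,
        within_var=within,
        among_var=among_var,
        n_subsections=int(focal.size),
        n_individuals=len(population_series),
    )


def specialization_table(corrected: pd.DataFrame,
                         by: str = "time_series",
                         metrics: Mapping[str, str] | None = None,
                         among: str = "means") -> pd.DataFrame:
    """Index for every individual and metric, grouped by ``by``.

    ``corrected`` needs columns individual_id, ``by``, qc_pass and the metric
    value columns (default d13c_corrected → metric "d13C" and
    trophic_position → "TP").  Only qc-passing subsections enter; groups with
    fewer than 2 individuals are skipped.
    """
    metrics = metrics or {"d13C": "d13c_corrected", "TP": "trophic_position"}
    if "qc_pass" in corrected.columns:
        corrected = corrected[corrected["qc_pass"].astype(bool)]
    rows = []
    for group, gdf in corrected.groupby(by, sort=True):
        series_ids = sorted(gdf["individual_id"].unique())
        if len(series_ids) < 2:
            continue
        for metric, col in metrics.items():
            pop = {iid: gdf.loc[gdf["individual_id"] == iid, col].to_numpy()
                   for iid in series_ids}
            pop = {iid: v for iid, v in pop.items() if v.size >= 2}
            if len(pop) < 2:
                continue
            for iid in pop:
                r = specialization_index(iid, pop, metric=metric, among=among)
                rows.append({by: group, "individual_id": iid,
                             "metric": metric, "s": r.s,
                             "within_var": r.within_var,
                             "among_var": r.among_var,
                             "n_subsections": r.n_subsections,
                             "n_individuals": r.n_individuals})
    return pd.DataFrame(rows)
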