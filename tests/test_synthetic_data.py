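"""Generator ground truth, determinism, and pipeline round trips."""

import numpy as np
import pandas as pd
import pytest

import isobeak as ib
from isobeak.io import (corrected_frame, specimens_from_frame,
                        subsections_from_frame)
from isobeak.specialization import specialization_table
from isobeak.synthetic_data import (PiecewiseTrend, PopulationParams,
                                    generate_population, generate_scenario,
                                    true_specialization)


def _correct(dataset):
    frames = []
    for sp in specimens_from_frame(dataset.beaks):
        subs = subsections_from_frame(dataset.subsections, sp.individual_id)
        frames.append(corrected_frame(ib.correct_profile(sp, subs), sp))
    return pd.concat(frames, ignore_index=True)


def test_trend_evaluation():
    tr = PiecewiseTrend(start_value=-18.0, rate_main=0.33, main_from=1,
                        main_to=4, rate_after=-0.05)
    assert tr.value(1) == pytest.approx(-18.0)
    assert tr.value(4) == pytest.approx(-18.0 + 3 * 0.33)
    assert tr.value(6) == pytest.approx(-18.0 + 3 * 0.33 - 2 * 0.05)


@pytest.mark.parametrize("sb,sw,expect", [(1.0, 1.0, 0.5), (1.0, 0.0, 0.0),
                                          (1.0, 2.0, 0.8)])
def test_true_specialization_closed_form(sb, sw, expect):
    assert true_specialization(sb, sw) == pytest.approx(expect)


def test_true_specialization_degenerate():
    with pytest.raises(ValueError):
        true_specialization(0.0, 0.0)


def test_fixed_seed_identical_bytes():
    a = generate_population(PopulationParams(n_individuals=3), seed=11)
    b = generate_population(PopulationParams(n_individuals=3), seed=11)
    assert a.subsections.to_csv(index=False) == b.subsections.to_csv(
        index=False)
    assert a.beaks.to_csv(index=False) == b.beaks.to_csv(index=False)
    c = generate_population(PopulationParams(n_individuals=3), seed=12)
    assert a.subsections.to_csv(index=False) != c.subsections.to_csv(
        index=False)


def test_schema_matches_io_contracts():
    data = generate_population(PopulationParams(n_individuals=2), seed=0)
    assert len(specimens_from_frame(data.beaks)) == 2
    subs = subsections_from_frame(data.subsections)
    assert all(s.end_mm > s.start_mm for s in subs)
    assert all(8 <= n for n in
               data.subsections.groupby("individual_id")["index"].max())


def test_round_trip_exact_at_zero_noise():
    params = PopulationParams(sigma_within_d13c=0.0, sigma_within_tp=0.0,
                              p_cn_outlier=0.0, n_individuals=4)
    data = generate_population(params, seed=2)
    corr = _correct(data).merge(data.truth, on=["individual_id", "index"])
    assert np.abs(corr.d13c_corrected - corr.d13c_true).max() < 0.02
    assert np.abs(corr.trophic_position - corr.tp_true).max() < 0.02


def test_specialist_limit_zero_within_noise():
    params = PopulationParams(sigma_within_d13c=0.0, sigma_within_tp=0.0,
                              p_cn_outlier=0.0, n_individuals=6,
                              d13c_trend=PiecewiseTrend(-18.0, 0.0),
                              tp_trend=PiecewiseTrend(3.5, 0.0))
    data = generate_population(params, seed=3)
    tab = specialization_table(_correct(data))
    assert (tab["s"] < 1e-12).all()


def test_generalist_limit_zero_between_variance():
    params = PopulationParams(sigma_between_d13c=0.0, sigma_between_tp=0.0,
                              p_cn_outlier=0.0, n_individuals=10,
                              n_subsections_range=(20, 23),
                              d13c_trend=PiecewiseTrend(-18.0, 0.0),
                              tp_trend=PiecewiseTrend(3.5, 0.0))
    data = generate_population(params, seed=4)
    tab = specialization_table(_correct(data))
    # among variance is only mean-sampling noise: s near its upper limit
    assert tab["s"].mean() > 0.85


def test_cn_outlier_accounting():
    params = PopulationParams(n_individuals=30, p_cn_outlier=0.10,
                              n_subsections_range=(12, 16))
    data = generate_population(params, seed=5)
    frac = 1.0 - data.subsections["cn_ratio"].between(2.90, 3.99).mean()
    n = len(data.subsections)
    tol = 3 * np.sqrt(0.10 * 0.90 / n)
    assert frac == pytest.approx(0.10, abs=tol)


def test_anterior_rate_recovery():
    params = PopulationParams(
        n_individuals=10, sigma_within_d13c=0.1, p_cn_outlier=0.0,
        d13c_trend=PiecewiseTrend(-18.0, 0.33, main_from=1, main_to=4,
                                  rate_after=-0.05))
    data = generate_population(params, seed=6)
    corr = _correct(data)
    slopes = []
    for _, g in corr[corr["index"] <= 4].groupby("individual_id"):
        slopes.append(np.polyfit(g["index"], g["d13c_corrected"], 1)[0])
    assert np.mean(slopes) == pytest.approx(0.33, abs=0.05)


def test_scenario_pack_structure():
    data = generate_scenario(seed=0)
    assert set(data.beaks["species"]) == {"G_fabricii", "T_sagittatus"}
    gf = data.beaks[data.beaks["species"] == "G_fabricii"]
    assert gf["time_series"].nunique() == 6
    ts = data.beaks[data.beaks["species"] == "T_sagittatus"]
    assert ts["time_series"].nunique() == 4
    assert data.beaks["year"].min() == 1844
    per_series = data.beaks.groupby(["species", "time_series"])[
        "individual_id"].nunique()
    assert per_series.between(2, 13).all()


def test_params_validation():
    with pytest.raises(ValueError):
        PopulationParams(n_individuals=1)
    with pytest.raises(ValueError):
        PopulationParams(n_subsections_range=(5, 10))
    with pytest.raises(ValueError):
        PopulationParams(sigma_within_d13c=-1.0)
    with pytest.raises(ValueError):
        PopulationParams(p_cn_outlier=1.5)
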