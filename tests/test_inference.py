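"""Trend regression, seasonal profiles, year-round tabulation, comparisons."""

import numpy as np
import pandas as pd
import pytest

import itnuse as iu

from conftest import make_households


def _summaries(points, stype="DHS"):
    return pd.DataFrame(
        [
            {
                "survey_id": f"{stype}{i}",
                "survey_type": stype,
                "survey_year": year,
                "pct_nets_used": pct,
            }
            for i, (year, pct) in enumerate(points)
        ]
    )


def test_constant_response_gives_zero_slope():
    fit = iu.fit_trend(_summaries([(2010, 70.0), (2015, 70.0), (2020, 70.0)]),
                       model="by_type_slope")
    assert fit["DHS:year"].estimate == pytest.approx(0.0, abs=1e-12)
    assert fit["DHS:intercept"].estimate == pytest.approx(70.0)


def test_three_point_slope_matches_closed_form():
    # closed-form OLS on (2010,60),(2015,70),(2020,80): slope exactly 2/yr
    fit = iu.fit_trend(_summaries([(2010, 60.0), (2015, 70.0), (2020, 80.0)]),
                       model="by_type_slope")
    assert fit["DHS:year"].estimate == pytest.approx(2.0, abs=1e-10)


def test_two_point_fit_agrees_with_exact_line():
    pts = [(2010, 55.0), (2014, 63.0), (2010, 55.0), (2014, 63.0)]
    fit = iu.fit_trend(_summaries(pts), model="by_type_slope")
    assert fit["DHS:year"].estimate == pytest.approx(2.0, rel=1e-10)
    assert fit["DHS:intercept"].estimate == pytest.approx(55.0 - 2.0 * 2010, rel=1e-10)


def test_type_offset_recovers_noiseless_offset_exactly():
    df = pd.concat(
        [
            _summaries([(2010, 60.0), (2015, 65.0), (2020, 70.0)], "DHS"),
            _summaries([(2011, 68.3), (2016, 73.3), (2019, 76.3)], "MIS"),
        ],
        ignore_index=True,
    )
    fit = iu.fit_trend(df, model="type_offset")
    assert fit["MIS"].estimate == pytest.approx(7.3, abs=1e-9)
    assert fit["year"].estimate == pytest.approx(1.0, abs=1e-9)


def test_trend_invariant_to_year_recentering():
    df = pd.concat(
        [
            _summaries([(2010, 61.0), (2015, 66.0), (2020, 72.0)], "DHS"),
            _summaries([(2012, 70.0), (2018, 75.0)], "MIS"),
        ],
        ignore_index=True,
    )
    fit = iu.fit_trend(df, model="type_offset")
    shifted = df.assign(survey_year=df["survey_year"] - 2000)
    fit2 = iu.fit_trend(shifted, model="type_offset")
    assert fit2["year"].estimate == pytest.approx(fit["year"].estimate, rel=1e-9)
    assert fit2["MIS"].estimate == pytest.approx(fit["MIS"].estimate, rel=1e-9)
    assert fit2["intercept"].estimate != pytest.approx(fit["intercept"].estimate)


def test_trend_preconditions_and_rank_errors():
    with pytest.raises(iu.EstimationError):
        iu.fit_trend(_summaries([(2010, 60.0), (2015, 70.0)]))
    lonely = pd.concat(
        [_summaries([(2010, 60.0), (2015, 66.0)], "DHS"),
         _summaries([(2012, 70.0)], "MIS")],
        ignore_index=True,
    )
    with pytest.raises(iu.EstimationError, match="MIS"):
        iu.fit_trend(lonely)
    same_year = _summaries([(2015, 60.0), (2015, 65.0), (2015, 70.0)])
    with pytest.raises(iu.EstimationError, match="collinear"):
        iu.fit_trend(same_year, model="by_type_slope")


def test_flat_season_profile_stays_near_constant(default_codebook):
    cfg = iu.SynthConfig(
        survey_id="FLAT", seed=12, n_clusters=120, households_per_cluster=20,
        base_use_prob=0.7, seasonal_amplitude=0.0,
        supply_use_offsets={"not_enough": 0.0, "enough": 0.0, "more_than_enough": 0.0},
    )
    hh, _, nets = iu.generate_survey(cfg)
    harmonized, _ = iu.harmonize(nets, default_codebook)
    profile, omitted = iu.seasonal_profile(harmonized, hh)
    assert omitted == []
    for _, row in profile.iterrows():
        se = 100.0 * np.sqrt(0.7 * 0.3 / row["n_nets"])
        assert abs(row["pct_used"] - 70.0) <= 3.5 * se


def test_stratum_estimates_recompose_to_overall(default_codebook, small_survey):
    _, (hh, _, nets) = small_survey
    harmonized, _ = iu.harmonize(nets, default_codebook)
    overall = iu.tabulate_reasons(harmonized, hh, strata="none")
    by_res = iu.tabulate_reasons(harmonized, hh, strata="residence")
    used = by_res[by_res["kind"] == "used"]
    recomposed = (used["pct"] * used["weight_sum"]).sum() / used["weight_sum"].sum()
    assert recomposed == pytest.approx(
        overall[overall["kind"] == "used"]["pct"].iloc[0], abs=1e-9
    )


def test_year_round_hand_tabulation():
    hh = make_households(
        [("h1", 1.0, 3, "rural", 6), ("h2", 1.0, 3, "rural", 6),
         ("h3", 1.0, 3, "rural", 6), ("h4", 1.0, 3, "rural", 6)]
    )
    hh["uses_nets_year_round"] = pd.array([True, True, False, False], dtype="boolean")
    hh["year_round_reasons"] = ["", "", "no/few mosquitoes", "too hot"]
    res = iu.year_round_tabulation(hh)
    row = res.table.iloc[0]
    assert row["pct_yes"] == pytest.approx(50.0)
    assert row["reason:no/few mosquitoes"] == pytest.approx(25.0)
    assert row["reason:too hot"] == pytest.approx(25.0)


def test_year_round_all_yes_has_no_reason_columns():
    hh = make_households([("h1", 1.0, 3, "rural", 6), ("h2", 1.0, 3, "rural", 6)])
    hh["uses_nets_year_round"] = pd.array([True, True], dtype="boolean")
    hh["year_round_reasons"] = ["", ""]
    res = iu.year_round_tabulation(hh)
    assert res.table.iloc[0]["pct_yes"] == pytest.approx(100.0)
    assert not [c for c in res.table.columns if c.startswith("reason:")]


def test_year_round_requires_net_owners():
    hh = make_households([("h1", 1.0, 3, "rural", 6)])
    hh["uses_nets_year_round"] = pd.array([pd.NA], dtype="boolean")
    with pytest.raises(iu.EstimationError):
        iu.year_round_tabulation(hh)


def test_stratified_compare_classifications():
    est = pd.DataFrame(
        {
            "survey_id": ["s1", "s1", "s2", "s2", "s3", "s3"],
            "stratum": ["urban", "rural"] * 3,
            "estimate": [70.0, 70.0, 37.4, 58.8, 71.1, 69.8],
        }
    )
    out = iu.stratified_compare(est, "residence").set_index("survey_id")
    assert out.loc["s1", "classification"] == "no_difference"
    assert out.loc["s2", "difference_pp"] == pytest.approx(-21.4)
    assert out.loc["s2", "classification"] == "rural_higher"
    # tolerance contract: a 1.3-point gap flips with the tolerance
    assert out.loc["s3", "classification"] == "no_difference"
    strict = iu.stratified_compare(est, "residence", tolerance_pp=0.0).set_index(
        "survey_id"
    )
    assert strict.loc["s3", "classification"] == "urban_higher"


def test_stratified_compare_schema_and_missing_stratum_errors():
    with pytest.raises(iu.SchemaError):
        iu.stratified_compare(pd.DataFrame({"survey_id": [], "stratum": []}))
    est = pd.DataFrame(
        {"survey_id": ["s1"], "stratum": ["urban"], "estimate": [50.0]}
    )
    with pytest.raises(iu.EstimationError):
        iu.stratified_compare(est, "residence")


def test_panel_offset_recovered_from_microdata():
    # MIS surveys generated 7.3 points above DHS; the pooled fit recovers it
    configs = []
    for stype, bump in (("DHS", 0.0), ("MIS", 0.073)):
        for k in range(30):
            configs.append(
                iu.SynthConfig(
                    survey_id=f"{stype}{k}",
                    survey_type=stype,
                    survey_year=2005 + (k % 15),
                    seed=1000 + len(configs),
                    n_clusters=30,
                    households_per_cluster=10,
                    base_use_prob=0.65 + bump,
                    supply_use_offsets={
                        "not_enough": 0.0, "enough": 0.0, "more_than_enough": 0.0
                    },
                )
            )
    hh, _, nets = iu.generate_multi_survey_panel(configs)
    summaries = iu.survey_use_summaries(hh, nets)
    fit = iu.fit_trend(summaries, model="type_offset")
    assert abs(fit["MIS"].estimate - 7.3) <= 1.5


def test_cluster_bootstrap_is_seeded_and_sane(small_survey):
    _, (hh, _, nets) = small_survey
    a = iu.bootstrap_pct_nets_used(nets, hh, n_reps=200, seed=3)
    b = iu.bootstrap_pct_nets_used(nets, hh, n_reps=200, seed=3)
    assert a == b
    assert a.se > 0
    assert a.ci_low <= a.estimate <= a.ci_high
    # same order of magnitude as the simple binomial SE
    p = a.estimate / 100.0
    naive = 100.0 * np.sqrt(p * (1 - p) / len(nets))
    assert naive / 4 <= a.se <= naive * 6
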