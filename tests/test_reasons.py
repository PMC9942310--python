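"""Reason codebook, harmonization, and percent-of-all-nets tabulation."""

import numpy as np
import pandas as pd
import pytest

import itnuse as iu
from itnuse.reasons import MISSING_LABEL, UNMAPPED_LABEL

from conftest import make_households, make_nets


@pytest.mark.parametrize(
    "raw,category",
    [
        ("too hot", "subjective"),
        ("saving for later", "extra"),
        ("usual user didn't sleep here", "objective"),
        ("no mosquitoes", "risk_perception"),
        ("not hung", "other"),
        ("not needed last night", "other"),
        ("chemicals not safe", "fears"),
        ("prefer other method", "net_attributes"),
        ("slept outdoors", "subjective"),
    ],
)
def test_default_codebook_category_assignments(default_codebook, raw, category):
    label, cat = default_codebook.lookup("ANY-SURVEY", raw)
    assert cat == category


def test_codebook_survey_specific_rows_override_defaults(default_codebook):
    rows = pd.concat(
        [
            default_codebook.df,
            pd.DataFrame(
                [
                    {
                        "survey_id": "UG2018",
                        "raw_code": "96",
                        "raw_label": "Saving to replace other net",
                        "canonical_label": "saving to replace other net",
                        "category": "extra",
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    cb = iu.ReasonCodebook(rows)
    assert cb.lookup("UG2018", "96") == ("saving to replace other net", "extra")
    assert cb.lookup("OTHER", "96") is None


@pytest.mark.parametrize(
    "mutate",
    [
        lambda df: pd.concat([df, df.iloc[[0]]], ignore_index=True),  # dup key
        lambda df: df.assign(category=["nonsense"] + list(df["category"][1:])),
        lambda df: pd.concat(  # one label, two categories
            [
                df,
                pd.DataFrame(
                    [
                        {
                            "survey_id": "X",
                            "raw_code": "zz",
                            "raw_label": "zz",
                            "canonical_label": df["canonical_label"].iloc[0],
                            "category": "fears"
                            if df["category"].iloc[0] != "fears"
                            else "extra",
                        }
                    ]
                ),
            ],
            ignore_index=True,
        ),
    ],
)
def test_invalid_codebooks_rejected(default_codebook, mutate):
    with pytest.raises(iu.CodebookError):
        iu.ReasonCodebook(mutate(default_codebook.df.copy()))


def test_harmonize_multiple_codes_and_used_nets(default_codebook):
    nets = make_nets(
        [
            ("h1", 1, True, False, "no mosquitoes;too hot"),
            ("h1", 2, True, True, ""),
        ]
    )
    out, unmapped = iu.harmonize(nets, default_codebook)
    assert unmapped == {}
    assert out.loc[0, "reason_categories"] == "risk_perception;subjective"
    assert out.loc[1, "canonical_labels"] == ""


def test_harmonize_missing_reason_becomes_other(default_codebook):
    nets = make_nets([("h1", 1, True, False, "")])
    out, _ = iu.harmonize(nets, default_codebook)
    assert out.loc[0, "canonical_labels"] == MISSING_LABEL
    assert out.loc[0, "reason_categories"] == "other"


def test_harmonize_strict_vs_lenient_on_unmapped(default_codebook):
    rows = [("h1", 1, True, False, "too hot")] * 49 + [
        ("h2", 1, True, False, "a dialect code")
    ]
    nets = make_nets([(h, i + 1, a, b, c) for i, (h, _, a, b, c) in enumerate(rows)])
    with pytest.raises(iu.HarmonizationError, match="a dialect code"):
        iu.harmonize(nets, default_codebook, strict=True)
    out, unmapped = iu.harmonize(nets, default_codebook, strict=False)
    assert unmapped == {"T1:a dialect code": 1}
    assert (out["canonical_labels"] == UNMAPPED_LABEL).sum() == 1


def _tabulate(nets, hh, mode="single", strata="none"):
    cb = iu.load_codebook()
    harmonized, _ = iu.harmonize(nets, cb)
    return iu.tabulate_reasons(harmonized, hh, strata=strata, response_mode=mode)


def test_single_mode_complete_enumeration():
    hh = make_households([("h1", 1.0, 4, "rural", 6)])
    nets = make_nets(
        [
            ("h1", 1, True, True, ""),
            ("h1", 2, True, True, ""),
            ("h1", 3, True, True, ""),
            ("h1", 4, True, False, "no mosquitoes"),
        ]
    )
    tab = _tabulate(nets, hh)
    used = tab[tab["kind"] == "used"]["pct"].iloc[0]
    cats = tab[tab["kind"] == "category"].set_index("name")["pct"]
    assert used == pytest.approx(75.0)
    assert cats["risk_perception"] == pytest.approx(25.0)
    for cat in set(iu.CATEGORIES) - {"risk_perception"}:
        assert cats[cat] == 0.0


def test_multiple_mode_totals_exceed_100():
    hh = make_households([("h1", 1.0, 4, "rural", 6)])
    nets = make_nets(
        [("h1", 1, True, True, ""), ("h1", 2, True, False, "too hot;no mosquitoes")]
    )
    tab = _tabulate(nets, hh, mode="multiple")
    used = tab[tab["kind"] == "used"]["pct"].iloc[0]
    cats = tab[tab["kind"] == "category"].set_index("name")["pct"]
    assert used == pytest.approx(50.0)
    assert cats["subjective"] == pytest.approx(50.0)
    assert cats["risk_perception"] == pytest.approx(50.0)
    assert used + cats.sum() == pytest.approx(150.0)


def test_same_category_labels_deduplicate():
    # two subjective labels on one net count once toward 'subjective'
    hh = make_households([("h1", 1.0, 4, "rural", 6)])
    nets = make_nets(
        [("h1", 1, True, False, "too hot;don't like smell"), ("h1", 2, True, True, "")]
    )
    tab = _tabulate(nets, hh, mode="multiple")
    cats = tab[tab["kind"] == "category"].set_index("name")["pct"]
    assert cats["subjective"] == pytest.approx(50.0)
    labels = tab[tab["kind"] == "label"].set_index("name")["pct"]
    assert labels["too hot"] == pytest.approx(50.0)
    assert labels["don't like smell"] == pytest.approx(50.0)


def test_synonym_splitting_leaves_category_percents_unchanged(default_codebook):
    # 'no/few mosquitoes' and 'no mosquitoes' map to one canonical label
    hh = make_households([("h1", 1.0, 4, "rural", 6), ("h2", 1.0, 3, "rural", 6)])
    merged_nets = make_nets(
        [("h1", 1, True, False, "no mosquitoes"), ("h2", 1, True, False, "no mosquitoes")]
    )
    split_nets = make_nets(
        [("h1", 1, True, False, "no mosquitoes"), ("h2", 1, True, False, "no/few mosquitoes")]
    )
    tab_a = _tabulate(merged_nets, hh)
    tab_b = _tabulate(split_nets, hh)
    for tab in (tab_a, tab_b):
        tab.sort_values(["kind", "name"], inplace=True, ignore_index=True)
    pd.testing.assert_frame_equal(
        tab_a[tab_a["kind"] != "label"], tab_b[tab_b["kind"] != "label"]
    )
    # label rows are identical as well: both raw codes share a canonical label
    assert (
        tab_b[tab_b["kind"] == "label"]["name"].tolist()
        == tab_a[tab_a["kind"] == "label"]["name"].tolist()
    )


def test_single_mode_stacks_sum_to_100_on_random_fixtures():
    rng = np.random.default_rng(4)
    labels = ["too hot", "no mosquitoes", "saving for later", "other"]
    for trial in range(20):
        rows = []
        for i in range(int(rng.integers(3, 30))):
            used = bool(rng.random() < 0.7)
            code = "" if used else labels[rng.integers(len(labels))]
            # some unused nets get no reason at all (missing)
            if not used and rng.random() < 0.2:
                code = ""
            rows.append((f"h{i}", 1, True, used, code))
        hh = make_households(
            [(f"h{i}", float(rng.uniform(0.5, 2.0)), 3, "rural", 6) for i in range(len(rows))]
        )
        tab = _tabulate(make_nets(rows), hh)
        used_pct = tab[tab["kind"] == "used"]["pct"].iloc[0]
        total = used_pct + tab[tab["kind"] == "category"]["pct"].sum()
        assert total == pytest.approx(100.0, abs=1e-9)


def test_empty_stratum_emitted_without_estimate():
    hh = make_households([("h1", 1.0, 4, "rural", 6)])
    nets = make_nets([("h1", 1, True, True, "")])
    nets["used_last_night"] = pd.array([pd.NA], dtype="boolean")
    cb = iu.load_codebook()
    harmonized, _ = iu.harmonize(nets, cb)
    tab = iu.tabulate_reasons(harmonized, hh, strata="none")
    assert len(tab) == 1
    row = tab.iloc[0]
    assert row["n_nets"] == 0 and row["n_missing_use"] == 1
    assert np.isnan(row["pct"])


def test_supply_stratified_tabulation_uses_all_nets_for_supply():
    # household with 2 nets / 4 members is 'enough' even though only 1 is an ITN
    hh = make_households([("h1", 1.0, 4, "rural", 6)])
    nets = make_nets(
        [("h1", 1, True, True, ""), ("h1", 2, False, False, "too hot")]
    )
    tab = _tabulate(nets, hh, strata="supply")
    assert set(tab["stratum"]) == {"enough"}
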