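"""Core net-coverage indicators.

Implements the indicator set used for monitoring ITN programmes from
household-survey microdata:

* **percent of nets used last night** — weighted share of all nets observed in
  the survey that were reported used the previous night (the Roll Back Malaria
  monitoring indicator); each net inherits its household's sampling weight.
* **household net supply** — classification of households by the ratio of nets
  (ITNs *and* untreated nets) to de facto members: fewer than 0.5 nets per
  person is ``not_enough``, 0.5 up to (but excluding) 0.75 is ``enough``,
  0.75 or more is ``more_than_enough``.  A one-person household with exactly
  one net is ``enough`` rather than ``more_than_enough``.
* **population ITN access** — the proportion of the de facto population that
  could sleep under an ITN if every ITN in the household covered up to two
  people: sum over households of ``min(2 * ITNs, members)`` relative to total
  members, weighted.
* **population ITN use** — the weighted share of de facto members who actually
  slept under an ITN, overall or stratified by household supply.

Supply classification compares exact rationals (``Fraction``) or pure integer
inequalities, never floats, so households sitting exactly on the 0.5 and 0.75
boundaries are always routed to the interval that includes its lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import EstimationError, TableValidationError

NOT_ENOUGH = "not_enough"
ENOUGH = "enough"
MORE_THAN_ENOUGH = "more_than_enough"
#: Sentinel for households that own no nets; not a supply category and excluded
#: from net-level tabulations.
NO_NETS = "no_nets"
SUPPLY_CATEGORIES = (NOT_ENOUGH, ENOUGH, MORE_THAN_ENOUGH)

_KEY = ["survey_id", "household_id"]


def classify_supply(n_nets_all: int, n_members: int) -> str:
    """Classify one household's net supply.

    Parameters
    ----------
    n_nets_all : int
        Nets owned by the household, counting both ITNs and untreated nets.
    n_members : int
        De facto household members (slept there last night); must be >= 1.

    Returns
    -------
    str
        One of ``not_enough`` / ``enough`` / ``more_than_enough``, or the
        ``no_nets`` sentinel when the household owns no nets.
    """
    n_nets_all = int(n_nets_all)
    n_members = int(n_members)
    if n_members < 1:
        raise ValueError("n_members must be >= 1 to classify net supply")
    if n_nets_all < 0:
        raise ValueError("n_nets_all must be non-negative")
    if n_nets_all == 0:
        return NO_NETS
    if n_nets_all == 1 and n_members == 1:
        return ENOUGH
    ratio = Fraction(n_nets_all, n_members)
    if ratio < Fraction(1, 2):
        return NOT_ENOUGH
    if ratio < Fraction(3, 4):
        return ENOUGH
    return MORE_THAN_ENOUGH


def classify_supply_series(n_nets_all, n_members) -> np.ndarray:
    """Vectorized :func:`classify_supply` using integer inequalities.

    ``r < 1/2`` is evaluated as ``2*nets < members`` and ``r < 3/4`` as
    ``4*nets < 3*members``, which is exact for integer counts.
    """
    nets = np.asarray(n_nets_all, dtype=np.int64)
    members = np.asarray(n_members, dtype=np.int64)
    if np.any(members < 1):
        raise ValueError("n_members must be >= 1 to classify net supply")
    if np.any(nets < 0):
        raise ValueError("n_nets_all must be non-negative")
    out = np.where(
        nets == 0,
        NO_NETS,
        np.where(
            2 * nets < members,
            NOT_ENOUGH,
            np.where(4 * nets < 3 * members, ENOUGH, MORE_THAN_ENOUGH),
        ),
    ).astype(object)
    out[(nets == 1) & (members == 1)] = ENOUGH
    return out


def household_indicators(households: pd.DataFrame, nets: pd.DataFrame) -> pd.DataFrame:
    """Per-household indicator table.

    Returns one row per household with net counts, nets per person, the supply
    category, the number of members who could sleep under the household's ITNs
    at two people per ITN (``potential_itn_users``) and the corresponding
    ``access_fraction``.
    """
    counts = (
        nets.groupby(_KEY)
        .agg(n_nets_all=("net_index", "size"), n_itns=("is_itn", "sum"))
        .astype({"n_itns": int})
    )
    out = households.set_index(_KEY)[["n_defacto_members", "weight"]].join(counts)
    out[["n_nets_all", "n_itns"]] = out[["n_nets_all", "n_itns"]].fillna(0).astype(int)
    members = out["n_defacto_members"].to_numpy(dtype=np.int64)
    out["nets_per_person"] = out["n_nets_all"] / members
    out["supply"] = classify_supply_series(out["n_nets_all"], members)
    out["potential_itn_users"] = np.minimum(2 * out["n_itns"].to_numpy(), members)
    out["access_fraction"] = out["potential_itn_users"] / members
    return out.reset_index()


@dataclass(frozen=True)
class ProportionEstimate:
    """A weighted proportion (or percent) with its unweighted base counts."""

    estimate: float
    n: int
    n_missing: int

    @property
    def effective_n(self) -> float:
        return self.n


def _attach_weights(nets: pd.DataFrame, households: pd.DataFrame) -> pd.DataFrame:
    merged = nets.merge(households[_KEY + ["weight"]], on=_KEY, how="left")
    if merged["weight"].isna().any():
        bad = merged.loc[merged["weight"].isna(), _KEY].drop_duplicates()
        raise TableValidationError(
            "nets reference households absent from the household table: "
            + ", ".join("/".join(map(str, row)) for row in bad.itertuples(index=False))
        )
    return merged


def pct_nets_used(
    nets: pd.DataFrame, households: pd.DataFrame, scope: str = "all_nets"
) -> ProportionEstimate:
    """Weighted percent of nets reported used the previous night.

    ``scope`` is ``"all_nets"`` (the monitoring indicator's denominator) or
    ``"itns_only"``.  Nets with a missing use report are excluded from both
    numerator and denominator; their count is disclosed in ``n_missing``.
    """
    if scope not in ("all_nets", "itns_only"):
        raise ValueError(f"unknown scope {scope!r}")
    merged = _attach_weights(nets, households)
    if scope == "itns_only":
        merged = merged[merged["is_itn"].astype(bool)]
    known = merged["used_last_night"].notna()
    n_missing = int((~known).sum())
    merged = merged[known]
    if merged.empty:
        raise EstimationError(f"no nets with a known use status in scope {scope!r}")
    w = merged["weight"].to_numpy(dtype=float)
    used = merged["used_last_night"].astype(bool).to_numpy()
    estimate = 100.0 * float((w * used).sum() / w.sum())
    return ProportionEstimate(estimate=estimate, n=int(len(merged)), n_missing=n_missing)


def population_itn_access(
    households: pd.DataFrame, nets: pd.DataFrame, persons_per_net: int = 2
) -> ProportionEstimate:
    """Weighted proportion of the population with access to an ITN.

    Each ITN is assumed to cover up to ``persons_per_net`` people (two, by the
    standard definition); households owning no ITN contribute zero covered
    members but full member counts to the denominator.
    """
    if households.empty:
        raise EstimationError("no households available for the access estimate")
    itns = (
        nets[nets["is_itn"].astype(bool)].groupby(_KEY).size().rename("n_itns")
    )
    hh = households.set_index(_KEY)[["n_defacto_members", "weight"]].join(itns)
    hh["n_itns"] = hh["n_itns"].fillna(0).astype(int)
    hh = hh[hh["n_defacto_members"] >= 1]
    if hh.empty:
        raise EstimationError("no households with de facto members >= 1")
    members = hh["n_defacto_members"].to_numpy(dtype=float)
    covered = np.minimum(persons_per_net * hh["n_itns"].to_numpy(dtype=float), members)
    w = hh["weight"].to_numpy(dtype=float)
    est = float((w * covered).sum() / (w * members).sum())
    return ProportionEstimate(estimate=est, n=int(len(hh)), n_missing=0)


def population_itn_use(
    members: pd.DataFrame,
    households: pd.DataFrame,
    nets: pd.DataFrame | None = None,
    by_supply: bool = False,
):
    """Weighted proportion of de facto members who slept under an ITN.

    With ``by_supply=True`` (requires ``nets`` to derive the household supply
    category) returns a dict mapping each supply category present — including
    ``no_nets`` — to its stratified :class:`ProportionEstimate`.
    """
    dm = members[members["defacto"].astype(bool)]
    merged = dm.merge(
        households[_KEY + ["weight", "n_defacto_members"]], on=_KEY, how="left"
    )
    if merged.empty:
        raise EstimationError("no de facto members available")

    def _prop(df: pd.DataFrame) -> ProportionEstimate:
        known = df["slept_under_itn"].notna()
        n_missing = int((~known).sum())
        df = df[known]
        if df.empty:
            raise EstimationError("no members with a known ITN-use status")
        w = df["weight"].to_numpy(dtype=float)
        slept = df["slept_under_itn"].astype(bool).to_numpy()
        return ProportionEstimate(
            estimate=float((w * slept).sum() / w.sum()),
            n=int(len(df)),
            n_missing=n_missing,
        )

    if not by_supply:
        return _prop(merged)
    if nets is None:
        raise ValueError("nets table is required for supply-stratified use")
    hh_ind = household_indicators(households, nets).set_index(_KEY)["supply"]
    merged = merged.join(hh_ind, on=_KEY)
    return {
        cat: _prop(grp)
        for cat, grp in merged.groupby("supply", sort=True)
        if not grp.empty
    }


def survey_use_summaries(households: pd.DataFrame, nets: pd.DataFrame) -> pd.DataFrame:
    """One row per survey with the percent of nets used, ready for trend fits.

    Expects the household table to carry ``survey_type`` (written by the
    synthetic generator; supply it yourself for external data).
    """
    rows = []
    for sid, hh in households.groupby("survey_id", sort=True):
        nn = nets[nets["survey_id"] == sid]
        est = pct_nets_used(nn, hh, scope="all_nets")
        rows.append(
            {
                "survey_id": sid,
                "survey_type": hh["survey_type"].iloc[0]
                if "survey_type" in hh
                else pd.NA,
                "survey_year": int(hh["interview_year"].max()),
                "pct_nets_used": est.estimate,
                "n_nets": est.n,
                "n_missing_use": est.n_missing,
            }
        )
    return pd.DataFrame(rows)
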