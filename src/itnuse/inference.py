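"""Cross-survey and within-survey estimation.

* :func:`fit_trend` — ordinary least squares on survey-level observations
  (one unweighted point per survey): either separate year-trends per survey
  type (``by_type_slope``) or a pooled model with a common slope and
  survey-type indicator offsets relative to DHS (``type_offset``).  MIS
  surveys run during peak transmission season, so their net-use rates sit
  systematically above DHS surveys conducted in drier months; the offset term
  quantifies that contrast.
* :func:`seasonal_profile` — monthly weighted percent of nets used and the
  percent of all nets unused per reason category, pooled across surveys, for
  seasonality analyses (use peaks in transmission season while the
  "no mosquitoes" risk-perception reasons peak in the dry months).
* :func:`year_round_tabulation` — the household-level "do members of this
  household use nets all year round?" series with its linear trend test.
* :func:`stratified_compare` — per-survey differences between two strata
  (urban vs rural by default) with a tolerance-based three-way
  classification.
* :func:`bootstrap_pct_nets_used` — stratified cluster-bootstrap uncertainty
  for the weighted percent of nets used (clusters resampled with replacement
  within strata), used in place of Taylor-linearized design variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError, SchemaError
from .reasons import CATEGORIES

_KEY = ["survey_id", "household_id"]


@dataclass(frozen=True)
class Coefficient:
    estimate: float
    se: float
    pvalue: float


@dataclass
class TrendFit:
    """OLS fit over survey-level observations."""

    model_spec: str
    coefficients: dict[str, Coefficient]
    n_surveys: int

    def __getitem__(self, term: str) -> Coefficient:
        return self.coefficients[term]


_REQUIRED_SUMMARY_COLS = ("survey_id", "survey_type", "survey_year", "pct_nets_used")


def _ols(y: np.ndarray, X: pd.DataFrame, label: str) -> dict[str, Coefficient]:
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise EstimationError(
            f"design matrix for {label} is rank deficient; collinear terms among "
            f"{list(X.columns)}"
        )
    res = sm.OLS(y, X).fit()
    return {
        name: Coefficient(
            float(res.params[name]), float(res.bse[name]), float(res.pvalues[name])
        )
        for name in X.columns
    }


def fit_trend(summaries: pd.DataFrame, model: str = "type_offset") -> TrendFit:
    """Fit a linear trend across surveys.

    ``summaries`` needs one row per survey with ``survey_id``, ``survey_type``,
    ``survey_year`` and ``pct_nets_used``.  ``model="by_type_slope"`` fits
    ``pct ~ year`` within each survey type (terms ``TYPE:intercept`` /
    ``TYPE:year``); ``model="type_offset"`` fits ``pct ~ year + type`` with
    DHS as the reference level (terms ``intercept``, ``year``, ``MIS``,
    ``MICS``).  Each survey is one unweighted observation.
    """
    missing = [c for c in _REQUIRED_SUMMARY_COLS if c not in summaries.columns]
    if missing:
        raise SchemaError(f"survey summaries are missing columns {missing}")
    df = summaries.reset_index(drop=True)
    n = len(df)
    if n < 3:
        raise EstimationError("trend fits need at least three surveys")
    counts = df["survey_type"].value_counts()
    thin = sorted(counts[counts < 2].index)
    if thin:
        raise EstimationError(
            f"each included survey type needs >= 2 surveys; too few for {thin}"
        )
    y = df["pct_nets_used"].to_numpy(dtype=float)
    year = df["survey_year"].to_numpy(dtype=float)

    if model == "type_offset":
        X = pd.DataFrame({"intercept": np.ones(n), "year": year})
        for stype in ("MIS", "MICS"):
            if stype in counts.index:
                X[stype] = (df["survey_type"] == stype).to_numpy(dtype=float)
        coefs = _ols(y, X, "type_offset model")
        return TrendFit("pct_nets_used ~ year + survey_type (DHS ref)", coefs, n)

    if model == "by_type_slope":
        coefs: dict[str, Coefficient] = {}
        for stype, grp in df.groupby("survey_type", sort=True):
            Xt = pd.DataFrame(
                {
                    "intercept": np.ones(len(grp)),
                    "year": grp["survey_year"].to_numpy(dtype=float),
                }
            )
            sub = _ols(
                grp["pct_nets_used"].to_numpy(dtype=float), Xt, f"{stype} trend"
            )
            coefs[f"{stype}:intercept"] = sub["intercept"]
            coefs[f"{stype}:year"] = sub["year"]
        return TrendFit("pct_nets_used ~ year within survey_type", coefs, n)

    raise ValueError(f"unknown trend model {model!r}")


def seasonal_profile(
    nets: pd.DataFrame, households: pd.DataFrame
) -> tuple[pd.DataFrame, list[int]]:
    """Monthly use and reason-category series, pooled across surveys.

    Requires harmonized nets.  Returns ``(profile, omitted_months)`` where
    ``profile`` has one row per calendar month present, with the weighted
    percent of nets used, per-category percents of all nets, and ``n_nets``;
    months with no usable nets are listed in ``omitted_months``.
    """
    from .reasons import tabulate_reasons

    tab = tabulate_reasons(nets, households, strata="month")
    # collapse across surveys within month: combine weighted sums
    tab = tab[tab["n_nets"] > 0].copy()
    tab["month"] = tab["stratum"].astype(int)
    tab["wsum"] = tab["pct"] * tab["weight_sum"] / 100.0

    rows = []
    for month, grp in tab.groupby("month", sort=True):
        denom = float(grp[grp["kind"] == "used"]["weight_sum"].sum())
        n_nets = int(grp[grp["kind"] == "used"]["n_nets"].sum())
        row = {"month": month, "n_nets": n_nets}
        used = grp[grp["kind"] == "used"]["wsum"].sum()
        row["pct_used"] = 100.0 * used / denom
        for cat in CATEGORIES:
            num = grp[(grp["kind"] == "category") & (grp["name"] == cat)]["wsum"].sum()
            row[f"category:{cat}"] = 100.0 * num / denom
        rows.append(row)
    profile = pd.DataFrame(rows)
    present = set(profile["month"]) if not profile.empty else set()
    omitted = [m for m in range(1, 13) if m not in present]
    return profile, omitted


@dataclass
class YearRoundResult:
    """Per-year weighted year-round-use series and its linear trend test."""

    table: pd.DataFrame
    slope: float | None
    slope_se: float | None
    slope_pvalue: float | None
    n_years: int = 0


def year_round_tabulation(
    households: pd.DataFrame, nets: pd.DataFrame | None = None
) -> YearRoundResult:
    """Tabulate the household "use nets all year round?" question by year.

    Restricted to households owning at least one net (derived from ``nets``
    when given, else from a non-missing response).  Per year: the weighted
    percent answering yes, and the weighted percent of *all* net-owning
    households citing each year-round non-use reason.  With three or more
    years an OLS trend (percent-yes on year) supplies the slope and its
    p-value.
    """
    if "uses_nets_year_round" not in households.columns:
        raise SchemaError("household table has no uses_nets_year_round column")
    hh = households.copy()
    if nets is not None:
        owned = nets.groupby(_KEY).size().rename("n_nets_owned")
        hh = hh.join(owned, on=_KEY)
        hh = hh[hh["n_nets_owned"].fillna(0) >= 1]
    else:
        hh = hh[hh["uses_nets_year_round"].notna()]
    if hh.empty:
        raise EstimationError("no net-owning households with year-round responses")

    rows = []
    for year, grp in hh.groupby("interview_year", sort=True):
        known = grp[grp["uses_nets_year_round"].notna()]
        if known.empty:
            continue
        w_all = float(grp["weight"].sum())
        w = known["weight"].to_numpy(dtype=float)
        yes = known["uses_nets_year_round"].astype(bool).to_numpy()
        row = {
            "interview_year": int(year),
            "pct_yes": 100.0 * float((w * yes).sum() / w.sum()),
            "n_households": int(len(known)),
        }
        no_hh = known[~yes]
        reason_w: dict[str, float] = {}
        if "year_round_reasons" in grp.columns and not no_hh.empty:
            for wt, reasons in zip(
                no_hh["weight"].to_numpy(dtype=float),
                no_hh["year_round_reasons"].fillna(""),
            ):
                for lab in {x for x in str(reasons).split(";") if x}:
                    reason_w[lab] = reason_w.get(lab, 0.0) + wt
        for lab, wt in sorted(reason_w.items()):
            row[f"reason:{lab}"] = 100.0 * wt / w_all
        rows.append(row)
    table = pd.DataFrame(rows).fillna(0.0)

    slope = slope_se = slope_p = None
    if len(table) >= 3:
        X = pd.DataFrame(
            {
                "intercept": np.ones(len(table)),
                "year": table["interview_year"].to_numpy(dtype=float),
            }
        )
        res = sm.OLS(table["pct_yes"].to_numpy(dtype=float), X).fit()
        slope = float(res.params["year"])
        slope_se = float(res.bse["year"])
        slope_p = float(res.pvalues["year"])
    return YearRoundResult(table, slope, slope_se, slope_p, n_years=len(table))


def stratified_compare(
    estimates: pd.DataFrame,
    stratifier: str = "residence",
    levels: tuple[str, str] | None = None,
    tolerance_pp: float = 2.0,
) -> pd.DataFrame:
    """Per-survey difference between two strata with sign classification.

    ``estimates`` needs columns ``survey_id``, ``stratum``, ``estimate`` (e.g.
    the ``kind == "used"`` rows of a reason tabulation).  The difference is
    ``levels[0] - levels[1]`` in percentage points; surveys within
    ``tolerance_pp`` of zero are classified ``no_difference``, otherwise
    ``<level>_higher`` for whichever stratum is larger.
    """
    for col in ("survey_id", "stratum", "estimate"):
        if col not in estimates.columns:
            raise SchemaError(f"estimates table is missing column {col!r}")
    if levels is None:
        levels = (
            ("urban", "rural")
            if stratifier == "residence"
            else ("more_than_enough", "not_enough")
        )
    a_level, b_level = levels
    rows = []
    for sid, grp in estimates.groupby("survey_id", sort=True):
        by_level = grp.set_index("stratum")["estimate"]
        if a_level not in by_level.index or b_level not in by_level.index:
            raise EstimationError(
                f"survey {sid!r} lacks estimates for both strata {levels}"
            )
        a, b = float(by_level[a_level]), float(by_level[b_level])
        diff = a - b
        if abs(diff) <= tolerance_pp:
            label = "no_difference"
        elif diff > 0:
            label = f"{a_level}_higher"
        else:
            label = f"{b_level}_higher"
        rows.append(
            {
                "survey_id": sid,
                a_level: a,
                b_level: b,
                "difference_pp": diff,
                "classification": label,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_reps: int
    seed: int


def bootstrap_pct_nets_used(
    nets: pd.DataFrame,
    households: pd.DataFrame,
    scope: str = "all_nets",
    n_reps: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """Stratified cluster-bootstrap SE for the weighted percent of nets used.

    Clusters are resampled with replacement within each stratum; the ratio
    estimator is recomputed per replicate from per-cluster weighted sums.  The
    interval is the 2.5/97.5 percentile of the replicate distribution.
    """
    merged = nets.merge(
        households[_KEY + ["weight", "cluster_id", "stratum_id"]], on=_KEY, how="left"
    )
    if scope == "itns_only":
        merged = merged[merged["is_itn"].astype(bool)]
    elif scope != "all_nets":
        raise ValueError(f"unknown scope {scope!r}")
    merged = merged[merged["used_last_night"].notna()]
    if merged.empty:
        raise EstimationError("no nets with a known use status to bootstrap")

    merged = merged.assign(
        _num=merged["weight"] * merged["used_last_night"].astype(bool).astype(float)
    )
    per_cluster = merged.groupby(["stratum_id", "cluster_id"]).agg(
        num=("_num", "sum"), den=("weight", "sum")
    )
    point = 100.0 * per_cluster["num"].sum() / per_cluster["den"].sum()

    rng = np.random.default_rng(seed)
    num_reps = np.zeros(n_reps)
    den_reps = np.zeros(n_reps)
    for stratum, grp in per_cluster.groupby(level="stratum_id"):
        k = len(grp)
        counts = rng.multinomial(k, np.full(k, 1.0 / k), size=n_reps)
        num_reps += counts @ grp["num"].to_numpy()
        den_reps += counts @ grp["den"].to_numpy()
    reps = 100.0 * num_reps / den_reps
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(
        estimate=float(point),
        se=float(np.std(reps, ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_reps=n_reps,
        seed=seed,
    )
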