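"""Reason-for-non-use harmonization and tabulation.

Survey questionnaires ask "why was this net not used last night?" but the
answer options differ between countries and over time (nearly 80 distinct
options across surveys).  This module maps survey-specific raw response codes
through a :class:`ReasonCodebook` to canonical labels, each belonging to one
of seven broad categories::

    extra, fears, net_attributes, objective, risk_perception, subjective, other

A default codebook implementing the standard MIS option set ships with the
package; per-survey answer dialects are additional codebook rows (data), never
code changes.

Tabulation reports every estimate as a weighted percent of **all nets** in the
stratum (not of unused nets), alongside the percent of nets used, so stacked
outputs reconstruct the standard stacked presentation: in single-response surveys
``pct_used + sum(categories) == 100`` exactly, while multiple-response surveys
may total more than 100% because one net can contribute to several
categories.  A net citing two labels of the *same* category still counts once
toward that category.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import CodebookError, HarmonizationError
from .indicators import household_indicators

CATEGORIES = (
    "extra",
    "fears",
    "net_attributes",
    "objective",
    "risk_perception",
    "subjective",
    "other",
)

#: Sentinel label for an unused net with no recorded reason.
MISSING_LABEL = "missing"
#: Sentinel label for raw codes absent from the codebook (lenient mode).
UNMAPPED_LABEL = "unmapped"

_KEY = ["survey_id", "household_id"]
_COLUMNS = ["survey_id", "raw_code", "raw_label", "canonical_label", "category"]


@dataclass
class ReasonCodebook:
    """Mapping (survey_id, raw_code) -> (canonical_label, category).

    Rows with ``survey_id == "*"`` act as defaults consulted when no
    survey-specific row matches.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise CodebookError(f"codebook is missing columns {missing}")
        self.df = self.df[_COLUMNS].astype(str)
        bad_cat = sorted(set(self.df["category"]) - set(CATEGORIES))
        if bad_cat:
            raise CodebookError(f"unknown reason categories {bad_cat}")
        dup = self.df[self.df.duplicated(["survey_id", "raw_code"], keep=False)]
        if not dup.empty:
            pairs = sorted(set(map(tuple, dup[["survey_id", "raw_code"]].itertuples(index=False))))
            raise CodebookError(f"duplicate (survey_id, raw_code) entries: {pairs}")
        label_cats = self.df.groupby("canonical_label")["category"].nunique()
        conflicted = sorted(label_cats[label_cats > 1].index)
        if conflicted:
            raise CodebookError(
                f"canonical labels mapped to more than one category: {conflicted}"
            )
        self._by_key = {
            (r.survey_id, r.raw_code): (r.canonical_label, r.category)
            for r in self.df.itertuples(index=False)
        }
        self._label_category = dict(
            zip(self.df["canonical_label"], self.df["category"])
        )

    def lookup(self, survey_id: str, raw_code: str):
        """Resolve a raw code, falling back to the ``"*"`` default rows."""
        hit = self._by_key.get((survey_id, raw_code))
        if hit is None:
            hit = self._by_key.get(("*", raw_code))
        return hit

    def category_of(self, canonical_label: str) -> str | None:
        return self._label_category.get(canonical_label)

    @classmethod
    def from_file(cls, path: str | Path) -> "ReasonCodebook":
        path = Path(path)
        try:
            if path.suffix.lower() in (".yaml", ".yml"):
                rows = yaml.safe_load(path.read_text())
                df = pd.DataFrame(rows)
            else:
                df = pd.read_csv(path, dtype=str)
        except CodebookError:
            raise
        except Exception as exc:
            raise CodebookError(f"cannot parse codebook {path}: {exc}") from exc
        return cls(df)

    @classmethod
    def default(cls) -> "ReasonCodebook":
        with resources.as_file(
            resources.files("itnuse").joinpath("data/default_codebook.csv")
        ) as p:
            return cls.from_file(p)


def load_codebook(path: str | Path | None = None) -> ReasonCodebook:
    """Load a codebook file, or the bundled default when ``path`` is None."""
    if path is None:
        return ReasonCodebook.default()
    return ReasonCodebook.from_file(path)


def harmonize(
    nets: pd.DataFrame, codebook: ReasonCodebook, strict: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Attach canonical labels and categories to each net row.

    Returns ``(nets_with_labels, unmapped_counts)`` where the new columns
    ``canonical_labels`` / ``reason_categories`` are semicolon-joined and
    parallel.  Unused nets with no recorded reason receive the auditable
    sentinel ``missing`` (category ``other``).  Unknown raw codes raise
    :class:`HarmonizationError` in strict mode; in lenient mode they become
    ``unmapped`` (category ``other``) and are tallied in ``unmapped_counts``
    keyed by ``(survey_id, raw_code)``.
    """
    out = nets.copy()
    labels_col: list[str] = []
    cats_col: list[str] = []
    unmapped: dict[tuple[str, str], int] = {}

    sids = out["survey_id"].to_numpy(dtype=object)
    used = out["used_last_night"].to_numpy(dtype=object)
    raw = out["raw_reason_codes"].fillna("").to_numpy(dtype=object)

    cache: dict[tuple[str, str], tuple[str, str]] = {}
    for i in range(len(out)):
        if used[i] is True or pd.isna(used[i]):
            labels_col.append("")
            cats_col.append("")
            continue
        codes = [c for c in str(raw[i]).split(";") if c != ""]
        if not codes:
            labels_col.append(MISSING_LABEL)
            cats_col.append("other")
            continue
        labels: list[str] = []
        cats: list[str] = []
        for code in codes:
            key = (sids[i], code)
            hit = cache.get(key)
            if hit is None:
                hit = codebook.lookup(sids[i], code)
                if hit is None:
                    if strict:
                        raise HarmonizationError(
                            f"survey {sids[i]!r}: reason code {code!r} not in codebook"
                        )
                    unmapped[key] = unmapped.get(key, 0) + 1
                    hit = (UNMAPPED_LABEL, "other")
                else:
                    cache[key] = hit
            if hit[0] not in labels:
                labels.append(hit[0])
                cats.append(hit[1])
        labels_col.append(";".join(labels))
        cats_col.append(";".join(cats))

    out["canonical_labels"] = labels_col
    out["reason_categories"] = cats_col
    return out, {f"{k[0]}:{k[1]}": v for k, v in unmapped.items()}


def _split(series: pd.Series) -> pd.Series:
    return series.map(lambda s: [x for x in str(s).split(";") if x])


def _stratum_rows(
    group: pd.DataFrame, denominator_weight: float
) -> tuple[float, dict[str, float], dict[str, float]]:
    """Weighted pct used plus per-category and per-label percents of all nets."""
    w = group["weight"].to_numpy(dtype=float)
    used = group["used_last_night"].astype(bool).to_numpy()
    pct_used = 100.0 * float((w * used).sum() / denominator_weight)

    unused = group[~used]
    label_pct: dict[str, float] = {}
    cat_pct: dict[str, float] = {cat: 0.0 for cat in CATEGORIES}
    if not unused.empty:
        lab_lists = _split(unused["canonical_labels"])
        cat_lists = _split(unused["reason_categories"])
        for wt, labs, cats in zip(
            unused["weight"].to_numpy(dtype=float), lab_lists, cat_lists
        ):
            for lab in dict.fromkeys(labs):
                label_pct[lab] = label_pct.get(lab, 0.0) + wt
            for cat in dict.fromkeys(cats):
                cat_pct[cat] = cat_pct.get(cat, 0.0) + wt
        scale = 100.0 / denominator_weight
        label_pct = {k: v * scale for k, v in sorted(label_pct.items())}
        cat_pct = {k: v * scale for k, v in cat_pct.items()}
    return pct_used, cat_pct, label_pct


def tabulate_reasons(
    nets: pd.DataFrame,
    households: pd.DataFrame,
    strata: str = "none",
    response_mode: str = "single",
) -> pd.DataFrame:
    """Weighted reason tabulation per survey and stratum.

    ``strata`` is one of ``none`` (overall), ``supply`` (household net-supply
    category), ``residence`` or ``month``.  Output is tidy: one row per
    survey x stratum x (used | category | label), with columns ``pct``
    (percent of all nets in the stratum with a known use status), ``n_nets``,
    ``n_missing_use`` and ``weight_sum``.  Strata with no usable nets are
    emitted with ``n_nets = 0`` and no estimate.
    """
    if strata not in ("none", "supply", "residence", "month"):
        raise ValueError(f"unknown strata spec {strata!r}")
    if response_mode not in ("single", "multiple"):
        raise ValueError(f"unknown response_mode {response_mode!r}")
    if "canonical_labels" not in nets.columns:
        raise ValueError("nets must be harmonized before tabulation (run harmonize)")

    hh_cols = households.set_index(_KEY)
    merged = nets.join(
        hh_cols[["weight"]
        + (["residence"] if strata == "residence" else [])
        + (["interview_month"] if strata == "month" else [])],
        on=_KEY,
    )
    if strata == "supply":
        supply = household_indicators(households, nets).set_index(_KEY)["supply"]
        merged = merged.join(supply, on=_KEY)
        merged["_stratum"] = merged["supply"]
    elif strata == "residence":
        merged["_stratum"] = merged["residence"]
    elif strata == "month":
        merged["_stratum"] = merged["interview_month"].astype(str)
    else:
        merged["_stratum"] = "overall"

    label_to_cat = _label_category_map(merged)
    rows = []
    for (sid, stratum), group in merged.groupby(["survey_id", "_stratum"], sort=True):
        known = group["used_last_night"].notna()
        n_missing = int((~known).sum())
        gk = group[known]
        base = {
            "survey_id": sid,
            "stratifier": strata,
            "stratum": stratum,
            "response_mode": response_mode,
            "n_nets": int(len(gk)),
            "n_missing_use": n_missing,
        }
        if gk.empty:
            rows.append({**base, "kind": "used", "name": "used", "category": "",
                         "pct": float("nan"), "weight_sum": 0.0})
            continue
        denom = float(gk["weight"].sum())
        pct_used, cat_pct, label_pct = _stratum_rows(gk, denom)
        rows.append({**base, "kind": "used", "name": "used", "category": "",
                     "pct": pct_used, "weight_sum": denom})
        for cat in CATEGORIES:
            rows.append({**base, "kind": "category", "name": cat, "category": cat,
                         "pct": cat_pct.get(cat, 0.0), "weight_sum": denom})
        for lab, pct in label_pct.items():
            rows.append({**base, "kind": "label", "name": lab,
                         "category": label_to_cat.get(lab, ""), "pct": pct,
                         "weight_sum": denom})
    return pd.DataFrame(rows)


def _label_category_map(nets: pd.DataFrame) -> dict[str, str]:
    """Label -> category mapping recovered from the harmonized columns."""
    mapping: dict[str, str] = {}
    combos = set(
        zip(nets["canonical_labels"].fillna(""), nets["reason_categories"].fillna(""))
    )
    for labs, cats in combos:
        lab_list = [x for x in str(labs).split(";") if x]
        cat_list = [x for x in str(cats).split(";") if x]
        for lab, cat in zip(lab_list, cat_list):
            mapping.setdefault(lab, cat)
    return mapping
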