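"""Household-roster reshaping and linkage validation.

National household surveys record nets in a *wide* roster: one row per
household with repeated slots (``is_itn_1``, ``is_itn_2``, ..., one column per
attribute per slot).  Analysis runs on the *long* "net file": one row per
observed net.  :func:`reshape_wide_to_long` performs that conversion; a slot
is considered present when **any** of its attribute columns is non-missing, so
partially answered nets are never dropped.  :func:`to_wide` is the inverse,
used for round-trip checks and for emitting roster-shaped fixtures.

:func:`validate_linkage` cross-checks the three tables (orphan nets or
members, duplicate keys, member-count mismatches) and returns a report rather
than raising, so callers decide how strict to be.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError, TableValidationError

#: Attributes recorded per net slot, in canonical column order.
SLOT_ATTRS = ("is_itn", "age_months", "used_last_night", "n_users", "raw_reason_codes")

_KEY = ["survey_id", "household_id"]
_SLOT_RE = re.compile(r"^(" + "|".join(SLOT_ATTRS) + r")_(\d+)$")

_ATTR_DTYPES = {
    "is_itn": "boolean",
    "age_months": "Int64",
    "used_last_night": "boolean",
    "n_users": "Int64",
    "raw_reason_codes": object,
}


def _slot_columns(columns) -> dict[int, dict[str, str]]:
    """Map slot index -> {attr: column name}; reject malformed slot columns."""
    slots: dict[int, dict[str, str]] = {}
    for col in columns:
        for attr in SLOT_ATTRS:
            if col == attr or (
                col.startswith(attr + "_") and not _SLOT_RE.match(col)
            ):
                raise SchemaError(
                    f"malformed net-slot column {col!r}; expected "
                    f"'{attr}_<index>' with a positive integer index"
                )
        m = _SLOT_RE.match(col)
        if m:
            attr, idx = m.group(1), int(m.group(2))
            if idx < 1:
                raise SchemaError(f"net-slot column {col!r} has index < 1")
            slots.setdefault(idx, {})[attr] = col
    return slots


def reshape_wide_to_long(
    wide: pd.DataFrame, max_slots: int | None = None
) -> pd.DataFrame:
    """Convert a wide household roster into the long net file.

    Emits one row per populated slot (any attribute non-missing; an empty
    string in ``raw_reason_codes`` counts as missing).  Raises
    :class:`SchemaError` for malformed slot columns or more slots than
    ``max_slots``, and :class:`TableValidationError` for contradictory slots
    where a net is marked used yet carries reason codes.
    """
    for key in _KEY:
        if key not in wide.columns:
            raise SchemaError(f"wide table is missing key column {key!r}")
    wide = wide.reset_index(drop=True)
    slots = _slot_columns(wide.columns)
    if max_slots is not None and slots and max(slots) > max_slots:
        raise SchemaError(
            f"wide table declares slot {max(slots)} above the maximum {max_slots}"
        )

    pieces = []
    for idx in sorted(slots):
        cols = slots[idx]
        part = wide[_KEY].copy()
        part["net_index"] = idx
        for attr in SLOT_ATTRS:
            if attr in cols:
                part[attr] = wide[cols[attr]].astype(_ATTR_DTYPES[attr])
            else:
                part[attr] = pd.array([pd.NA] * len(wide), dtype=_ATTR_DTYPES[attr])
        codes = part["raw_reason_codes"]
        codes_present = codes.notna() & (codes.astype(object) != "")
        present = codes_present
        for attr in ("is_itn", "age_months", "used_last_night", "n_users"):
            present = present | part[attr].notna()
        part = part[present]
        part["_order"] = part.index
        pieces.append(part)

    if not pieces:
        long = pd.DataFrame(
            {
                col: pd.Series(dtype=_ATTR_DTYPES.get(col, object))
                for col in _KEY + ["net_index"] + list(SLOT_ATTRS)
            }
        )
        long["net_index"] = long["net_index"].astype("int64")
        return long

    long = pd.concat(pieces, ignore_index=True)
    long = long.sort_values(["_order", "net_index"], kind="stable").drop(columns="_order")
    long = long.reset_index(drop=True)
    long["net_index"] = long["net_index"].astype("int64")
    long["raw_reason_codes"] = long["raw_reason_codes"].fillna("").astype(object)

    contradictory = (long["used_last_night"] == True) & (  # noqa: E712
        long["raw_reason_codes"] != ""
    )
    if contradictory.any():
        rows = long.loc[contradictory, _KEY + ["net_index"]]
        listing = ", ".join(
            "/".join(map(str, r)) for r in rows.itertuples(index=False)
        )
        raise TableValidationError(
            f"nets marked used but carrying non-use reasons: {listing}"
        )
    return long


def to_wide(households: pd.DataFrame, nets: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`reshape_wide_to_long`.

    Returns the household table with appended slot columns ``attr_k`` for
    ``k = 1..max(net_index)``; households without nets keep all slots missing.
    """
    wide = households.copy()
    if nets.empty:
        return wide
    max_slot = int(nets["net_index"].max())
    indexed = nets.set_index(_KEY)
    wide = wide.set_index(_KEY)
    for k in range(1, max_slot + 1):
        sub = indexed[indexed["net_index"] == k]
        for attr in SLOT_ATTRS:
            col = sub[attr].reindex(wide.index)
            if _ATTR_DTYPES[attr] is not object:
                col = col.astype(_ATTR_DTYPES[attr])
            wide[f"{attr}_{k}"] = col
    return wide.reset_index()


@dataclass
class LinkageReport:
    """Findings from cross-table validation; empty lists mean a clean linkage."""

    orphan_nets: list = field(default_factory=list)
    orphan_members: list = field(default_factory=list)
    member_count_mismatches: list = field(default_factory=list)
    duplicate_households: list = field(default_factory=list)
    duplicate_nets: list = field(default_factory=list)
    duplicate_members: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.orphan_nets
            or self.orphan_members
            or self.member_count_mismatches
            or self.duplicate_households
            or self.duplicate_nets
            or self.duplicate_members
        )

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "orphan_nets": self.orphan_nets,
            "orphan_members": self.orphan_members,
            "member_count_mismatches": self.member_count_mismatches,
            "duplicate_households": self.duplicate_households,
            "duplicate_nets": self.duplicate_nets,
            "duplicate_members": self.duplicate_members,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        if self.ok:
            return "linkage OK: no findings"
        lines = ["linkage FINDINGS:"]
        for name in (
            "orphan_nets",
            "orphan_members",
            "member_count_mismatches",
            "duplicate_households",
            "duplicate_nets",
            "duplicate_members",
        ):
            items = getattr(self, name)
            if items:
                lines.append(f"  {name} ({len(items)}):")
                lines.extend(f"    {item}" for item in items[:20])
                if len(items) > 20:
                    lines.append(f"    ... and {len(items) - 20} more")
        return "\n".join(lines)


def load_survey_recode(path, survey_id: str):  # pragma: no cover - interface stub
    """Adapter interface for real survey recode files (household/member/net).

    Declared so downstream code can target a stable entry point; parsing the
    hierarchical recode formats (e.g. Stata .dta rosters with HML* variables)
    is survey-specific and intentionally not implemented here.  Implementations
    must return ``(households, members, nets)`` following the CSV schemas in
    this module and :mod:`itnuse.io`.
    """
    raise NotImplementedError(
        "no recode adapter is bundled; supply tables in the documented "
        "household/member/net schemas instead"
    )


def validate_linkage(
    households: pd.DataFrame, members: pd.DataFrame, nets: pd.DataFrame
) -> LinkageReport:
    """Cross-check household/member/net tables; returns a :class:`LinkageReport`."""
    report = LinkageReport()
    hh_keys = set(map(tuple, households[_KEY].itertuples(index=False)))

    dup_hh = households[_KEY][households.duplicated(_KEY, keep=False)]
    report.duplicate_households = sorted(
        set(map(tuple, dup_hh.itertuples(index=False)))
    )

    if not nets.empty:
        net_keys = nets[_KEY + ["net_index"]]
        dup = net_keys[net_keys.duplicated(keep=False)]
        report.duplicate_nets = sorted(set(map(tuple, dup.itertuples(index=False))))
        orphan_mask = [
            tuple(row) not in hh_keys for row in nets[_KEY].itertuples(index=False)
        ]
        report.orphan_nets = sorted(
            set(
                map(
                    tuple,
                    nets.loc[orphan_mask, _KEY + ["net_index"]].itertuples(index=False),
                )
            )
        )

    if not members.empty:
        mem_keys = members[_KEY + ["member_id"]]
        dup = mem_keys[mem_keys.duplicated(keep=False)]
        report.duplicate_members = sorted(set(map(tuple, dup.itertuples(index=False))))
        orphan_mask = [
            tuple(row) not in hh_keys for row in members[_KEY].itertuples(index=False)
        ]
        report.orphan_members = sorted(
            set(
                map(
                    tuple,
                    members.loc[orphan_mask, _KEY + ["member_id"]].itertuples(
                        index=False
                    ),
                )
            )
        )

    defacto = members[members["defacto"].astype(bool)] if not members.empty else members
    counts = (
        defacto.groupby(_KEY).size() if not members.empty else pd.Series(dtype=int)
    )
    for row in households.itertuples(index=False):
        key = (row.survey_id, row.household_id)
        actual = int(counts.get(key, 0))
        expected = int(row.n_defacto_members)
        if actual != expected:
            report.member_count_mismatches.append(
                {
                    "survey_id": key[0],
                    "household_id": key[1],
                    "expected": expected,
                    "actual": actual,
                }
            )
    return report
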