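"""Synthetic household-survey generator.

Generates linked household / member / net tables with the statistical
structure national malaria household surveys (DHS, MIS, MICS) share:

* a cluster-stratified design — clusters are assigned urban or rural (the two
  strata), drawn with unequal selection probabilities, and every household in
  a cluster inherits the inverse-probability weight (normalized to mean 1);
* household sizes from a shifted Poisson (minimum one de facto member);
* net ownership from ``Binomial(ceil(members/2) + 1, net_acquisition_rate)``,
  which produces all three supply categories including "more than enough";
* per-net use the previous night with supply-category offsets and an optional
  sinusoidal seasonal modulation peaking at ``peak_month``;
* reasons for non-use attached only to unused nets, drawn from
  residence-specific label distributions; in multiple-response mode a second,
  distinct reason is added with probability ``multi_extra_prob``;
* member-level ITN use consistent with net user counts (at most two users per
  net, never more sleepers than members).

Everything is driven by a single :class:`numpy.random.Generator` seeded from
``SynthConfig.seed``, so identical configurations reproduce byte-identical
tables.

Two member-use regimes exist.  By default, members sleep under *used* ITNs at
two per net, so population ITN use is an emergent quantity.  When
``member_itn_use_probs`` targets a supply category, the generator instead
calibrates per-household binomial draws against the two-per-ITN access cap
(water-filling expected sleepers across households) so the realized
category-level use proportion is unbiased for the configured target, then
derives net used-flags and user counts from the sleepers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SynthConfig
from .errors import ConfigurationError
from .indicators import classify_supply_series

NET_COLUMNS = [
    "survey_id",
    "household_id",
    "net_index",
    "is_itn",
    "age_months",
    "used_last_night",
    "n_users",
    "raw_reason_codes",
]


def _waterfill(target: np.ndarray, cap: np.ndarray) -> np.ndarray:
    """Distribute ``sum(target)`` across households without exceeding ``cap``.

    Starts from ``min(target, cap)`` and iteratively reallocates the clipped
    mass to households with remaining slack, proportionally to that slack.
    Returns expected sleeper counts ``e`` with ``e <= cap`` and
    ``sum(e) == min(sum(target), sum(cap))`` up to numerical tolerance.
    """
    total = float(target.sum())
    e = np.minimum(target.astype(float), cap.astype(float))
    for _ in range(100):
        deficit = total - e.sum()
        slack = cap - e
        room = slack.sum()
        if deficit <= 1e-9 or room <= 1e-12:
            break
        e = np.minimum(e + deficit * slack / room, cap)
    return e


def _within_group_rank(group_ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """0-based rank of each masked element within its (sorted) group."""
    rank = np.zeros(len(group_ids), dtype=np.int64)
    idx = np.flatnonzero(mask)
    if idx.size:
        g = group_ids[idx]
        boundaries = np.flatnonzero(np.diff(g)) + 1
        starts = np.concatenate(([0], boundaries))
        offsets = np.arange(idx.size) - np.repeat(starts, np.diff(np.concatenate((starts, [idx.size]))))
        rank[idx] = offsets
    return rank


def generate_survey(
    config: SynthConfig | dict,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one survey; returns ``(households, members, nets)``.

    Output schemas match the CSV schemas documented in the README: households
    carry design variables (cluster, stratum, normalized weight), de facto
    size, residence, interview year/month (plus ``survey_type`` metadata and,
    when configured, the year-round-use columns); members carry a de facto
    flag and ``slept_under_itn``; nets carry ITN status, age, the
    used-last-night flag (nullable), user counts, and semicolon-joined raw
    reason codes for unused nets.
    """
    if isinstance(config, dict):
        config = SynthConfig(**config)
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_c, hpc = cfg.n_clusters, cfg.households_per_cluster
    n_h = n_c * hpc

    urban_cluster = rng.random(n_c) < cfg.urban_fraction
    selection_prob = rng.uniform(0.5, 1.5, n_c)
    hh_cluster = np.repeat(np.arange(n_c), hpc)
    weight = 1.0 / selection_prob[hh_cluster]
    weight = weight / weight.mean()

    household_id = np.array([f"h{i + 1:06d}" for i in range(n_h)], dtype=object)
    cluster_id = np.array([f"c{i + 1:04d}" for i in range(n_c)], dtype=object)[hh_cluster]
    residence = np.where(urban_cluster[hh_cluster], "urban", "rural")

    members_per_hh = 1 + rng.poisson(max(cfg.household_size_mean - 1.0, 0.0), n_h)
    month = rng.choice(np.asarray(cfg.fieldwork_months, dtype=int), size=n_h)

    trials = (np.ceil(members_per_hh / 2) + 1).astype(int)
    n_nets = rng.binomial(trials, cfg.net_acquisition_rate)
    supply = classify_supply_series(n_nets, members_per_hh)

    # ---- net rows ---------------------------------------------------------
    total = int(n_nets.sum())
    hh_idx = np.repeat(np.arange(n_h), n_nets)
    start = np.cumsum(n_nets) - n_nets
    net_index = np.arange(total) - start[hh_idx] + 1

    is_itn = rng.random(total) < cfg.itn_fraction
    age_months = rng.integers(0, 60, total)
    itns_per_hh = np.bincount(hh_idx[is_itn], minlength=n_h) if total else np.zeros(n_h, int)

    use_prob_hh = np.full(n_h, cfg.base_use_prob)
    for cat, off in cfg.supply_use_offsets.items():
        use_prob_hh[supply == cat] += off
    season = 1.0 + cfg.seasonal_amplitude * np.cos(
        2.0 * np.pi * (month - cfg.peak_month) / 12.0
    )
    use_prob_hh = np.clip(use_prob_hh * season, 0.0, 1.0)
    used = rng.random(total) < use_prob_hh[hh_idx]
    missing_use = rng.random(total) < cfg.missing_use_prob

    # ---- member-use calibration (direct mode) -----------------------------
    targeted = np.zeros(n_h, dtype=bool)
    sleepers_target = np.zeros(n_h, dtype=np.int64)
    if cfg.member_itn_use_probs:
        cap = np.minimum(2 * itns_per_hh, members_per_hh)
        for cat in sorted(cfg.member_itn_use_probs):
            p = cfg.member_itn_use_probs[cat]
            mask = supply == cat
            if not mask.any():
                continue
            targeted |= mask
            e = _waterfill(p * members_per_hh[mask], cap[mask].astype(float))
            cap_m = cap[mask]
            q = np.divide(e, cap_m, out=np.zeros_like(e), where=cap_m > 0)
            sleepers_target[mask] = rng.binomial(cap_m, np.clip(q, 0.0, 1.0))
        # ITN used-flags follow from the sleeper counts in targeted households
        itn_rank = _within_group_rank(hh_idx, is_itn)
        need = np.ceil(sleepers_target / 2).astype(np.int64)
        override = targeted[hh_idx] & is_itn
        used[override] = itn_rank[override] < need[hh_idx[override]]
        missing_use[targeted[hh_idx]] = False

    used_eff = used & ~missing_use
    used_itn = used_eff & is_itn
    used_itns_per_hh = (
        np.bincount(hh_idx[used_itn], minlength=n_h) if total else np.zeros(n_h, int)
    )
    sleepers = np.where(
        targeted,
        sleepers_target,
        np.minimum(2 * used_itns_per_hh, members_per_hh),
    )

    used_itn_rank = _within_group_rank(hh_idx, used_itn)
    n_users = np.zeros(total, dtype=np.int64)
    n_users[used_itn] = np.clip(sleepers[hh_idx[used_itn]] - 2 * used_itn_rank[used_itn], 0, 2)
    used_untreated = used_eff & ~is_itn
    n_users[used_untreated] = np.minimum(2, members_per_hh[hh_idx[used_untreated]])

    # ---- reasons for non-use ----------------------------------------------
    unused = (~used) & (~missing_use)
    missing_reason = unused & (rng.random(total) < cfg.missing_reason_prob)
    draw = np.flatnonzero(unused & ~missing_reason)
    reason_strings = np.full(total, "", dtype=object)
    if draw.size:
        labels = sorted(
            set(cfg.reason_probs["rural"]) | set(cfg.reason_probs["urban"])
        )
        base = {
            res: np.array([cfg.reason_probs[res].get(lbl, 0.0) for lbl in labels])
            for res in ("rural", "urban")
        }
        res_net = residence[hh_idx[draw]]
        mo_net = month[hh_idx[draw]]
        prob = np.where(
            (res_net == "urban")[:, None], base["urban"][None, :], base["rural"][None, :]
        ).astype(float)
        if cfg.antiphase_reason_label is not None:
            j = labels.index(cfg.antiphase_reason_label)
            prob[:, j] *= 1.0 - cfg.antiphase_amplitude * np.cos(
                2.0 * np.pi * (mo_net - cfg.peak_month) / 12.0
            )
        prob /= prob.sum(axis=1, keepdims=True)
        # Gumbel-max trick: argmax of log p + Gumbel noise is a categorical
        # draw; the runner-up is a draw without replacement.
        gumbel = rng.gumbel(size=prob.shape)
        log_p = np.full_like(prob, -np.inf)
        np.log(prob, out=log_p, where=prob > 0)
        scores = log_p + gumbel
        order = np.argsort(-scores, axis=1)
        first = order[:, 0]
        if cfg.response_mode == "multiple" and len(labels) > 1:
            extra = rng.random(draw.size) < cfg.multi_extra_prob
            second = order[:, 1]
            second_ok = extra & (prob[np.arange(draw.size), second] > 0)
            for pos, net_i in enumerate(draw):
                if second_ok[pos]:
                    reason_strings[net_i] = (
                        labels[first[pos]] + ";" + labels[second[pos]]
                    )
                else:
                    reason_strings[net_i] = labels[first[pos]]
        else:
            for pos, net_i in enumerate(draw):
                reason_strings[net_i] = labels[first[pos]]

    # ---- assemble tables ---------------------------------------------------
    used_col = pd.array(used, dtype="boolean")
    used_col[missing_use] = pd.NA
    n_users_col = pd.array(n_users, dtype="Int64")
    n_users_col[missing_use] = pd.NA

    nets = pd.DataFrame(
        {
            "survey_id": cfg.survey_id,
            "household_id": household_id[hh_idx],
            "net_index": net_index.astype(np.int64),
            "is_itn": pd.array(is_itn, dtype="boolean"),
            "age_months": pd.array(age_months, dtype="Int64"),
            "used_last_night": used_col,
            "n_users": n_users_col,
            "raw_reason_codes": reason_strings,
        }
    )

    mem_total = int(members_per_hh.sum())
    mem_hh = np.repeat(np.arange(n_h), members_per_hh)
    mem_start = np.cumsum(members_per_hh) - members_per_hh
    mem_rank = np.arange(mem_total) - mem_start[mem_hh]
    members = pd.DataFrame(
        {
            "survey_id": cfg.survey_id,
            "household_id": household_id[mem_hh],
            "member_id": [
                f"{hid}-m{r + 1}" for hid, r in zip(household_id[mem_hh], mem_rank)
            ],
            "defacto": pd.array(np.ones(mem_total, dtype=bool), dtype="boolean"),
            "slept_under_itn": pd.array(mem_rank < sleepers[mem_hh], dtype="boolean"),
        }
    )

    households = pd.DataFrame(
        {
            "survey_id": cfg.survey_id,
            "household_id": household_id,
            "cluster_id": cluster_id,
            "stratum_id": residence,
            "weight": weight,
            "n_defacto_members": members_per_hh.astype(np.int64),
            "residence": residence,
            "interview_year": cfg.survey_year,
            "interview_month": month.astype(np.int64),
            "survey_type": cfg.survey_type,
        }
    )

    if cfg.year_round_yes_prob is not None:
        owners = n_nets >= 1
        yes = rng.random(n_h) < cfg.year_round_yes_prob
        yes_col = pd.array(yes, dtype="boolean")
        yes_col[~owners] = pd.NA
        yr_labels = sorted(cfg.year_round_reason_probs)
        yr_p = np.array([cfg.year_round_reason_probs[lbl] for lbl in yr_labels])
        yr_p = yr_p / yr_p.sum()
        reasons = np.full(n_h, "", dtype=object)
        ask = np.flatnonzero(owners & ~yes)
        if ask.size:
            picks = rng.choice(len(yr_labels), size=ask.size, p=yr_p)
            for pos, hh_i in enumerate(ask):
                reasons[hh_i] = yr_labels[picks[pos]]
        households["uses_nets_year_round"] = yes_col
        households["year_round_reasons"] = reasons

    return households, members, nets


def generate_multi_survey_panel(
    configs: list[SynthConfig | dict],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Concatenate surveys generated from each config into one panel.

    Requires at least two configurations with distinct ``survey_id``;
    per-survey structure is exactly that of :func:`generate_survey`, and
    ``(survey_id, household_id)`` remains the unique household key.
    """
    if not configs:
        raise ConfigurationError("survey panel needs at least two configurations")
    parsed = [c if isinstance(c, SynthConfig) else SynthConfig(**c) for c in configs]
    if len(parsed) < 2:
        raise ConfigurationError("survey panel needs at least two configurations")
    ids = [c.survey_id for c in parsed]
    dupes = {sid for sid in ids if ids.count(sid) > 1}
    if dupes:
        raise ConfigurationError(f"duplicate survey_id in panel: {sorted(dupes)}")
    tables = [generate_survey(c) for c in parsed]
    return tuple(
        pd.concat(parts, ignore_index=True) for parts in zip(*tables)
    )  # type: ignore[return-value]


def simulate_survey_summaries(
    n_per_type: int,
    year_range: tuple[int, int] = (2003, 2021),
    base_pct: float = 70.0,
    slope: float = 0.0,
    type_offsets: dict[str, float] | None = None,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate survey-level percent-of-nets-used summaries for trend studies.

    Each survey contributes one observation ``base + slope*(year - y0) +
    offset[type] + N(0, noise_sd)`` clipped to [0, 100]; years are sampled
    uniformly within ``year_range``.  The default offsets encode the study
    conditions of the cross-survey comparison: MIS surveys, run during peak
    transmission season, sit 7.3 percentage points above DHS, while MICS do
    not differ from DHS.
    """
    if n_per_type < 1:
        raise ConfigurationError("n_per_type must be >= 1")
    if type_offsets is None:
        type_offsets = {"DHS": 0.0, "MIS": 7.3, "MICS": 0.0}
    rng = np.random.default_rng(seed)
    rows = []
    y0, y1 = year_range
    for stype in ("DHS", "MIS", "MICS"):
        years = rng.integers(y0, y1 + 1, size=n_per_type)
        noise = rng.normal(0.0, noise_sd, size=n_per_type)
        pct = np.clip(
            base_pct + slope * (years - y0) + type_offsets.get(stype, 0.0) + noise,
            0.0,
            100.0,
        )
        for k in range(n_per_type):
            rows.append(
                {
                    "survey_id": f"{stype}-{k + 1:03d}",
                    "survey_type": stype,
                    "survey_year": int(years[k]),
                    "pct_nets_used": float(pct[k]),
                }
            )
    return pd.DataFrame(rows)
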