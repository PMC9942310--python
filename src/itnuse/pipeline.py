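"""End-to-end pipeline: simulate -> reshape -> indicators -> reasons -> inference.

Each stage reads its inputs from and writes its outputs to a run directory,
so stages can be re-run individually on top of earlier outputs (or on
user-supplied tables following the same CSV schemas).  A JSON
:class:`RunManifest` records the configuration hash, per-stage seeds, wall
times, and a SHA-256 digest of every input and output file — two runs with
the same configuration and seeds produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import SynthConfig
from .errors import (
    ConfigurationError,
    DependencyError,
    TableValidationError,
)
from .indicators import (
    household_indicators,
    pct_nets_used,
    population_itn_access,
    population_itn_use,
    survey_use_summaries,
)
from .inference import (
    fit_trend,
    seasonal_profile,
    stratified_compare,
    year_round_tabulation,
    bootstrap_pct_nets_used,
)
from .io import read_table, write_table
from .net_records import reshape_wide_to_long, to_wide, validate_linkage
from .reasons import harmonize, load_codebook, tabulate_reasons
from .synth import generate_multi_survey_panel, generate_survey

PIPELINE_STAGES = ("simulate", "reshape", "indicators", "reasons", "inference")

_FILES = {
    "households": "households.csv",
    "members": "members.csv",
    "nets_wide": "nets_wide.csv",
    "nets": "nets.csv",
    "linkage": "linkage_report.json",
    "hh_indicators": "household_indicators.csv",
    "survey_estimates": "survey_estimates.csv",
    "tabulations": "reason_tabulations.csv",
    "trend": "trend_fit.json",
    "seasonal": "seasonal_profile.csv",
    "residence": "residence_comparison.csv",
    "year_round": "year_round.csv",
}


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seeds: list = field(default_factory=list)
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def load_pipeline_config(path: str | Path) -> dict:
    """Parse and minimally validate a YAML/JSON pipeline configuration."""
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except Exception as exc:
        raise ConfigurationError(f"cannot parse pipeline config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    return _normalize_config(cfg)


def _normalize_config(cfg: dict) -> dict:
    cfg = dict(cfg)
    surveys = cfg.get("surveys")
    if not surveys or not isinstance(surveys, list):
        raise ConfigurationError("pipeline config needs a non-empty 'surveys' list")
    base_seed = int(cfg.get("seed", 0))
    parsed = []
    for i, entry in enumerate(surveys):
        if not isinstance(entry, dict):
            raise ConfigurationError(f"surveys[{i}] must be a mapping")
        entry = dict(entry)
        entry.setdefault("seed", base_seed + i)
        parsed.append(SynthConfig(**entry))
    cfg["surveys"] = parsed
    cfg.setdefault("codebook", None)
    cfg.setdefault("strata", ["supply", "residence"])
    cfg.setdefault("trend_model", "type_offset")
    cfg.setdefault("bootstrap_reps", 0)
    cfg.setdefault("tolerance_pp", 2.0)
    cfg["seed"] = base_seed
    return cfg


def _config_hash(cfg: dict) -> str:
    payload = {
        k: ([c.model_dump() for c in v] if k == "surveys" else v)
        for k, v in cfg.items()
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _require(outdir: Path, names: list[str], stage: str, produced_by: str) -> None:
    for name in names:
        if not (outdir / _FILES[name]).exists():
            raise DependencyError(
                f"stage {stage!r} requires {_FILES[name]} produced by {produced_by!r}"
            )


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    stages: list[str] | None = None,
    strict: bool = True,
) -> RunManifest:
    """Run the requested stages (all five by default) into ``outdir``."""
    if not isinstance(config, dict):
        config = load_pipeline_config(config)
    else:
        config = _normalize_config(config)
    stages = list(stages) if stages else list(PIPELINE_STAGES)
    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise ConfigurationError(f"unknown pipeline stage(s) {unknown}")
    stages = [s for s in PIPELINE_STAGES if s in stages]

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=_config_hash(config),
        seeds=[c.seed for c in config["surveys"]],
    )

    runners = {
        "simulate": _stage_simulate,
        "reshape": _stage_reshape,
        "indicators": _stage_indicators,
        "reasons": _stage_reasons,
        "inference": _stage_inference,
    }
    for stage in stages:
        t0 = time.perf_counter()
        inputs, outputs = runners[stage](config, outdir, manifest, strict)
        manifest.stages[stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 4),
            "inputs": {name: sha256_file(outdir / name) for name in inputs},
            "outputs": {name: sha256_file(outdir / name) for name in outputs},
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, outdir: Path, manifest, strict):
    configs = cfg["surveys"]
    if len(configs) == 1:
        households, members, nets = generate_survey(configs[0])
    else:
        households, members, nets = generate_multi_survey_panel(configs)
    write_table(households, outdir / _FILES["households"])
    write_table(members, outdir / _FILES["members"])
    # emit the roster in wide form so the reshape stage mirrors real inputs
    wide = to_wide(households[["survey_id", "household_id"]], nets)
    write_table(wide, outdir / _FILES["nets_wide"])
    return [], [_FILES["households"], _FILES["members"], _FILES["nets_wide"]]


def _stage_reshape(cfg, outdir: Path, manifest, strict):
    _require(outdir, ["households", "members", "nets_wide"], "reshape", "simulate")
    wide = read_table(outdir / _FILES["nets_wide"])
    households = read_table(outdir / _FILES["households"])
    members = read_table(outdir / _FILES["members"])
    nets = reshape_wide_to_long(wide)
    write_table(nets, outdir / _FILES["nets"])
    report = validate_linkage(households, members, nets)
    (outdir / _FILES["linkage"]).write_text(report.to_json(indent=2))
    if not report.ok:
        manifest.warnings.append("linkage validation produced findings")
        if strict:
            raise TableValidationError(str(report))
    return [_FILES["nets_wide"]], [_FILES["nets"], _FILES["linkage"]]


def _stage_indicators(cfg, outdir: Path, manifest, strict):
    _require(outdir, ["households", "members", "nets"], "indicators", "reshape")
    households = read_table(outdir / _FILES["households"])
    members = read_table(outdir / _FILES["members"])
    nets = read_table(outdir / _FILES["nets"])

    hh_ind = household_indicators(households, nets)
    write_table(hh_ind, outdir / _FILES["hh_indicators"])

    rows = []
    for sid, hh in households.groupby("survey_id", sort=True):
        nn = nets[nets["survey_id"] == sid]
        mm = members[members["survey_id"] == sid]
        for scope in ("all_nets", "itns_only"):
            est = pct_nets_used(nn, hh, scope=scope)
            rows.append(
                _est_row(sid, "pct_nets_used", scope, "overall", est.estimate, est.n, est.n_missing)
            )
        acc = population_itn_access(hh, nn)
        rows.append(_est_row(sid, "population_itn_access", "itns_only", "overall",
                             acc.estimate, acc.n, acc.n_missing))
        use = population_itn_use(mm, hh)
        rows.append(_est_row(sid, "population_itn_use", "itns_only", "overall",
                             use.estimate, use.n, use.n_missing))
        for cat, est in population_itn_use(mm, hh, nets=nn, by_supply=True).items():
            rows.append(_est_row(sid, "population_itn_use", "itns_only", cat,
                                 est.estimate, est.n, est.n_missing))
        if cfg.get("bootstrap_reps", 0):
            boot = bootstrap_pct_nets_used(
                nn, hh, n_reps=int(cfg["bootstrap_reps"]), seed=int(cfg["seed"])
            )
            rows.append(_est_row(sid, "pct_nets_used_bootstrap_se", "all_nets",
                                 "overall", boot.se, boot.n_reps, 0))
    write_table(pd.DataFrame(rows), outdir / _FILES["survey_estimates"])
    return (
        [_FILES["households"], _FILES["members"], _FILES["nets"]],
        [_FILES["hh_indicators"], _FILES["survey_estimates"]],
    )


def _est_row(sid, name, scope, stratum, estimate, n, n_missing):
    return {
        "survey_id": sid,
        "estimate_name": name,
        "scope": scope,
        "stratum": stratum,
        "weighted_estimate": estimate,
        "n": n,
        "n_missing": n_missing,
    }


def _stage_reasons(cfg, outdir: Path, manifest, strict):
    _require(outdir, ["households", "nets"], "reasons", "reshape")
    households = read_table(outdir / _FILES["households"])
    nets = read_table(outdir / _FILES["nets"])
    codebook = load_codebook(cfg.get("codebook"))
    harmonized, unmapped = harmonize(nets, codebook, strict=strict)
    if unmapped:
        manifest.warnings.append(f"unmapped reason codes: {unmapped}")
    mode = cfg["surveys"][0].response_mode if cfg.get("surveys") else "single"
    tabs = [tabulate_reasons(harmonized, households, strata="none", response_mode=mode)]
    for strata in cfg.get("strata", []):
        tabs.append(
            tabulate_reasons(harmonized, households, strata=strata, response_mode=mode)
        )
    write_table(pd.concat(tabs, ignore_index=True), outdir / _FILES["tabulations"])
    write_table(harmonized, outdir / "nets_harmonized.csv")
    return (
        [_FILES["households"], _FILES["nets"]],
        [_FILES["tabulations"], "nets_harmonized.csv"],
    )


def _stage_inference(cfg, outdir: Path, manifest, strict):
    _require(outdir, ["households", "nets"], "inference", "reshape")
    households = read_table(outdir / _FILES["households"])
    nets = read_table(outdir / _FILES["nets"])
    outputs = []

    summaries = survey_use_summaries(households, nets)
    try:
        fit = fit_trend(summaries, model=cfg.get("trend_model", "type_offset"))
        trend = {
            "model": fit.model_spec,
            "n_surveys": fit.n_surveys,
            "coefficients": {
                term: {"estimate": c.estimate, "se": c.se, "pvalue": c.pvalue}
                for term, c in fit.coefficients.items()
            },
        }
    except Exception as exc:  # too few surveys is a legitimate partial run
        manifest.warnings.append(f"trend fit skipped: {exc}")
        trend = {"skipped": str(exc)}
    (outdir / _FILES["trend"]).write_text(json.dumps(trend, indent=2))
    outputs.append(_FILES["trend"])

    harm_path = outdir / "nets_harmonized.csv"
    if harm_path.exists():
        harmonized = read_table(harm_path)
        profile, omitted = seasonal_profile(harmonized, households)
        if omitted:
            manifest.warnings.append(f"months with no nets omitted: {omitted}")
        write_table(profile, outdir / _FILES["seasonal"])
        outputs.append(_FILES["seasonal"])

        tab = tabulate_reasons(harmonized, households, strata="residence")
        used = tab[tab["kind"] == "used"].rename(columns={"pct": "estimate"})
        try:
            comp = stratified_compare(
                used[["survey_id", "stratum", "estimate"]],
                stratifier="residence",
                tolerance_pp=float(cfg.get("tolerance_pp", 2.0)),
            )
            write_table(comp, outdir / _FILES["residence"])
            outputs.append(_FILES["residence"])
        except Exception as exc:
            manifest.warnings.append(f"residence comparison skipped: {exc}")

    if "uses_nets_year_round" in households.columns:
        yr = year_round_tabulation(households, nets)
        table = yr.table.copy()
        table.attrs = {}
        write_table(table, outdir / _FILES["year_round"])
        outputs.append(_FILES["year_round"])

    return [_FILES["households"], _FILES["nets"]], outputs
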