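"""Synthetic-survey configuration.

:class:`SynthConfig` parameterizes one synthetic household survey: its sampling
design (clusters, households per cluster, urban share), household composition,
net acquisition, per-net use probabilities (with supply-category offsets and a
smooth seasonal modulation), and the reason-for-non-use response process under
single- or multiple-response questionnaire modes.

Defaults are calibrated so a survey generated out of the box resembles the
large DHS/MIS/MICS surveys this package is designed to analyse: roughly 70%
of nets used the previous night overall, with use highest in households that
own too few nets (not_enough), intermediate with an adequate supply (enough),
and markedly lower where nets exceed needs (more_than_enough).
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigurationError

SUPPLY_LEVELS = ("not_enough", "enough", "more_than_enough")

#: Default per-label reason probabilities for unused nets, conditional on
#: residence.  Labels are canonical (they resolve through the bundled
#: codebook); each stratum sums to 1 so single-response mode is well defined.
#: Rural respondents cite low perceived malaria risk ("no mosquitoes") more
#: often, urban respondents discomfort ("too hot"), mirroring the typical
#: urban/rural contrast in these surveys.
DEFAULT_REASON_PROBS: dict[str, dict[str, float]] = {
    "rural": {
        "saving for later": 0.23,
        "no mosquitoes": 0.27,
        "too hot": 0.13,
        "don't like smell": 0.04,
        "slept outdoors": 0.04,
        "too old/torn/dirty": 0.05,
        "usual user didn't sleep here": 0.04,
        "don't like colour/shape/size": 0.02,
        "chemicals not safe": 0.01,
        "other": 0.17,
    },
    "urban": {
        "saving for later": 0.23,
        "no mosquitoes": 0.21,
        "too hot": 0.19,
        "don't like smell": 0.04,
        "slept outdoors": 0.04,
        "too old/torn/dirty": 0.05,
        "usual user didn't sleep here": 0.04,
        "don't like colour/shape/size": 0.02,
        "chemicals not safe": 0.01,
        "other": 0.17,
    },
}

#: Default answer mix for the household-level "why not year round?" follow-up.
DEFAULT_YEAR_ROUND_REASON_PROBS: dict[str, float] = {
    "no/few mosquitoes": 0.60,
    "too hot": 0.22,
    "don't like net": 0.10,
    "forgot": 0.08,
}


class SynthConfig(BaseModel):
    """Parameters for one synthetic survey.

    Probabilities are proportions in [0, 1]; the net-use probability for a net
    in a household of supply category *c* interviewed in month *m* is::

        clip( (base_use_prob + supply_use_offsets[c])
              * (1 + seasonal_amplitude * cos(2*pi*(m - peak_month)/12)), 0, 1)

    ``reason_probs`` may be given flat (one mapping applied to both residence
    strata) or keyed by ``"urban"``/``"rural"``.
    """

    model_config = {"extra": "forbid"}

    survey_id: str
    survey_type: Literal["DHS", "MIS", "MICS"] = "DHS"
    survey_year: int = 2015
    n_clusters: int = Field(default=100, gt=0)
    households_per_cluster: int = Field(default=25, gt=0)
    urban_fraction: float = Field(default=0.35, ge=0.0, le=1.0)
    household_size_mean: float = Field(default=4.5, gt=0.0)
    net_acquisition_rate: float = Field(default=0.55, gt=0.0, le=1.0)
    itn_fraction: float = Field(default=0.85, ge=0.0, le=1.0)
    base_use_prob: float = Field(default=0.711, ge=0.0, le=1.0)
    supply_use_offsets: dict[str, float] = Field(
        default={"not_enough": 0.041, "enough": 0.0, "more_than_enough": -0.179}
    )
    seasonal_amplitude: float = Field(default=0.0, ge=0.0, le=1.0)
    peak_month: int = Field(default=9, ge=1, le=12)
    reason_probs: dict = Field(default=DEFAULT_REASON_PROBS)
    response_mode: Literal["single", "multiple"] = "single"
    multi_extra_prob: float = Field(default=0.3, ge=0.0, le=1.0)
    fieldwork_months: list[int] = Field(default=list(range(1, 13)))
    missing_use_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    missing_reason_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    member_itn_use_probs: Optional[dict[str, float]] = None
    antiphase_reason_label: Optional[str] = None
    antiphase_amplitude: float = Field(default=0.0, ge=0.0, le=1.0)
    year_round_yes_prob: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    year_round_reason_probs: dict[str, float] = Field(
        default=DEFAULT_YEAR_ROUND_REASON_PROBS
    )
    seed: int = 0

    def __init__(self, **data):
        try:
            super().__init__(**data)
        except ValidationError as exc:  # surface offending field names
            fields = sorted(
                {
                    ".".join(str(part) for part in err["loc"]) or "<config>"
                    for err in exc.errors()
                }
            )
            raise ConfigurationError(
                f"invalid configuration field(s) {fields}: {exc}"
            ) from None

    # -- cross-field checks -------------------------------------------------

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        bad_supply = set(self.supply_use_offsets) - set(SUPPLY_LEVELS)
        if bad_supply:
            raise ValueError(
                f"supply_use_offsets has unknown supply categories {sorted(bad_supply)}"
            )
        if not self.fieldwork_months:
            raise ValueError("fieldwork_months must name at least one month")
        if any(m < 1 or m > 12 for m in self.fieldwork_months):
            raise ValueError("fieldwork_months entries must lie in 1..12")

        probs = self.reason_probs
        if probs and not isinstance(next(iter(probs.values())), dict):
            probs = {"urban": dict(probs), "rural": dict(probs)}
        if set(probs) != {"urban", "rural"}:
            raise ValueError(
                "reason_probs must be keyed by residence ('urban'/'rural') or be flat"
            )
        for res, mapping in probs.items():
            if not mapping:
                raise ValueError(f"reason_probs[{res!r}] is empty")
            for label, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"reason_probs[{res!r}][{label!r}] outside [0, 1]")
            if self.response_mode == "single":
                total = sum(mapping.values())
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"reason_probs[{res!r}] must sum to 1 in single-response "
                        f"mode (got {total:.6f})"
                    )
        object.__setattr__(self, "reason_probs", probs)

        if self.member_itn_use_probs is not None:
            bad = set(self.member_itn_use_probs) - set(SUPPLY_LEVELS)
            if bad:
                raise ValueError(
                    f"member_itn_use_probs has unknown supply categories {sorted(bad)}"
                )
            for cat, p in self.member_itn_use_probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"member_itn_use_probs[{cat!r}] outside [0, 1]")

        if self.antiphase_reason_label is not None:
            for res, mapping in probs.items():
                if self.antiphase_reason_label not in mapping:
                    raise ValueError(
                        f"antiphase_reason_label {self.antiphase_reason_label!r} "
                        f"missing from reason_probs[{res!r}]"
                    )

        if self.year_round_yes_prob is not None:
            if not self.year_round_reason_probs:
                raise ValueError("year_round_reason_probs is empty")
            for label, p in self.year_round_reason_probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"year_round_reason_probs[{label!r}] outside [0, 1]"
                    )
        return self
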