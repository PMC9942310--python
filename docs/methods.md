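# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of `itnuse`.

## The analysis pipeline

The unit of observation is the *net*: household rosters are reshaped from
wide (one row per household, repeated net slots) to long (one row per net).
A slot counts as present when **any** of its attribute columns is
non-missing; DHS-style rosters contain partially answered nets and dropping
them would bias use percentages.  A net marked used that also carries
non-use reasons is a hard validation error — the two fields are mutually
exclusive by construction of the questionnaire.

All survey estimates are Hájek-style weighted ratios: each net or member
inherits its household weight, and estimates are invariant to uniform weight
rescaling.  Nets with a missing used-last-night flag are excluded from both
numerator and denominator, with the excluded count disclosed alongside every
estimate; the alternative (imputing non-use) would deflate use levels by an
unknowable amount.

### Supply classification

Nets-per-person thresholds are interpreted as the half-open partition
[0, 0.5), [0.5, 0.75), [0.75, ∞) — each interval includes its lower bound,
which is the only reading that makes the three verbal definitions ("less
than 0.5", "0.5 to 0.75", "0.75 or more") a partition.  The one-person /
one-net household is classified `enough` rather than `more_than_enough` by
explicit rule.  Ratios are compared as exact rationals (`Fraction`, or
equivalent integer cross-multiplication in the vectorized path) because
boundary households are common (2 nets / 4 people) and binary floating
point cannot represent 0.5·members exactly for all counts.  Supply counts
*all* nets; access counts ITNs only — the two indicators deliberately use
different numerators.

### Reason harmonization and tabulation

The codebook is a five-column table (survey, raw code, raw label, canonical
label, category); rows with survey `*` are fallbacks.  Harmonization is
strict by default (an unknown code aborts with the survey and code named);
lenient mode maps unknown codes to the auditable sentinel `unmapped`
(category `other`) and reports counts.  An unused net with no recorded
reason becomes `missing` (category `other`) so single-response stacks still
close at 100%.

Percentages are always of **all nets with a known use status** in the
stratum.  Within a net, labels are deduplicated, and a net citing two labels
of one category contributes its weight once to that category but once to
each distinct label — this is what makes multiple-response totals exceed
100% at the category level while category percentages remain invariant to
splitting a raw code into synonyms.

### Trend, seasonality, year-round use

The cross-survey trend model is OLS with one *unweighted* observation per
survey: survey-level estimates are already weighted within survey, and
cross-survey comparisons of this kind treat surveys as exchangeable points.
Two parameterizations are provided because survey-type contrasts can be
framed either way: per-type simple regressions (`by_type_slope`) and a
pooled model with a common slope and MIS/MICS indicator offsets against a
DHS reference (`type_offset`).  Design matrices are rank-checked before
fitting, and fits are invariant to recentering the year covariate.

Seasonal profiles pool surveys and aggregate per calendar interview month:
weighted percent of nets used and weighted percent of all nets per reason
category.  Months without nets are omitted and flagged rather than
interpolated.

The year-round-use question is household-level and restricted to households
owning at least one net.  Reasons for "no" are tabulated as percentages of
*all* net-owning households (not of "no" households).  The trend test is
OLS of the yearly weighted percent on year — the simplest test that yields
a single trend p-value; with fewer than three years no test is run.

Within-survey uncertainty, where needed, comes from a stratified cluster
bootstrap (clusters resampled with replacement within strata, 500 replicates
by default, seeded): it is assumption-light and matches the design-based
clustering structure without implementing Taylor linearization.  This is a
deliberate design choice; point estimates are unaffected.

### Urban/rural comparison

`stratified_compare` reports per-survey percentage-point differences and a
three-way classification with a ±2 pp default tolerance for "no
difference".  No principled tolerance exists for this classification; 2 pp
is of the order of the sampling error of a typical survey-level net-use
estimate, and the parameter is exposed (`tolerance_pp`) precisely because
it is a convention.

## The synthetic-data generator

The generator produces the structures the analysis assumes, not a
demographic microsimulation:

| parameter | default | rationale |
|---|---|---|
| clusters × households | 100 × 25 | typical national-survey order of magnitude, scaled down |
| household size | 1 + Poisson(3.5) | positive sizes with realistic skew, mean 4.5 |
| nets per household | Binomial(⌈m/2⌉+1, 0.55) | yields all three supply categories incl. over-supply |
| weights | 1 / U(0.5, 1.5) cluster selection, mean-normalized | exercises weighted estimators without a sampling frame |
| ITN share of nets | 0.85 | most nets in recent surveys are ITNs |
| base use probability | 0.711 | the "enough" category sits at the low-70s level |
| supply offsets | +0.041 / 0 / −0.179 | reproduces the characteristic 75 / 71 / 53 use split by supply |
| seasonality | use × (1 + a·cos(2π(month − peak)/12)), clipped | smooth transmission-season peak; off by default |
| reason mix | see `DEFAULT_REASON_PROBS` | extra and risk-perception dominant, attributes/fears rare; rural cites "no mosquitoes" more, urban "too hot" |

Reasons attach only to unused nets.  In multiple-response mode each unused
net draws a second, distinct label with probability `multi_extra_prob`
(default 0.3) via Gumbel top-k sampling (categorical draws without
replacement).  An optional anti-phase modulation multiplies one label's
probability by (1 − a·cos(2π(month − peak)/12)) before renormalizing, so
risk-perception responses can peak in the dry season while use peaks in the
transmission season.

Member-level ITN use has two regimes.  By default members are assigned to
*used* ITNs two at a time, so population use emerges from net use.  When a
target use proportion is configured for a supply category
(`member_itn_use_probs`), per-household binomial draws are calibrated
against the two-per-ITN access cap: expected sleeper counts are
water-filled across households (clipped mass reallocated to households with
slack) so the category-level expectation equals the target exactly whenever
it is feasible; net used-flags and user counts are then derived from the
sleepers.  Without this calibration, naive per-member draws are biased
downward by the cap and configured use levels would be systematically
missed.  A used net may carry zero counted users in the default regime
(e.g. all members already covered by earlier nets) — user counts enumerate
de facto members only.

What the generator does **not** emulate: net ageing and attrition,
within-household sleeping arrangements, non-de-facto visitors,
spatially structured transmission, or item non-response patterns beyond
independent missingness (`missing_use_prob`, `missing_reason_prob`).
Passing recovery tests on this generator therefore demonstrates estimator
correctness under a clean complex-survey design — not robustness to the
messiness of real fieldwork data.

## Determinism and problem sizes

Every stochastic step flows from one `numpy` PRNG seeded per survey; the
pipeline writes a manifest with seeds and SHA-256 digests, and identical
configurations reproduce byte-identical CSVs.  The test suite and the
acceptance script size their simulations to what the checked property
needs: exact-oracle checks run on exhaustive grids (180 supply cells, 1,000
allocation households); recovery checks use surveys of roughly 10,000–12,500
households (≥ 20,000 nets) for point recovery at three standard errors,
72,000 households for the monthly profile (≥ 10,000 nets per month), 200
replicate panels of 90 surveys for offset bias and coverage, and 8 × 1,000
households for the year-round trend.  Standard-error bands for weighted
estimates use the Kish effective sample size.

## Limitations

* The adapter for real DHS/MICS recode files is an interface only; mapping
  HML* variables into the package's schemas is survey-specific work.
* Category assignments of a few labels (e.g. "slept outdoors" under
  subjective, "prefer other method" under net attributes) are debatable;
  they are codebook data and can be re-assigned without code changes.
* The bootstrap treats clusters as the only stage of clustering;
  within-household correlation beyond the cluster level is not separately
  modelled.
* Single- and multiple-response surveys are tabulated on the same scale but
  are not statistically equivalent; pooling them mixes elicitation modes.
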