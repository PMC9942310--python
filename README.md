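# itnuse

Analysis of insecticide-treated-net (ITN) use — and of the reasons people
give for *not* using a net — from household-survey microdata of the
DHS/MIS/MICS family.

National malaria household surveys record a roster of every net a household
owns: whether it is an ITN, its age, whether it was used the previous night,
and (in some surveys) why it was not.  This package is for malaria
programme analysts and survey methodologists who want to compute the
standard net-coverage indicator set from such microdata, harmonize the
wildly inconsistent reason-for-non-use answer options across surveys into a
comparable seven-category taxonomy, and study how use varies with household
net supply, residence, season and time.

Because the real microdata are restricted-access, the package ships a
synthetic survey generator that emulates their structure — cluster-stratified
design with sampling weights, de facto household members, per-net attributes,
single- and multiple-response reason questions — so the entire pipeline is
runnable and testable out of the box.

## Indicators

For a household *h* with $m_h$ de facto members (people who slept there last
night), $n_h$ nets (ITNs and untreated), $k_h$ ITNs, and sampling weight
$w_h$:

* **Percent of nets used last night** (the Roll Back Malaria monitoring
  indicator): $100 \cdot \sum w_h u_i / \sum w_h$ over all nets *i* observed
  in the survey with a known use flag $u_i$; each net inherits its
  household's weight.  Both an all-nets and an ITNs-only scope are exposed.
* **Household net supply**: the ratio $r_h = n_h/m_h$ classifies households
  as `not_enough` ($r_h < 0.5$), `enough` ($0.5 \le r_h < 0.75$) or
  `more_than_enough` ($r_h \ge 0.75$), with the special case that a
  one-person household owning exactly one net is `enough`.  The comparison
  uses exact rational arithmetic so boundary households (e.g. 2 nets, 4
  people) never misclassify through floating point.
* **Population ITN access**: $\sum w_h \min(2 k_h, m_h) / \sum w_h m_h$ —
  the share of the population that could sleep under an ITN if each ITN
  covered up to two people.
* **Population ITN use**: the weighted share of de facto members who
  actually slept under an ITN, overall and by supply category.

Reasons for non-use are mapped through a codebook (data, not code) to
canonical labels in seven categories — *extra, fears, net attributes,
objective, risk perception, subjective, other* — and tabulated as weighted
percentages **of all nets**, so single-response surveys stack to exactly
100% (used + categories) while multiple-response surveys may exceed it.
Cross-survey trends are ordinary least squares on survey-level points, with
either per-type slopes or survey-type offsets (DHS reference); uncertainty
for within-survey proportions is available via a stratified cluster
bootstrap.

## Worked example

```python
import itnuse as iu

cfg = iu.SynthConfig(survey_id="EX-2016", seed=7, n_clusters=100,
                     households_per_cluster=25)
households, members, nets = iu.generate_survey(cfg)

use = iu.pct_nets_used(nets, households)
access = iu.population_itn_access(households, nets)
pop_use = iu.population_itn_use(members, households)

codebook = iu.load_codebook()              # bundled seven-category codebook
harmonized, _ = iu.harmonize(nets, codebook)
tab = iu.tabulate_reasons(harmonized, households, strata="supply")
```

Output for this configuration:

```
2500 households, 11328 members, 4778 nets
percent of nets used last night: 68.6% (n=4778)
population ITN access: 0.646; population ITN use: 0.474
```

and the category percentages among nets in `more_than_enough` households:

```
           name   pct
          extra 13.45
          fears  0.43
 net_attributes  0.46
      objective  4.64
risk_perception  9.84
     subjective 10.07
          other  8.71
```

Read: in households owning at least three nets per four people, 13.45% of
all nets went unused because they were *extra* (being saved or stored away),
while net attributes and chemical fears are negligible — the typical pattern
for well-supplied households.  The "pct" column plus the percent used sums
to 100 in single-response mode.

## Command line

```bash
itnuse run --config demo.yaml --outdir runs/demo     # full pipeline
itnuse reshape --wide nets_wide.csv --out nets.csv   # roster -> net file
itnuse trend --summaries survey_summaries.csv --model type_offset
```

The pipeline stages (`simulate`, `reshape`, `indicators`, `reasons`,
`inference`) write tidy CSVs plus a JSON run manifest with seeds and SHA-256
digests of every output; identical configs and seeds reproduce byte-identical
runs.  A demo configuration is bundled at
`src/itnuse/data/demo_config.yaml`.  Exit codes: 0 ok, 2 validation,
3 configuration, 4 missing dependency.

### Input schemas

Wide rosters use slot columns `is_itn_1 … is_itn_K`, `age_months_k`,
`used_last_night_k`, `n_users_k`, `raw_reason_codes_k` (semicolon-joined
codes) next to `survey_id`/`household_id`; a slot is present when any of its
attributes is non-missing.  Long tables follow the column sets documented in
`itnuse.net_records` and `itnuse.io`.

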