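# Demo pipeline configuration: a small four-survey panel (two DHS, two MIS)
# sized to run in seconds.  MIS fieldwork concentrates in peak transmission
# months; DHS spreads over the drier part of the year.
seed: 20150
strata: [supply, residence]
trend_model: type_offset
bootstrap_reps: 0
tolerance_pp: 2.0
surveys:
  - survey_id: DEMO-DHS-2012
    survey_type: DHS
    survey_year: 2012
    n_clusters: 15
    households_per_cluster: 12
    fieldwork_months: [1, 2, 3, 4, 5, 6]
  - survey_id: DEMO-DHS-2016
    survey_type: DHS
    survey_year: 2016
    n_clusters: 15
    households_per_cluster: 12
    fieldwork_months: [1, 2, 3, 4, 5, 6]
    year_round_yes_prob: 0.6
  - survey_id: DEMO-MIS-2014
    survey_type: MIS
    survey_year: 2014
    n_clusters: 15
    households_per_cluster: 12
    fieldwork_months: [8, 9, 10]
    response_mode: multiple
  - survey_id: DEMO-MIS-2018
    survey_type: MIS
    survey_year: 2018
    n_clusters: 15
    households_per_cluster: 12
    fieldwork_months: [8, 9, 10]
    response_mode: multiple
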