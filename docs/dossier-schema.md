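# Evidence dossier schema

An *agent dossier* collects the totality of reported preclinical animal
stroke-model evidence for one candidate therapy.  YAML is the primary
dialect; JSON is accepted everywhere (it is a YAML subset).  Enum tokens
are matched case-insensitively.  Optional fields are omitted, never
written as `null`.

```yaml
agent_id: nerinetide           # free-text identifier, unique to the dossier
agent_name: "Nerinetide (NA1)" # display name (optional)
modality: drug                 # drug | device
studies:
  - study_id: smith_2019       # unique within the dossier
    lab_id: lab_ucla_01        # performing laboratory (replication item)
    species: rat               # mouse | rat | rabbit | pig | sheep |
                               # nonhuman_primate | other
    age_class: aged            # juvenile | young_adult | aged
    sex_composition: both      # male | female | both | unreported
    comorbidity: hypertension  # none | hypertension | diabetes |
                               # hyperglycemia | obesity |
                               # advanced_age_plus_comorbid | other
    ischemia_model: transient  # transient | permanent
    occlusion_duration_min: 90 # required iff transient, > 0
    experiments:
      - experiment_id: e1
        treatment_start_min: 60   # minutes from ischemia onset (onset = 0);
                                  # pre-onset administration is ≤ 0
        route: intravenous        # see route vocabulary below
        dose_value: 2.6           # optional; requires dose_unit
        dose_unit: mg/kg
        outcomes:
          - kind: infarct_volume  # infarct_volume | behavioral
            timepoint_days: 1     # assessment time after ischemia, ≥ 0
            direction: lower_is_better  # optional; defaults:
                                        # infarct_volume → lower_is_better,
                                        # behavioral → higher_is_better
            treated: {n: 12, mean: 30.0, sd: 10.0}
            control: {n: 12, mean: 50.0, sd: 10.0}
            reported_p: 0.01    # optional; preferred over the Welch t-test
```

## Invariants

- every study needs ≥ 1 experiment; every experiment ≥ 1 outcome;
- each arm needs `n ≥ 2` and `sd ≥ 0`;
- `occlusion_duration_min` is present exactly when `ischemia_model:
  transient`, and positive;
- `dose_value` and `dose_unit` appear together or not at all;
- `study_id` values are unique within a dossier;
- `reported_p`, when present, lies in [0, 1].

`primed2 validate dossier.yaml` (or `primed2.validate_dossier`) reports
every violation with a path such as
`studies[smith_2019].experiments[e1].outcomes[0].treated.n`.

## Route vocabulary

`intravenous`, `intraarterial`, `intraperitoneal`, `subcutaneous`,
`intramuscular`, `oral`, `intranasal`, `intracerebroventricular`,
`intracerebral`, `intrathecal`, `implanted_electrode`,
`noninvasive_device`, `other`.

Which routes count as clinically feasible is a *scoring* question, not a
data question: the mapping lives in `ScoringConfig.route_feasibility_map`
and can be overridden per analysis.

## Sex composition

`unreported` is a distinct token and is never treated as `both`: a study
that does not report the sex of its animals cannot contribute to the
both-sexes item.

## Age class

`age_class` is assigned by the curator.  For rodents the usual guidance is
`aged` ≥ 18 months; the threshold is documentation, not code — other
species need species-appropriate judgment.

## Companion CSV formats

Per-study effects (consumed by `primed2 pool`):

    study_id,n_t,mean_t,sd_t,n_c,mean_c,sd_c,direction

Rater scores (consumed by `primed2 kappa`):

    rater_id,agent_id,item_id,score
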