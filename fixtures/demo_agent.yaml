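agent_id: demo_agent
agent_name: Demo neuroprotectant
modality: drug
studies:
  - study_id: lab1_rat_aged
    lab_id: lab_1
    species: rat
    age_class: aged
    sex_composition: both
    comorbidity: hypertension
    ischemia_model: transient
    occlusion_duration_min: 90
    experiments:
      - experiment_id: e1
        treatment_start_min: 120
        route: intravenous
        outcomes:
          - kind: infarct_volume
            timepoint_days: 1
            treated: {n: 12, mean: 32.0, sd: 10.0}
            control: {n: 12, mean: 50.0, sd: 10.0}
          - kind: behavioral
            timepoint_days: 7
            treated: {n: 12, mean: 62.0, sd: 8.0}
            control: {n: 12, mean: 57.0, sd: 8.0}
  - study_id: lab2_mouse_adult
    lab_id: lab_2
    species: mouse
    age_class: young_adult
    sex_composition: male
    comorbidity: none
    ischemia_model: permanent
    experiments:
      - experiment_id: e1
        treatment_start_min: 30
        route: intravenous
        outcomes:
          - kind: infarct_volume
            timepoint_days: 1
            treated: {n: 10, mean: 41.0, sd: 9.0}
            control: {n: 10, mean: 52.0, sd: 9.0}
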