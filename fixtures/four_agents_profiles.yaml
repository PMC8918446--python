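# Score-profile sheet for the four exemplar acute-stroke therapies:
# two drugs (nerinetide/NA1, trans-sodium crocetinate/TSC) and two devices
# (cathodal transcranial direct-current stimulation, fastigial nucleus
# stimulation).
#
# SYNTHETIC / PARTIAL TRANSCRIPTION: only cell values pinned by the
# published prose are filled in; every other cell is `~` (unknown) and
# renders grey.  Pinned facts:
#   - time_epochs and infarct_magnitude scored 2 for all four agents;
#   - sex scored 0 for three of the four agents;
#   - age, species-and-laboratory reproducibility, and feasible_window
#     scored 2 for three of the four agents;
#   - comorbidities scored 0 or 1 for every agent (individual values not
#     published, so left unknown here);
#   - route of delivery did not score high for fastigial nucleus
#     stimulation (depth-electrode implantation), encoded as 0.
# The assignment of each "three of four" fact to named agents is a
# reconstruction (the exception is placed on FNS, the lowest-scoring
# agent); unpublished cells stay unknown rather than guessed.
schema: primed2-profiles/1
agents:
  - agent_id: nerinetide
    agent_name: "Nerinetide (NA1)"
    modality: drug
    items:
      age: 2
      sex: 0
      species: 2
      comorbidities: ~
      replication: 2
      time_epochs: 2
      feasible_window: 2
      route: ~
      infarct_magnitude: 2
      behavioral: ~
      dose_response: ~
  - agent_id: tsc
    agent_name: "Trans-sodium crocetinate"
    modality: drug
    items:
      age: 2
      sex: 0
      species: 2
      comorbidities: ~
      replication: 2
      time_epochs: 2
      feasible_window: 2
      route: ~
      infarct_magnitude: 2
      behavioral: ~
      dose_response: ~
  - agent_id: c_tdcs
    agent_name: "Cathodal tDCS"
    modality: device
    items:
      age: 2
      sex: 0
      species: 2
      comorbidities: ~
      replication: 2
      time_epochs: 2
      feasible_window: 2
      route: ~
      infarct_magnitude: 2
      behavioral: ~
      dose_response: ~
  - agent_id: fns
    agent_name: "Fastigial nucleus stimulation"
    modality: device
    items:
      age: ~
      sex: ~
      species: ~
      comorbidities: ~
      replication: ~
      time_epochs: 2
      feasible_window: ~
      route: 0
      infarct_magnitude: 2
      behavioral: ~
      dose_response: ~
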