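# primed2

Deterministic scoring of the **cumulative preclinical evidence** for a
candidate acute ischemic-stroke therapy — the PRIMED² translational-
readiness instrument as a Python library and CLI.

Many neuroprotective therapies that looked effective in animal stroke
models have failed in human trials.  Per-study quality checklists (STAIR,
ARRIVE, risk-of-bias tools) ask whether individual experiments were well
designed; PRIMED² asks a complementary question about the *whole
literature* for one agent: has benefit been shown across ages, sexes,
species and comorbid models, in clinically attainable time windows and
delivery routes, reproducibly across laboratories, and with effects large
enough to matter?

Given an evidence dossier (all reported animal studies for one agent, as
YAML/JSON summary statistics), the package computes:

- the **11 domain scores**, each 0/1/2 under operationalised rules —
  4 dichotomous items (sex, replication, feasible time window, route)
  scored 0 or 2, and 7 graded items (age, species, comorbidities, time
  epochs, infarct magnitude, behavioral magnitude, dose–response);
- pooled **standardized mean differences**: per-outcome Cohen's
  *d* = (x̄_c − x̄_t)/s_pooled (oriented so benefit is positive), pooled by
  DerSimonian–Laird random effects (default), fixed effect, or
  cross-study median, banded small [0.2, 0.4) / medium [0.4, 0.7) /
  large [0.7, ∞);
- the optional **summary total** (0–22, reported with the caution that it
  obscures item-level granularity);
- **inter-rater reliability**: Cohen's κ = (p_o − p_e)/(1 − p_e) over
  (agent, item) rating units, with linear/quadratic weighted variants and
  consensus resolution;
- the **traffic-light figure**: a deterministic SVG grid, one row per
  item, one column per agent, red/yellow/green for 0/1/2.

A seeded synthetic-dossier generator with exact profile recovery
(`primed2.synthetic_data`) makes every pipeline stage testable without any
external data.  See `docs/methods.md` for the scoring rules and modelling
choices, and `docs/dossier-schema.md` for the input format.

## Worked example

Score a two-study dossier (`fixtures/demo_agent.yaml`, abridged — full schema in
`docs/dossier-schema.md`): an aged, hypertensive, both-sex rat study with
treatment 120 min after a 90-min transient occlusion, plus a young-adult
male mouse study treated 30 min after permanent occlusion, from a second
laboratory:

```sh
primed2 score fixtures/demo_agent.yaml
```

prints the profile as JSON (excerpt):

```json
{
  "agent_id": "demo_agent",
  "items": [
    {"item_id": "age", "score": 2,
     "rationale": "benefit demonstrated in aged animals", ...},
    {"item_id": "comorbidities", "score": 1,
     "rationale": "benefit in one comorbid model (hypertension)", ...},
    {"item_id": "time_epochs", "score": 2,
     "rationale": "benefit in 2 timing epoch(s): post_onset_permanent, post_reperfusion", ...},
    {"item_id": "infarct_magnitude", "score": 2,
     "rationale": "pooled d = 1.513 over k = 2 infarct-volume outcome(s): large effect", ...},
    {"item_id": "behavioral", "score": 1,
     "rationale": "pooled d = 0.625 over k = 1 behavioral outcome(s): medium effect", ...},
    {"item_id": "dose_response", "score": 0,
     "rationale": "fewer than two distinct dose levels tested", ...}
  ],
  "total": 18
}
```

Reading it: both timing items score 2 (benefit in two epochs, including a
start ≥ 45 min — attainable in human workflows), the infarct effect pools
to d = 1.513 (large → 2), the single behavioural outcome gives d = 0.625
(medium → 1), comorbidity evidence exists in one model only (1), and no
dose–response was tested (0), for a total of 18/22.

Other subcommands:

```sh
primed2 validate dossier.yaml                 # schema check, exit 1 on violations
primed2 pool effects.csv --method dl          # pooled SMD as one-line JSON
primed2 kappa rater_a.csv rater_b.csv         # inter-rater agreement
primed2 plot scores.json ... -o grid.svg      # traffic-light grid
primed2 plot fixtures/four_agents_profiles.yaml -o four_agents.svg
primed2 report scores.json -o report.md       # per-agent markdown report
primed2 simulate --profile spec.yaml --seed 7 -o dossier.yaml
```

`fixtures/four_agents_profiles.yaml` is a partial transcription of the
published profiles of four exemplar agents (nerinetide, trans-sodium
crocetinate, cathodal tDCS, fastigial nucleus stimulation); cells not
pinned by the published prose are marked unknown and render grey.

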