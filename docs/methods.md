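# Methods

## The instrument

PRIMED² rates the *cumulative* preclinical evidence for a candidate acute
ischemic-stroke therapy — drug or device — on 11 items, each scored 0
(low), 1 (intermediate) or 2 (high strength).  It complements
per-study quality checklists (STAIR, ARRIVE, risk-of-bias tools) by asking
a different question: not "was this study well designed?" but "has the
literature as a whole demonstrated what a clinical trial would need?"

Four items are dichotomous (scores 0/2 only): `sex`, `replication`,
`feasible_window`, `route`.  Seven are graded (0/1/2): `age`, `species`,
`comorbidities`, `time_epochs`, `infarct_magnitude`, `behavioral`,
`dose_response`.

The published item grouping enumerates ten items across four content
domains (animal diversity ×4, time windows ×2, delivery route ×1, effect
robustness ×3) while the roster has eleven; we take the eleventh to be
**replication across laboratories**, consistent with the instrument's
emphasis on "reproducibility across species and laboratories" — species
diversity and laboratory replication are scored as separate items.
Likewise the dichotomy assignment beyond `feasible_window` (the only item
the text names as 0/2) is a reconstruction: `sex`, `route` and
`replication` are yes/no questions by nature.  Both choices are design
decisions of this implementation, flagged here prominently.

## Benefit

The instrument's rules hinge on whether an outcome "demonstrates benefit",
which the published description leaves qualitative.  We operationalise it
per outcome as

    benefit  ⇔  d ≥ 0.2 (oriented so benefit is positive)  AND  p < 0.05

with `p` the study's reported p-value when available, else a two-sided
Welch t-test computed from the summary statistics.  Both thresholds
(`benefit_min_d`, `benefit_alpha`) are configurable.  The d-gate keeps
trivially small but over-powered effects from counting; the p-gate keeps
large but unreliable point estimates from counting.

## Timing epochs

Treatment timing is encoded as minutes relative to ischemia onset
(onset = 0, pre-onset ≤ 0).  Four epochs are distinguished:

| epoch | condition |
| --- | --- |
| `pre_onset` | start ≤ 0 (prior to or concurrent with onset) |
| `intra_ischemia_transient` | transient model, 0 < start < occlusion end |
| `post_onset_permanent` | permanent model, start > 0 |
| `post_reperfusion` | transient model, start ≥ occlusion end |

A start exactly at reperfusion counts as post-reperfusion.  The
`time_epochs` item counts distinct epochs with benefit (0 → 0, 1 → 1,
≥2 → 2).  The `feasible_window` item asks whether any benefit was shown
with a start ≥ 45 min after onset — the earliest treatment start achieved
in a pivotal human acute-stroke trial; the cutpoint is configurable
(`feasible_window_min`).  Pre-onset administration can never satisfy it.

## Effect magnitude

Per-outcome effects are two-sample Cohen's d with pooled SD; the sampling
variance uses the common large-sample approximation
`(n_t+n_c)/(n_t·n_c) + d²/(2(n_t+n_c))`.  Per item, all infarct-volume
(resp. behavioural) outcomes are pooled; the default pooling is
DerSimonian–Laird random effects, falling back to inverse-variance fixed
effect at k = 1, with cross-study median and a Hedges small-sample
correction available as options (`pooling_method`, `hedges`; the
correction is off by default since the instrument names plain Cohen's d).
Pooled values are banded half-open: none [−∞, 0.2), small [0.2, 0.4),
medium [0.4, 0.7), large [0.7, ∞) — the published ranges "0.2–0.39 /
0.4–0.69 / ≥ 0.7" read as a gap-free partition.  Mapping onto scores:
large → 2, medium → 1, small/none → 0; the conservative reading that a
small pooled effect does not support readiness (set
`magnitude_small_scores_one` for the lenient variant).  Negative
(harmful) pooled d is retained, not truncated, and lands in "none".

The `dose_response` item requires ≥ 2 distinct tested dose levels, at
least one dosed experiment with benefit, and a monotone non-decreasing
pooled d across dose levels (ties count as monotone): 2 levels → 1,
≥3 levels → 2, non-monotone → 0.

`behavioral_uses_magnitude=False` switches the behavioural item from
magnitude banding to durability: 1 for benefit at any timepoint, 2 when a
benefit persists ≥ 7 days post-ischemia.

## Summary total and display

The optional total is the plain sum (0–22).  Every rendered total carries
the caution that it fails to convey the granular information of each scale
item; no low/intermediate/high banding of totals is applied.  The figural
output is a risk-of-bias-style traffic-light grid (items as rows grouped
by domain, agents as columns; red/yellow/green for 0/1/2, grey for cells
whose value is unknown in a transcribed profile).  Default colours
#d73027 / #fec44f / #1a9850 are colour-blind-considered approximations of
the published scheme; rendering is deterministic.

## Inter-rater reliability

Cohen's kappa over pooled (agent, item) units is the default — the reading
most consistent with a single published coefficient for 4 agents × 11
items; linear/quadratic weighted variants and per-agent grouping are
provided for sensitivity analysis.  Kappa computation symmetrises the
confusion matrix before weighting, which is algebraically a no-op but
makes κ(a,b) and κ(b,a) bit-identical.  The published κ = 0.88 cannot be
recomputed here because pre-consensus rater-level scores were not
published; the reliability module is instead validated against brute-force
oracles and distributional properties (κ = 1 for identical raters, mean
κ ≈ 0 for independent raters).

## Synthetic dossiers

`synthetic_data.generate_dossier` maps a target 11-item profile to a
dossier that the default-config scorer maps back exactly (property-tested
over random realizable profiles).  Construction, not simulation, provides
the guarantee:

- study rosters (species, laboratory, comorbidity cycles; a single age
  class and sex composition) realise the diversity items with the minimum
  number of studies (1, or 2 when a two-level diversity item demands it);
- treatment starts are drawn from {−5, 30, 90} min against a 60-min
  transient occlusion to hit the required epoch set and the 45-min window;
- arm summary statistics are exact population values — control mean
  uniform in [40, 60] (the only use of the RNG), SD = `noise_sd` (default
  10), treated mean offset by d·SD, n = 12 per arm — with true d of 0.30 /
  0.55 / 1.20 for magnitude targets 0/1/2, each ≥ 0.05 clear of a category
  boundary so pooling cannot cross it;
- benefit status is carried by a reported p (0.001 beneficial, 0.9 null),
  decoupling the significance gate from effect magnitude so that, e.g., a
  dossier can demonstrate benefit everywhere yet pool to a small effect;
- dose ladders (2–3 levels, d stepped by ±0.05 around the magnitude
  target) realise the dose–response item without disturbing the pooled
  category.

`sampled=True` instead draws finite normal samples per arm and leaves the
p-value to the Welch test — a stress mode for the benefit gate, for which
exact profile recovery is deliberately *not* guaranteed.

What the generator does **not** emulate: historical effect-size inflation,
publication bias, heterogeneous study sizes, correlated outcomes within
experiments, or realistic species/comorbidity frequencies.  Passing
recovery tests therefore demonstrates the scorer's rule logic, not its
behaviour on the messiness of the real literature.

`generate_rating_pair` simulates the two-rater design: rater A is the
ground truth; rater B flips each rating independently with a given
probability to a uniformly chosen different category.

## Numerical and edge-case choices

- Zero pooled SD with equal means yields d = 0; with unequal means it
  raises a degenerate-variance error.
- The benefit gate short-circuits on d < 0.2 before any p-value is
  computed, so identical zero-variance arms are simply "no benefit".
- DL tau² is truncated at 0; a non-positive weight denominator (not
  reachable with valid variances) also yields tau² = 0.
- Dose-level monotonicity uses a 1e-12 tolerance for ties.
- Unknown cells in a transcribed profile sheet stay unknown (grey);
  totals are suppressed unless every cell is known.

## Test scales

The suite exercises 500 generated dossiers for score-set discipline, 50
for exact profile recovery, 100 for serialisation round-trips, 200 random
instances per numeric oracle (tolerance 1e-10; kappa 1e-12), and 10,000
simulated independent rater pairs of 300 units for the kappa null
(mean within ±0.02 of 0); the whole suite runs in a few seconds.
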