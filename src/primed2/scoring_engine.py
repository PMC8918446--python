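"""The PRIMED² instrument: 11-item strength-of-evidence scoring.

Each item rates one facet of the cumulative preclinical evidence for a
candidate acute-stroke therapy on a 0–2 scale.  Four items are dichotomous
(0 or 2 only): sex, replication, feasible_window, route.  The remaining
seven are graded (0/1/2).  Items, grouped by content domain:

Animal diversity
    age            benefit includes aged animals (2), young-adult only (1),
                   juvenile only or none (0)
    sex            benefit demonstrated in both sexes (2) or not (0)
    species        number of species with benefit: 0 / 1 / ≥2 → 0 / 1 / 2
    comorbidities  distinct comorbid models with benefit: 0 / 1 / ≥2
Reproducibility
    replication    benefit from ≥2 independent laboratories (2) or not (0)
Treatment timing
    time_epochs    distinct timing epochs with benefit: 0 / 1 / ≥2 → 0/1/2
    feasible_window benefit with treatment start ≥ 45 min after onset (2)
Delivery route
    route          benefit via a clinically feasible route (2) or not (0)
Effect magnitude
    infarct_magnitude pooled d over infarct outcomes: large 2, medium 1,
                   small/none 0
    behavioral     same banding over behavioural outcomes
    dose_response  monotone non-decreasing pooled d across ≥3 dose levels
                   (2), 2 increasing levels (1), else 0

"Benefit" for an outcome is operationalised as an oriented Cohen's
d ≥ 0.2 together with p < 0.05, where p is the reported value when
available and a Welch two-sample t-test from the summary statistics
otherwise.  All thresholds live in :class:`ScoringConfig`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, field_validator
from scipy import stats as _stats

from . import effect_size as es
from .evidence_model import (
    AgentDossier,
    Experiment,
    IschemiaModel,
    OutcomeKind,
    OutcomeMeasure,
    Route,
    SexComposition,
    StudyRecord,
    validate_dossier,
)

__all__ = [
    "ITEM_IDS",
    "DICHOTOMOUS_ITEMS",
    "GRADED_ITEMS",
    "ITEM_GROUPS",
    "TimingEpoch",
    "ItemScore",
    "ScoreProfile",
    "ScoringConfig",
    "classify_epoch",
    "shows_benefit",
    "score_item",
    "score_agent",
    "summary_total",
]

#: Canonical item order (grouped by content domain).
ITEM_IDS: tuple[str, ...] = (
    "age",
    "sex",
    "species",
    "comorbidities",
    "replication",
    "time_epochs",
    "feasible_window",
    "route",
    "infarct_magnitude",
    "behavioral",
    "dose_response",
)

#: Items with 0/2 responses only.
DICHOTOMOUS_ITEMS: frozenset[str] = frozenset(
    {"sex", "replication", "feasible_window", "route"})

#: Items with graded 0/1/2 responses.
GRADED_ITEMS: tuple[str, ...] = tuple(
    i for i in ITEM_IDS if i not in DICHOTOMOUS_ITEMS)

#: Content-domain grouping used by the figural display.
ITEM_GROUPS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Animal diversity", ("age", "sex", "species", "comorbidities")),
    ("Reproducibility", ("replication",)),
    ("Treatment timing", ("time_epochs", "feasible_window")),
    ("Delivery route", ("route",)),
    ("Effect magnitude", ("infarct_magnitude", "behavioral", "dose_response")),
)


class TimingEpoch(str, enum.Enum):
    """Relation of treatment start to ischemia onset and reperfusion."""

    PRE_ONSET = "pre_onset"
    INTRA_ISCHEMIA_TRANSIENT = "intra_ischemia_transient"
    POST_ONSET_PERMANENT = "post_onset_permanent"
    POST_REPERFUSION = "post_reperfusion"


_DEFAULT_ROUTE_FEASIBILITY: dict[Route, bool] = {
    Route.INTRAVENOUS: True,
    Route.INTRAARTERIAL: True,
    Route.INTRAPERITONEAL: True,  # rodent proxy for systemic delivery
    Route.SUBCUTANEOUS: True,
    Route.INTRAMUSCULAR: True,
    Route.ORAL: True,
    Route.INTRANASAL: True,
    Route.NONINVASIVE_DEVICE: True,
    Route.INTRACEREBROVENTRICULAR: False,
    Route.INTRACEREBRAL: False,
    Route.INTRATHECAL: False,
    Route.IMPLANTED_ELECTRODE: False,
    Route.OTHER: False,
}


class ScoringConfig(BaseModel):
    """All tunable thresholds and options of the instrument.

    The defaults are the instrument's published rules: a 45-minute
    clinically attainable treatment-start window (the earliest start
    achieved in a pivotal human acute-stroke trial), effect-size cutpoints
    0.2 / 0.4 / 0.7, and benefit defined as d ≥ 0.2 with p < 0.05.
    """

    model_config = ConfigDict(extra="forbid")

    feasible_window_min: float = 45.0
    effect_boundaries: tuple[float, float, float] = es.DEFAULT_BOUNDARIES
    benefit_alpha: float = 0.05
    benefit_min_d: float = 0.2
    route_feasibility_map: dict[Route, bool] = dict(_DEFAULT_ROUTE_FEASIBILITY)
    pooling_method: es.PoolMethod = es.PoolMethod.RANDOM_DL
    hedges: bool = False
    aged_min_months: float = 18.0  # curator guidance for rodent age_class
    behavioral_uses_magnitude: bool = True
    magnitude_small_scores_one: bool = False

    @field_validator("effect_boundaries")
    @classmethod
    def _boundaries_increasing(cls, v):
        if not (0 < v[0] < v[1] < v[2]):
            raise ValueError("cutpoints must be positive and strictly increasing")
        return v

    @field_validator("benefit_alpha")
    @classmethod
    def _alpha_open_unit(cls, v):
        if not (0.0 < v < 1.0):
            raise ValueError("benefit_alpha must be in (0, 1)")
        return v

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        """Load a config file; absent keys take the built-in defaults."""
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(doc)


class ItemScore(BaseModel):
    """One 0/1/2 rating with its rationale and supporting studies."""

    model_config = ConfigDict(extra="forbid")

    item_id: str
    score: int
    rationale: str
    contributing_study_ids: list[str] = []

    @field_validator("item_id")
    @classmethod
    def _known_item(cls, v):
        if v not in ITEM_IDS:
            raise ValueError(f"unknown item {v!r}; items are {list(ITEM_IDS)}")
        return v

    @field_validator("score")
    @classmethod
    def _score_range(cls, v):
        if v not in (0, 1, 2):
            raise ValueError("score must be 0, 1 or 2")
        return v


class ScoreProfile(BaseModel):
    """The full 11-item profile for one agent, with the optional total."""

    model_config = ConfigDict(extra="forbid")

    agent_id: str
    items: list[ItemScore]
    total: int

    def model_post_init(self, __context) -> None:
        ids = [i.item_id for i in self.items]
        if sorted(ids) != sorted(ITEM_IDS):
            raise ValueError("profile must carry exactly the 11 instrument items")
        if self.total != sum(i.score for i in self.items):
            raise ValueError("total must equal the sum of item scores")
        for item in self.items:
            if item.item_id in DICHOTOMOUS_ITEMS and item.score == 1:
                raise ValueError(f"dichotomous item {item.item_id!r} cannot score 1")

    def score_of(self, item_id: str) -> int:
        for item in self.items:
            if item.item_id == item_id:
                return item.score
        raise KeyError(item_id)


def classify_epoch(experiment: Experiment, study: StudyRecord) -> TimingEpoch:
    """Assign an experiment to a timing epoch.

    start ≤ 0 → pre-onset; a positive start during a transient occlusion →
    intra-ischemia; a positive start in a permanent model → post-onset
    permanent; a start at or after reperfusion → post-reperfusion.
    """
    start = experiment.treatment_start_min
    if start <= 0:
        return TimingEpoch.PRE_ONSET
    if study.ischemia_model is IschemiaModel.PERMANENT:
        return TimingEpoch.POST_ONSET_PERMANENT
    occ = study.occlusion_duration_min
    if occ is None:
        raise ValueError(
            f"study {study.study_id!r}: transient model without occlusion duration")
    if start < occ:
        return TimingEpoch.INTRA_ISCHEMIA_TRANSIENT
    return TimingEpoch.POST_REPERFUSION


def shows_benefit(outcome: OutcomeMeasure, config: ScoringConfig) -> bool:
    """Does one outcome demonstrate benefit?

    True iff the oriented Cohen's d is at least ``benefit_min_d`` AND the
    comparison is significant at ``benefit_alpha``.  The reported p-value
    is used when present; otherwise a two-sided Welch t-test is computed
    from the summary statistics.
    """
    est = es.cohens_d(outcome)
    if est.d < config.benefit_min_d:
        return False
    if outcome.reported_p is not None:
        p = outcome.reported_p
    else:
        t, c = outcome.treated, outcome.control
        p = float(_stats.ttest_ind_from_stats(
            t.mean, t.sd, t.n, c.mean, c.sd, c.n, equal_var=False).pvalue)
    return p < config.benefit_alpha


@dataclass(frozen=True)
class _OutcomeRecord:
    study: StudyRecord
    experiment: Experiment
    outcome: OutcomeMeasure
    epoch: TimingEpoch
    benefit: bool


def _index(dossier: AgentDossier, config: ScoringConfig) -> list[_OutcomeRecord]:
    records = []
    for study in dossier.studies:
        for exp in study.experiments:
            epoch = classify_epoch(exp, study)
            for outcome in exp.outcomes:
                records.append(_OutcomeRecord(
                    study=study,
                    experiment=exp,
                    outcome=outcome,
                    epoch=epoch,
                    benefit=shows_benefit(outcome, config),
                ))
    return records


def _benefit_studies(records) -> dict[str, StudyRecord]:
    return {r.study.study_id: r.study for r in records if r.benefit}


def _magnitude_score(category: es.EffectCategory, config: ScoringConfig) -> int:
    if category is es.EffectCategory.LARGE:
        return 2
    if category is es.EffectCategory.MEDIUM:
        return 1
    if category is es.EffectCategory.SMALL and config.magnitude_small_scores_one:
        return 1
    return 0


def _pool_records(records, config: ScoringConfig) -> Optional[es.PooledEffect]:
    estimates = [es.cohens_d(r.outcome, study_id=r.study.study_id)
                 for r in records]
    if not estimates:
        return None
    return es.pool(
        estimates,
        method=config.pooling_method,
        boundaries=config.effect_boundaries,
        hedges=config.hedges,
    )


def _score_age(records, config):
    ages = {r.study.age_class.value for r in records if r.benefit}
    studies = _benefit_studies(records)
    if "aged" in ages:
        ids = sorted(s for s, st in studies.items() if st.age_class.value == "aged")
        return 2, "benefit demonstrated in aged animals", ids
    if "young_adult" in ages:
        ids = sorted(s for s, st in studies.items()
                     if st.age_class.value == "young_adult")
        return 1, "benefit demonstrated in young-adult animals only", ids
    if "juvenile" in ages:
        return 0, "benefit demonstrated only in juvenile animals", sorted(studies)
    return 0, "no outcome demonstrates benefit", []


def _score_sex(records, config):
    studies = _benefit_studies(records)
    sexes = {st.sex_composition for st in studies.values()}
    both = (SexComposition.BOTH in sexes
            or (SexComposition.MALE in sexes and SexComposition.FEMALE in sexes))
    if both:
        ids = sorted(s for s, st in studies.items()
                     if st.sex_composition in (SexComposition.BOTH,
                                               SexComposition.MALE,
                                               SexComposition.FEMALE))
        return 2, "benefit demonstrated in both sexes", ids
    return 0, "benefit not demonstrated in both sexes", sorted(studies)


def _score_species(records, config):
    studies = _benefit_studies(records)
    species = {st.species.value for st in studies.values()}
    n = len(species)
    if n == 0:
        return 0, "no species with demonstrated benefit", []
    label = ", ".join(sorted(species))
    score = 2 if n >= 2 else 1
    return score, f"benefit demonstrated in {n} species ({label})", sorted(studies)


def _score_comorbidities(records, config):
    studies = _benefit_studies(records)
    comorbid = {st.comorbidity.value for st in studies.values()
                if st.comorbidity.value != "none"}
    if not comorbid:
        return 0, "benefit demonstrated only in healthy animals", sorted(studies)
    ids = sorted(s for s, st in studies.items() if st.comorbidity.value != "none")
    label = ", ".join(sorted(comorbid))
    if len(comorbid) >= 2:
        return 2, f"benefit in ≥2 comorbid models ({label})", ids
    return 1, f"benefit in one comorbid model ({label})", ids


def _score_replication(records, config):
    studies = _benefit_studies(records)
    labs = {st.lab_id for st in studies.values()}
    if len(labs) >= 2:
        return 2, f"benefit replicated across {len(labs)} laboratories", sorted(studies)
    return 0, "benefit not replicated across independent laboratories", sorted(studies)


def _score_time_epochs(records, config):
    epochs = sorted({r.epoch.value for r in records if r.benefit})
    ids = sorted(_benefit_studies(records))
    n = len(epochs)
    score = 0 if n == 0 else (1 if n == 1 else 2)
    if n == 0:
        return 0, "no timing epoch with demonstrated benefit", []
    return score, f"benefit in {n} timing epoch(s): {', '.join(epochs)}", ids


def _score_feasible_window(records, config):
    hits = {r.study.study_id for r in records
            if r.benefit
            and r.experiment.treatment_start_min >= config.feasible_window_min}
    if hits:
        return 2, (f"benefit with treatment start ≥ {config.feasible_window_min:g} "
                   "min after ischemia onset"), sorted(hits)
    return 0, (f"no benefit with treatment start ≥ {config.feasible_window_min:g} "
               "min after ischemia onset"), []


def _score_route(records, config):
    hits = {r.study.study_id for r in records
            if r.benefit
            and config.route_feasibility_map.get(r.experiment.route, False)}
    if hits:
        return 2, "benefit via a clinically feasible delivery route", sorted(hits)
    return 0, "no benefit via a clinically feasible delivery route", []


def _score_magnitude(records, config, kind: OutcomeKind, label: str):
    relevant = [r for r in records if r.outcome.kind is kind]
    pooled = _pool_records(relevant, config)
    if pooled is None:
        return 0, f"no {label} outcomes reported", []
    score = _magnitude_score(pooled.category, config)
    ids = sorted({r.study.study_id for r in relevant})
    return score, (f"pooled d = {pooled.d_pooled:.3f} over k = {pooled.k} "
                   f"{label} outcome(s): {pooled.category.value} effect"), ids


def _score_behavioral_durability(records, config):
    # alternative behavioural rule: reward demonstrated late-timepoint benefit
    hits = [r for r in records
            if r.outcome.kind is OutcomeKind.BEHAVIORAL and r.benefit]
    if not hits:
        return 0, "no behavioral outcome demonstrates benefit", []
    ids = sorted({r.study.study_id for r in hits})
    if any(r.outcome.timepoint_days >= 7 for r in hits):
        return 2, "durable behavioral benefit (≥7 days post-ischemia)", ids
    return 1, "behavioral benefit at early timepoints only", ids


def _score_dose_response(records, config):
    dosed = [r for r in records if r.experiment.dose_value is not None]
    by_dose: dict[float, list[_OutcomeRecord]] = {}
    for r in dosed:
        by_dose.setdefault(float(r.experiment.dose_value), []).append(r)
    if len(by_dose) < 2:
        return 0, "fewer than two distinct dose levels tested", []
    if not any(r.benefit for r in dosed):
        return 0, "no dosed experiment demonstrates benefit", []
    doses = sorted(by_dose)
    pooled_d = [_pool_records(by_dose[dose], config).d_pooled for dose in doses]
    monotone = all(b >= a - 1e-12 for a, b in zip(pooled_d, pooled_d[1:]))
    ids = sorted({r.study.study_id for r in dosed})
    if not monotone:
        return 0, (f"pooled d not monotone over {len(doses)} dose levels"), ids
    if len(doses) >= 3:
        return 2, (f"monotone non-decreasing pooled d over {len(doses)} "
                   "dose levels"), ids
    return 1, "benefit increasing across 2 dose levels", ids


_ITEM_SCORERS = {
    "age": _score_age,
    "sex": _score_sex,
    "species": _score_species,
    "comorbidities": _score_comorbidities,
    "replication": _score_replication,
    "time_epochs": _score_time_epochs,
    "feasible_window": _score_feasible_window,
    "route": _score_route,
    "infarct_magnitude": lambda r, c: _score_magnitude(
        r, c, OutcomeKind.INFARCT_VOLUME, "infarct-volume"),
    "behavioral": lambda r, c: (
        _score_magnitude(r, c, OutcomeKind.BEHAVIORAL, "behavioral")
        if c.behavioral_uses_magnitude
        else _score_behavioral_durability(r, c)),
    "dose_response": _score_dose_response,
}


def _score_item_from_index(records, item_id: str,
                           config: ScoringConfig) -> ItemScore:
    if item_id not in _ITEM_SCORERS:
        raise KeyError(
            f"unknown item {item_id!r}; the 11 items are {list(ITEM_IDS)}")
    score, rationale, ids = _ITEM_SCORERS[item_id](records, config)
    return ItemScore(item_id=item_id, score=score, rationale=rationale,
                     contributing_study_ids=ids)


def score_item(dossier: AgentDossier, item_id: str,
               config: Optional[ScoringConfig] = None) -> ItemScore:
    """Score one instrument item for an agent dossier."""
    config = config or ScoringConfig()
    return _score_item_from_index(_index(dossier, config), item_id, config)


def score_agent(dossier: AgentDossier,
                config: Optional[ScoringConfig] = None) -> ScoreProfile:
    """Score all 11 items and assemble the agent's profile.

    A pure function of (dossier, config): repeated calls give identical
    results.  Raises :class:`~primed2.evidence_model.DossierValidationError`
    on an invalid dossier.
    """
    from .evidence_model import DossierValidationError

    config = config or ScoringConfig()
    violations = validate_dossier(dossier)
    if violations:
        raise DossierValidationError(violations)
    records = _index(dossier, config)
    items = [_score_item_from_index(records, item_id, config)
             for item_id in ITEM_IDS]
    return ScoreProfile(
        agent_id=dossier.agent_id,
        items=items,
        total=sum(i.score for i in items),
    )


def summary_total(profile: ScoreProfile) -> int:
    """The optional summary total (0–22), the plain sum of item scores.

    Report it with caution: it fails to convey the granular information of
    each scale item.
    """
    return sum(i.score for i in profile.items)
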