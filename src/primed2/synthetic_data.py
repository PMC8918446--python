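"""Seeded generators of dossiers and rating pairs with known ground truth.

:func:`generate_dossier` constructs, from a target 11-item score profile,
an evidence dossier that the scoring engine maps back to exactly that
profile under the default configuration: study rosters (species, age, sex,
comorbidity, laboratory) realise the diversity items; treatment start times
realise the epoch and window items; per-arm summary statistics with the
treated mean offset by d·SD realise the magnitude categories; and dose
ladders realise the dose–response item.

Arm statistics are exact population values by default (mean offset =
d_true·noise_sd, n = 12 per arm), so category boundaries are hit
deterministically; ``sampled=True`` instead draws finite-sample normal data
for stress-testing the benefit gate.  Benefit significance is carried by a
reported p-value (0.001 for beneficial outcomes, 0.9 otherwise) so that
small-but-real effects (pooled d ≈ 0.3) can demonstrate benefit without
inflating the magnitude items.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .evidence_model import (
    AgeClass,
    AgentDossier,
    Comorbidity,
    Direction,
    Experiment,
    IschemiaModel,
    Modality,
    OutcomeKind,
    OutcomeMeasure,
    Route,
    SexComposition,
    Species,
    StudyRecord,
    SummaryStats,
)
from .reliability import RatingSet
from .scoring_engine import DICHOTOMOUS_ITEMS, ITEM_IDS

__all__ = [
    "ProfileSpec",
    "InfeasibleProfileError",
    "check_realizable",
    "generate_dossier",
    "random_profile_spec",
    "generate_rating_pair",
]

N_PER_ARM = 12
OCCLUSION_MIN = 60.0

#: Magnitude-item score → true SMD generated for that category, chosen with
#: ≥0.05 margin from the 0.2/0.4/0.7 cutpoints so pooling noise cannot
#: cross a boundary.
DEFAULT_D_TRUE: dict[int, float] = {0: 0.30, 1: 0.55, 2: 1.20}

_BENEFIT_P = 0.001
_NULL_P = 0.9


class InfeasibleProfileError(ValueError):
    """The requested target profile cannot be realised as a dossier."""


class ProfileSpec(BaseModel):
    """A target score profile plus generation knobs."""

    model_config = ConfigDict(extra="forbid")

    target_scores: dict[str, int]
    n_studies: Optional[int] = None  # default: the minimum feasible count
    infarct_d_true: dict[int, float] = dict(DEFAULT_D_TRUE)
    noise_sd: float = 10.0
    seed: int = 0
    sampled: bool = False

    @field_validator("target_scores")
    @classmethod
    def _check_targets(cls, v):
        missing = set(ITEM_IDS) - set(v)
        extra = set(v) - set(ITEM_IDS)
        if missing or extra:
            raise ValueError(
                f"target_scores must cover exactly the 11 items "
                f"(missing {sorted(missing)}, extra {sorted(extra)})")
        for item, score in v.items():
            if score not in (0, 1, 2):
                raise ValueError(f"{item}: target score must be 0, 1 or 2")
            if item in DICHOTOMOUS_ITEMS and score == 1:
                raise ValueError(f"{item} is dichotomous; 1 is not a valid target")
        return v


def _min_studies(targets: dict[str, int]) -> int:
    need_two = (targets["species"] == 2 or targets["comorbidities"] == 2
                or targets["replication"] == 2)
    return 2 if need_two else 1


def check_realizable(targets: dict[str, int],
                     n_studies: Optional[int] = None) -> list[str]:
    """Return the reasons (if any) a target profile cannot be generated."""
    problems: list[str] = []
    benefit = targets["time_epochs"] >= 1
    if benefit and targets["species"] == 0:
        problems.append(
            "time_epochs ≥ 1 implies benefit exists, so species must be ≥ 1")
    if not benefit:
        for item in ("age", "sex", "species", "comorbidities", "replication",
                     "feasible_window", "route", "dose_response"):
            if targets[item] != 0:
                problems.append(
                    f"{item} > 0 requires demonstrated benefit (time_epochs ≥ 1)")
    if n_studies is not None and n_studies < _min_studies(targets):
        problems.append(
            f"n_studies = {n_studies} too small; profile needs "
            f"≥ {_min_studies(targets)} studies")
    return problems


def _starts(targets: dict[str, int]) -> list[float]:
    """Treatment start times realising the epoch and window targets."""
    benefit = targets["time_epochs"] >= 1
    if not benefit:
        return [30.0]
    feasible = targets["feasible_window"] == 2
    two_epochs = targets["time_epochs"] == 2
    if feasible and two_epochs:
        return [-5.0, 90.0]   # pre-onset + post-reperfusion (90 ≥ 45)
    if feasible:
        return [90.0]         # post-reperfusion only
    if two_epochs:
        return [-5.0, 30.0]   # pre-onset + intra-ischemia, both < 45
    return [30.0]             # intra-ischemia only


def _outcome(kind: OutcomeKind, d_true: float, noise_sd: float, benefit: bool,
             rng: np.random.Generator, sampled: bool,
             timepoint_days: float = 1.0) -> OutcomeMeasure:
    control_mean = float(np.round(rng.uniform(40.0, 60.0), 3))
    offset = d_true * noise_sd
    if kind is OutcomeKind.INFARCT_VOLUME:
        direction = Direction.LOWER_IS_BETTER
        treated_mean = control_mean - offset
    else:
        direction = Direction.HIGHER_IS_BETTER
        treated_mean = control_mean + offset
    if sampled:
        t_draw = rng.normal(treated_mean, noise_sd, N_PER_ARM)
        c_draw = rng.normal(control_mean, noise_sd, N_PER_ARM)
        treated = SummaryStats(n=N_PER_ARM, mean=float(t_draw.mean()),
                               sd=float(t_draw.std(ddof=1)))
        control = SummaryStats(n=N_PER_ARM, mean=float(c_draw.mean()),
                               sd=float(c_draw.std(ddof=1)))
        reported_p = None
    else:
        treated = SummaryStats(n=N_PER_ARM, mean=round(treated_mean, 6),
                               sd=noise_sd)
        control = SummaryStats(n=N_PER_ARM, mean=control_mean, sd=noise_sd)
        reported_p = _BENEFIT_P if benefit else _NULL_P
    return OutcomeMeasure(
        kind=kind,
        timepoint_days=timepoint_days,
        direction=direction,
        treated=treated,
        control=control,
        reported_p=reported_p,
    )


def generate_dossier(spec: ProfileSpec) -> AgentDossier:
    """Build a dossier whose default-config score profile equals the target.

    Deterministic given ``spec.seed``.  Raises
    :class:`InfeasibleProfileError` when the target profile is
    self-contradictory or ``n_studies`` is too small.
    """
    targets = spec.target_scores
    problems = check_realizable(targets, spec.n_studies)
    if problems:
        raise InfeasibleProfileError("; ".join(problems))
    rng = np.random.default_rng(spec.seed)
    benefit = targets["time_epochs"] >= 1
    k_min = _min_studies(targets)
    n_studies = spec.n_studies if spec.n_studies is not None else k_min

    species_roster = ([Species.RAT, Species.MOUSE]
                      if targets["species"] == 2 else [Species.RAT])
    comorb_roster = {
        0: [Comorbidity.NONE],
        1: [Comorbidity.HYPERTENSION],
        2: [Comorbidity.HYPERTENSION, Comorbidity.DIABETES],
    }[targets["comorbidities"]]
    lab_roster = (["lab_01", "lab_02"]
                  if targets["replication"] == 2 else ["lab_01"])
    age = {0: AgeClass.JUVENILE, 1: AgeClass.YOUNG_ADULT,
           2: AgeClass.AGED}[targets["age"]]
    sex = SexComposition.BOTH if targets["sex"] == 2 else SexComposition.MALE
    route = (Route.INTRAVENOUS if targets["route"] == 2
             else Route.INTRACEREBROVENTRICULAR)
    starts = _starts(targets)
    d_infarct = spec.infarct_d_true[targets["infarct_magnitude"]]
    d_behav = spec.infarct_d_true.get(targets["behavioral"], 0.0)

    studies = []
    for s in range(n_studies):
        experiments = []
        for e, start in enumerate(starts):
            outcomes = [_outcome(OutcomeKind.INFARCT_VOLUME, d_infarct,
                                 spec.noise_sd, benefit, rng, spec.sampled)]
            if e == 0 and targets["behavioral"] >= 1:
                outcomes.append(_outcome(
                    OutcomeKind.BEHAVIORAL, d_behav, spec.noise_sd, benefit,
                    rng, spec.sampled, timepoint_days=7.0))
            experiments.append(Experiment(
                experiment_id=f"S{s + 1:02d}E{e + 1:02d}",
                treatment_start_min=start,
                route=route,
                outcomes=outcomes,
            ))
        # dose ladder on the first study only: monotone non-decreasing d
        if s == 0 and targets["dose_response"] >= 1:
            m = d_infarct
            ladder = ([m, m + 0.05] if targets["dose_response"] == 1
                      else [m - 0.05, m, m + 0.05])
            for j, d_dose in enumerate(ladder):
                experiments.append(Experiment(
                    experiment_id=f"S{s + 1:02d}D{j + 1:02d}",
                    treatment_start_min=starts[0],
                    route=route,
                    dose_value=10.0 * (j + 1),
                    dose_unit="mg/kg",
                    outcomes=[_outcome(OutcomeKind.INFARCT_VOLUME, d_dose,
                                       spec.noise_sd, benefit, rng,
                                       spec.sampled)],
                ))
        studies.append(StudyRecord(
            study_id=f"study_{s + 1:02d}",
            lab_id=lab_roster[s % len(lab_roster)],
            species=species_roster[s % len(species_roster)],
            age_class=age,
            sex_composition=sex,
            comorbidity=comorb_roster[s % len(comorb_roster)],
            ischemia_model=IschemiaModel.TRANSIENT,
            occlusion_duration_min=OCCLUSION_MIN,
            experiments=experiments,
        ))
    return AgentDossier(
        agent_id=f"synthetic_{spec.seed}",
        agent_name=f"Synthetic agent (seed {spec.seed})",
        modality=Modality.DRUG,
        studies=studies,
    )


def random_profile_spec(seed: int, noise_sd: float = 10.0,
                        p_no_benefit: float = 0.1) -> ProfileSpec:
    """Draw a random *realizable* target profile (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    targets: dict[str, int] = {}
    if rng.random() < p_no_benefit:
        for item in ITEM_IDS:
            targets[item] = 0
        # magnitude items may still be nonzero without demonstrated benefit
        targets["infarct_magnitude"] = int(rng.integers(0, 3))
        targets["behavioral"] = int(rng.integers(0, 3))
    else:
        targets["time_epochs"] = int(rng.integers(1, 3))
        targets["species"] = int(rng.integers(1, 3))
        targets["age"] = int(rng.integers(0, 3))
        targets["comorbidities"] = int(rng.integers(0, 3))
        targets["infarct_magnitude"] = int(rng.integers(0, 3))
        targets["behavioral"] = int(rng.integers(0, 3))
        targets["dose_response"] = int(rng.integers(0, 3))
        for item in ("sex", "replication", "feasible_window", "route"):
            targets[item] = int(rng.choice([0, 2]))
    return ProfileSpec(target_scores=targets, seed=int(seed),
                       noise_sd=noise_sd)


def generate_rating_pair(
    true_scores: RatingSet,
    disagreement_rate: float,
    seed: int,
) -> tuple[RatingSet, RatingSet]:
    """Simulate a two-rater design around a ground-truth rating set.

    Rater A reproduces the truth; rater B independently flips each rating
    with the given probability to a uniformly chosen *different* category.
    """
    if not (0.0 <= disagreement_rate <= 1.0):
        raise ValueError("disagreement_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a = RatingSet(rater_id="rater_a", ratings=dict(true_scores.ratings))
    b_ratings = {}
    for key in sorted(true_scores.ratings):
        value = true_scores.ratings[key]
        if rng.random() < disagreement_rate:
            others = [v for v in (0, 1, 2) if v != value]
            value = int(others[rng.integers(0, len(others))])
        b_ratings[key] = value
    b = RatingSet(rater_id="rater_b", ratings=b_ratings)
    return a, b
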