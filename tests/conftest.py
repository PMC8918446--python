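from pathlib import Path

import pytest

from primed2.evidence_model import (
    AgentDossier,
    Experiment,
    OutcomeMeasure,
    StudyRecord,
    SummaryStats,
)
from primed2.scoring_engine import ScoringConfig

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


def make_outcome(mean_t=30.0, mean_c=50.0, sd=10.0, n=12, kind="infarct_volume",
                 direction=None, reported_p=None, timepoint_days=1.0):
    return OutcomeMeasure(
        kind=kind,
        timepoint_days=timepoint_days,
        direction=direction,
        treated=SummaryStats(n=n, mean=mean_t, sd=sd),
        control=SummaryStats(n=n, mean=mean_c, sd=sd),
        reported_p=reported_p,
    )


def make_experiment(start=90.0, route="intravenous", outcomes=None,
                    experiment_id="E1", dose_value=None, dose_unit=None):
    return Experiment(
        experiment_id=experiment_id,
        treatment_start_min=start,
        route=route,
        dose_value=dose_value,
        dose_unit=dose_unit,
        outcomes=outcomes if outcomes is not None else [make_outcome()],
    )


def make_study(study_id="S1", lab_id="lab_A", species="rat",
               age_class="young_adult", sex="male", comorbidity="none",
               model="transient", occlusion=60.0, experiments=None):
    return StudyRecord(
        study_id=study_id,
        lab_id=lab_id,
        species=species,
        age_class=age_class,
        sex_composition=sex,
        comorbidity=comorbidity,
        ischemia_model=model,
        occlusion_duration_min=occlusion if model == "transient" else None,
        experiments=experiments if experiments is not None else [make_experiment()],
    )


def make_dossier(*studies, agent_id="agent_x"):
    if not studies:
        studies = (make_study(),)
    return AgentDossier(agent_id=agent_id, agent_name=agent_id,
                        modality="drug", studies=list(studies))


@pytest.fixture
def config():
    return ScoringConfig()


@pytest.fixture
def fixtures_dir():
    return FIXTURES
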