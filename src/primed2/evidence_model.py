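"""Domain model for preclinical stroke-therapy evidence dossiers.

An :class:`AgentDossier` is the unit of scoring: the totality of reported
animal-model evidence for one candidate acute-stroke therapy, organised as
studies → experiments → treated-vs-control outcome summaries.  Only summary
statistics (n, mean, SD per arm) are stored, never individual-animal data.

Structural typing is enforced at construction (pydantic); the scientific
invariants (arm sizes, occlusion duration for transient models, dose
value/unit pairing, study-id uniqueness) are checked by
:func:`validate_dossier`, which reports violations as data so that a curator
can see every problem in one pass.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = [
    "Species",
    "AgeClass",
    "SexComposition",
    "Comorbidity",
    "IschemiaModel",
    "Route",
    "OutcomeKind",
    "Direction",
    "Modality",
    "SummaryStats",
    "OutcomeMeasure",
    "Experiment",
    "StudyRecord",
    "AgentDossier",
    "Violation",
    "DossierFormatError",
    "DossierValidationError",
    "load_dossier",
    "write_dossier",
    "validate_dossier",
]


class _CIStrEnum(str, enum.Enum):
    """String enum with case-insensitive parsing from input documents."""

    @classmethod
    def _missing_(cls, value):
        if isinstance(value, str):
            folded = value.strip().lower()
            for member in cls:
                if member.value == folded:
                    return member
        return None


class Species(_CIStrEnum):
    MOUSE = "mouse"
    RAT = "rat"
    RABBIT = "rabbit"
    PIG = "pig"
    SHEEP = "sheep"
    NONHUMAN_PRIMATE = "nonhuman_primate"
    OTHER = "other"


class AgeClass(_CIStrEnum):
    JUVENILE = "juvenile"
    YOUNG_ADULT = "young_adult"
    AGED = "aged"


class SexComposition(_CIStrEnum):
    MALE = "male"
    FEMALE = "female"
    BOTH = "both"
    # deliberately distinct from "both": never silently upgraded
    UNREPORTED = "unreported"


class Comorbidity(_CIStrEnum):
    NONE = "none"
    HYPERTENSION = "hypertension"
    DIABETES = "diabetes"
    HYPERGLYCEMIA = "hyperglycemia"
    OBESITY = "obesity"
    ADVANCED_AGE_PLUS_COMORBID = "advanced_age_plus_comorbid"
    OTHER = "other"


class IschemiaModel(_CIStrEnum):
    TRANSIENT = "transient"
    PERMANENT = "permanent"


class Route(_CIStrEnum):
    INTRAVENOUS = "intravenous"
    INTRAARTERIAL = "intraarterial"
    INTRAPERITONEAL = "intraperitoneal"
    SUBCUTANEOUS = "subcutaneous"
    INTRAMUSCULAR = "intramuscular"
    ORAL = "oral"
    INTRANASAL = "intranasal"
    INTRACEREBROVENTRICULAR = "intracerebroventricular"
    INTRACEREBRAL = "intracerebral"
    INTRATHECAL = "intrathecal"
    IMPLANTED_ELECTRODE = "implanted_electrode"
    NONINVASIVE_DEVICE = "noninvasive_device"
    OTHER = "other"


class OutcomeKind(_CIStrEnum):
    INFARCT_VOLUME = "infarct_volume"
    BEHAVIORAL = "behavioral"


class Direction(_CIStrEnum):
    LOWER_IS_BETTER = "lower_is_better"
    HIGHER_IS_BETTER = "higher_is_better"


class Modality(_CIStrEnum):
    DRUG = "drug"
    DEVICE = "device"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", use_enum_values=False)


class SummaryStats(_Model):
    """Per-arm summary: animal count, outcome mean, outcome SD."""

    n: int
    mean: float
    sd: float


class OutcomeMeasure(_Model):
    """One treated-vs-control comparison at one assessment timepoint."""

    kind: OutcomeKind
    timepoint_days: float = 0.0
    direction: Optional[Direction] = None
    treated: SummaryStats
    control: SummaryStats
    reported_p: Optional[float] = None

    def model_post_init(self, __context) -> None:
        # infarct volume shrinking is the beneficial direction by default
        if self.direction is None:
            if self.kind is OutcomeKind.INFARCT_VOLUME:
                self.direction = Direction.LOWER_IS_BETTER
            else:
                self.direction = Direction.HIGHER_IS_BETTER


class Experiment(_Model):
    """One treatment arm configuration (timing, route, dose) with outcomes.

    ``treatment_start_min`` is minutes relative to ischemia onset (onset = 0);
    pre-onset administration is encoded as a value ≤ 0.
    """

    experiment_id: str
    treatment_start_min: float
    route: Route
    dose_value: Optional[float] = None
    dose_unit: Optional[str] = None
    outcomes: list[OutcomeMeasure] = []


class StudyRecord(_Model):
    """One published study: animal model characteristics plus experiments."""

    study_id: str
    lab_id: str
    species: Species
    age_class: AgeClass
    sex_composition: SexComposition
    comorbidity: Comorbidity
    ischemia_model: IschemiaModel
    occlusion_duration_min: Optional[float] = None
    experiments: list[Experiment] = []


class AgentDossier(_Model):
    """All preclinical evidence for one candidate agent."""

    agent_id: str
    agent_name: str = ""
    modality: Modality = Modality.DRUG
    studies: list[StudyRecord] = []


@dataclass(frozen=True)
class Violation:
    """One invariant violation, addressed by a path into the document."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


class DossierFormatError(ValueError):
    """The source text could not be parsed in the requested format."""


class DossierValidationError(ValueError):
    """The document parsed but violates the dossier schema."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "invalid dossier:\n" + "\n".join(f"  - {v}" for v in violations)
        )


def validate_dossier(dossier: AgentDossier) -> list[Violation]:
    """Check every schema invariant; return violations as data (never raises).

    An empty list means the dossier is valid.  Each violation names the
    study/experiment/field where it occurred.
    """
    out: list[Violation] = []
    seen_ids: set[str] = set()
    for study in dossier.studies:
        sid = study.study_id
        if sid in seen_ids:
            out.append(Violation(f"studies[{sid}]", f"duplicate study_id {sid!r}"))
        seen_ids.add(sid)
        base = f"studies[{sid}]"
        if study.ischemia_model is IschemiaModel.TRANSIENT:
            if study.occlusion_duration_min is None:
                out.append(Violation(
                    f"{base}.occlusion_duration_min",
                    "required for transient ischemia models",
                ))
            elif study.occlusion_duration_min <= 0:
                out.append(Violation(
                    f"{base}.occlusion_duration_min", "must be > 0"))
        elif study.occlusion_duration_min is not None:
            out.append(Violation(
                f"{base}.occlusion_duration_min",
                "must be absent for permanent ischemia models",
            ))
        if not study.experiments:
            out.append(Violation(f"{base}.experiments", "must be non-empty"))
        for exp in study.experiments:
            ebase = f"{base}.experiments[{exp.experiment_id}]"
            if (exp.dose_value is None) != (exp.dose_unit is None):
                out.append(Violation(
                    f"{ebase}.dose_value",
                    "dose_value and dose_unit must be given together",
                ))
            if exp.dose_value is not None and exp.dose_value < 0:
                out.append(Violation(f"{ebase}.dose_value", "must be ≥ 0"))
            if not exp.outcomes:
                out.append(Violation(f"{ebase}.outcomes", "must be non-empty"))
            for i, om in enumerate(exp.outcomes):
                obase = f"{ebase}.outcomes[{i}]"
                if om.timepoint_days < 0:
                    out.append(Violation(f"{obase}.timepoint_days", "must be ≥ 0"))
                if om.reported_p is not None and not (0.0 <= om.reported_p <= 1.0):
                    out.append(Violation(f"{obase}.reported_p", "must be in [0, 1]"))
                for arm_name, arm in (("treated", om.treated), ("control", om.control)):
                    if arm.n < 2:
                        out.append(Violation(f"{obase}.{arm_name}.n", "must be ≥ 2"))
                    if arm.sd < 0:
                        out.append(Violation(f"{obase}.{arm_name}.sd", "must be ≥ 0"))
    if not dossier.studies:
        out.append(Violation("studies", "must be non-empty"))
    return out


def _infer_format(source, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("yaml", "json"):
            raise ValueError(f"format must be 'yaml' or 'json', got {fmt!r}")
        return fmt
    if isinstance(source, (str, Path)):
        suffix = Path(source).suffix.lower()
        if suffix == ".json":
            return "json"
    return "yaml"  # YAML is the primary dialect; JSON is a YAML subset


def _parse(text: str, fmt: str):
    if fmt == "json":
        try:
            return json.loads(text)
        except json.JSONDecodeError as exc:
            raise DossierFormatError(
                f"JSON parse error at line {exc.lineno}: {exc.msg}") from exc
    try:
        return yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise DossierFormatError(f"YAML parse error{line}: {exc}") from exc


def _pydantic_violations(exc: ValidationError) -> list[Violation]:
    out = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"])
        msg = err["msg"]
        if err["type"] == "enum":
            msg = f"unknown value {err.get('input')!r}; {msg}"
        out.append(Violation(path or "<root>", msg))
    return out


def load_dossier(
    source: Union[str, Path, IO[str]],
    format: Optional[str] = None,
) -> AgentDossier:
    """Load and fully validate an agent dossier from YAML or JSON.

    ``source`` may be a path or an open text stream.  The format is taken
    from the ``format`` argument, else inferred from the file suffix
    (defaulting to YAML, of which JSON is a subset).  Enum tokens are matched
    case-insensitively.

    Raises
    ------
    DossierFormatError
        On parse failure, naming the offending line.
    DossierValidationError
        On unknown enum tokens, wrong structure, or violated invariants;
        carries a list of :class:`Violation`.
    """
    fmt = _infer_format(source, format)
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    doc = _parse(text, fmt)
    if not isinstance(doc, dict):
        raise DossierValidationError(
            [Violation("<root>", "document must be a mapping")])
    try:
        dossier = AgentDossier.model_validate(doc)
    except ValidationError as exc:
        raise DossierValidationError(_pydantic_violations(exc)) from exc
    violations = validate_dossier(dossier)
    if violations:
        raise DossierValidationError(violations)
    return dossier


def _to_plain(dossier: AgentDossier) -> dict:
    # exclude optional fields left unset so round-trips carry no nulls
    return dossier.model_dump(mode="json", exclude_none=True)


def write_dossier(dossier: AgentDossier, format: str = "yaml") -> str:
    """Serialise a dossier to YAML or JSON text.

    Field and study order are preserved, optional absent fields are omitted,
    and the output is deterministic: ``load_dossier`` of the result equals
    the input field-for-field, and a second write is byte-identical.
    """
    fmt = _infer_format(None, format)
    plain = _to_plain(dossier)
    if fmt == "json":
        return json.dumps(plain, indent=2) + "\n"
    return yaml.safe_dump(plain, sort_keys=False, allow_unicode=True)
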