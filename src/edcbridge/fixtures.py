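"""Deterministic generators for every input the test suite needs.

Everything here is seed-driven: the same seed always produces the same
instruments, payloads and rating matrices, byte for byte. Ground-truth
labels (planted rule violations) ride alongside the generated data, never
inside it, so pipeline code cannot cheat.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field

from .logic import Comparison, Literal, Selected
from .model import (
    TYPE_VALIDATION_KIND,
    Choice,
    ChoiceList,
    FieldDef,
    FieldType,
    InstrumentDef,
    SemanticTag,
    ValidationSpec,
)
from .ontology import OntologySpec, generate_ontology
from .quality import ValidationRule, VisitConfig

__all__ = [
    "ToyProject",
    "DEFAULT_BASE_IRI",
    "CSUQ_ITEM_MEANS",
    "CSUQ_RESPONDENTS",
    "RESPONDENT_GENDER_COUNTS",
    "REGISTRY_PROJECTS",
    "treatment_instrument",
    "make_toy_project",
    "make_random_instrument",
    "simulate_submissions",
    "make_csuq_matrix",
]

DEFAULT_BASE_IRI = "http://vocab.redbox.technology/vocab/treatment"

#: published per-item means of the 16-question usability survey
CSUQ_ITEM_MEANS = [
    6.25, 6.19, 6.44, 6.38, 6.06, 6.25,
    5.19, 5.38, 5.63, 6.00, 6.44, 5.94,
    5.94, 6.00, 5.94, 6.25,
]
CSUQ_RESPONDENTS = 17
RESPONDENT_GENDER_COUNTS = {"men": 7, "women": 9, "not_answered": 1}

#: deployment registry rows: (name, centers, instruments, fields, expected records)
REGISTRY_PROJECTS = [
    ("I", 3, 4, 175, 2500),
    ("II", 12, 14, 679, 3800),
    ("III", 10, 9, 183, 1020),
    ("IV", 3, 24, 528, 1000),
    ("V", 5, 14, 357, 500),
]

_WORDS = [
    "cough", "fever", "chills", "fatigue", "sweat", "weight", "appetite",
    "smear", "culture", "xray", "contact", "bcg", "hiv", "diabetes",
]
_FIELD_STEMS = [
    "age", "weight_kg", "height_cm", "visit_date", "onset", "followup",
    "notes_free", "sample_time", "score", "dose", "temp", "duration",
]


@dataclass
class ToyProject:
    instrument: InstrumentDef
    ontology: OntologySpec
    visit_configs: list[VisitConfig]
    rules: list[ValidationRule]
    participant_field: str = "participant_code"
    reference_field: str = "start_date"
    project_id: str = "toy"


def treatment_instrument() -> InstrumentDef:
    """The canonical 3-field treatment form used across the examples:
    two validated date boxes around a single-choice clinical form."""
    instr = InstrumentDef("treatment")
    instr.choice_lists["clinical_form"] = ChoiceList(
        "clinical_form",
        [Choice("1", "Pulmonary"), Choice("2", "Extrapulmonary")],
    )
    instr.fields = [
        FieldDef("start_date", FieldType.DATE, "Start date",
                 validation=ValidationSpec(kind="date_ymd")),
        FieldDef("clinical_form", FieldType.SELECT_ONE, "TB clinical form",
                 choice_list="clinical_form"),
        FieldDef("discharg_date", FieldType.DATE, "Discharge date",
                 validation=ValidationSpec(kind="date_ymd")),
    ]
    return instr


def make_random_instrument(seed: int, n_extra: int = 0, name: str = "toy_form") -> InstrumentDef:
    """A seeded instrument exercising every field type.

    Contains a fixed skeleton (participant code, the treatment trio, one
    field per remaining type, skip logic and a bounded integer) plus
    ``n_extra`` randomized text/integer/select fields.
    """
    rng = random.Random(seed)
    instr = InstrumentDef(name)

    instr.choice_lists["clinical_form"] = ChoiceList(
        "clinical_form",
        [Choice("1", "Pulmonary"), Choice("2", "Extrapulmonary")],
    )
    symptoms = rng.sample(_WORDS, k=rng.randint(2, 4))
    instr.choice_lists["symptoms"] = ChoiceList(
        "symptoms", [Choice(w, w.capitalize()) for w in symptoms]
    )
    instr.choice_lists["sex"] = ChoiceList(
        "sex", [Choice("1", "Male"), Choice("2", "Female")]
    )

    instr.fields = [
        FieldDef("participant_code", FieldType.TEXT, "Participant code",
                 required=True, participant_id=True, identifier=True),
        FieldDef("start_date", FieldType.DATE, "Start date",
                 validation=ValidationSpec(kind="date_ymd"),
                 tag=SemanticTag("hxl_hashtag", "#date+start")),
        FieldDef("clinical_form", FieldType.SELECT_ONE, "TB clinical form",
                 choice_list="clinical_form"),
        FieldDef("discharg_date", FieldType.DATE, "Discharge date",
                 validation=ValidationSpec(kind="date_ymd")),
        FieldDef("sex", FieldType.SELECT_ONE, "Sex", choice_list="sex"),
        FieldDef("age", FieldType.INTEGER, "Age in years",
                 validation=ValidationSpec(kind="integer", min="0", max="120")),
        FieldDef("weight", FieldType.DECIMAL, "Weight (kg)",
                 validation=ValidationSpec(kind="number")),
        FieldDef("checkbox_symptoms", FieldType.SELECT_MULTIPLE, "Symptoms",
                 choice_list="symptoms"),
        FieldDef("symptom_onset", FieldType.DATE, "Symptom onset",
                 relevant=Selected("checkbox_symptoms", symptoms[0]),
                 validation=ValidationSpec(kind="date_ymd")),
        FieldDef("visit_time", FieldType.TIME, "Visit time",
                 validation=ValidationSpec(kind="time")),
        FieldDef("followup_at", FieldType.DATETIME, "Follow-up at",
                 validation=ValidationSpec(kind="datetime_ymd")),
        FieldDef("bmi", FieldType.CALC, guidance_hint="Body mass index",
                 calculation="[weight]/(([height]/100)*([height]/100))"),
        FieldDef("height", FieldType.INTEGER, "Height (cm)",
                 relevant=Comparison("age", ">=", Literal("18", quoted=False)),
                 validation=ValidationSpec(kind="integer")),
        FieldDef("consent_note", FieldType.NOTE, "Read the consent text aloud"),
        FieldDef("consent_scan", FieldType.FILE, "Consent scan"),
    ]

    used = {f.name for f in instr.fields}
    for i in range(n_extra):
        stem = rng.choice(_FIELD_STEMS)
        fname = f"{stem}_{i}"
        while fname in used:
            fname += "x"
        used.add(fname)
        kind = rng.choice(["text", "integer", "select_one", "select_multiple"])
        if kind == "text":
            instr.fields.append(FieldDef(fname, FieldType.TEXT, stem.replace("_", " ")))
        elif kind == "integer":
            lo, hi = sorted(rng.sample(range(0, 200), 2))
            instr.fields.append(
                FieldDef(fname, FieldType.INTEGER, stem,
                         validation=ValidationSpec(kind="integer", min=str(lo), max=str(hi)))
            )
        else:
            ln = f"list_{fname}"
            codes = rng.sample(_WORDS, k=rng.randint(2, 3))
            instr.choice_lists[ln] = ChoiceList(ln, [Choice(c, c.title()) for c in codes])
            if kind == "select_multiple":
                fname = f"checkbox_{fname}"
            instr.fields.append(
                FieldDef(fname, FieldType(kind), stem, choice_list=ln)
            )
    return instr


def make_toy_project(seed: int) -> ToyProject:
    """The standard test project: the treatment trio embedded in a seeded
    instrument covering every field type, visit offsets {0, 7, 30, 90},
    and a small rule set with known semantics."""
    instr = make_random_instrument(seed, n_extra=3)
    ontology = generate_ontology(treatment_instrument(), DEFAULT_BASE_IRI, "v1")
    visits = [
        VisitConfig("visit_0", 0, 0, [instr.name]),
        VisitConfig("visit_7", 7, 0, [instr.name]),
        VisitConfig("visit_30", 30, 0, [instr.name]),
        VisitConfig("visit_90", 90, 0, [instr.name]),
    ]
    rules = [
        ValidationRule("r_age_range", "toy", instr.name, "age", "range",
                       {"min": 0, "max": 120}),
        ValidationRule("r_sex_required", "toy", instr.name, "sex", "required", {}),
        ValidationRule("r_start_format", "toy", instr.name, "start_date",
                       "format", {"format": "date_ymd"}),
    ]
    return ToyProject(instrument=instr, ontology=ontology, visit_configs=visits, rules=rules)


# ---------------------------------------------------------------------------
# submissions
# ---------------------------------------------------------------------------


@dataclass
class PlantedTruth:
    """Ground truth for one simulated payload."""

    participant: str
    violations: list[tuple[str, str]] = dc_field(default_factory=list)  # (field, rule_id)


def simulate_submissions(
    project: ToyProject,
    n: int,
    seed: int,
    missingness: float = 0.0,
    violation_rate: float = 0.0,
) -> tuple[list[dict], list[PlantedTruth]]:
    """Seeded platform-style payloads plus their ground-truth labels.

    Each payload carries realistic metadata keys (``_id``, ``_uuid``,
    ``meta/instanceID``, ``formhub/uuid``, ``start``/``end``) alongside the
    answers. With probability ``violation_rate`` per payload, exactly one
    rule from the project's rule set is deliberately broken, and that
    (field, rule) pair is recorded in the returned truth labels. Clean
    payloads are guaranteed to pass every rule.
    """
    rng = random.Random(seed)
    instr = project.instrument
    payloads: list[dict] = []
    truths: list[PlantedTruth] = []
    symptoms = instr.choice_lists["symptoms"].codes()

    for i in range(n):
        participant = f"P-{i + 1:03d}"
        day = rng.randint(1, 28)
        answers = {
            "participant_code": participant,
            "start_date": f"2023-01-{day:02d}",
            "clinical_form": rng.choice(["1", "2"]),
            "discharg_date": f"2023-06-{day:02d}",
            "sex": rng.choice(["1", "2"]),
            "age": str(rng.randint(18, 90)),
            "weight": f"{rng.uniform(40, 95):.1f}",
            "checkbox_symptoms": " ".join(
                sorted(rng.sample(symptoms, k=rng.randint(1, len(symptoms))))
            ),
            "visit_time": f"{rng.randint(8, 16):02d}:{rng.choice(['00', '15', '30', '45'])}",
            "followup_at": f"2023-02-{day:02d} 10:30",
            "height": str(rng.randint(150, 195)),
        }
        if symptoms[0] in answers["checkbox_symptoms"].split():
            answers["symptom_onset"] = f"2022-12-{day:02d}"

        truth = PlantedTruth(participant)
        if rng.random() < violation_rate:
            rule = rng.choice(project.rules)
            if rule.rule_type == "range":
                answers[rule.field] = str(int(rule.params["max"]) + rng.randint(1, 50))
            elif rule.rule_type == "required":
                answers[rule.field] = ""
            else:  # format
                answers[rule.field] = f"{rng.randint(1, 28)}/{rng.randint(1, 12)}/2023"
            truth.violations.append((rule.field, rule.rule_id))
        else:
            for fname in list(answers):
                if fname in ("participant_code", "start_date", "age", "sex"):
                    continue  # rule-covered fields stay clean and present
                if rng.random() < missingness:
                    del answers[fname]

        payload = {
            "_id": 100000 + i,
            "_uuid": f"{seed:08x}-{i:04d}-4000-8000-00000000{i:04d}",
            "meta/instanceID": f"uuid:{seed:08x}-{i:04d}",
            "formhub/uuid": f"{seed:016x}",
            "start": f"2023-01-{day:02d}T09:00:00",
            "end": f"2023-01-{day:02d}T09:25:00",
            "_submission_time": f"2023-01-{day:02d}T09:26:00",
            **answers,
        }
        payloads.append(payload)
        truths.append(truth)
    return payloads, truths


# ---------------------------------------------------------------------------
# usability-survey matrices
# ---------------------------------------------------------------------------

_SUBSCALES = {
    "sysuse": range(0, 6),
    "infoqual": range(6, 12),
    "intqual": range(12, 15),
    "overall": range(0, 16),
}

_TOL = 0.05


class InfeasibleTarget(ValueError):
    pass


def make_csuq_matrix(
    target_means: list[float], n: int, seed: int
) -> list[list[int]]:
    """Integer 1-7 ratings (n x 16) whose column means hit the targets
    within +/-0.05 *and* whose rounded subscale scores equal the scores
    computed directly from the targets.

    Construction: per-column sums start at the nearest achievable integer
    sum, then are nudged within tolerance until each subscale mean falls in
    the same half-up rounding bin as the target score (rounding-compensated
    assignment). Raises :class:`InfeasibleTarget` when no assignment exists
    for the given ``n``.
    """
    from .reporting import round_half_up, score_csuq

    if len(target_means) != 16:
        raise ValueError("need 16 target means")
    if n < 1:
        raise ValueError("n must be >= 1")
    for m in target_means:
        if not 1 <= m <= 7:
            raise InfeasibleTarget(f"target mean {m} outside [1, 7]")

    sums = [int(round_half_up(m * n, 0)) for m in target_means]

    def in_tol(j: int, s: int) -> bool:
        return n <= s <= 7 * n and abs(s / n - target_means[j]) <= _TOL

    for j, s in enumerate(sums):
        if not in_tol(j, s):
            raise InfeasibleTarget(
                f"column {j + 1}: no achievable sum within {_TOL} of mean "
                f"{target_means[j]} at n={n}"
            )

    desired = score_csuq(target_means).display()

    def adjust(scale: str) -> None:
        columns = _SUBSCALES[scale]
        size = len(columns) * n
        want = desired[scale]
        for _ in range(4 * size):
            current = round_half_up(sum(sums[j] for j in columns) / size)
            if current == want:
                return
            step = 1 if current < want else -1
            # question 16 belongs only to the overall score, so prefer it
            # when nudging overall; elsewhere any in-tolerance column works
            order = [15] + [j for j in columns if j != 15] if scale == "overall" else list(columns)
            for j in order:
                if not in_tol(j, sums[j] + step):
                    continue
                if scale == "overall" and j != 15:
                    trial = sums.copy()
                    trial[j] += step
                    if not _all_subscales_ok(trial, desired, n):
                        continue
                sums[j] += step
                break
            else:
                raise InfeasibleTarget(
                    f"cannot reach {scale} score {want} within tolerance at n={n}"
                )
        raise InfeasibleTarget(f"{scale} adjustment did not converge at n={n}")

    for scale in ("sysuse", "infoqual", "intqual", "overall"):
        adjust(scale)

    rng = random.Random(seed)
    columns: list[list[int]] = []
    for j, s in enumerate(sums):
        base, extra = divmod(s, n)
        ratings = [base + 1] * extra + [base] * (n - extra)
        rng.shuffle(ratings)
        columns.append(ratings)
    return [[columns[j][i] for j in range(16)] for i in range(n)]


def _all_subscales_ok(sums: list[int], desired: dict, n: int) -> bool:
    from .reporting import round_half_up

    for scale in ("sysuse", "infoqual", "intqual"):
        cols = _SUBSCALES[scale]
        if round_half_up(sum(sums[j] for j in cols) / (len(cols) * n)) != desired[scale]:
            return False
    return True


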