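"""Instrument -> REDCap-dialect data dictionary conversion.

Type mapping (one row per field; checkbox option expansion happens at the
record level, not here):

==================  ==============  =================
model type          field_type      validation_type
==================  ==============  =================
text                text
integer             text            integer
decimal             text            number
date                text            date_ymd
datetime            text            datetime_ymd
time                text            time
select_one          radio
select_multiple     checkbox
calc                calc
note                descriptive
file                file
==================  ==============  =================

Multiple-selection fields must be named ``checkbox_...``; the naming
pre-check runs before any conversion and a failure aborts with no partial
output.
"""

from __future__ import annotations

import io
import logging
import zipfile
from dataclasses import dataclass, field as dc_field, fields as dc_fields
from pathlib import Path

from .logic import (
    LogicExpr,
    Selected,
    TrueConst,
    parse_logic,
    render_logic,
)
from .model import (
    Choice,
    ChoiceList,
    FieldDef,
    FieldType,
    InstrumentDef,
    SemanticTag,
    ValidationSpec,
    validate_instrument,
)

__all__ = [
    "DictionaryRow",
    "DataDictionary",
    "PrecheckFailed",
    "CHECKBOX_PREFIX",
    "precheck_names",
    "map_field",
    "render_branching",
    "convert_instrument",
    "instrument_from_dictionary",
    "package_zip",
]

logger = logging.getLogger(__name__)

CHECKBOX_PREFIX = "checkbox_"

#: the 18 data-dictionary columns, in REDCap import order
DICTIONARY_HEADER = [
    "Variable / Field Name",
    "Form Name",
    "Section Header",
    "Field Type",
    "Field Label",
    "Choices, Calculations, OR Slider Labels",
    "Field Note",
    "Text Validation Type OR Show Slider Number",
    "Text Validation Min",
    "Text Validation Max",
    "Identifier?",
    "Branching Logic (Show field only if...)",
    "Required Field?",
    "Custom Alignment",
    "Question Number (surveys only)",
    "Matrix Group Name",
    "Matrix Ranking?",
    "Field Annotation",
]

_TYPE_MAP: dict[FieldType, tuple[str, str]] = {
    FieldType.TEXT: ("text", ""),
    FieldType.INTEGER: ("text", "integer"),
    FieldType.DECIMAL: ("text", "number"),
    FieldType.DATE: ("text", "date_ymd"),
    FieldType.DATETIME: ("text", "datetime_ymd"),
    FieldType.TIME: ("text", "time"),
    FieldType.SELECT_ONE: ("radio", ""),
    FieldType.SELECT_MULTIPLE: ("checkbox", ""),
    FieldType.CALC: ("calc", ""),
    FieldType.NOTE: ("descriptive", ""),
    FieldType.FILE: ("file", ""),
}
_TYPE_UNMAP = {
    ("text", ""): FieldType.TEXT,
    ("text", "integer"): FieldType.INTEGER,
    ("text", "number"): FieldType.DECIMAL,
    ("text", "date_ymd"): FieldType.DATE,
    ("text", "datetime_ymd"): FieldType.DATETIME,
    ("text", "time"): FieldType.TIME,
    ("radio", ""): FieldType.SELECT_ONE,
    ("checkbox", ""): FieldType.SELECT_MULTIPLE,
    ("calc", ""): FieldType.CALC,
    ("descriptive", ""): FieldType.NOTE,
    ("file", ""): FieldType.FILE,
}


class PrecheckFailed(ValueError):
    """Naming-convention pre-check failed; carries the violation list."""

    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations))
        self.violations = violations


@dataclass
class DictionaryRow:
    variable_name: str
    form_name: str
    section_header: str = ""
    field_type: str = "text"
    field_label: str = ""
    choices_or_calc: str = ""
    field_note: str = ""
    validation_type: str = ""
    validation_min: str = ""
    validation_max: str = ""
    identifier: str = ""
    branching_logic: str = ""
    required: str = ""
    alignment: str = ""
    question_number: str = ""
    matrix_group: str = ""
    matrix_rank: str = ""
    field_annotation: str = ""

    def as_list(self) -> list[str]:
        return [getattr(self, f.name) for f in dc_fields(self)]

    @classmethod
    def from_list(cls, cells: list[str]) -> "DictionaryRow":
        names = [f.name for f in dc_fields(cls)]
        if len(cells) != len(names):
            raise ValueError(f"expected {len(names)} columns, got {len(cells)}")
        return cls(**dict(zip(names, cells)))


@dataclass
class DataDictionary:
    form_name: str
    rows: list[DictionaryRow] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.variable_name for r in self.rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in dictionary")
        for row in self.rows:
            if not row.variable_name:
                raise ValueError("empty variable name in dictionary")
            parse_logic(row.branching_logic, "redcap")  # raises on bad logic


def precheck_names(instr: InstrumentDef) -> list[str]:
    """One violation per multiple-selection field not named ``checkbox_*``."""
    return [
        f"field {f.name!r}: multiple-selection fields must be named "
        f"starting with {CHECKBOX_PREFIX!r}"
        for f in instr.fields
        if f.type is FieldType.SELECT_MULTIPLE and not f.name.startswith(CHECKBOX_PREFIX)
    ]


def render_branching(expr: LogicExpr | None) -> str:
    """Render a logic tree as REDCap branching-logic text.

    Membership becomes the checkbox idiom ``[f(c)] = '1'``; ``!=`` becomes
    ``<>``; constant-true renders empty (unconditional field).
    """
    if expr is None or isinstance(expr, TrueConst):
        return ""
    return render_logic(expr, "redcap")


def _serialize_choices(cl: ChoiceList) -> str:
    return " | ".join(f"{c.code}, {c.label}" for c in cl.choices)


def _parse_choices(text: str) -> list[Choice]:
    choices = []
    for part in text.split("|"):
        part = part.strip()
        if not part:
            continue
        code, _, label = part.partition(",")
        choices.append(Choice(code.strip(), label.strip()))
    return choices


def map_field(fld: FieldDef, form_name: str, instr: InstrumentDef | None = None) -> list[DictionaryRow]:
    """Map one field to its dictionary row(s).

    Names, choice codes and labels are carried verbatim. A calc field with
    an empty label borrows its guidance hint as the label (XLSForm has no
    label slot for calculations). An unmappable constraint is dropped with
    a logged warning, never an error.
    """
    field_type, validation_type = _TYPE_MAP[fld.type]
    row = DictionaryRow(variable_name=fld.name, form_name=form_name)
    row.field_type = field_type
    row.validation_type = fld.validation.kind or validation_type
    row.field_label = fld.label

    if fld.type is FieldType.CALC:
        row.choices_or_calc = fld.calculation or ""
        if not fld.label and fld.guidance_hint:
            row.field_label = fld.guidance_hint
    elif fld.is_select:
        if instr is not None and fld.choice_list in instr.choice_lists:
            row.choices_or_calc = _serialize_choices(instr.choice_lists[fld.choice_list])
    if fld.type is not FieldType.CALC and fld.guidance_hint:
        row.field_note = fld.guidance_hint

    row.validation_min = fld.validation.min or ""
    row.validation_max = fld.validation.max or ""
    if fld.constraint is not None and fld.validation.min is None and fld.validation.max is None:
        logger.warning(
            "field %s: constraint %r has no dictionary equivalent; dropped",
            fld.name,
            render_logic(fld.constraint, "xlsform"),
        )

    row.identifier = "y" if fld.identifier else ""
    row.required = "y" if fld.required else ""
    row.branching_logic = render_branching(fld.relevant)
    if fld.tag is not None:
        row.field_annotation = fld.tag.value
    return [row]


def convert_instrument(instr: InstrumentDef, form_name: str) -> DataDictionary:
    """Convert a whole instrument; total on precheck-passing instruments.

    Raises :class:`PrecheckFailed` (and produces no partial output) when the
    checkbox naming convention or an instrument invariant is violated.
    """
    problems = precheck_names(instr)
    if problems:
        raise PrecheckFailed(problems)
    problems = validate_instrument(instr)
    if problems:
        raise PrecheckFailed(problems)
    dd = DataDictionary(form_name.lower())
    for fld in instr.fields:
        dd.rows.extend(map_field(fld, dd.form_name, instr))
    return dd


def instrument_from_dictionary(dd: DataDictionary) -> InstrumentDef:
    """Reverse mapping: rebuild an instrument from a data dictionary.

    Used to verify field-level equivalence after conversion and by the ETL
    pipeline to recover the schema registered for a form. Each select
    field's choices become a choice list named after the field.
    """
    instr = InstrumentDef(dd.form_name)
    for row in dd.rows:
        key = (row.field_type, row.validation_type)
        ftype = _TYPE_UNMAP.get(key) or _TYPE_UNMAP.get((row.field_type, ""))
        if ftype is None:
            raise ValueError(
                f"row {row.variable_name!r}: unmappable field_type {row.field_type!r}"
            )
        validation = ValidationSpec(
            kind=row.validation_type or None,
            min=row.validation_min or None,
            max=row.validation_max or None,
        )
        choice_list = None
        if ftype in (FieldType.SELECT_ONE, FieldType.SELECT_MULTIPLE):
            choice_list = row.variable_name
            instr.choice_lists[choice_list] = ChoiceList(
                choice_list, _parse_choices(row.choices_or_calc)
            )
        relevant = parse_logic(row.branching_logic, "redcap")
        if isinstance(relevant, TrueConst):
            relevant = None
        tag = None
        if row.field_annotation:
            kind = "hxl_hashtag" if row.field_annotation.startswith("#") else "ontology_property"
            tag = SemanticTag(kind, row.field_annotation)
        instr.fields.append(
            FieldDef(
                name=row.variable_name,
                type=ftype,
                label=row.field_label,
                choice_list=choice_list,
                required=row.required == "y",
                relevant=relevant,
                validation=validation,
                guidance_hint=row.field_note or None,
                identifier=row.identifier == "y",
                tag=tag,
                calculation=row.choices_or_calc if ftype is FieldType.CALC else None,
            )
        )
    return instr


def package_zip(dd: DataDictionary, path: str | Path) -> Path:
    """Write the dictionary CSV into a zip archive (manual-upload bundle)."""
    from .store import write_dictionary

    path = Path(path)
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("instrument.csv", write_dictionary(dd))
    path.write_bytes(buf.getvalue())
    return path


def branching_refs_selected(expr: LogicExpr) -> list[Selected]:
    """All membership nodes in a tree (helper for checkbox-aware consumers)."""
    out: list[Selected] = []

    def walk(e: LogicExpr) -> None:
        if isinstance(e, Selected):
            out.append(e)
        for attr in ("items",):
            for child in getattr(e, attr, ()) or ():
                walk(child)
        inner = getattr(e, "item", None)
        if inner is not None:
            walk(inner)

    walk(expr)
    return out
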