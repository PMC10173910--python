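"""XLSForm workbook I/O (survey / choices / settings sheets).

Reads and writes the XLSX flavour of the XLSForm standard. The survey sheet
may carry an extra ``hxl`` column whose hashtags become semantic tags on the
resulting fields. Groups, repeats, multi-language labels and cascading
selects are out of scope.

A constraint of the canonical shape ``. >= A and . <= B`` is treated as
validation sugar: it is folded into the field's ``validation.min``/``max``
on read and synthesised back on write, so min/max bounds survive the round
trip regardless of which representation authored them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import openpyxl
from openpyxl.workbook import Workbook

from .logic import (
    And,
    Comparison,
    Literal,
    LogicExpr,
    TrueConst,
    parse_logic,
    render_logic,
)
from .model import (
    TYPE_VALIDATION_KIND,
    Choice,
    ChoiceList,
    FieldDef,
    FieldType,
    InstrumentDef,
    SemanticTag,
    ValidationSpec,
    validate_instrument,
)

__all__ = ["XlsformError", "read_xlsform", "write_xlsform"]

SURVEY_COLUMNS = [
    "type",
    "name",
    "label",
    "relevant",
    "constraint",
    "constraint_message",
    "required",
    "calculation",
    "guidance_hint",
    "hxl",
]

# XLSForm type tokens -> model types ("calculate" is the XLSForm spelling)
_TYPE_TOKENS = {
    "text": FieldType.TEXT,
    "integer": FieldType.INTEGER,
    "decimal": FieldType.DECIMAL,
    "date": FieldType.DATE,
    "datetime": FieldType.DATETIME,
    "time": FieldType.TIME,
    "calculate": FieldType.CALC,
    "calc": FieldType.CALC,
    "note": FieldType.NOTE,
    "file": FieldType.FILE,
}
_TYPE_OUT = {
    FieldType.TEXT: "text",
    FieldType.INTEGER: "integer",
    FieldType.DECIMAL: "decimal",
    FieldType.DATE: "date",
    FieldType.DATETIME: "datetime",
    FieldType.TIME: "time",
    FieldType.CALC: "calculate",
    FieldType.NOTE: "note",
    FieldType.FILE: "file",
}


class XlsformError(ValueError):
    """Malformed workbook; the message names the row/column at fault."""


def _cell(value) -> str:
    return "" if value is None else str(value).strip()


def _sheet_rows(ws) -> tuple[list[str], list[dict[str, str]]]:
    rows = list(ws.iter_rows(values_only=True))
    if not rows:
        return [], []
    header = [_cell(v).lower() for v in rows[0]]
    out = []
    for raw in rows[1:]:
        row = {header[i]: _cell(raw[i]) for i in range(min(len(header), len(raw)))}
        if any(v for v in row.values()):
            out.append(row)
    return header, out


def _bounds_constraint(expr: LogicExpr) -> tuple[str | None, str | None] | None:
    """Match the canonical bound patterns on the self reference.

    ``. >= A and . <= B`` -> (A, B); one-sided ``. >= A`` / ``. <= B`` give
    (A, None) / (None, B). Anything else returns None.
    """
    if isinstance(expr, Comparison) and expr.field == ".":
        if expr.op == ">=":
            return expr.literal.text, None
        if expr.op == "<=":
            return None, expr.literal.text
        return None
    if not (isinstance(expr, And) and len(expr.items) == 2):
        return None
    lo, hi = expr.items
    if (
        isinstance(lo, Comparison)
        and isinstance(hi, Comparison)
        and lo.field == "."
        and hi.field == "."
        and lo.op == ">="
        and hi.op == "<="
    ):
        return lo.literal.text, hi.literal.text
    return None


def read_xlsform(source: Union[str, Path, Workbook], name: str | None = None) -> InstrumentDef:
    """Read an XLSForm workbook (path or openpyxl Workbook) into an instrument.

    The instrument name comes from, in order of preference: the ``name``
    argument, the settings sheet's ``form_id``, the file stem.
    """
    if isinstance(source, Workbook):
        wb = source
        stem = "form"
    else:
        path = Path(source)
        if path.suffix.lower() == ".xls":
            raise XlsformError(
                "legacy .xls workbooks are not supported by this reader; "
                "re-save the form as .xlsx"
            )
        wb = openpyxl.load_workbook(path, data_only=True)
        stem = path.stem

    if "survey" not in wb.sheetnames:
        raise XlsformError("workbook has no 'survey' sheet")
    header, survey_rows = _sheet_rows(wb["survey"])
    for col in ("type", "name", "label"):
        if col not in header:
            raise XlsformError(f"survey sheet is missing required column {col!r}")

    choice_lists: dict[str, ChoiceList] = {}
    if "choices" in wb.sheetnames:
        _, choice_rows = _sheet_rows(wb["choices"])
        for i, row in enumerate(choice_rows, start=2):
            list_name = row.get("list_name", "").lower()
            if not list_name:
                raise XlsformError(f"choices row {i}: empty list_name")
            cl = choice_lists.setdefault(list_name, ChoiceList(list_name, []))
            cl.choices.append(Choice(row.get("name", ""), row.get("label", "")))

    form_id = form_title = ""
    if "settings" in wb.sheetnames:
        _, settings_rows = _sheet_rows(wb["settings"])
        if settings_rows:
            form_id = settings_rows[0].get("form_id", "")
            form_title = settings_rows[0].get("form_title", "")
    del form_title  # title is presentation-only; the id is the identity

    instr = InstrumentDef(name or form_id or stem, choice_lists=choice_lists)

    for i, row in enumerate(survey_rows, start=2):
        type_token = row["type"]
        parts = type_token.split(None, 1)
        base = parts[0].lower()
        if base in ("select_one", "select_multiple"):
            if len(parts) != 2:
                raise XlsformError(f"survey row {i}, column 'type': {base} needs a list name")
            ftype = FieldType(base)
            list_ref = parts[1].strip().lower()
            if list_ref not in choice_lists:
                raise XlsformError(
                    f"survey row {i}, column 'type': unknown choice list {list_ref!r}"
                )
        elif base in _TYPE_TOKENS:
            ftype = _TYPE_TOKENS[base]
            list_ref = None
        else:
            raise XlsformError(f"survey row {i}, column 'type': unknown type {base!r}")

        validation = ValidationSpec(kind=TYPE_VALIDATION_KIND.get(ftype))
        constraint = parse_logic(row.get("constraint", ""), "xlsform")
        if isinstance(constraint, TrueConst):
            constraint = None
        if constraint is not None:
            bounds = _bounds_constraint(constraint)
            if bounds is not None:
                validation.min, validation.max = bounds
                constraint = None

        relevant = parse_logic(row.get("relevant", ""), "xlsform")
        if isinstance(relevant, TrueConst):
            relevant = None

        hxl = row.get("hxl", "")
        tag = SemanticTag("hxl_hashtag", hxl) if hxl else None

        instr.fields.append(
            FieldDef(
                name=row["name"],
                type=ftype,
                label=row.get("label", ""),
                choice_list=list_ref,
                required=row.get("required", "").lower() in ("true", "yes", "1"),
                relevant=relevant,
                constraint=constraint,
                validation=validation,
                guidance_hint=row.get("guidance_hint") or None,
                tag=tag,
                calculation=row.get("calculation") or None,
            )
        )

    problems = validate_instrument(instr)
    if problems:
        raise XlsformError("workbook yields an invalid instrument: " + "; ".join(problems))
    return instr


def write_xlsform(instr: InstrumentDef, path: Union[str, Path, None] = None) -> Workbook:
    """Render an instrument as an XLSForm workbook.

    Returns the openpyxl workbook; also saves it when ``path`` is given.
    ``read_xlsform(write_xlsform(i))`` equals ``i`` on every FieldDef
    attribute representable in XLSForm (identifier/participant flags and
    ontology tags live in project metadata, not the form).
    """
    wb = Workbook()
    survey = wb.active
    survey.title = "survey"
    survey.append(SURVEY_COLUMNS)
    for fld in instr.fields:
        if fld.is_select:
            type_token = f"{fld.type.value} {fld.choice_list}"
        else:
            type_token = _TYPE_OUT[fld.type]
        constraint = fld.constraint
        constraint_text = render_logic(constraint, "xlsform") if constraint else ""
        if not constraint_text and (fld.validation.min is not None or fld.validation.max is not None):
            lo, hi = fld.validation.min, fld.validation.max
            parts = []
            if lo is not None:
                parts.append(Comparison(".", ">=", _lit(lo)))
            if hi is not None:
                parts.append(Comparison(".", "<=", _lit(hi)))
            bound_expr = parts[0] if len(parts) == 1 else And(tuple(parts))
            constraint_text = render_logic(bound_expr, "xlsform")
        survey.append(
            [
                type_token,
                fld.name,
                fld.label,
                render_logic(fld.relevant, "xlsform") if fld.relevant else "",
                constraint_text,
                "",
                "yes" if fld.required else "",
                fld.calculation or "",
                fld.guidance_hint or "",
                fld.tag.value if fld.tag and fld.tag.kind == "hxl_hashtag" else "",
            ]
        )

    choices = wb.create_sheet("choices")
    choices.append(["list_name", "name", "label"])
    for cl in instr.choice_lists.values():
        for choice in cl.choices:
            choices.append([cl.name, choice.code, choice.label])

    settings = wb.create_sheet("settings")
    settings.append(["form_title", "form_id"])
    settings.append([instr.name, instr.name])

    if path is not None:
        wb.save(Path(path))
    return wb


def _lit(text: str) -> Literal:
    from .logic import _NUM_RE

    return Literal(text, quoted=not _NUM_RE.match(text))
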