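"""Canonical in-memory model of data-collection instruments and records.

An :class:`InstrumentDef` is the lingua franca shared by every I/O format in
this package: XLSForm workbooks, REDCap-style data dictionaries and ontology
specifications all read into / write out of this one representation.

Conventions
-----------
* Field and choice-list names are lower-cased on ingest; labels are kept
  verbatim.
* Dates are naive ISO calendar dates (``YYYY-MM-DD``); datetimes are
  ``YYYY-MM-DD HH:MM``.
* Multiple-selection answers are stored checkbox-expanded on records:
  one ``name___code`` key per option, valued ``"1"`` / ``"0"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Optional

__all__ = [
    "FieldType",
    "Choice",
    "ChoiceList",
    "ValidationSpec",
    "SemanticTag",
    "FieldDef",
    "InstrumentDef",
    "FlatRecord",
    "validate_instrument",
    "NAME_RE",
]

NAME_RE = re.compile(r"^[a-z][a-z0-9_]*$")

# Placeholder field reference meaning "the field owning this expression";
# used in constraint expressions (XLSForm writes it as a bare dot).
SELF_REF = "."


class FieldType(str, Enum):
    """Closed enumeration of supported field types."""

    TEXT = "text"
    INTEGER = "integer"
    DECIMAL = "decimal"
    DATE = "date"
    DATETIME = "datetime"
    TIME = "time"
    CALC = "calc"
    SELECT_ONE = "select_one"
    SELECT_MULTIPLE = "select_multiple"
    NOTE = "note"
    FILE = "file"


#: validation "kind" implied by a field type, where one exists
TYPE_VALIDATION_KIND = {
    FieldType.INTEGER: "integer",
    FieldType.DECIMAL: "number",
    FieldType.DATE: "date_ymd",
    FieldType.DATETIME: "datetime_ymd",
    FieldType.TIME: "time",
}


@dataclass(frozen=True)
class Choice:
    code: str
    label: str

    def __post_init__(self) -> None:
        if not self.code or any(c.isspace() for c in self.code):
            raise ValueError(f"choice code must be a non-empty token: {self.code!r}")


@dataclass
class ChoiceList:
    name: str
    choices: list[Choice]

    def codes(self) -> list[str]:
        return [c.code for c in self.choices]


@dataclass
class ValidationSpec:
    """Optional text-validation kind plus optional min/max bounds."""

    kind: Optional[str] = None  # date_ymd | datetime_ymd | time | integer | number
    min: Optional[str] = None
    max: Optional[str] = None

    def is_empty(self) -> bool:
        return self.kind is None and self.min is None and self.max is None


@dataclass(frozen=True)
class SemanticTag:
    """A machine-readable annotation: either an ontology property IRI or an
    HXL hashtag."""

    kind: str  # "ontology_property" | "hxl_hashtag"
    value: str

    def __post_init__(self) -> None:
        if self.kind not in ("ontology_property", "hxl_hashtag"):
            raise ValueError(f"unknown tag kind: {self.kind!r}")


@dataclass
class FieldDef:
    name: str
    type: FieldType
    label: str = ""
    choice_list: Optional[str] = None
    required: bool = False
    relevant: Optional["LogicExpr"] = None  # noqa: F821 - see logic module
    constraint: Optional["LogicExpr"] = None  # noqa: F821
    validation: ValidationSpec = dc_field(default_factory=ValidationSpec)
    guidance_hint: Optional[str] = None
    identifier: bool = False
    participant_id: bool = False
    tag: Optional[SemanticTag] = None
    calculation: Optional[str] = None

    def __post_init__(self) -> None:
        self.name = self.name.lower()
        if isinstance(self.type, str):
            self.type = FieldType(self.type)

    @property
    def is_select(self) -> bool:
        return self.type in (FieldType.SELECT_ONE, FieldType.SELECT_MULTIPLE)


@dataclass
class InstrumentDef:
    name: str
    fields: list[FieldDef] = dc_field(default_factory=list)
    choice_lists: dict[str, ChoiceList] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.name = self.name.lower()

    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def get_field(self, name: str) -> FieldDef:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def choices_for(self, fld: FieldDef) -> ChoiceList:
        if fld.choice_list is None:
            raise KeyError(f"field {fld.name!r} has no choice list")
        return self.choice_lists[fld.choice_list]


@dataclass
class FlatRecord:
    """One participant-event's values, keyed by field name.

    Multiple-selection answers are held checkbox-expanded: ``name___code``
    keys with "1"/"0" values. Values are *not* validated here; the quality
    module flags type mismatches instead of rejecting records.
    """

    record_id: str
    values: dict[str, str] = dc_field(default_factory=dict)
    event: Optional[str] = None


def validate_instrument(instr: InstrumentDef) -> list[str]:
    """Check every InstrumentDef invariant; return human-readable violations.

    An empty list means the instrument is valid. Violations are data, not
    exceptions: each message names the offending field and the rule broken.
    """
    from .logic import field_refs  # local import to avoid a cycle

    violations: list[str] = []
    seen: set[str] = set()
    names = set(instr.field_names())
    participant_fields = [f.name for f in instr.fields if f.participant_id]
    if len(participant_fields) > 1:
        violations.append(
            "multiple participant_id fields: " + ", ".join(participant_fields)
        )

    for list_name, cl in instr.choice_lists.items():
        if not cl.choices:
            violations.append(f"choice list {list_name!r}: empty")
        codes = cl.codes()
        if len(set(codes)) != len(codes):
            violations.append(f"choice list {list_name!r}: duplicate choice codes")

    for fld in instr.fields:
        if fld.name in seen:
            violations.append(f"field {fld.name!r}: duplicate field name")
        seen.add(fld.name)
        if not NAME_RE.match(fld.name):
            violations.append(
                f"field {fld.name!r}: name must match [a-z][a-z0-9_]*"
            )
        if fld.is_select:
            if fld.choice_list is None:
                violations.append(f"field {fld.name!r}: select field without choice list")
            elif fld.choice_list not in instr.choice_lists:
                violations.append(
                    f"field {fld.name!r}: unresolved choice list {fld.choice_list!r}"
                )
        for attr in ("relevant", "constraint"):
            expr = getattr(fld, attr)
            if expr is None:
                continue
            for ref in field_refs(expr):
                if ref == SELF_REF:
                    if attr != "constraint":
                        violations.append(
                            f"field {fld.name!r}: '.' reference outside constraint"
                        )
                elif ref not in names:
                    violations.append(
                        f"field {fld.name!r}: {attr} references unknown field {ref!r}"
                    )
        v = fld.validation
        if v.min is not None and v.max is not None:
            lo, hi = _comparable(v.min), _comparable(v.max)
            if type(lo) is type(hi) and lo > hi:  # incomparable pairs are skipped
                violations.append(f"field {fld.name!r}: validation min > max")
        if fld.tag is not None:
            if fld.tag.kind == "hxl_hashtag" and not fld.tag.value.startswith("#"):
                violations.append(
                    f"field {fld.name!r}: HXL tag must start with '#'"
                )
            if fld.tag.kind == "ontology_property" and "://" not in fld.tag.value:
                violations.append(
                    f"field {fld.name!r}: ontology tag must be an absolute IRI"
                )
    return violations


def _comparable(text: str):
    """Best-effort coercion of a literal for min/max comparison."""
    try:
        return float(text)
    except (TypeError, ValueError):
        return str(text)
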