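"""Ontology <-> instrument bridging.

An :class:`OntologySpec` is an ordered set of datatype properties with
literal ranges and optional min/max restrictions. Instruments can be
derived from ontologies (one field per property) and generated from
instruments (one property per field); annotated datasets can be remapped
across ontology versions.

Serialization is a deterministic Turtle subset: datatype properties with
``rdfs:label``, ``rdfs:range`` (xsd types) and ``schema:minValue`` /
``schema:maxValue`` restriction annotations. Classes, object properties
and OWL axioms beyond this subset are skipped with a warning on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field
from typing import Optional

from .model import (
    NAME_RE,
    Choice,
    ChoiceList,
    FieldDef,
    FieldType,
    FlatRecord,
    InstrumentDef,
    SemanticTag,
    ValidationSpec,
    validate_instrument,
)

__all__ = [
    "PropertyDef",
    "OntologySpec",
    "VersionMapping",
    "RemapReport",
    "DROP",
    "derive_instrument",
    "generate_ontology",
    "serialize_ontology",
    "parse_ontology",
    "remap_annotations",
]

logger = logging.getLogger(__name__)

#: explicit drop marker for version mappings
DROP = "__drop__"

RANGES = ("string", "integer", "decimal", "date", "datetime", "time")

_RANGE_TO_XSD = {
    "string": "xsd:string",
    "integer": "xsd:integer",
    "decimal": "xsd:decimal",
    "date": "xsd:date",
    "datetime": "xsd:dateTime",
    "time": "xsd:time",
}
_XSD_TO_RANGE = {v: k for k, v in _RANGE_TO_XSD.items()}

_RANGE_TO_FIELDTYPE = {
    "string": FieldType.TEXT,
    "integer": FieldType.INTEGER,
    "decimal": FieldType.DECIMAL,
    "date": FieldType.DATE,
    "datetime": FieldType.DATETIME,
    "time": FieldType.TIME,
}
# select fields and everything else without a crisper literal shape map to
# a plain string range
_FIELDTYPE_TO_RANGE = {
    FieldType.TEXT: "string",
    FieldType.INTEGER: "integer",
    FieldType.DECIMAL: "decimal",
    FieldType.DATE: "date",
    FieldType.DATETIME: "datetime",
    FieldType.TIME: "time",
    FieldType.CALC: "string",
    FieldType.SELECT_ONE: "string",
    FieldType.SELECT_MULTIPLE: "string",
    FieldType.NOTE: "string",
    FieldType.FILE: "string",
}

_PREFIXES = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "schema": "http://schema.org/",
}


@dataclass
class PropertyDef:
    iri: str
    local_name: str
    range: str = "string"
    min_value: Optional[str] = None
    max_value: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.range not in RANGES:
            raise ValueError(f"unknown range {self.range!r}")


@dataclass
class OntologySpec:
    base_iri: str
    version_label: str = "v1"
    properties: list[PropertyDef] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.base_iri:
            raise ValueError("base_iri must be non-empty")
        iris = [p.iri for p in self.properties]
        if len(set(iris)) != len(iris):
            raise ValueError("duplicate property IRIs")


@dataclass
class VersionMapping:
    from_version: str
    to_version: str
    property_map: dict[str, str] = dc_field(default_factory=dict)  # old IRI -> new IRI or DROP


@dataclass
class RemapReport:
    mapped: int = 0
    dropped: int = 0
    unmapped: int = 0
    unmapped_iris: list[str] = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# derivation / generation
# ---------------------------------------------------------------------------


def derive_instrument(onto: OntologySpec, form_name: str) -> InstrumentDef:
    """One field per property, in property order.

    The field name is the property local name, the type follows the literal
    range (text is the default for string/unknown), min/max restrictions
    become the field's validation bounds, and each field carries its source
    IRI as an ``ontology_property`` semantic tag.
    """
    instr = InstrumentDef(form_name)
    seen: set[str] = set()
    for prop in onto.properties:
        name = prop.local_name.lower()
        if name in seen:
            raise ValueError(f"duplicate field name after normalization: {name!r}")
        seen.add(name)
        ftype = _RANGE_TO_FIELDTYPE[prop.range]
        from .model import TYPE_VALIDATION_KIND

        instr.fields.append(
            FieldDef(
                name=name,
                type=ftype,
                label=prop.label or _label_from_name(name),
                validation=ValidationSpec(
                    kind=TYPE_VALIDATION_KIND.get(ftype),
                    min=prop.min_value,
                    max=prop.max_value,
                ),
                tag=SemanticTag("ontology_property", prop.iri),
            )
        )
    problems = validate_instrument(instr)
    if problems:
        raise ValueError("derived instrument is invalid: " + "; ".join(problems))
    return instr


def _label_from_name(name: str) -> str:
    return name.replace("_", " ").capitalize()


def generate_ontology(
    instr: InstrumentDef, base_iri: str, version_label: str = "v1"
) -> OntologySpec:
    """One datatype property per field: ``iri = base_iri + "/" + name``.

    The property local name is the field's variable name verbatim; select
    fields map to a plain string range.
    """
    if "://" not in base_iri:
        raise ValueError(f"base IRI must be absolute: {base_iri!r}")
    base = base_iri.rstrip("/")
    onto = OntologySpec(base_iri=base, version_label=version_label)
    for fld in instr.fields:
        onto.properties.append(
            PropertyDef(
                iri=f"{base}/{fld.name}",
                local_name=fld.name,
                range=_FIELDTYPE_TO_RANGE[fld.type],
                min_value=fld.validation.min,
                max_value=fld.validation.max,
                label=fld.label or None,
            )
        )
    return onto


# ---------------------------------------------------------------------------
# Turtle serialization
# ---------------------------------------------------------------------------


def _ttl_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


def _ttl_unescape(text: str) -> str:
    return (
        text.replace("\\n", "\n").replace('\\"', '"').replace("\\\\", "\\")
    )


def serialize_ontology(onto: OntologySpec) -> str:
    """Deterministic Turtle rendering: stable prefix block, properties in
    spec order, one predicate per line."""
    lines = [f"@prefix {p}: <{iri}> ." for p, iri in _PREFIXES.items()]
    lines.append("")
    lines.append(f"<{onto.base_iri}> a owl:Ontology ;")
    lines.append(f'    owl:versionInfo "{_ttl_escape(onto.version_label)}" .')
    for prop in onto.properties:
        lines.append("")
        preds = [f"<{prop.iri}> a owl:DatatypeProperty"]
        if prop.label:
            preds.append(f'    rdfs:label "{_ttl_escape(prop.label)}"')
        preds.append(f"    rdfs:range {_RANGE_TO_XSD[prop.range]}")
        if prop.min_value is not None:
            preds.append(f'    schema:minValue "{_ttl_escape(prop.min_value)}"')
        if prop.max_value is not None:
            preds.append(f'    schema:maxValue "{_ttl_escape(prop.max_value)}"')
        lines.append(" ;\n".join(preds) + " .")
    return "\n".join(lines) + "\n"


_PREFIX_RE = re.compile(r"^@prefix\s+(\w*):\s*<([^>]*)>\s*\.\s*$")
_TOKEN_TTL = re.compile(
    r"""<[^>]*>|"(?:[^"\\]|\\.)*"|\w[\w-]*:[\w._-]+|[;.,]|a\b""", re.X
)


def parse_ontology(doc: str) -> OntologySpec:
    """Parse the supported Turtle subset back into an :class:`OntologySpec`.

    Triples outside the subset (classes, object properties, unknown
    predicates) are skipped with a warning; a document that cannot be
    tokenized at all raises ``ValueError``.
    """
    prefixes: dict[str, str] = {}
    body_lines = []
    for line in doc.splitlines():
        m = _PREFIX_RE.match(line.strip())
        if m:
            prefixes[m.group(1)] = m.group(2)
        else:
            body_lines.append(line)
    body = "\n".join(body_lines)

    # split into statements on top-level ' .'
    tokens = _TOKEN_TTL.findall(body)
    leftover = _TOKEN_TTL.sub("", body).strip()
    if leftover:
        raise ValueError(f"malformed ontology document near {leftover[:40]!r}")

    statements: list[list[str]] = []
    current: list[str] = []
    for tok in tokens:
        if tok == ".":
            if current:
                statements.append(current)
                current = []
        else:
            current.append(tok)
    if current:
        raise ValueError("ontology document does not end with '.'")

    def expand(tok: str) -> str:
        if tok.startswith("<") and tok.endswith(">"):
            return tok[1:-1]
        if ":" in tok:
            prefix, _, local = tok.partition(":")
            if prefix in prefixes:
                return prefixes[prefix] + local
        return tok

    base_iri = ""
    version = "v1"
    properties: list[PropertyDef] = []

    owl_ns = prefixes.get("owl", _PREFIXES["owl"])
    rdfs_ns = prefixes.get("rdfs", _PREFIXES["rdfs"])
    schema_ns = prefixes.get("schema", _PREFIXES["schema"])

    for stmt in statements:
        subject = expand(stmt[0])
        # parse predicate-object groups split on ';'
        groups: list[list[str]] = [[]]
        for tok in stmt[1:]:
            if tok == ";":
                groups.append([])
            else:
                groups[-1].append(tok)
        po: dict[str, str] = {}
        for group in groups:
            if len(group) < 2:
                continue
            pred = "rdf:type" if group[0] == "a" else group[0]
            po[expand(pred) if pred != "rdf:type" else "rdf:type"] = group[1]

        rtype = po.get("rdf:type", "")
        rtype_iri = expand(rtype) if rtype else ""
        if rtype_iri == owl_ns + "Ontology":
            base_iri = subject
            vi = po.get(owl_ns + "versionInfo")
            if vi and vi.startswith('"'):
                version = _ttl_unescape(vi[1:-1])
            continue
        if rtype_iri != owl_ns + "DatatypeProperty":
            logger.warning("skipping non-datatype-property subject <%s>", subject)
            continue
        range_tok = po.get(rdfs_ns + "range", "xsd:string")
        range_iri = expand(range_tok)
        xsd_ns = prefixes.get("xsd", _PREFIXES["xsd"])
        range_name = _XSD_TO_RANGE.get(
            "xsd:" + range_iri[len(xsd_ns):] if range_iri.startswith(xsd_ns) else range_tok,
            None,
        )
        if range_name is None:
            logger.warning("property <%s>: unsupported range %s; using string", subject, range_tok)
            range_name = "string"

        def lit(key: str) -> Optional[str]:
            v = po.get(key)
            return _ttl_unescape(v[1:-1]) if v and v.startswith('"') else None

        properties.append(
            PropertyDef(
                iri=subject,
                local_name=subject.rsplit("/", 1)[-1].rsplit("#", 1)[-1],
                range=range_name,
                min_value=lit(schema_ns + "minValue"),
                max_value=lit(schema_ns + "maxValue"),
                label=lit(rdfs_ns + "label"),
            )
        )

    if not base_iri:
        if properties:
            base_iri = properties[0].iri.rsplit("/", 1)[0]
        else:
            raise ValueError("document declares no ontology and no properties")
    return OntologySpec(base_iri=base_iri, version_label=version, properties=properties)


# ---------------------------------------------------------------------------
# version remapping
# ---------------------------------------------------------------------------


def remap_annotations(
    records: list[FlatRecord],
    field_tags: dict[str, str],
    vm: VersionMapping,
) -> tuple[list[FlatRecord], dict[str, str], RemapReport]:
    """Rewrite dataset annotations from one ontology version to another.

    ``field_tags`` maps field names to their current property IRIs. Mapped
    tags are rewritten, tags mapped to :data:`DROP` are removed along with
    their columns, and tags absent from the mapping are reported unmapped
    and left untouched. Values of surviving columns are never modified.
    """
    report = RemapReport()
    new_tags: dict[str, str] = {}
    dropped_fields: set[str] = set()
    for fld, iri in field_tags.items():
        target = vm.property_map.get(iri)
        if target is None:
            report.unmapped += 1
            report.unmapped_iris.append(iri)
            new_tags[fld] = iri
        elif target == DROP:
            report.dropped += 1
            dropped_fields.add(fld)
        else:
            report.mapped += 1
            new_tags[fld] = target

    out_records = []
    for rec in records:
        values = {
            k: v
            for k, v in rec.values.items()
            if k.split("___")[0] not in dropped_fields
        }
        out_records.append(FlatRecord(rec.record_id, values, event=rec.event))
    return out_records, new_tags, report


def instrument_choice_note(instr: InstrumentDef) -> dict[str, list[Choice]]:
    """Choices per select field (documentation aid for generated ontologies)."""
    out: dict[str, list[Choice]] = {}
    for fld in instr.fields:
        if fld.is_select and fld.choice_list in instr.choice_lists:
            out[fld.name] = list(instr.choice_lists[fld.choice_list].choices)
    return out
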