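"""The submission processor: authenticate, clean, transform, resolve the
record id, import, and run post-save actions.

The pipeline is usable entirely offline from JSON files; the HTTP receiver
described for live deployments is just a thin adapter over
:func:`process_submission` and is intentionally not part of this package.

Stage order inside :func:`process_submission` is fixed:

1. authenticate (rejection persists nothing);
2. parse: strip platform metadata keys and group prefixes;
3. transform: checkbox expansion and value normalization;
4. resolve the record id from the participant identifier;
5. duplicate check;
6. import (upsert + change log);
7. post-save actions: lock, then notifications.

Stages 4-7 run inside one store transaction: a failure at any point leaves
the store byte-identical to its state before the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

from .dictionary import instrument_from_dictionary
from .model import FieldType, FlatRecord, InstrumentDef
from .store import RedcapStore, StoreError

__all__ = [
    "ProcessSettings",
    "ProcessOutcome",
    "AuthenticationFailed",
    "EmptyAfterCleaning",
    "UnknownField",
    "UnresolvedParticipant",
    "DEFAULT_METADATA_KEYS",
    "authenticate",
    "parse_submission",
    "transform_record",
    "resolve_record",
    "process_submission",
    "on_record_changed",
]

#: platform metadata keys removed during cleaning (configurable per call)
DEFAULT_METADATA_KEYS = frozenset(
    {"start", "end", "today", "deviceid", "username", "phonenumber", "simserial"}
)
_METADATA_PREFIXES = ("_", "meta/", "formhub/")


class AuthenticationFailed(PermissionError):
    """Credentials rejected; deliberately carries no detail about which part
    of the pair failed."""


class EmptyAfterCleaning(ValueError):
    """Nothing but platform metadata remained in the payload."""


class UnknownField(KeyError):
    pass


class UnresolvedParticipant(LookupError):
    """A non-first form arrived for a participant with no existing record."""


@dataclass
class ProcessSettings:
    """Per-instrument processing options (the 'extra actions')."""

    event: Optional[str] = None
    check_duplicates: bool = True
    lock_on_save: bool = False
    notify_respondent: bool = False
    notify_team: bool = False
    respondent_address: str = "respondent"
    metadata_keys: frozenset[str] = DEFAULT_METADATA_KEYS


@dataclass
class ProcessOutcome:
    record_id: str
    created_new: bool
    actions_performed: list[str] = dc_field(default_factory=list)
    issues: list[str] = dc_field(default_factory=list)


def authenticate(credentials: tuple[str, str], project_id: str, store: RedcapStore) -> bool:
    """Basic-auth check against the project's processor credentials."""
    project = store.get_project(project_id)  # raises on unknown project
    username, password = credentials
    return bool(username) and username == project.username and password == project.password


def parse_submission(
    payload: dict,
    instr: InstrumentDef,
    metadata_keys: frozenset[str] = DEFAULT_METADATA_KEYS,
) -> dict[str, str]:
    """Remove platform metadata and strip group prefixes.

    Keys starting with ``_``, or under ``meta/`` / ``formhub/``, or in the
    metadata blocklist are dropped; a key like ``group/field`` keeps only
    its terminal segment. Remaining keys must not collide after stripping.
    """
    if not payload:
        raise EmptyAfterCleaning("empty payload")
    cleaned: dict[str, str] = {}
    for key, value in payload.items():
        if key.startswith(_METADATA_PREFIXES):
            continue
        terminal = key.rsplit("/", 1)[-1].lower()
        if terminal in metadata_keys or key.lower() in metadata_keys:
            continue
        cleaned[terminal] = "" if value is None else str(value)
    if not cleaned:
        raise EmptyAfterCleaning("payload contains only platform metadata")
    return cleaned


def transform_record(
    cleaned: dict[str, str],
    instr: InstrumentDef,
    record_id: str = "",
    event: Optional[str] = None,
) -> FlatRecord:
    """Build a FlatRecord: expand multi-select answers into ``name___code``
    0/1 entries; pass other values through unchanged.

    Unknown keys raise :class:`UnknownField`; an answer code outside the
    field's choice list is flagged on the record's issue side-channel by the
    caller (not fatal here: the stray code is simply not representable and
    is reported).
    """
    known = {f.name: f for f in instr.fields}
    values: dict[str, str] = {}
    issues: list[str] = []
    for key, value in cleaned.items():
        fld = known.get(key)
        if fld is None:
            raise UnknownField(f"field {key!r} is not in instrument {instr.name!r}")
        if fld.type is FieldType.SELECT_MULTIPLE:
            codes = set(str(value).split())
            valid = instr.choices_for(fld).codes()
            for code in sorted(codes - set(valid)):
                issues.append(f"field {key!r}: code {code!r} not in choice list")
            for code in valid:
                values[f"{key}___{code}"] = "1" if code in codes else "0"
        else:
            values[key] = _normalize(str(value), fld)
    rec = FlatRecord(record_id=record_id, values=values, event=event)
    rec.issues = issues  # type: ignore[attr-defined]  # side channel for the pipeline
    return rec


def _normalize(value: str, fld) -> str:
    value = value.strip()
    if fld.type is FieldType.DATETIME and "T" in value:
        value = value.replace("T", " ")[:16]
    return value


def resolve_record(
    store: RedcapStore,
    project_id: str,
    form_name: str,
    participant_value: str,
) -> tuple[str, bool]:
    """Map a participant identifier to a record id.

    First-form submissions from unseen participants get a freshly generated
    id; anything else must match an existing record's stored participant
    value, otherwise :class:`UnresolvedParticipant` is raised (the caller
    parks the submission).
    """
    pfield = store.participant_field(project_id)
    if pfield is None:
        raise StoreError(f"project {project_id!r} has no participant_id field designated")
    existing = store.find_record_by_value(project_id, pfield, participant_value)
    if existing is not None:
        return existing, False
    if store.is_first_form(project_id, form_name):
        return store.next_record_id(project_id), True
    raise UnresolvedParticipant(
        f"participant {participant_value!r} unknown and {form_name!r} is not the entry form"
    )


def process_submission(
    store: RedcapStore,
    project_id: str,
    form_name: str,
    payload: dict,
    credentials: tuple[str, str],
    settings: ProcessSettings | None = None,
) -> ProcessOutcome:
    """Run the full pipeline for one submission payload."""
    settings = settings or ProcessSettings()
    if not authenticate(credentials, project_id, store):
        raise AuthenticationFailed("authentication failed")

    instr = instrument_from_dictionary(store.get_dictionary(project_id, form_name))
    cleaned = parse_submission(payload, instr, settings.metadata_keys)

    pfield = store.participant_field(project_id)
    if pfield is None:
        raise StoreError(f"project {project_id!r} has no participant_id field designated")
    participant_value = cleaned.get(pfield, "")

    rec = transform_record(cleaned, instr, event=settings.event)
    issues = list(getattr(rec, "issues", []))
    try:
        record_id, created_new = resolve_record(
            store, project_id, form_name, participant_value
        )
    except UnresolvedParticipant:
        # the park log must survive even though nothing else is persisted
        store.park_submission(project_id, form_name, payload, "unresolved participant")
        raise

    with store.transaction():
        rec.record_id = record_id
        actions: list[str] = []

        if settings.check_duplicates and not created_new:
            stored = store.export_records(
                project_id, record_id=record_id, form_name=form_name,
                event=settings.event or "",
            )
            if stored and _same_values(stored[0].values, rec.values):
                actions.append("duplicate_flagged")
                return ProcessOutcome(record_id, False, actions, issues)
            if stored:
                # same participant/form/event with differing values: import as
                # an update and open a data query for review
                issue = store.find_open_query(project_id, record_id, pfield, "duplicate")
                if issue is None:
                    store.open_query(project_id, record_id, pfield, "duplicate")
                issues.append("duplicate submission with differing values")

        store.import_record(project_id, form_name, rec)

        if settings.lock_on_save:
            store.lock_record(project_id, record_id, form_name)
            actions.append("locked")
        if settings.notify_team:
            for recipient, channel in store.alert_recipients(project_id) or [("team", "email")]:
                store.log_notification(
                    project_id, recipient, channel, "submission_received",
                    f"submission:{form_name}:{record_id}",
                    f"New submission for record {record_id} on {form_name}",
                    sent_at=store._now(),
                )
            actions.append("notified_team")
        if settings.notify_respondent:
            store.log_notification(
                project_id, settings.respondent_address, "email", "submission_receipt",
                f"receipt:{form_name}:{record_id}",
                "Thank you, your submission was received",
                sent_at=store._now(),
            )
            actions.append("notified_respondent")

    return ProcessOutcome(record_id, created_new, actions, issues)


def _same_values(stored: dict, incoming: dict) -> bool:
    return {k: str(v) for k, v in stored.items()} == {k: str(v) for k, v in incoming.items()}


def on_record_changed(
    store: RedcapStore, project_id: str, record_id: str, form_name: str
) -> Optional[dict]:
    """Change monitor (the data-entry-trigger path): export the record's
    current state and append it to the change log iff it differs from the
    last logged snapshot. Returns the new entry, or None for a no-op edit."""
    records = store.export_records(project_id, record_id=record_id, form_name=form_name)
    if not records:
        raise StoreError(f"unknown record {record_id!r} on form {form_name!r}")
    current = {k: str(v) for rec in records for k, v in rec.values.items()}
    entries = store.changelog_entries(project_id, record_id=record_id, form_name=form_name)
    if entries and entries[-1]["snapshot"] == current:
        return None
    return store.append_changelog(project_id, record_id, form_name, current)
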