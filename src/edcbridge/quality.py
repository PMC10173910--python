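"""Data-quality engine: rule validation with an issue lifecycle, visit
scheduling and status panel, and alert generation.

Scheduling of the periodic runs belongs to cron; this module exposes single
entry points (:func:`run_validation_cycle`, :func:`generate_alerts`) that
are idempotent on unchanged data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from typing import Optional

from .store import RedcapStore

__all__ = [
    "ValidationRule",
    "VisitConfig",
    "VisitCell",
    "Notification",
    "evaluate_rule",
    "run_validation_cycle",
    "schedule_visits",
    "visit_status",
    "build_visits_panel",
    "VisitsPanel",
    "generate_alerts",
]

_FORMAT_RES = {
    "date_ymd": re.compile(r"^\d{4}-\d{2}-\d{2}$"),
    "datetime_ymd": re.compile(r"^\d{4}-\d{2}-\d{2} \d{2}:\d{2}(:\d{2})?$"),
    "time": re.compile(r"^\d{2}:\d{2}$"),
    "integer": re.compile(r"^-?\d+$"),
    "number": re.compile(r"^-?\d+(\.\d+)?$"),
}

#: alert dedupe window: one calendar day per (recipient, reason-instance)
DEDUPE_DAYS = 1


@dataclass
class ValidationRule:
    rule_id: str
    project_id: str
    form: str
    field: str
    rule_type: str  # range | format | required | regex
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rule_type == "range" and not (
            "min" in self.params or "max" in self.params
        ):
            raise ValueError(f"rule {self.rule_id}: range rule needs min and/or max")
        if self.rule_type == "format" and self.params.get("format") not in _FORMAT_RES:
            raise ValueError(f"rule {self.rule_id}: unknown format name")
        if self.rule_type == "regex" and "pattern" not in self.params:
            raise ValueError(f"rule {self.rule_id}: regex rule needs a pattern")


@dataclass
class VisitConfig:
    event_name: str
    day_offset: int
    window_after: int = 0
    linked_forms: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.day_offset < 0 or self.window_after < 0:
            raise ValueError("offsets must be zero or positive")


@dataclass
class VisitCell:
    record_id: str
    event_name: str
    due_date: str
    status: str  # carried_out | not_carried_out | pending


@dataclass
class VisitsPanel:
    cells: list[VisitCell]
    events: list[str]
    record_ids: list[str]
    missing_reference: list[str]  # participants without a reference date


@dataclass
class Notification:
    recipient: str
    channel: str
    reason: str  # open_query | pending_visit | validation_issue
    body: str
    sent_at: str


_DATE_RE = _FORMAT_RES["date_ymd"]
_NUM_RE = _FORMAT_RES["number"]


def _cmp_value(text: str):
    if _NUM_RE.match(text):
        return float(text)
    if _DATE_RE.match(text):
        return date.fromisoformat(text)
    return text


def evaluate_rule(rule: ValidationRule, value: Optional[str]) -> tuple[bool, str]:
    """Apply one rule to one stored value; returns (passed, message).

    Only ``required`` fails on an empty value — a range/format/regex check
    of an unanswered field passes (completeness is the required rule's job).
    """
    value = "" if value is None else str(value)
    if rule.rule_type == "required":
        if value == "":
            return False, f"field {rule.field!r} is required but empty"
        return True, ""
    if value == "":
        return True, ""
    if rule.rule_type == "range":
        v = _cmp_value(value)
        lo = rule.params.get("min")
        hi = rule.params.get("max")
        if lo is not None and _in_order(v, _cmp_value(str(lo))) < 0:
            return False, (
                f"field {rule.field!r}: value {value!r} below minimum {lo!r}"
            )
        if hi is not None and _in_order(v, _cmp_value(str(hi))) > 0:
            return False, (
                f"field {rule.field!r}: value {value!r} above maximum {hi!r}"
            )
        return True, ""
    if rule.rule_type == "format":
        name = rule.params["format"]
        if not _FORMAT_RES[name].match(value):
            return False, (
                f"field {rule.field!r}: value {value!r} does not match format {name}"
            )
        return True, ""
    if rule.rule_type == "regex":
        if not re.fullmatch(rule.params["pattern"], value):
            return False, (
                f"field {rule.field!r}: value {value!r} does not match pattern"
            )
        return True, ""
    raise ValueError(f"malformed rule {rule.rule_id!r}: type {rule.rule_type!r}")


def _in_order(a, b) -> int:
    if type(a) is not type(b):
        a, b = str(a), str(b)
    return -1 if a < b else (1 if a > b else 0)


def _rules_from_store(store: RedcapStore, project_id: str) -> list[ValidationRule]:
    return [
        ValidationRule(
            rule_id=r["rule_id"],
            project_id=r["project_id"],
            form=r["form"],
            field=r["field"],
            rule_type=r["rule_type"],
            params=r["params"],
        )
        for r in store.list_rules(project_id)
    ]


def run_validation_cycle(
    store: RedcapStore, project_id: str, now: str = ""
) -> dict[str, int]:
    """One validation sweep over every (record, rule) pair.

    New failures open a query and alert the recipients list; failures with
    an already-open query are left untouched; open queries whose value now
    passes are resolved. Re-running on unchanged data is a no-op.
    """
    rules = _rules_from_store(store, project_id)
    opened = resolved = unchanged = 0
    failing: set[tuple[str, str, str]] = set()
    for rule in rules:
        for rec in store.export_records(project_id, form_name=rule.form):
            passed, message = evaluate_rule(rule, rec.values.get(rule.field))
            key = (rec.record_id, rule.field, rule.rule_id)
            if not passed:
                failing.add(key)
                if store.find_open_query(project_id, *key) is None:
                    store.open_query(project_id, *key, now=now or None)
                    opened += 1
                    for recipient, channel in store.alert_recipients(project_id):
                        store.log_notification(
                            project_id, recipient, channel, "validation_issue",
                            f"issue:{rec.record_id}:{rule.field}:{rule.rule_id}",
                            message, sent_at=now or store._now(),
                        )
                else:
                    unchanged += 1
    for issue in store.list_queries(project_id, status="open"):
        if issue.rule_id == "duplicate":
            continue  # ETL-owned queries are closed by humans, not by rules
        key = (issue.record_id, issue.field_name, issue.rule_id)
        if key not in failing:
            store.resolve_query(issue.issue_id, now=now or None)
            resolved += 1
    return {"opened": opened, "resolved": resolved, "unchanged": unchanged}


# ---------------------------------------------------------------------------
# visits
# ---------------------------------------------------------------------------


def schedule_visits(
    reference_date: str, configs: list[VisitConfig]
) -> list[tuple[str, str]]:
    """Due date per configured event: reference + day_offset calendar days."""
    ref = date.fromisoformat(reference_date)
    return [
        (cfg.event_name, (ref + timedelta(days=cfg.day_offset)).isoformat())
        for cfg in configs
    ]


def visit_status(due_date: str, window_after: int, has_data: bool, today: str) -> str:
    """carried_out if data exists; not_carried_out once the window has
    passed without data; pending otherwise."""
    if has_data:
        return "carried_out"
    due = date.fromisoformat(due_date)
    if date.fromisoformat(today) > due + timedelta(days=window_after):
        return "not_carried_out"
    return "pending"


def build_visits_panel(
    store: RedcapStore,
    project_id: str,
    today: str,
    reference_field: str | None = None,
) -> VisitsPanel:
    """The participants x visits status matrix, always computed from the
    current store state (never cached).

    A visit counts as carried out when every linked form has a stored
    record for that participant under the visit's event name. Participants
    whose reference date is missing are listed separately, never silently
    dropped.
    """
    reference_field = reference_field or store.get_project(project_id).reference_field
    if not reference_field:
        raise ValueError(f"project {project_id!r} has no reference date field configured")
    configs = [
        VisitConfig(
            event_name=c["event_name"],
            day_offset=c["day_offset"],
            window_after=c["window_after"],
            linked_forms=c["linked_forms"],
        )
        for c in store.visit_configs(project_id)
    ]

    records = store.export_records(project_id)
    record_ids: list[str] = []
    references: dict[str, str] = {}
    for rec in records:
        if rec.record_id not in record_ids:
            record_ids.append(rec.record_id)
        if rec.values.get(reference_field):
            references[rec.record_id] = rec.values[reference_field]

    # (record, event, form) triples with stored data
    filled = {
        (r["record_id"], r["event"], r["form_name"])
        for r in store.conn.execute(
            "SELECT record_id, event, form_name FROM records WHERE project_id=?",
            (project_id,),
        )
    }

    cells: list[VisitCell] = []
    missing: list[str] = []
    for record_id in record_ids:
        ref = references.get(record_id)
        if ref is None or not _DATE_RE.match(ref):
            # missing or unparseable reference date: listed, never dropped
            missing.append(record_id)
            continue
        for cfg, (event_name, due) in zip(configs, schedule_visits(ref, configs)):
            has_data = bool(cfg.linked_forms) and all(
                (record_id, cfg.event_name, form) in filled for form in cfg.linked_forms
            )
            cells.append(
                VisitCell(
                    record_id=record_id,
                    event_name=event_name,
                    due_date=due,
                    status=visit_status(due, cfg.window_after, has_data, today),
                )
            )
    return VisitsPanel(
        cells=cells,
        events=[c.event_name for c in configs],
        record_ids=[r for r in record_ids if r not in missing],
        missing_reference=missing,
    )


# ---------------------------------------------------------------------------
# alerts
# ---------------------------------------------------------------------------


def generate_alerts(
    store: RedcapStore,
    project_id: str,
    now: str,
    reference_field: str | None = None,
) -> list[Notification]:
    """Periodic reminders: one notification per (recipient, reason-instance)
    about open queries and overdue visits, deduplicated within a one-day
    window against the alert log."""
    recipients = store.alert_recipients(project_id)
    if not recipients:
        return []
    today = now[:10]
    cutoff = (date.fromisoformat(today) - timedelta(days=DEDUPE_DAYS)).isoformat()

    wanted: list[tuple[str, str, str]] = []  # (reason, reason_key, body)
    for issue in store.list_queries(project_id, status="open"):
        wanted.append(
            (
                "open_query",
                f"query:{issue.issue_id}",
                f"Query #{issue.issue_id} on record {issue.record_id}"
                f" field {issue.field_name} is awaiting an answer",
            )
        )
    try:
        panel = build_visits_panel(store, project_id, today, reference_field)
    except ValueError:
        panel = None
    if panel is not None:
        for cell in panel.cells:
            if cell.status == "not_carried_out":
                wanted.append(
                    (
                        "pending_visit",
                        f"visit:{cell.record_id}:{cell.event_name}",
                        f"Visit {cell.event_name} for record {cell.record_id}"
                        f" was due {cell.due_date} and has no data",
                    )
                )

    recent = {
        (n["recipient"], n["reason_key"])
        for n in store.notifications(project_id)
        if n["reason"] in ("open_query", "pending_visit") and n["sent_at"][:10] > cutoff
    }

    out: list[Notification] = []
    for recipient, channel in recipients:
        for reason, key, body in wanted:
            if (recipient, key) in recent:
                continue
            store.log_notification(project_id, recipient, channel, reason, key, body, now)
            out.append(Notification(recipient, channel, reason, body, now))
    return out
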