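"""Embedded store emulating the REDCap surfaces the framework relies on.

Backed by a single SQLite database (file or in-memory) whose tables mirror
the metadata model: ``redcap_project``, ``redcap_forms``, ``form_metadata``,
``redcap_validation_types`` / ``_rules`` / ``_issues``, ``redcap_visits``,
``redcap_visits_config``, ``redcap_alerts`` and ``redcap_alerts_log``, plus
the records / change-log / lock tables the record API needs.

The module also owns data-dictionary CSV I/O (18-column REDCap header,
UTF-8, byte-stable writer).
"""

from __future__ import annotations

import csv
import io
import json
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Iterable, Optional

from .dictionary import DICTIONARY_HEADER, DataDictionary, DictionaryRow
from .model import FlatRecord, SemanticTag

__all__ = [
    "RedcapStore",
    "StoreError",
    "LockedRecord",
    "write_dictionary",
    "read_dictionary",
    "ProjectConfig",
    "QueryIssue",
]


class StoreError(KeyError):
    """Unknown project / record / issue, or an illegal state transition."""


class LockedRecord(RuntimeError):
    """Attempted mutation of a locked record."""


# ---------------------------------------------------------------------------
# dictionary CSV I/O
# ---------------------------------------------------------------------------


def write_dictionary(dd: DataDictionary) -> str:
    """Serialize a dictionary as REDCap import CSV. Byte-stable: the same
    dictionary always yields identical text."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(DICTIONARY_HEADER)
    for row in dd.rows:
        writer.writerow(row.as_list())
    return buf.getvalue()


def read_dictionary(text: str, form_name: str | None = None) -> DataDictionary:
    """Parse dictionary CSV; the header must match the 18 known columns."""
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError("empty dictionary CSV") from None
    if header != DICTIONARY_HEADER:
        raise ValueError(
            f"dictionary header mismatch: expected {len(DICTIONARY_HEADER)} "
            f"standard columns, got {header[:3]}..."
        )
    rows = [DictionaryRow.from_list(cells) for cells in reader if any(cells)]
    name = form_name or (rows[0].form_name if rows else "form")
    return DataDictionary(name, rows)  # DataDictionary checks duplicates


# ---------------------------------------------------------------------------
# typed views
# ---------------------------------------------------------------------------


@dataclass
class ProjectConfig:
    project_id: str
    name: str
    api_url: str
    api_token: str
    description: str = ""
    username: str = ""
    password: str = ""
    reference_field: str = ""


@dataclass
class QueryIssue:
    issue_id: int
    project_id: str
    record_id: str
    field_name: str
    rule_id: str
    status: str
    opened_at: str
    resolved_at: Optional[str] = None


_SCHEMA = """
CREATE TABLE IF NOT EXISTS redcap_project (
    project_id TEXT PRIMARY KEY,
    name TEXT NOT NULL,
    api_url TEXT NOT NULL,
    api_token TEXT NOT NULL,
    description TEXT DEFAULT '',
    username TEXT DEFAULT '',
    password TEXT DEFAULT '',
    reference_field TEXT DEFAULT '',
    record_counter INTEGER DEFAULT 0
);
CREATE TABLE IF NOT EXISTS redcap_forms (
    project_id TEXT NOT NULL,
    form_name TEXT NOT NULL,
    order_index INTEGER NOT NULL,
    is_first INTEGER NOT NULL DEFAULT 0,
    dictionary_csv TEXT,
    PRIMARY KEY (project_id, form_name)
);
CREATE TABLE IF NOT EXISTS form_metadata (
    project_id TEXT NOT NULL,
    form_name TEXT NOT NULL,
    field_name TEXT NOT NULL,
    tag_kind TEXT,
    tag_value TEXT,
    identifier INTEGER DEFAULT 0,
    participant_id INTEGER DEFAULT 0,
    PRIMARY KEY (project_id, form_name, field_name)
);
CREATE TABLE IF NOT EXISTS redcap_validation_types (
    rule_type TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS redcap_validation_rules (
    rule_id TEXT PRIMARY KEY,
    project_id TEXT NOT NULL,
    form_name TEXT NOT NULL,
    field_name TEXT NOT NULL,
    rule_type TEXT NOT NULL,
    params TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE IF NOT EXISTS redcap_validation_issues (
    issue_id INTEGER PRIMARY KEY AUTOINCREMENT,
    project_id TEXT NOT NULL,
    record_id TEXT NOT NULL,
    field_name TEXT NOT NULL,
    rule_id TEXT NOT NULL,
    status TEXT NOT NULL DEFAULT 'open',
    opened_at TEXT NOT NULL,
    resolved_at TEXT
);
CREATE UNIQUE INDEX IF NOT EXISTS one_open_issue
    ON redcap_validation_issues (project_id, record_id, field_name, rule_id)
    WHERE status = 'open';
CREATE TABLE IF NOT EXISTS redcap_visits (
    project_id TEXT NOT NULL,
    record_id TEXT NOT NULL,
    event_name TEXT NOT NULL,
    due_date TEXT NOT NULL,
    status TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS redcap_visits_config (
    project_id TEXT NOT NULL,
    event_name TEXT NOT NULL,
    day_offset INTEGER NOT NULL,
    window_after INTEGER NOT NULL DEFAULT 0,
    linked_forms TEXT NOT NULL DEFAULT '[]',
    order_index INTEGER NOT NULL,
    PRIMARY KEY (project_id, event_name)
);
CREATE TABLE IF NOT EXISTS redcap_alerts (
    project_id TEXT NOT NULL,
    recipient TEXT NOT NULL,
    channel TEXT NOT NULL DEFAULT 'email',
    PRIMARY KEY (project_id, recipient, channel)
);
CREATE TABLE IF NOT EXISTS redcap_alerts_log (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    project_id TEXT NOT NULL,
    recipient TEXT NOT NULL,
    channel TEXT NOT NULL,
    reason TEXT NOT NULL,
    reason_key TEXT NOT NULL,
    body TEXT NOT NULL,
    sent_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS records (
    project_id TEXT NOT NULL,
    record_id TEXT NOT NULL,
    event TEXT NOT NULL DEFAULT '',
    form_name TEXT NOT NULL,
    field_values TEXT NOT NULL,
    PRIMARY KEY (project_id, record_id, event, form_name)
);
CREATE TABLE IF NOT EXISTS record_locks (
    project_id TEXT NOT NULL,
    record_id TEXT NOT NULL,
    form_name TEXT NOT NULL,
    PRIMARY KEY (project_id, record_id, form_name)
);
CREATE TABLE IF NOT EXISTS changelog (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    project_id TEXT NOT NULL,
    record_id TEXT NOT NULL,
    form_name TEXT NOT NULL,
    timestamp TEXT NOT NULL,
    snapshot TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS parked_submissions (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    project_id TEXT NOT NULL,
    form_name TEXT NOT NULL,
    payload TEXT NOT NULL,
    reason TEXT NOT NULL,
    parked_at TEXT NOT NULL
);
"""

_RULE_TYPES = ("range", "format", "required", "regex")


class RedcapStore:
    """The embedded project/record store. Not thread-safe; one per process."""

    def __init__(self, path: str = ":memory:"):
        self.conn = sqlite3.connect(path)
        self.conn.row_factory = sqlite3.Row
        self.conn.executescript(_SCHEMA)
        self.conn.executemany(
            "INSERT OR IGNORE INTO redcap_validation_types (rule_type) VALUES (?)",
            [(t,) for t in _RULE_TYPES],
        )
        self.conn.commit()
        self._clock = 0
        self._txn_depth = 0

    def close(self) -> None:
        self.conn.close()

    @contextmanager
    def transaction(self):
        """All-or-nothing mutation scope (used for ETL atomicity).

        While a transaction is open, per-operation commits are deferred; an
        exception rolls back every mutation made inside the scope.
        """
        self._txn_depth += 1
        try:
            yield
        except BaseException:
            self._txn_depth -= 1
            if self._txn_depth == 0:
                self.conn.rollback()
            raise
        else:
            self._txn_depth -= 1
            if self._txn_depth == 0:
                self.conn.commit()

    def _commit(self) -> None:
        if self._txn_depth == 0:
            self.conn.commit()

    def _now(self) -> str:
        # Monotonic logical timestamp; wall time is injected by callers that
        # care about calendar semantics (visits, alert dedupe).
        self._clock += 1
        return f"t{self._clock:08d}"

    # -- projects ---------------------------------------------------------

    def create_project(
        self,
        project_id: str,
        name: str,
        api_url: str = "local://redcap",
        api_token: str = "local-token",
        description: str = "",
        username: str = "",
        password: str = "",
        reference_field: str = "",
    ) -> ProjectConfig:
        if not api_token:
            raise ValueError("api_token must be non-empty")
        try:
            self.conn.execute(
                "INSERT INTO redcap_project (project_id, name, api_url, api_token,"
                " description, username, password, reference_field)"
                " VALUES (?,?,?,?,?,?,?,?)",
                (project_id, name, api_url, api_token, description, username,
                 password, reference_field),
            )
        except sqlite3.IntegrityError:
            raise StoreError(f"project {project_id!r} already exists") from None
        self._commit()
        return self.get_project(project_id)

    def get_project(self, project_id: str) -> ProjectConfig:
        row = self.conn.execute(
            "SELECT * FROM redcap_project WHERE project_id=?", (project_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown project {project_id!r}")
        return ProjectConfig(
            project_id=row["project_id"],
            name=row["name"],
            api_url=row["api_url"],
            api_token=row["api_token"],
            description=row["description"],
            username=row["username"],
            password=row["password"],
            reference_field=row["reference_field"],
        )

    # -- forms and dictionaries ------------------------------------------

    def register_form(
        self,
        project_id: str,
        dd: DataDictionary,
        is_first: bool = False,
    ) -> None:
        """Register a form and its dictionary. The first form registered for
        a project is its entry form unless ``is_first`` reassigns it."""
        self.get_project(project_id)
        count = self.conn.execute(
            "SELECT COUNT(*) FROM redcap_forms WHERE project_id=?", (project_id,)
        ).fetchone()[0]
        if count == 0:
            is_first = True
        if is_first:
            self.conn.execute(
                "UPDATE redcap_forms SET is_first=0 WHERE project_id=?", (project_id,)
            )
        try:
            self.conn.execute(
                "INSERT INTO redcap_forms (project_id, form_name, order_index,"
                " is_first, dictionary_csv) VALUES (?,?,?,?,?)",
                (project_id, dd.form_name, count, int(is_first), write_dictionary(dd)),
            )
        except sqlite3.IntegrityError:
            raise StoreError(
                f"form {dd.form_name!r} already registered in {project_id!r}"
            ) from None
        self._commit()

    def get_dictionary(self, project_id: str, form_name: str) -> DataDictionary:
        row = self.conn.execute(
            "SELECT dictionary_csv FROM redcap_forms WHERE project_id=? AND form_name=?",
            (project_id, form_name),
        ).fetchone()
        if row is None or row[0] is None:
            raise StoreError(f"no dictionary for form {form_name!r} in {project_id!r}")
        return read_dictionary(row[0], form_name)

    def is_first_form(self, project_id: str, form_name: str) -> bool:
        row = self.conn.execute(
            "SELECT is_first FROM redcap_forms WHERE project_id=? AND form_name=?",
            (project_id, form_name),
        ).fetchone()
        if row is None:
            raise StoreError(f"form {form_name!r} not registered in {project_id!r}")
        return bool(row[0])

    def list_forms(self, project_id: str) -> list[str]:
        return [
            r[0]
            for r in self.conn.execute(
                "SELECT form_name FROM redcap_forms WHERE project_id=? ORDER BY order_index",
                (project_id,),
            )
        ]

    # -- field metadata ---------------------------------------------------

    def set_field_metadata(
        self,
        project_id: str,
        form_name: str,
        field_name: str,
        tag: Optional[SemanticTag] = None,
        identifier: bool = False,
        participant_id: bool = False,
    ) -> None:
        if participant_id:
            existing = self.conn.execute(
                "SELECT field_name FROM form_metadata WHERE project_id=?"
                " AND participant_id=1 AND NOT (form_name=? AND field_name=?)",
                (project_id, form_name, field_name),
            ).fetchone()
            if existing is not None:
                raise StoreError(
                    f"project {project_id!r} already has participant_id field"
                    f" {existing[0]!r}"
                )
        self.conn.execute(
            "INSERT OR REPLACE INTO form_metadata (project_id, form_name, field_name,"
            " tag_kind, tag_value, identifier, participant_id) VALUES (?,?,?,?,?,?,?)",
            (
                project_id,
                form_name,
                field_name,
                tag.kind if tag else None,
                tag.value if tag else None,
                int(identifier),
                int(participant_id),
            ),
        )
        self._commit()

    def participant_field(self, project_id: str) -> Optional[str]:
        row = self.conn.execute(
            "SELECT field_name FROM form_metadata WHERE project_id=? AND participant_id=1",
            (project_id,),
        ).fetchone()
        return None if row is None else row[0]

    # -- record ids -------------------------------------------------------

    def next_record_id(self, project_id: str) -> str:
        """Strictly increasing integer ids rendered as text, starting at "1";
        never reused, even after record deletion."""
        self.get_project(project_id)
        cur = self.conn.execute(
            "UPDATE redcap_project SET record_counter = record_counter + 1"
            " WHERE project_id=? RETURNING record_counter",
            (project_id,),
        )
        value = cur.fetchone()[0]
        self._commit()
        return str(value)

    # -- records ----------------------------------------------------------

    def import_record(self, project_id: str, form_name: str, rec: FlatRecord) -> None:
        """Upsert by (record_id, event, form); every import appends a
        change-log entry. Rejects locked records and unknown fields."""
        dd = self.get_dictionary(project_id, form_name)
        known = {r.variable_name for r in dd.rows}
        for key in rec.values:
            base = key.split("___")[0]
            if base not in known:
                raise StoreError(f"unknown field {key!r} for form {form_name!r}")
        if self.is_locked(project_id, rec.record_id, form_name):
            raise LockedRecord(
                f"record {rec.record_id!r} is locked on form {form_name!r}"
            )
        event = rec.event or ""
        existing = self.conn.execute(
            "SELECT field_values FROM records WHERE project_id=? AND record_id=?"
            " AND event=? AND form_name=?",
            (project_id, rec.record_id, event, form_name),
        ).fetchone()
        values = dict(json.loads(existing[0])) if existing else {}
        values.update({k: str(v) for k, v in rec.values.items()})
        self.conn.execute(
            "INSERT OR REPLACE INTO records (project_id, record_id, event, form_name,"
            " field_values) VALUES (?,?,?,?,?)",
            (project_id, rec.record_id, event, form_name, json.dumps(values, sort_keys=True)),
        )
        self.conn.execute(
            "INSERT INTO changelog (project_id, record_id, form_name, timestamp, snapshot)"
            " VALUES (?,?,?,?,?)",
            (
                project_id,
                rec.record_id,
                form_name,
                self._now(),
                json.dumps({k: str(v) for k, v in rec.values.items()}, sort_keys=True),
            ),
        )
        self._commit()

    def export_records(
        self,
        project_id: str,
        record_id: str | None = None,
        form_name: str | None = None,
        event: str | None = None,
    ) -> list[FlatRecord]:
        sql = "SELECT record_id, event, form_name, field_values FROM records WHERE project_id=?"
        args: list = [project_id]
        if record_id is not None:
            sql += " AND record_id=?"
            args.append(record_id)
        if form_name is not None:
            sql += " AND form_name=?"
            args.append(form_name)
        if event is not None:
            sql += " AND event=?"
            args.append(event)
        sql += " ORDER BY CAST(record_id AS INTEGER), record_id, event, form_name"
        out = []
        for row in self.conn.execute(sql, args):
            out.append(
                FlatRecord(
                    record_id=row["record_id"],
                    event=row["event"] or None,
                    values=json.loads(row["field_values"]),
                )
            )
        return out

    def find_record_by_value(
        self, project_id: str, field_name: str, value: str
    ) -> Optional[str]:
        """Record id whose stored value for ``field_name`` equals ``value``."""
        for rec in self.export_records(project_id):
            if rec.values.get(field_name) == value:
                return rec.record_id
        return None

    # -- locking ----------------------------------------------------------

    def lock_record(self, project_id: str, record_id: str, form_name: str) -> None:
        """Idempotent lock; the record must exist."""
        if not self._record_exists(project_id, record_id):
            raise StoreError(f"unknown record {record_id!r}")
        self.conn.execute(
            "INSERT OR IGNORE INTO record_locks (project_id, record_id, form_name)"
            " VALUES (?,?,?)",
            (project_id, record_id, form_name),
        )
        self._commit()

    def unlock_record(self, project_id: str, record_id: str, form_name: str) -> None:
        self.conn.execute(
            "DELETE FROM record_locks WHERE project_id=? AND record_id=? AND form_name=?",
            (project_id, record_id, form_name),
        )
        self._commit()

    def is_locked(self, project_id: str, record_id: str, form_name: str) -> bool:
        return (
            self.conn.execute(
                "SELECT 1 FROM record_locks WHERE project_id=? AND record_id=?"
                " AND form_name=?",
                (project_id, record_id, form_name),
            ).fetchone()
            is not None
        )

    def _record_exists(self, project_id: str, record_id: str) -> bool:
        return (
            self.conn.execute(
                "SELECT 1 FROM records WHERE project_id=? AND record_id=? LIMIT 1",
                (project_id, record_id),
            ).fetchone()
            is not None
        )

    # -- queries (resolution workflow) ------------------------------------

    def open_query(
        self,
        project_id: str,
        record_id: str,
        field_name: str,
        rule_id: str,
        now: str | None = None,
    ) -> QueryIssue:
        """Open an issue; at most one open issue per (record, field, rule)."""
        try:
            cur = self.conn.execute(
                "INSERT INTO redcap_validation_issues (project_id, record_id,"
                " field_name, rule_id, status, opened_at) VALUES (?,?,?,?,'open',?)"
                " RETURNING issue_id, opened_at",
                (project_id, record_id, field_name, rule_id, now or self._now()),
            )
            issue_id, opened_at = cur.fetchone()
        except sqlite3.IntegrityError:
            raise StoreError(
                f"open issue already exists for ({record_id}, {field_name}, {rule_id})"
            ) from None
        self._commit()
        return QueryIssue(issue_id, project_id, record_id, field_name, rule_id, "open", opened_at)

    def find_open_query(
        self, project_id: str, record_id: str, field_name: str, rule_id: str
    ) -> Optional[QueryIssue]:
        row = self.conn.execute(
            "SELECT * FROM redcap_validation_issues WHERE project_id=? AND record_id=?"
            " AND field_name=? AND rule_id=? AND status='open'",
            (project_id, record_id, field_name, rule_id),
        ).fetchone()
        return None if row is None else self._issue(row)

    def list_queries(self, project_id: str, status: str | None = None) -> list[QueryIssue]:
        sql = "SELECT * FROM redcap_validation_issues WHERE project_id=?"
        args: list = [project_id]
        if status is not None:
            sql += " AND status=?"
            args.append(status)
        sql += " ORDER BY issue_id"
        return [self._issue(r) for r in self.conn.execute(sql, args)]

    def resolve_query(self, issue_id: int, now: str | None = None) -> QueryIssue:
        """Legal transition: open -> resolved, once. Re-raising an issue later
        creates a new issue_id via :meth:`open_query`."""
        row = self.conn.execute(
            "SELECT * FROM redcap_validation_issues WHERE issue_id=?", (issue_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown issue {issue_id}")
        if row["status"] != "open":
            raise StoreError(f"issue {issue_id} is not open (status={row['status']!r})")
        resolved_at = now or self._now()
        self.conn.execute(
            "UPDATE redcap_validation_issues SET status='resolved', resolved_at=?"
            " WHERE issue_id=?",
            (resolved_at, issue_id),
        )
        self._commit()
        row = self.conn.execute(
            "SELECT * FROM redcap_validation_issues WHERE issue_id=?", (issue_id,)
        ).fetchone()
        return self._issue(row)

    @staticmethod
    def _issue(row: sqlite3.Row) -> QueryIssue:
        return QueryIssue(
            issue_id=row["issue_id"],
            project_id=row["project_id"],
            record_id=row["record_id"],
            field_name=row["field_name"],
            rule_id=row["rule_id"],
            status=row["status"],
            opened_at=row["opened_at"],
            resolved_at=row["resolved_at"],
        )

    # -- change log -------------------------------------------------------

    def changelog_entries(
        self, project_id: str, record_id: str | None = None, form_name: str | None = None
    ) -> list[dict]:
        sql = "SELECT * FROM changelog WHERE project_id=?"
        args: list = [project_id]
        if record_id is not None:
            sql += " AND record_id=?"
            args.append(record_id)
        if form_name is not None:
            sql += " AND form_name=?"
            args.append(form_name)
        sql += " ORDER BY id"
        return [
            {
                "id": r["id"],
                "record_id": r["record_id"],
                "form_name": r["form_name"],
                "timestamp": r["timestamp"],
                "snapshot": json.loads(r["snapshot"]),
            }
            for r in self.conn.execute(sql, args)
        ]

    def append_changelog(
        self, project_id: str, record_id: str, form_name: str, snapshot: dict
    ) -> dict:
        cur = self.conn.execute(
            "INSERT INTO changelog (project_id, record_id, form_name, timestamp, snapshot)"
            " VALUES (?,?,?,?,?) RETURNING id, timestamp",
            (project_id, record_id, form_name, self._now(), json.dumps(snapshot, sort_keys=True)),
        )
        entry_id, ts = cur.fetchone()
        self._commit()
        return {
            "id": entry_id,
            "record_id": record_id,
            "form_name": form_name,
            "timestamp": ts,
            "snapshot": snapshot,
        }

    # -- notifications ----------------------------------------------------

    def log_notification(
        self,
        project_id: str,
        recipient: str,
        channel: str,
        reason: str,
        reason_key: str,
        body: str,
        sent_at: str,
    ) -> None:
        self.conn.execute(
            "INSERT INTO redcap_alerts_log (project_id, recipient, channel, reason,"
            " reason_key, body, sent_at) VALUES (?,?,?,?,?,?,?)",
            (project_id, recipient, channel, reason, reason_key, body, sent_at),
        )
        self._commit()

    def notifications(self, project_id: str) -> list[dict]:
        return [
            dict(r)
            for r in self.conn.execute(
                "SELECT * FROM redcap_alerts_log WHERE project_id=? ORDER BY id",
                (project_id,),
            )
        ]

    def add_alert_recipient(self, project_id: str, recipient: str, channel: str = "email") -> None:
        if channel not in ("email", "sms"):
            raise ValueError(f"unknown channel {channel!r}")
        self.conn.execute(
            "INSERT OR IGNORE INTO redcap_alerts (project_id, recipient, channel) VALUES (?,?,?)",
            (project_id, recipient, channel),
        )
        self._commit()

    def alert_recipients(self, project_id: str) -> list[tuple[str, str]]:
        return [
            (r["recipient"], r["channel"])
            for r in self.conn.execute(
                "SELECT recipient, channel FROM redcap_alerts WHERE project_id=?"
                " ORDER BY recipient, channel",
                (project_id,),
            )
        ]

    # -- validation rules -------------------------------------------------

    def add_rule(
        self,
        rule_id: str,
        project_id: str,
        form_name: str,
        field_name: str,
        rule_type: str,
        params: dict | None = None,
    ) -> None:
        if rule_type not in _RULE_TYPES:
            raise ValueError(f"unknown rule type {rule_type!r}")
        self.conn.execute(
            "INSERT OR REPLACE INTO redcap_validation_rules (rule_id, project_id,"
            " form_name, field_name, rule_type, params) VALUES (?,?,?,?,?,?)",
            (rule_id, project_id, form_name, field_name, rule_type, json.dumps(params or {})),
        )
        self._commit()

    def list_rules(self, project_id: str) -> list[dict]:
        return [
            {
                "rule_id": r["rule_id"],
                "project_id": r["project_id"],
                "form": r["form_name"],
                "field": r["field_name"],
                "rule_type": r["rule_type"],
                "params": json.loads(r["params"]),
            }
            for r in self.conn.execute(
                "SELECT * FROM redcap_validation_rules WHERE project_id=? ORDER BY rule_id",
                (project_id,),
            )
        ]

    # -- visit configs ----------------------------------------------------

    def add_visit_config(
        self,
        project_id: str,
        event_name: str,
        day_offset: int,
        window_after: int = 0,
        linked_forms: Iterable[str] = (),
    ) -> None:
        if day_offset < 0 or window_after < 0:
            raise ValueError("offsets must be non-negative")
        count = self.conn.execute(
            "SELECT COUNT(*) FROM redcap_visits_config WHERE project_id=?", (project_id,)
        ).fetchone()[0]
        try:
            self.conn.execute(
                "INSERT INTO redcap_visits_config (project_id, event_name, day_offset,"
                " window_after, linked_forms, order_index) VALUES (?,?,?,?,?,?)",
                (project_id, event_name, day_offset, window_after,
                 json.dumps(list(linked_forms)), count),
            )
        except sqlite3.IntegrityError:
            raise StoreError(f"visit {event_name!r} already configured") from None
        self._commit()

    def visit_configs(self, project_id: str) -> list[dict]:
        return [
            {
                "event_name": r["event_name"],
                "day_offset": r["day_offset"],
                "window_after": r["window_after"],
                "linked_forms": json.loads(r["linked_forms"]),
            }
            for r in self.conn.execute(
                "SELECT * FROM redcap_visits_config WHERE project_id=? ORDER BY order_index",
                (project_id,),
            )
        ]

    # -- parked submissions ----------------------------------------------

    def park_submission(
        self, project_id: str, form_name: str, payload: dict, reason: str
    ) -> None:
        self.conn.execute(
            "INSERT INTO parked_submissions (project_id, form_name, payload, reason, parked_at)"
            " VALUES (?,?,?,?,?)",
            (project_id, form_name, json.dumps(payload, sort_keys=True), reason, self._now()),
        )
        self._commit()

    def parked_submissions(self, project_id: str) -> list[dict]:
        return [
            {
                "form_name": r["form_name"],
                "payload": json.loads(r["payload"]),
                "reason": r["reason"],
                "parked_at": r["parked_at"],
            }
            for r in self.conn.execute(
                "SELECT * FROM parked_submissions WHERE project_id=? ORDER BY id",
                (project_id,),
            )
        ]
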