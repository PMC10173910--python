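import datetime

import pytest

from conftest import CREDENTIALS
from edcbridge import fixtures as fx
from edcbridge.etl import ProcessSettings, process_submission
from edcbridge.model import FlatRecord
from edcbridge.quality import (
    ValidationRule,
    VisitConfig,
    build_visits_panel,
    evaluate_rule,
    generate_alerts,
    run_validation_cycle,
    schedule_visits,
    visit_status,
)


def rule(rule_type, field="age", **params):
    return ValidationRule("r1", "toy", "toy_form", field, rule_type, params)


class TestEvaluateRule:
    def test_range_fail_above(self):
        ok, msg = evaluate_rule(rule("range", min=0, max=120), "250")
        assert not ok and "age" in msg and "250" in msg

    def test_required_empty_fails(self):
        ok, msg = evaluate_rule(rule("required"), "")
        assert not ok and "required" in msg

    def test_format_date_passes(self):
        ok, _ = evaluate_rule(rule("format", format="date_ymd"), "2023-01-31")
        assert ok

    def test_format_date_fails(self):
        ok, _ = evaluate_rule(rule("format", format="date_ymd"), "31/01/2023")
        assert not ok

    def test_regex(self):
        ok, _ = evaluate_rule(rule("regex", pattern=r"P-\d{3}"), "P-001")
        assert ok
        ok, _ = evaluate_rule(rule("regex", pattern=r"P-\d{3}"), "x")
        assert not ok

    def test_non_required_rules_pass_on_empty(self):
        assert evaluate_rule(rule("range", min=0, max=10), "")[0]
        assert evaluate_rule(rule("format", format="date_ymd"), None)[0]

    def test_date_range_comparison(self):
        r = rule("range", field="d", min="2023-01-01", max="2023-12-31")
        assert evaluate_rule(r, "2023-06-15")[0]
        assert not evaluate_rule(r, "2024-01-01")[0]

    def test_malformed_rule_params(self):
        with pytest.raises(ValueError):
            ValidationRule("r", "p", "f", "x", "range", {})
        with pytest.raises(ValueError):
            ValidationRule("r", "p", "f", "x", "format", {"format": "nope"})

    def test_boundary_values_against_brute_force(self):
        """min-1 / min / max / max+1 agree with a direct numeric check."""
        for lo, hi in [(0, 120), (5, 5), (-10, 10)]:
            r = rule("range", min=lo, max=hi)
            for value in (lo - 1, lo, hi, hi + 1):
                expected = lo <= value <= hi
                assert evaluate_rule(r, str(value))[0] is expected


class TestValidationCycle:
    def test_open_then_idempotent_then_resolve(self, store, toy_project):
        form = toy_project.instrument.name
        store.import_record("toy", form, FlatRecord("1", {"age": "250", "sex": "1", "participant_code": "P-001",
                                                          "start_date": "2023-01-01"}))
        result = run_validation_cycle(store, "toy", now="2023-02-01")
        assert result["opened"] == 1 and result["resolved"] == 0

        result = run_validation_cycle(store, "toy", now="2023-02-01")
        assert result["opened"] == 0  # fixed point after one cycle

        store.import_record("toy", form, FlatRecord("1", {"age": "40"}))
        result = run_validation_cycle(store, "toy", now="2023-02-02")
        assert result["resolved"] == 1
        assert store.list_queries("toy", status="open") == []

    def test_new_issue_notifies_recipients(self, store, toy_project):
        form = toy_project.instrument.name
        store.import_record("toy", form, FlatRecord("1", {"age": "999", "sex": "2", "participant_code": "P",
                                                          "start_date": "2023-01-01"}))
        run_validation_cycle(store, "toy", now="2023-02-01")
        notes = [n for n in store.notifications("toy") if n["reason"] == "validation_issue"]
        assert len(notes) == 1 and notes[0]["recipient"] == "team@example.org"

    def test_planted_truth_recovery(self, store, toy_project):
        """The engine flags exactly the planted violations: no false
        positives on clean synthetic data, no misses."""
        form = toy_project.instrument.name
        payloads, truths = fx.simulate_submissions(toy_project, 30, seed=6, violation_rate=0.3)
        for payload in payloads:
            process_submission(store, "toy", form, payload, CREDENTIALS,
                               ProcessSettings(event="visit_0"))
        run_validation_cycle(store, "toy", now="2023-03-01")
        participant_to_record = {
            r.values["participant_code"]: r.record_id for r in store.export_records("toy")
        }
        expected = {
            (participant_to_record[t.participant], f, r)
            for t in truths
            for (f, r) in t.violations
        }
        detected = {
            (q.record_id, q.field_name, q.rule_id)
            for q in store.list_queries("toy", status="open")
        }
        assert expected  # the seed must actually plant something
        assert detected == expected


class TestVisits:
    def test_offset_arithmetic(self):
        cfgs = [VisitConfig("m1", 30)]
        assert schedule_visits("2023-01-01", cfgs) == [("m1", "2023-01-31")]

    def test_zero_offset(self):
        assert schedule_visits("2023-01-01", [VisitConfig("d0", 0)]) == [("d0", "2023-01-01")]

    def test_offsets_strictly_increasing(self):
        cfgs = [VisitConfig(f"v{o}", o) for o in (0, 7, 30, 90)]
        due = [d for _, d in schedule_visits("2023-01-15", cfgs)]
        assert len(due) == 4
        assert due == sorted(due) and len(set(due)) == 4

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            VisitConfig("v", -1)

    @pytest.mark.parametrize(
        "due,window,has_data,today,expected",
        [
            ("2023-01-31", 0, True, "2020-01-01", "carried_out"),
            ("2023-01-31", 0, False, "2023-03-01", "not_carried_out"),
            ("2023-01-31", 0, False, "2023-01-31", "pending"),
            ("2023-01-31", 5, False, "2023-02-05", "pending"),  # inside window
            ("2023-01-31", 5, False, "2023-02-06", "not_carried_out"),
            ("2099-01-01", 0, False, "2023-01-01", "pending"),
        ],
    )
    def test_visit_status(self, due, window, has_data, today, expected):
        assert visit_status(due, window, has_data, today) == expected


class TestPanel:
    def fill(self, store, toy_project, n, events=("visit_0",)):
        form = toy_project.instrument.name
        payloads, _ = fx.simulate_submissions(toy_project, n, seed=2)
        for payload in payloads:
            for event in events:
                process_submission(store, "toy", form, payload, CREDENTIALS,
                                   ProcessSettings(event=event))

    def test_cardinality(self, store, toy_project):
        self.fill(store, toy_project, 3)
        panel = build_visits_panel(store, "toy", "2023-02-15")
        assert len(panel.cells) == 3 * 4

    def test_pointwise_status_oracle(self, store, toy_project):
        self.fill(store, toy_project, 5)
        today = "2023-02-15"
        panel = build_visits_panel(store, "toy", today)
        cfg_by_event = {c.event_name: c for c in toy_project.visit_configs}
        refs = {
            r.record_id: r.values["start_date"]
            for r in store.export_records("toy")
            if r.values.get("start_date")
        }
        for cell in panel.cells:
            cfg = cfg_by_event[cell.event_name]
            ref = datetime.date.fromisoformat(refs[cell.record_id])
            due = ref + datetime.timedelta(days=cfg.day_offset)
            assert cell.due_date == due.isoformat()
            has_data = bool(
                store.export_records("toy", record_id=cell.record_id,
                                     event=cell.event_name)
            )
            assert cell.status == visit_status(
                cell.due_date, cfg.window_after, has_data, today
            )

    def test_full_row_carried_out(self, store, toy_project):
        self.fill(store, toy_project, 1, events=("visit_0", "visit_7", "visit_30", "visit_90"))
        panel = build_visits_panel(store, "toy", "2023-06-01")
        assert [c.status for c in panel.cells] == ["carried_out"] * 4

    def test_missing_reference_listed_not_dropped(self, store, toy_project):
        form = toy_project.instrument.name
        store.import_record("toy", form, FlatRecord("9", {"participant_code": "P-X"}))
        panel = build_visits_panel(store, "toy", "2023-02-15")
        assert panel.missing_reference == ["9"]

    def test_21_visit_study_cardinality(self, toy_project):
        """A maximal deployment profile: 21 visits x 2 participants = 42 cells."""
        from conftest import provision
        from edcbridge.store import RedcapStore

        store = RedcapStore()
        project = fx.make_toy_project(4)
        project.visit_configs = [
            VisitConfig(f"visit_{i:02d}", 7 * i, 0, [project.instrument.name])
            for i in range(21)
        ]
        provision(store, project)
        payloads, _ = fx.simulate_submissions(project, 2, seed=3)
        for payload in payloads:
            process_submission(store, "toy", project.instrument.name, payload,
                               CREDENTIALS, ProcessSettings(event="visit_00"))
        panel = build_visits_panel(store, "toy", "2023-02-15")
        assert len(panel.cells) == 2 * 21
        store.close()


class TestAlerts:
    def test_open_queries_notify_each_recipient(self, store):
        store.open_query("toy", "1", "age", "r1")
        store.open_query("toy", "2", "age", "r1")
        sent = generate_alerts(store, "toy", "2023-02-01")
        assert len(sent) == 2
        assert {n.reason for n in sent} == {"open_query"}

    def test_dedupe_window(self, store):
        store.open_query("toy", "1", "age", "r1")
        assert len(generate_alerts(store, "toy", "2023-02-01")) == 1
        assert generate_alerts(store, "toy", "2023-02-01") == []
        # a day later the reminder fires again
        assert len(generate_alerts(store, "toy", "2023-02-03")) == 1

    def test_overdue_visit_notification(self, store, toy_project):
        form = toy_project.instrument.name
        payloads, _ = fx.simulate_submissions(toy_project, 1, seed=8)
        process_submission(store, "toy", form, payloads[0], CREDENTIALS,
                           ProcessSettings(event="visit_0"))
        sent = generate_alerts(store, "toy", "2024-01-01")
        pending = [n for n in sent if n.reason == "pending_visit"]
        assert len(pending) == 3  # visits 7/30/90 overdue; visit_0 has data

    def test_no_recipients_no_alerts(self, toy_project):
        from conftest import provision
        from edcbridge.store import RedcapStore

        store = RedcapStore()
        store.create_project("p2", "NoRecipients")
        store.open_query("p2", "1", "f", "r")
        assert generate_alerts(store, "p2", "2023-01-01") == []
        store.close()

    def test_log_append_only_and_duplicate_free(self, store):
        store.open_query("toy", "1", "age", "r1")
        generate_alerts(store, "toy", "2023-02-01")
        generate_alerts(store, "toy", "2023-02-01")
        log = [n for n in store.notifications("toy") if n["reason"] == "open_query"]
        keys = [(n["recipient"], n["reason_key"], n["sent_at"][:10]) for n in log]
        assert len(keys) == len(set(keys))
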