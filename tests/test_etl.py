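import pytest

from conftest import CREDENTIALS
from edcbridge import fixtures as fx
from edcbridge.etl import (
    AuthenticationFailed,
    EmptyAfterCleaning,
    ProcessSettings,
    UnknownField,
    UnresolvedParticipant,
    authenticate,
    on_record_changed,
    parse_submission,
    process_submission,
    resolve_record,
    transform_record,
)
from edcbridge.model import FlatRecord


def snapshot(store):
    """Full content snapshot of every mutable table (atomicity oracle)."""
    tables = (
        "records", "changelog", "record_locks", "redcap_validation_issues",
        "redcap_alerts_log", "parked_submissions",
    )
    return {
        t: store.conn.execute(f"SELECT * FROM {t} ORDER BY rowid").fetchall()
        for t in tables
    }


class TestAuthenticate:
    def test_correct_pair(self, store):
        assert authenticate(CREDENTIALS, "toy", store) is True

    def test_wrong_password(self, store):
        assert authenticate((CREDENTIALS[0], "nope"), "toy", store) is False

    def test_empty_credentials(self, store):
        assert authenticate(("", ""), "toy", store) is False

    def test_unknown_project(self, store):
        from edcbridge.store import StoreError

        with pytest.raises(StoreError):
            authenticate(CREDENTIALS, "ghost", store)


class TestParseSubmission:
    def test_metadata_removed(self, toy_project):
        cleaned = parse_submission(
            {"_id": 5, "_uuid": "u-1", "age": "34"}, toy_project.instrument
        )
        assert cleaned == {"age": "34"}

    def test_group_prefix_stripped(self, toy_project):
        cleaned = parse_submission({"grp/sex": "1", "_id": 1}, toy_project.instrument)
        assert cleaned == {"sex": "1"}

    def test_blocklist_keys_removed(self, toy_project):
        cleaned = parse_submission(
            {"start": "x", "end": "y", "today": "z", "deviceid": "d",
             "meta/instanceID": "i", "formhub/uuid": "u", "age": "20"},
            toy_project.instrument,
        )
        assert cleaned == {"age": "20"}

    def test_only_metadata_raises(self, toy_project):
        with pytest.raises(EmptyAfterCleaning):
            parse_submission({"_id": 1, "meta/instanceID": "x"}, toy_project.instrument)

    def test_empty_payload_raises(self, toy_project):
        with pytest.raises(EmptyAfterCleaning):
            parse_submission({}, toy_project.instrument)


class TestTransformRecord:
    def test_checkbox_expansion(self, toy_project):
        instr = toy_project.instrument
        codes = instr.choice_lists["symptoms"].codes()
        picked = codes[:2]
        rec = transform_record({"checkbox_symptoms": " ".join(picked)}, instr)
        for code in codes:
            expected = "1" if code in picked else "0"
            assert rec.values[f"checkbox_symptoms___{code}"] == expected

    def test_empty_checkbox_all_zero(self, toy_project):
        instr = toy_project.instrument
        rec = transform_record({"checkbox_symptoms": ""}, instr)
        assert set(rec.values.values()) == {"0"}

    def test_passthrough_text(self, toy_project):
        rec = transform_record({"age": "34"}, toy_project.instrument)
        assert rec.values == {"age": "34"}

    def test_unknown_field_named(self, toy_project):
        with pytest.raises(UnknownField, match="bogus"):
            transform_record({"bogus": "x"}, toy_project.instrument)

    def test_stray_code_flagged_not_fatal(self, toy_project):
        instr = toy_project.instrument
        rec = transform_record({"checkbox_symptoms": "zzz"}, instr)
        assert any("zzz" in issue for issue in rec.issues)
        assert all(v == "0" for v in rec.values.values())


class TestResolveRecord:
    def test_new_participant_first_form(self, store, toy_project):
        rid, created = resolve_record(store, "toy", toy_project.instrument.name, "P-001")
        assert (rid, created) == ("1", True)

    def test_known_participant(self, store, toy_project):
        form = toy_project.instrument.name
        store.import_record("toy", form, FlatRecord("1", {"participant_code": "P-001"}))
        rid, created = resolve_record(store, "toy", form, "P-001")
        assert (rid, created) == ("1", False)

    def test_unknown_participant_non_first_form(self, store, toy_project):
        dd = __import__("edcbridge").convert_instrument(fx.treatment_instrument(), "treatment")
        store.register_form("toy", dd)  # second, non-entry form
        with pytest.raises(UnresolvedParticipant):
            resolve_record(store, "toy", "treatment", "P-999")


class TestProcessSubmission:
    def payloads(self, toy_project, n=3, **kw):
        return fx.simulate_submissions(toy_project, n, seed=4, **kw)[0]

    def all_on(self):
        return ProcessSettings(
            event="visit_0", check_duplicates=True, lock_on_save=True,
            notify_team=True, notify_respondent=True,
        )

    def test_first_submission_all_actions(self, store, toy_project):
        payload = self.payloads(toy_project)[0]
        outcome = process_submission(
            store, "toy", toy_project.instrument.name, payload, CREDENTIALS, self.all_on()
        )
        assert outcome.created_new is True
        assert outcome.record_id == "1"
        assert set(outcome.actions_performed) == {"locked", "notified_team", "notified_respondent"}
        assert "duplicate_flagged" not in outcome.actions_performed
        reasons = {n["reason"] for n in store.notifications("toy")}
        assert {"submission_received", "submission_receipt"} <= reasons

    def test_identical_resubmission_flags_duplicate(self, store, toy_project):
        form = toy_project.instrument.name
        payload = self.payloads(toy_project)[0]
        settings = ProcessSettings(event="visit_0")
        process_submission(store, "toy", form, payload, CREDENTIALS, settings)
        outcome = process_submission(store, "toy", form, payload, CREDENTIALS, settings)
        assert "duplicate_flagged" in outcome.actions_performed
        assert len(store.export_records("toy")) == 1
        assert len(store.changelog_entries("toy")) == 1  # second import skipped

    def test_differing_resubmission_updates_and_opens_query(self, store, toy_project):
        form = toy_project.instrument.name
        payload = self.payloads(toy_project)[0]
        settings = ProcessSettings(event="visit_0")
        process_submission(store, "toy", form, payload, CREDENTIALS, settings)
        changed = {**payload, "age": "99"}
        outcome = process_submission(store, "toy", form, changed, CREDENTIALS, settings)
        assert "duplicate_flagged" not in outcome.actions_performed
        assert store.export_records("toy")[0].values["age"] == "99"
        open_queries = store.list_queries("toy", status="open")
        assert any(q.rule_id == "duplicate" for q in open_queries)

    def test_bad_credentials_store_untouched(self, store, toy_project):
        before = snapshot(store)
        with pytest.raises(AuthenticationFailed):
            process_submission(
                store, "toy", toy_project.instrument.name,
                self.payloads(toy_project)[0], ("processor", "wrong"),
            )
        assert snapshot(store) == before

    def test_end_to_end_conservation(self, store, toy_project):
        """Every non-metadata answer appears in the exported record, modulo
        checkbox expansion."""
        form = toy_project.instrument.name
        instr = toy_project.instrument
        for payload in self.payloads(toy_project, n=5):
            process_submission(
                store, "toy", form, payload, CREDENTIALS, ProcessSettings(event="visit_0")
            )
            cleaned = parse_submission(payload, instr)
            participant = cleaned["participant_code"]
            rec = next(
                r for r in store.export_records("toy")
                if r.values.get("participant_code") == participant
            )
            for key, value in cleaned.items():
                fld = instr.get_field(key)
                if fld.type.value == "select_multiple":
                    for code in str(value).split():
                        assert rec.values.get(f"{key}___{code}") == "1"
                else:
                    assert rec.values.get(key) == str(value).strip()

    def test_duplicate_idempotence_stream(self, store, toy_project):
        """Re-processing an identical payload stream never creates records."""
        form = toy_project.instrument.name
        payloads = self.payloads(toy_project, n=6)
        settings = ProcessSettings(event="visit_0")
        for payload in payloads + payloads:
            process_submission(store, "toy", form, payload, CREDENTIALS, settings)
        assert len(store.export_records("toy")) == 6

    def test_unresolved_participant_parked(self, store, toy_project):
        followup = fx.make_random_instrument(1, name="followup")
        dd = __import__("edcbridge").convert_instrument(followup, "followup")
        store.register_form("toy", dd)  # second, non-entry form
        payload = {"_id": 1, "start_date": "2023-01-01", "participant_code": "P-404"}
        before = snapshot(store)
        with pytest.raises(UnresolvedParticipant):
            process_submission(store, "toy", "followup", payload, CREDENTIALS)
        after = snapshot(store)
        # only the park log changed
        assert after["parked_submissions"] != before["parked_submissions"]
        assert {k: v for k, v in after.items() if k != "parked_submissions"} == {
            k: v for k, v in before.items() if k != "parked_submissions"
        }
        assert store.parked_submissions("toy")[0]["reason"] == "unresolved participant"

    def test_atomicity_on_locked_record(self, store, toy_project):
        form = toy_project.instrument.name
        payload = self.payloads(toy_project)[0]
        settings = ProcessSettings(event="visit_0")
        process_submission(store, "toy", form, payload, CREDENTIALS, settings)
        store.lock_record("toy", "1", form)
        before = snapshot(store)
        from edcbridge.store import LockedRecord

        with pytest.raises(LockedRecord):
            process_submission(
                store, "toy", form, {**payload, "age": "77"}, CREDENTIALS, settings
            )
        assert snapshot(store) == before


class TestChangeMonitor:
    def test_external_edit_logged(self, store, toy_project):
        form = toy_project.instrument.name
        store.import_record("toy", form, FlatRecord("1", {"age": "40"}))
        # simulate an edit made directly in the capture system
        store.conn.execute(
            "UPDATE records SET field_values='{\"age\": \"41\"}' WHERE record_id='1'"
        )
        store.conn.commit()
        entry = on_record_changed(store, "toy", "1", form)
        assert entry is not None and entry["snapshot"]["age"] == "41"

    def test_noop_edit_no_entry(self, store, toy_project):
        form = toy_project.instrument.name
        store.import_record("toy", form, FlatRecord("1", {"age": "40"}))
        assert on_record_changed(store, "toy", "1", form) is None

    def test_three_edits_three_entries(self, store, toy_project):
        form = toy_project.instrument.name
        store.import_record("toy", form, FlatRecord("1", {"age": "40"}))
        for new_age in ("41", "42", "43"):
            store.conn.execute(
                f'UPDATE records SET field_values=\'{{"age": "{new_age}"}}\' WHERE record_id=\'1\''
            )
            store.conn.commit()
            assert on_record_changed(store, "toy", "1", form) is not None
        entries = store.changelog_entries("toy", record_id="1")
        assert len(entries) == 4  # 1 import + 3 monitored edits
        stamps = [e["timestamp"] for e in entries]
        assert stamps == sorted(stamps)

    def test_unknown_record(self, store, toy_project):
        from edcbridge.store import StoreError

        with pytest.raises(StoreError):
            on_record_changed(store, "toy", "77", toy_project.instrument.name)
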