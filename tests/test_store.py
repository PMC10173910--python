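import random

import pytest

from edcbridge import fixtures as fx
from edcbridge.dictionary import convert_instrument
from edcbridge.model import FlatRecord
from edcbridge.store import (
    LockedRecord,
    RedcapStore,
    StoreError,
    read_dictionary,
    write_dictionary,
)


class TestDictionaryCsv:
    def test_empty_dictionary_header_only(self):
        from edcbridge.dictionary import DataDictionary

        text = write_dictionary(DataDictionary("f"))
        assert text.count("\n") == 1
        assert text.startswith("Variable / Field Name,")

    def test_treatment_dictionary_four_lines(self):
        dd = convert_instrument(fx.treatment_instrument(), "treatment")
        text = write_dictionary(dd)
        assert len(text.rstrip("\n").split("\n")) == 4

    def test_writer_is_byte_stable(self):
        dd = convert_instrument(fx.make_toy_project(2).instrument, "toy_form")
        assert write_dictionary(dd) == write_dictionary(dd)

    @pytest.mark.parametrize("seed", [1, 4, 8])
    def test_round_trip(self, seed):
        dd = convert_instrument(fx.make_random_instrument(seed, n_extra=2), "f")
        back = read_dictionary(write_dictionary(dd), "f")
        assert back.rows == dd.rows

    def test_header_mismatch(self):
        with pytest.raises(ValueError, match="header"):
            read_dictionary("a,b,c\n1,2,3\n")

    def test_duplicate_variable_names_rejected(self):
        dd = convert_instrument(fx.treatment_instrument(), "t")
        text = write_dictionary(dd)
        line = text.rstrip("\n").split("\n")[1]
        with pytest.raises(ValueError, match="duplicate"):
            read_dictionary(text + line + "\n")


class TestRecordIds:
    def test_fresh_project_starts_at_one(self, store):
        assert store.next_record_id("toy") == "1"

    def test_counter_semantics(self, store):
        for _ in range(3):
            store.next_record_id("toy")
        assert store.next_record_id("toy") == "4"

    def test_successive_calls_distinct(self, store):
        assert store.next_record_id("toy") != store.next_record_id("toy")

    def test_unknown_project(self, store):
        with pytest.raises(StoreError):
            store.next_record_id("ghost")


class TestRecords:
    def form(self, toy_project):
        return toy_project.instrument.name

    def test_import_export_round_trip(self, store, toy_project):
        rec = FlatRecord("1", {"age": "40", "participant_code": "P-001"})
        store.import_record("toy", self.form(toy_project), rec)
        (out,) = store.export_records("toy", record_id="1")
        assert out.values == rec.values

    def test_unknown_field_named(self, store, toy_project):
        with pytest.raises(StoreError, match="bogus"):
            store.import_record("toy", self.form(toy_project), FlatRecord("1", {"bogus": "x"}))

    def test_import_to_locked_record(self, store, toy_project):
        form = self.form(toy_project)
        store.import_record("toy", form, FlatRecord("1", {"age": "40"}))
        store.lock_record("toy", "1", form)
        with pytest.raises(LockedRecord):
            store.import_record("toy", form, FlatRecord("1", {"age": "41"}))
        assert store.export_records("toy", record_id="1")[0].values["age"] == "40"

    def test_upsert_two_imports_one_record_two_log_entries(self, store, toy_project):
        form = self.form(toy_project)
        store.import_record("toy", form, FlatRecord("1", {"age": "40"}))
        store.import_record("toy", form, FlatRecord("1", {"age": "41"}))
        assert len(store.export_records("toy")) == 1
        assert len(store.changelog_entries("toy", record_id="1")) == 2

    def test_changelog_conservation(self, store, toy_project):
        """Change-log length equals the number of imports."""
        form = self.form(toy_project)
        rng = random.Random(5)
        n_imports = 0
        for _ in range(25):
            rid = str(rng.randint(1, 4))
            store.import_record("toy", form, FlatRecord(rid, {"age": str(rng.randint(1, 99))}))
            n_imports += 1
        assert len(store.changelog_entries("toy")) == n_imports

    def test_changelog_timestamps_non_decreasing(self, store, toy_project):
        form = self.form(toy_project)
        for i in range(5):
            store.import_record("toy", form, FlatRecord("1", {"age": str(i)}))
        stamps = [e["timestamp"] for e in store.changelog_entries("toy", record_id="1")]
        assert stamps == sorted(stamps)


class TestLocking:
    def test_lock_idempotent(self, store, toy_project):
        form = toy_project.instrument.name
        store.import_record("toy", form, FlatRecord("1", {"age": "1"}))
        store.lock_record("toy", "1", form)
        store.lock_record("toy", "1", form)  # no error
        assert store.is_locked("toy", "1", form)

    def test_lock_unknown_record(self, store, toy_project):
        with pytest.raises(StoreError):
            store.lock_record("toy", "99", toy_project.instrument.name)


class TestQueries:
    def test_resolve_open_issue(self, store):
        issue = store.open_query("toy", "1", "age", "r1")
        resolved = store.resolve_query(issue.issue_id)
        assert resolved.status == "resolved"
        assert resolved.resolved_at is not None

    def test_resolve_twice_is_error(self, store):
        issue = store.open_query("toy", "1", "age", "r1")
        store.resolve_query(issue.issue_id)
        with pytest.raises(StoreError):
            store.resolve_query(issue.issue_id)

    def test_duplicate_open_issue_rejected(self, store):
        store.open_query("toy", "1", "age", "r1")
        with pytest.raises(StoreError):
            store.open_query("toy", "1", "age", "r1")

    def test_reopen_creates_new_issue_id(self, store):
        first = store.open_query("toy", "1", "age", "r1")
        store.resolve_query(first.issue_id)
        second = store.open_query("toy", "1", "age", "r1")
        assert second.issue_id != first.issue_id

    def test_open_issue_uniqueness_under_interleaving(self, store):
        """Arbitrary open/resolve interleavings never yield two open issues
        for the same (record, field, rule)."""
        rng = random.Random(11)
        keys = [("1", "age", "r1"), ("1", "age", "r2"), ("2", "age", "r1")]
        for _ in range(200):
            key = rng.choice(keys)
            open_issue = store.find_open_query("toy", *key)
            if rng.random() < 0.5:
                if open_issue is None:
                    store.open_query("toy", *key)
            elif open_issue is not None:
                store.resolve_query(open_issue.issue_id)
            for k in keys:
                n_open = sum(
                    1
                    for q in store.list_queries("toy", status="open")
                    if (q.record_id, q.field_name, q.rule_id) == k
                )
                assert n_open <= 1

    def test_unknown_issue(self, store):
        with pytest.raises(StoreError):
            store.resolve_query(12345)


class TestProjectRegistry:
    def test_duplicate_project_rejected(self, store):
        with pytest.raises(StoreError):
            store.create_project("toy", "Again")

    def test_empty_token_rejected(self):
        s = RedcapStore()
        with pytest.raises(ValueError):
            s.create_project("p", "P", api_token="")

    def test_one_first_form_per_project(self, store, toy_project):
        dd = convert_instrument(fx.treatment_instrument(), "treatment")
        store.register_form("toy", dd, is_first=True)
        rows = store.conn.execute(
            "SELECT form_name FROM redcap_forms WHERE project_id='toy' AND is_first=1"
        ).fetchall()
        assert len(rows) == 1 and rows[0][0] == "treatment"

    def test_participant_field_unique_per_project(self, store, toy_project):
        with pytest.raises(StoreError):
            store.set_field_metadata(
                "toy", toy_project.instrument.name, "age", participant_id=True
            )
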