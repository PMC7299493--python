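"""Standardisation rules, profile validation, and importation."""

import csv

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reclink.profiles import (
    MISSING,
    DatasetProfile,
    DerivedOutput,
    FieldSpec,
    ImportError_,
    import_dataset,
    parse_date,
    profile_from_dict,
    standardise_value,
    validate_profile,
)
from reclink.stores import LinkageStore

NAME_RULES = ("trim", "uppercase", "strip_punctuation", "collapse_whitespace")
NAME_SPEC = FieldSpec("surname", "name", NAME_RULES, (DerivedOutput("surname_sx", "soundex"),))
DATE_SPEC = FieldSpec("dob", "date", ("trim", "parse_date"))


class TestStandardiseValue:
    @pytest.mark.parametrize(
        "raw,cleaned",
        [
            (" mary-anne ", "MARY ANNE"),  # hyphen collapses to single space
            ("O'Brien", "O BRIEN"),
            ("  smith  jones ", "SMITH JONES"),
            ("MARY ANNE", "MARY ANNE"),  # already clean: no-op
        ],
    )
    def test_name_cleaning(self, raw, cleaned):
        assert standardise_value(raw, NAME_SPEC).value == cleaned

    @pytest.mark.parametrize("raw", ["", "   ", "\t"])
    def test_blank_maps_to_missing(self, raw):
        res = standardise_value(raw, NAME_SPEC)
        assert res.value is MISSING
        assert res.derived["surname_sx"] is MISSING

    def test_derived_phonetic_on_cleaned_value(self):
        res = standardise_value(" smith ", NAME_SPEC)
        assert res.derived["surname_sx"] == "S530"

    @pytest.mark.parametrize(
        "raw,iso",
        [
            ("1980-04-12", "1980-04-12"),
            ("12/04/1980", "1980-04-12"),  # day-first
            ("19800412", "1980-04-12"),
            ("1980-04", "1980-04"),  # partial retained, not imputed
            ("1980", "1980"),
        ],
    )
    def test_date_parsing(self, raw, iso):
        assert standardise_value(raw, DATE_SPEC).value == iso

    def test_unparseable_date_flagged(self):
        res = standardise_value("31/02/1980", DATE_SPEC)
        assert res.value is MISSING
        assert res.parse_failed

    def test_parse_date_rejects_invalid_calendar(self):
        assert parse_date("1980-13-01") is None
        assert parse_date("not a date") is None

    @settings(derandomize=True, max_examples=200)
    @given(st.text(max_size=25))
    def test_idempotence(self, raw):
        once = standardise_value(raw, NAME_SPEC)
        if once.value is MISSING:
            return
        twice = standardise_value(once.value, NAME_SPEC)
        assert twice.value == once.value
        assert twice.derived == once.derived

    @settings(derandomize=True, max_examples=100)
    @given(st.dates())
    def test_date_idempotence(self, d):
        iso = d.isoformat()
        once = standardise_value(iso, DATE_SPEC)
        assert once.value == iso
        assert standardise_value(once.value, DATE_SPEC).value == iso


class TestValidateProfile:
    def test_well_formed(self):
        prof = DatasetProfile("ds", (NAME_SPEC, DATE_SPEC), row_id_field="row_id")
        assert validate_profile(prof) == []

    def test_duplicate_field_name(self):
        prof = DatasetProfile("ds", (NAME_SPEC, NAME_SPEC), row_id_field="row_id")
        violations = validate_profile(prof)
        assert any("duplicate" in v.message and v.field == "surname" for v in violations)

    def test_rule_kind_mismatch(self):
        bad = FieldSpec("surname", "name", ("parse_date",))
        prof = DatasetProfile("ds", (bad,), row_id_field="row_id")
        violations = validate_profile(prof)
        assert len(violations) == 1
        assert violations[0].rule == "parse_date"

    def test_unknown_rule_token(self):
        bad = FieldSpec("surname", "name", ("frobnicate",))
        violations = validate_profile(DatasetProfile("ds", (bad,), row_id_field="row_id"))
        assert any(v.rule == "frobnicate" for v in violations)

    def test_derived_name_collision(self):
        a = FieldSpec("surname", "name", NAME_RULES, (DerivedOutput("dob", "soundex"),))
        prof = DatasetProfile("ds", (a, DATE_SPEC), row_id_field="row_id")
        assert any("collides" in v.message for v in validate_profile(prof))

    def test_version_bump(self):
        prof = DatasetProfile("ds", (NAME_SPEC,), row_id_field="row_id")
        assert prof.bump_version().version == prof.version + 1

    def test_profile_from_dict_defaults(self):
        prof = profile_from_dict(
            {"dataset_id": "x", "row_id_field": "id",
             "fields": [{"name": "surname", "kind": "name"}]}
        )
        assert prof.field_specs[0].cleaning_rules == NAME_RULES
        assert validate_profile(prof) == []


class TestImportDataset:
    def _profile(self):
        return DatasetProfile("ds", (NAME_SPEC, DATE_SPEC), row_id_field="row_id")

    def test_clean_import(self):
        store = LinkageStore()
        rows = [{"row_id": f"r{i}", "surname": "Smith", "dob": "1980-01-01"} for i in range(5)]
        report = import_dataset(store, rows, self._profile())
        assert (report.rows_read, report.rows_accepted, report.rows_rejected) == (5, 5, 0)
        assert len(store.records) == 5
        assert store.records["ds:r0"].values["surname"] == "SMITH"

    def test_duplicate_row_id_is_hard_error(self):
        store = LinkageStore()
        rows = [{"row_id": "dup", "surname": "A", "dob": ""},
                {"row_id": "dup", "surname": "B", "dob": ""}]
        with pytest.raises(ImportError_, match="dup"):
            import_dataset(store, rows, self._profile())

    def test_missing_mandatory_column(self):
        store = LinkageStore()
        with pytest.raises(ImportError_, match="row_id"):
            import_dataset(store, [{"surname": "A"}], self._profile())

    def test_missing_counts(self):
        store = LinkageStore()
        rows = [{"row_id": f"r{i}", "surname": "" if i < 10 else "Smith", "dob": "1980-01-01"}
                for i in range(100)]
        report = import_dataset(store, rows, self._profile())
        assert report.missing_counts["surname"] == 10
        assert report.missing_counts["dob"] == 0

    def test_reimport_refused_then_forced(self):
        store = LinkageStore()
        rows = [{"row_id": "r1", "surname": "Smith", "dob": ""}]
        import_dataset(store, rows, self._profile())
        with pytest.raises(ImportError_, match="already"):
            import_dataset(store, rows, self._profile())
        prof2 = self._profile()
        with pytest.raises(Exception):  # same rows again even with flag: dup record ids
            import_dataset(store, rows, prof2, re_import=True)

    def test_completeness_rows_read_equals_accepted_plus_rejected(self):
        store = LinkageStore()
        rows = [{"row_id": "r1", "surname": "A", "dob": ""},
                {"row_id": "", "surname": "B", "dob": ""}]
        report = import_dataset(store, rows, self._profile())
        assert report.rows_read == report.rows_accepted + report.rows_rejected
        assert report.rows_rejected == 1

    def test_csv_roundtrip_determinism(self, tmp_path):
        path = tmp_path / "in.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["row_id", "surname", "dob"])
            writer.writeheader()
            writer.writerow({"row_id": "r1", "surname": " o'brien ", "dob": "12/04/1980"})
        s1, s2 = LinkageStore(), LinkageStore()
        import_dataset(s1, str(path), self._profile())
        import_dataset(s2, str(path), self._profile())
        assert s1.records["ds:r1"].values == s2.records["ds:r1"].values
        assert s1.records["ds:r1"].values == {"surname": "O BRIEN", "dob": "1980-04-12"}

    def test_import_writes_audit_event(self):
        store = LinkageStore()
        import_dataset(store, [{"row_id": "r1", "surname": "A", "dob": ""}], self._profile())
        events = store.query_events(kind="data_change")
        assert len(events) == 1
        assert events[0].payload["action"] == "import"
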