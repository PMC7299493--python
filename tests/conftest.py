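"""Shared fixtures: tiny in-memory stores and hand-built records."""

from __future__ import annotations

import pytest

from reclink.profiles import DatasetProfile, DerivedOutput, FieldSpec, import_dataset
from reclink.stores import LinkageStore


def person_profile(dataset_id: str = "ds", extra: tuple = ()) -> DatasetProfile:
    specs = (
        FieldSpec("given_name", "name", ("trim", "uppercase", "strip_punctuation", "collapse_whitespace"),
                  (DerivedOutput("given_name_sx", "soundex"),)),
        FieldSpec("surname", "name", ("trim", "uppercase", "strip_punctuation", "collapse_whitespace"),
                  (DerivedOutput("surname_sx", "soundex"),)),
        FieldSpec("sex", "sex", ("trim", "sex_normalise")),
        FieldSpec("dob", "date", ("trim", "parse_date")),
        FieldSpec("locality", "locality", ("trim", "uppercase", "strip_punctuation", "collapse_whitespace")),
    ) + extra
    return DatasetProfile(dataset_id, specs, row_id_field="row_id")


def make_store(rows, dataset_id: str = "ds", profile: DatasetProfile | None = None) -> LinkageStore:
    """Build a store from row dicts; missing columns are filled blank."""
    profile = profile or person_profile(dataset_id)
    store = LinkageStore()
    filled = []
    for i, row in enumerate(rows, 1):
        base = {"row_id": row.get("row_id", f"r{i:03d}")}
        for fs in profile.field_specs:
            base[fs.name] = row.get(fs.name, "")
        filled.append(base)
    import_dataset(store, filled, profile)
    return store


@pytest.fixture
def small_store() -> LinkageStore:
    return make_store(
        [
            {"row_id": "a", "given_name": "Mary", "surname": "Smith", "sex": "F",
             "dob": "1980-04-12", "locality": "Perth"},
            {"row_id": "b", "given_name": "Mary", "surname": "Smyth", "sex": "F",
             "dob": "1980-04-12", "locality": "Perth"},
            {"row_id": "c", "given_name": "John", "surname": "Jones", "sex": "M",
             "dob": "1975-01-30", "locality": "Albany"},
            {"row_id": "d", "given_name": "Jon", "surname": "Jones", "sex": "M",
             "dob": "1975-01-30", "locality": "Albany"},
        ]
    )
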