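"""Dataset profiles: the user-authored recipe for standardising one dataset.

A :class:`DatasetProfile` declares, per identifying field, a semantic kind
(name, date, sex, ...), an ordered list of cleaning rules, and derived
outputs such as phonetic codes.  The importation service applies the profile
to every source row, producing :class:`StandardisedRecord` objects that carry
only cleaned values — raw values are never stored.

Missing data is represented by ``None`` (the module constant :data:`MISSING`),
never the empty string, so "cleaned to nothing" and "absent at source" stay
distinguishable downstream (a missing field contributes zero match weight).
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from ._text import soundex

MISSING = None

SEMANTIC_KINDS = ("name", "date", "sex", "address", "locality", "numeric_id", "freetext")

# which cleaning rules each semantic kind may carry
_TEXT_KINDS = ("name", "address", "locality", "freetext", "sex")
RULES: dict[str, tuple[str, ...]] = {
    "trim": SEMANTIC_KINDS,
    "uppercase": _TEXT_KINDS,
    "strip_punctuation": ("name", "locality", "freetext"),
    "collapse_whitespace": _TEXT_KINDS,
    "digits_only": ("numeric_id",),
    "parse_date": ("date",),
    "sex_normalise": ("sex",),
    "address_standardise": ("address",),
}

DERIVED_TRANSFORMS = ("soundex", "first4", "year_of")

# street-type abbreviation expansion shipped with the package (toy lookup;
# full gazetteer-backed address reference data is out of scope)
ADDRESS_ABBREVIATIONS = {
    "ST": "STREET",
    "RD": "ROAD",
    "AVE": "AVENUE",
    "AV": "AVENUE",
    "HWY": "HIGHWAY",
    "PL": "PLACE",
    "CT": "COURT",
    "CRES": "CRESCENT",
    "DR": "DRIVE",
    "LN": "LANE",
    "TCE": "TERRACE",
    "U": "UNIT",
    "APT": "UNIT",
    "FL": "FLAT",
}

_PUNCT_TO_SPACE = re.compile(r"[-']+")
_PUNCT_DROP = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class DerivedOutput:
    """A derived column computed from the cleaned value (e.g. a phonetic code)."""

    name: str
    transform: str  # one of DERIVED_TRANSFORMS


@dataclass(frozen=True)
class FieldSpec:
    name: str
    semantic_kind: str
    cleaning_rules: tuple[str, ...] = ()
    derived_outputs: tuple[DerivedOutput, ...] = ()
    strict: bool = False  # strict dates: parse failure recorded as field rejection

    def __post_init__(self):
        object.__setattr__(self, "cleaning_rules", tuple(self.cleaning_rules))
        object.__setattr__(self, "derived_outputs", tuple(self.derived_outputs))


@dataclass(frozen=True)
class DatasetProfile:
    dataset_id: str
    field_specs: tuple[FieldSpec, ...]
    row_id_field: str
    version: int = 1

    def __post_init__(self):
        object.__setattr__(self, "field_specs", tuple(self.field_specs))

    @property
    def field_names(self) -> list[str]:
        return [fs.name for fs in self.field_specs]

    def spec_for(self, name: str) -> FieldSpec:
        for fs in self.field_specs:
            if fs.name == name:
                return fs
        raise KeyError(name)

    def bump_version(self) -> "DatasetProfile":
        """Return a copy with version incremented by exactly one."""
        return replace(self, version=self.version + 1)


@dataclass(frozen=True)
class StandardisedRecord:
    """One cleaned row in the demographic store."""

    record_id: str  # dataset_id + ":" + source row id
    dataset_id: str
    values: dict  # field name -> cleaned value or MISSING
    derived: dict  # derived column name -> value or MISSING
    import_run_id: str

    def get(self, name: str):
        if name in self.values:
            return self.values[name]
        return self.derived.get(name, MISSING)


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str
    message: str


@dataclass
class ImportReport:
    dataset_id: str
    import_run_id: str
    rows_read: int = 0
    rows_accepted: int = 0
    rows_rejected: int = 0
    missing_counts: dict = field(default_factory=dict)  # field -> count
    parse_failures: dict = field(default_factory=dict)  # field -> count


# ---------------------------------------------------------------------------
# date parsing

_ISO_FULL = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")
_ISO_MONTH = re.compile(r"^(\d{4})-(\d{2})$")
_ISO_YEAR = re.compile(r"^(\d{4})$")
_DMY = re.compile(r"^(\d{1,2})[/.](\d{1,2})[/.](\d{4})$")
_COMPACT = re.compile(r"^(\d{4})(\d{2})(\d{2})$")

_DAYS_IN_MONTH = (31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def _valid_ymd(y: int, m: int, d: int) -> bool:
    return 1 <= m <= 12 and 1 <= d <= _DAYS_IN_MONTH[m - 1]


def parse_date(raw: str) -> Optional[str]:
    """Parse to an ISO-8601 calendar date string, or None if unparseable.

    Partial dates are retained at their stated precision ("1980" and
    "1980-04" round-trip unchanged) rather than imputed to a full date.
    Day-first order is assumed for slashed dates.
    """
    s = raw.strip()
    m = _ISO_FULL.match(s)
    if m:
        y, mo, d = (int(g) for g in m.groups())
        return s if _valid_ymd(y, mo, d) else None
    m = _ISO_MONTH.match(s)
    if m and 1 <= int(m.group(2)) <= 12:
        return s
    if _ISO_YEAR.match(s):
        return s
    m = _DMY.match(s)
    if m:
        d, mo, y = (int(g) for g in m.groups())
        if _valid_ymd(y, mo, d):
            return f"{y:04d}-{mo:02d}-{d:02d}"
        return None
    m = _COMPACT.match(s)
    if m:
        y, mo, d = (int(g) for g in m.groups())
        if _valid_ymd(y, mo, d):
            return f"{y:04d}-{mo:02d}-{d:02d}"
    return None


# ---------------------------------------------------------------------------
# cleaning rules


def _apply_rule(rule: str, value: str) -> Optional[str]:
    """Apply one rule to a non-missing string; None signals a parse failure."""
    if rule == "trim":
        return value.strip()
    if rule == "uppercase":
        return value.upper()
    if rule == "strip_punctuation":
        value = _PUNCT_TO_SPACE.sub(" ", value)
        value = _PUNCT_DROP.sub("", value)
        return _WS.sub(" ", value).strip()
    if rule == "collapse_whitespace":
        return _WS.sub(" ", value).strip()
    if rule == "digits_only":
        return "".join(c for c in value if c.isdigit())
    if rule == "parse_date":
        return parse_date(value)
    if rule == "sex_normalise":
        v = value.strip().upper()
        if v in ("M", "MALE", "1"):
            return "M"
        if v in ("F", "FEMALE", "2"):
            return "F"
        return ""
    if rule == "address_standardise":
        v = value.upper()
        # "5/12 FOO ST" -> unit / street-number split
        v = re.sub(r"^(\d+)\s*/\s*(\d+)", r"UNIT \1 \2", v)
        v = _PUNCT_TO_SPACE.sub(" ", v)
        v = _PUNCT_DROP.sub("", v)
        tokens = [ADDRESS_ABBREVIATIONS.get(t, t) for t in v.split()]
        return " ".join(tokens)
    raise ValueError(f"unknown cleaning rule: {rule}")


def _derived_value(transform: str, cleaned: Optional[str]):
    if cleaned is MISSING or cleaned == "":
        return MISSING
    if transform == "soundex":
        code = soundex(cleaned)
        return code if code else MISSING
    if transform == "first4":
        return cleaned[:4]
    if transform == "year_of":
        return cleaned[:4] if len(cleaned) >= 4 and cleaned[:4].isdigit() else MISSING
    raise ValueError(f"unknown derived transform: {transform}")


@dataclass(frozen=True)
class CleanResult:
    value: object  # cleaned value or MISSING
    derived: dict
    parse_failed: bool = False


def standardise_value(raw: Optional[str], spec: FieldSpec) -> CleanResult:
    """Clean one raw value under a field spec.

    Deterministic and idempotent: re-cleaning a cleaned value is a no-op.
    Blank or whitespace-only input maps to :data:`MISSING`; derived outputs
    (phonetic codes etc.) are computed on the cleaned value.
    """
    if raw is MISSING or str(raw).strip() == "":
        return CleanResult(MISSING, {d.name: MISSING for d in spec.derived_outputs})
    value: Optional[str] = str(raw)
    parse_failed = False
    for rule in spec.cleaning_rules:
        value = _apply_rule(rule, value)
        if value is None:
            parse_failed = True
            break
        if value == "":
            # cleaned away entirely (e.g. pure punctuation) -> missing
            value = None
            break
    cleaned = MISSING if value in (None, "") else value
    derived = {d.name: _derived_value(d.transform, cleaned) for d in spec.derived_outputs}
    return CleanResult(cleaned, derived, parse_failed)


def validate_profile(profile: DatasetProfile) -> list[Violation]:
    """Machine-readable invariant check; empty list iff the profile is valid."""
    violations: list[Violation] = []
    seen: set[str] = set()
    all_names = set(profile.field_names)
    for fs in profile.field_specs:
        if fs.name in seen:
            violations.append(Violation(fs.name, "", f"duplicate field name: {fs.name}"))
        seen.add(fs.name)
        if fs.semantic_kind not in SEMANTIC_KINDS:
            violations.append(
                Violation(fs.name, "", f"unknown semantic kind: {fs.semantic_kind}")
            )
            continue
        for rule in fs.cleaning_rules:
            if rule not in RULES:
                violations.append(Violation(fs.name, rule, f"unknown rule token: {rule}"))
            elif fs.semantic_kind not in RULES[rule]:
                violations.append(
                    Violation(
                        fs.name,
                        rule,
                        f"rule {rule!r} not permitted on kind {fs.semantic_kind!r}",
                    )
                )
        for d in fs.derived_outputs:
            if d.transform not in DERIVED_TRANSFORMS:
                violations.append(
                    Violation(fs.name, d.transform, f"unknown derived transform: {d.transform}")
                )
            if d.name in all_names:
                violations.append(
                    Violation(
                        fs.name, d.transform, f"derived name collides with source field: {d.name}"
                    )
                )
    if profile.version < 1:
        violations.append(Violation("", "", "profile version must be >= 1"))
    return violations


# default rule sequences per kind, used by profile_from_dict when rules omitted
DEFAULT_RULES = {
    "name": ("trim", "uppercase", "strip_punctuation", "collapse_whitespace"),
    "date": ("trim", "parse_date"),
    "sex": ("trim", "sex_normalise"),
    "address": ("trim", "address_standardise", "collapse_whitespace"),
    "locality": ("trim", "uppercase", "strip_punctuation", "collapse_whitespace"),
    "numeric_id": ("trim", "digits_only"),
    "freetext": ("trim", "uppercase", "collapse_whitespace"),
}


def profile_from_dict(cfg: dict) -> DatasetProfile:
    """Build a profile from a declarative mapping (parsed YAML/JSON)."""
    specs = []
    for f in cfg["fields"]:
        kind = f["kind"]
        rules = tuple(f.get("rules", DEFAULT_RULES.get(kind, ("trim",))))
        derived = tuple(
            DerivedOutput(d["name"], d["transform"]) for d in f.get("derived", [])
        )
        specs.append(
            FieldSpec(
                name=f["name"],
                semantic_kind=kind,
                cleaning_rules=rules,
                derived_outputs=derived,
                strict=bool(f.get("strict", False)),
            )
        )
    return DatasetProfile(
        dataset_id=cfg["dataset_id"],
        field_specs=tuple(specs),
        row_id_field=cfg["row_id_field"],
        version=int(cfg.get("version", 1)),
    )


def profile_from_yaml(path) -> DatasetProfile:
    import yaml

    with open(path) as fh:
        return profile_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# importation


class ImportError_(Exception):
    """Hard importation error (duplicate row ids, missing mandatory column)."""


def _file_digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_csv_rows(path) -> tuple[list[str], list[dict]]:
    """RFC-4180 CSV with mandatory header row, UTF-8."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ImportError_("source file has no header row")
        return list(reader.fieldnames), list(reader)


def import_dataset(store, source, profile: DatasetProfile, re_import: bool = False) -> ImportReport:
    """Standardise and load one delimited file into the demographic store.

    ``source`` is a CSV path or an iterable of row dicts (the latter is how
    the synthetic generator feeds the store without touching disk).  Returns
    an :class:`ImportReport`; writes a data-change audit event.  Re-importing
    the same bytes under the same profile version is refused unless
    ``re_import`` is set.
    """
    violations = validate_profile(profile)
    if violations:
        raise ImportError_(f"profile invalid: {violations}")

    if isinstance(source, (str, Path)):
        header, rows = read_csv_rows(Path(source))
        digest = _file_digest(Path(source))
    else:
        rows = [dict(r) for r in source]
        header = list(rows[0].keys()) if rows else [profile.row_id_field]
        h = hashlib.sha256()
        for r in rows:
            h.update(repr(sorted(r.items())).encode())
        digest = h.hexdigest()

    if profile.row_id_field not in header:
        raise ImportError_(f"missing mandatory column: {profile.row_id_field}")

    import_key = (profile.dataset_id, profile.version, digest)
    if store.seen_import(import_key) and not re_import:
        raise ImportError_(
            f"dataset {profile.dataset_id!r} v{profile.version}: identical file already "
            "imported (pass re_import to force)"
        )

    from collections import Counter

    row_ids = [r.get(profile.row_id_field, "") for r in rows]
    counts = Counter(i for i in row_ids if i not in (None, ""))
    dupes = sorted(i for i, c in counts.items() if c > 1)
    if dupes:
        raise ImportError_(f"duplicate source row ids: {dupes}")

    run_id = store.new_import_run_id()
    report = ImportReport(profile.dataset_id, run_id)
    report.missing_counts = {fs.name: 0 for fs in profile.field_specs}
    report.parse_failures = {fs.name: 0 for fs in profile.field_specs}

    records = []
    for row in rows:
        report.rows_read += 1
        row_id = row[profile.row_id_field]
        if row_id is None or str(row_id).strip() == "":
            report.rows_rejected += 1
            continue
        values: dict = {}
        derived: dict = {}
        for fs in profile.field_specs:
            res = standardise_value(row.get(fs.name, MISSING), fs)
            values[fs.name] = res.value
            derived.update(res.derived)
            if res.value is MISSING:
                report.missing_counts[fs.name] += 1
            if res.parse_failed:
                report.parse_failures[fs.name] += 1
        rec = StandardisedRecord(
            record_id=f"{profile.dataset_id}:{row_id}",
            dataset_id=profile.dataset_id,
            values=values,
            derived=derived,
            import_run_id=run_id,
        )
        records.append(rec)
        report.rows_accepted += 1

    store.add_records(records, import_key, run_id, profile)
    return report
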