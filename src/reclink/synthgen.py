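"""Synthetic longitudinal populations with ground truth, plus evaluation.

The generator emulates the event-based, error-laden person data a linkage
unit receives: a "hospital" dataset with a skewed number of event records
per person (geometric, so a few people accrue many admissions) and a
"deaths" dataset covering a fraction of the population.  Surnames follow a
Zipf-like distribution (default exponent 1.5) so common and rare values
coexist — the contrast the frequency-adjusted weights exploit.  Corruption
(typos, phonetic-preserving substitutions, day/month transpositions,
missingness, surname changes) is applied per field, independently, after
truth assignment, so the truth table always reflects the uncorrupted
person identity.

Everything is driven by a mandatory seed; the same spec yields
byte-identical output.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np

from .matching import (
    FieldWeights,
    LinkageStrategy,
    MatchCondition,
    MatchFunction,
    StrategyField,
)
from .prep import BlockingScheme, BlockKey, KeyPart
from .profiles import DatasetProfile, DerivedOutput, FieldSpec

# Shipped value lists.  Surname families deliberately include phonetic
# variants (SMITH/SMYTH, JOHNSON/JOHNSTON, ...) so phonetic blocking and
# partial string agreement are exercised.
SURNAMES = [
    "SMITH", "JONES", "WILLIAMS", "BROWN", "TAYLOR", "WILSON", "JOHNSON", "WHITE",
    "MARTIN", "ANDERSON", "THOMPSON", "NGUYEN", "THOMAS", "WALKER", "HARRIS", "LEE",
    "RYAN", "ROBINSON", "KELLY", "KING", "DAVIS", "WRIGHT", "EVANS", "ROBERTS",
    "GREEN", "HALL", "WOOD", "JACKSON", "CLARKE", "PATEL", "KHAN", "LEWIS",
    "JAMES", "PHILLIPS", "MASON", "MITCHELL", "YOUNG", "MORRIS", "HILL", "COOPER",
    "WARD", "BELL", "WATSON", "BAKER", "ADAMS", "ARMSTRONG", "GRAHAM", "STEWART",
    "MURRAY", "CAMPBELL", "HUGHES", "EDWARDS", "TURNER", "COLLINS", "BARNES",
    "FISHER", "PALMER", "HOLMES", "MILLS", "WEBB", "CHAPMAN", "GRANT", "REID",
    "MCDONALD", "FRASER", "HAMILTON", "DUNCAN", "FERGUSON", "SUTHERLAND",
    "SMYTH", "JOHNSTON", "CLARK", "STUART", "MACDONALD", "OBRIEN", "OCONNOR",
    "WALSH", "BYRNE", "GALLAGHER", "DOYLE",
]
GIVEN_F = [
    "MARY", "MARGARET", "ELIZABETH", "SARAH", "EMMA", "OLIVIA", "CHLOE", "SOPHIE",
    "EMILY", "JESSICA", "GRACE", "HANNAH", "LUCY", "KATE", "ANNA", "RUTH",
    "HELEN", "CLAIRE", "FIONA", "LAURA", "AMY", "RACHEL", "REBECCA", "ALICE",
    "JANE", "SUSAN", "KAREN", "JULIA", "NICOLE", "MICHELLE", "AMELIA", "ISLA",
    "EVIE", "GEORGIA", "HOLLY", "ZOE", "ELLA", "MIA", "ABIGAIL", "FREYA",
]
GIVEN_M = [
    "JOHN", "WILLIAM", "JAMES", "DAVID", "ROBERT", "MICHAEL", "THOMAS", "PETER",
    "GEORGE", "HENRY", "JACK", "OLIVER", "CHARLES", "DANIEL", "MATTHEW", "ANDREW",
    "JOSHUA", "LUKE", "SAMUEL", "BENJAMIN", "RICHARD", "EDWARD", "PAUL", "MARK",
    "STEPHEN", "ALEXANDER", "PATRICK", "SEAN", "LIAM", "CONNOR", "RYAN", "ETHAN",
    "NOAH", "LACHLAN", "ANGUS", "HAMISH", "CALLUM", "FINN", "OSCAR", "HUGO",
]
LOCALITIES = [
    "PERTH", "FREMANTLE", "SUBIACO", "JOONDALUP", "ARMADALE", "MIDLAND",
    "ROCKINGHAM", "MANDURAH", "BUNBURY", "GERALDTON", "ALBANY", "KALGOORLIE",
    "BROOME", "KARRATHA", "NORTHAM", "BUSSELTON", "ESPERANCE", "COLLIE",
    "NARROGIN", "KATANNING",
]

_VOWELS = "AEIOU"
_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class CorruptionModel:
    """Per-field error probabilities, each applied independently."""

    typo: float = 0.0  # one-character substitution (names, locality)
    phonetic_sub: float = 0.0  # vowel swap preserving the phonetic code
    date_transpose: float = 0.0  # day/month swap on date of birth
    missing: float = 0.0  # field blanked
    name_change: float = 0.0  # surname replaced (marriage etc.)

    def validate(self) -> list[str]:
        bad = [
            k
            for k, v in self.__dict__.items()
            if not (0.0 <= v <= 1.0)
        ]
        return [f"corruption probability out of [0,1]: {k}" for k in bad]


def uniform_corruption(p: float) -> CorruptionModel:
    """Every operator at the same per-field rate ``p``."""
    return CorruptionModel(p, p, p, p, p)


@dataclass(frozen=True)
class PopulationSpec:
    n_persons: int
    seed: int  # mandatory: full reproducibility
    mean_events: float = 3.0  # geometric event count per person (>=1)
    zipf_exponent: float = 1.5  # surname frequency skew
    given_zipf_exponent: float = 1.2
    death_fraction: float = 0.25
    dob_years: tuple = (1920, 2005)
    event_years: tuple = (2005, 2020)
    corruption: CorruptionModel = field(default_factory=CorruptionModel)

    def validate(self) -> list[str]:
        errs = self.corruption.validate()
        if self.n_persons < 1:
            errs.append("n_persons must be positive")
        if self.mean_events < 1:
            errs.append("mean_events must be >= 1")
        if not (0 <= self.death_fraction <= 1):
            errs.append("death_fraction out of [0,1]")
        return errs


@dataclass
class SyntheticPopulation:
    datasets: dict  # dataset name -> list of row dicts (CSV-shaped)
    truth: dict  # record_id ("dataset:row_id") -> person_id
    spec: PopulationSpec


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def _rand_date(rng, years: tuple) -> tuple[int, int, int]:
    y = int(rng.integers(years[0], years[1] + 1))
    m = int(rng.integers(1, 13))
    d = int(rng.integers(1, [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m - 1] + 1))
    return y, m, d


def _iso(y: int, m: int, d: int) -> str:
    return f"{y:04d}-{m:02d}-{d:02d}"


def _typo(rng, s: str) -> str:
    if not s:
        return s
    i = int(rng.integers(0, len(s)))
    repl = _LETTERS[int(rng.integers(0, 26))]
    while repl == s[i]:
        repl = _LETTERS[int(rng.integers(0, 26))]
    return s[:i] + repl + s[i + 1 :]


def _phonetic_sub(rng, s: str) -> str:
    """Alter the string while preserving its Soundex code: swap an internal
    vowel, or double an internal consonant when no vowel is available."""
    positions = [i for i, c in enumerate(s) if i > 0 and c in _VOWELS]
    if positions:
        i = positions[int(rng.integers(0, len(positions)))]
        repl = _VOWELS[int(rng.integers(0, 5))]
        while repl == s[i]:
            repl = _VOWELS[int(rng.integers(0, 5))]
        return s[:i] + repl + s[i + 1 :]
    if len(s) > 1:
        i = int(rng.integers(1, len(s)))
        return s[:i] + s[i] + s[i:]
    return s


def _transpose_date(iso: str) -> str:
    y, m, d = iso.split("-")
    if int(d) <= 12 and d != m:
        return f"{y}-{d}-{m}"
    return iso


def generate(spec: PopulationSpec, out_dir=None) -> SyntheticPopulation:
    """Generate the population and its event datasets.

    Emits a "hospital" dataset (one row per event) and a "deaths" dataset
    (at most one row per person), with overlapping persons and a truth
    table mapping every record to its person.  With ``out_dir`` set, the
    datasets and the truth table are also written as headered CSV files.
    """
    errs = spec.validate()
    if errs:
        raise ValueError("; ".join(errs))
    rng = np.random.default_rng(spec.seed)
    n = spec.n_persons

    surname_p = _zipf_probs(len(SURNAMES), spec.zipf_exponent)
    given_p_f = _zipf_probs(len(GIVEN_F), spec.given_zipf_exponent)
    given_p_m = _zipf_probs(len(GIVEN_M), spec.given_zipf_exponent)

    persons = []
    for pid in range(n):
        sex = "F" if rng.random() < 0.5 else "M"
        given = (
            GIVEN_F[int(rng.choice(len(GIVEN_F), p=given_p_f))]
            if sex == "F"
            else GIVEN_M[int(rng.choice(len(GIVEN_M), p=given_p_m))]
        )
        surname = SURNAMES[int(rng.choice(len(SURNAMES), p=surname_p))]
        dob = _iso(*_rand_date(rng, spec.dob_years))
        locality = LOCALITIES[int(rng.integers(0, len(LOCALITIES)))]
        n_events = min(int(rng.geometric(1.0 / spec.mean_events)), 15)
        event_dates = sorted(
            _iso(*_rand_date(rng, spec.event_years)) for _ in range(n_events)
        )
        dies = rng.random() < spec.death_fraction
        death_date = None
        if dies:
            last = int(event_dates[-1][:4]) if event_dates else spec.event_years[1]
            death_date = _iso(*_rand_date(rng, (last + 1, last + 3)))
        persons.append(
            {
                "person_id": f"p{pid:06d}",
                "sex": sex,
                "given_name": given,
                "surname": surname,
                "dob": dob,
                "locality": locality,
                "event_dates": event_dates,
                "death_date": death_date,
            }
        )

    c = spec.corruption

    def corrupt_name(value: str, allow_change: bool = False) -> str:
        if allow_change and rng.random() < c.name_change:
            value = SURNAMES[int(rng.choice(len(SURNAMES), p=surname_p))]
        if rng.random() < c.typo:
            value = _typo(rng, value)
        if rng.random() < c.phonetic_sub:
            value = _phonetic_sub(rng, value)
        if rng.random() < c.missing:
            return ""
        return value

    def corrupt_dob(value: str) -> str:
        if rng.random() < c.date_transpose:
            value = _transpose_date(value)
        if rng.random() < c.missing:
            return ""
        return value

    def corrupt_sex(value: str) -> str:
        return "" if rng.random() < c.missing else value

    def identity_fields(p) -> dict:
        return {
            "given_name": corrupt_name(p["given_name"]),
            "surname": corrupt_name(p["surname"], allow_change=True),
            "sex": corrupt_sex(p["sex"]),
            "dob": corrupt_dob(p["dob"]),
            "locality": corrupt_name(p["locality"]),
        }

    hospital_rows = []
    deaths_rows = []
    truth = {}
    hosp_counter = itertools.count(1)
    death_counter = itertools.count(1)
    for p in persons:
        for ev in p["event_dates"]:
            row_id = f"h{next(hosp_counter):07d}"
            hospital_rows.append({"row_id": row_id, **identity_fields(p), "event_date": ev})
            truth[f"hospital:{row_id}"] = p["person_id"]
        if p["death_date"] is not None:
            row_id = f"d{next(death_counter):07d}"
            deaths_rows.append(
                {"row_id": row_id, **identity_fields(p), "death_date": p["death_date"]}
            )
            truth[f"deaths:{row_id}"] = p["person_id"]

    pop = SyntheticPopulation(
        {"hospital": hospital_rows, "deaths": deaths_rows}, truth, spec
    )
    if out_dir is not None:
        write_population(pop, out_dir)
    return pop


def write_population(pop: SyntheticPopulation, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, rows in pop.datasets.items():
        if not rows:
            continue
        with open(out / f"{name}.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    with open(out / "truth.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "person_id"])
        for rid, pid in sorted(pop.truth.items()):
            writer.writerow([rid, pid])


def read_truth(path) -> dict:
    with open(path, newline="", encoding="utf-8") as fh:
        return {r["record_id"]: r["person_id"] for r in csv.DictReader(fh)}


# ---------------------------------------------------------------------------
# default profiles / blocking / strategy for the generated datasets


def default_profiles() -> dict:
    def identity_specs():
        return [
            FieldSpec("given_name", "name", ("trim", "uppercase", "strip_punctuation", "collapse_whitespace"),
                      (DerivedOutput("given_name_sx", "soundex"),)),
            FieldSpec("surname", "name", ("trim", "uppercase", "strip_punctuation", "collapse_whitespace"),
                      (DerivedOutput("surname_sx", "soundex"),)),
            FieldSpec("sex", "sex", ("trim", "sex_normalise")),
            FieldSpec("dob", "date", ("trim", "parse_date")),
            FieldSpec("locality", "locality", ("trim", "uppercase", "strip_punctuation", "collapse_whitespace")),
        ]

    hospital = DatasetProfile(
        "hospital",
        tuple(identity_specs() + [FieldSpec("event_date", "date", ("trim", "parse_date"))]),
        row_id_field="row_id",
    )
    deaths = DatasetProfile(
        "deaths",
        tuple(identity_specs() + [FieldSpec("death_date", "date", ("trim", "parse_date"))]),
        row_id_field="row_id",
    )
    return {"hospital": hospital, "deaths": deaths}


def default_blocking(scope=("*", "*")) -> BlockingScheme:
    """Multi-key union: phonetic surname x birth year, phonetic given name x
    birth year, exact date of birth, and phonetic surname x locality (the
    fallback for records missing or corrupting the date of birth)."""
    return BlockingScheme(
        "default",
        (
            BlockKey((KeyPart("surname", "phonetic"), KeyPart("dob", "year_of"))),
            BlockKey((KeyPart("given_name", "phonetic"), KeyPart("dob", "year_of"))),
            BlockKey((KeyPart("dob", "identity"),)),
            BlockKey((KeyPart("surname", "phonetic"), KeyPart("locality", "identity"))),
        ),
        scope=scope,
    )


def default_strategy(
    blocking: Optional[BlockingScheme] = None,
    lower: float = 7.0,
    upper: float = 12.0,
    cardinality: str = "none",
) -> LinkageStrategy:
    """The package's default person-matching strategy for the generated data.

    m/u values are priors a linkage analyst would assign for administrative
    data with a few percent per-field error: names compared by Jaro-Winkler
    with chain-based frequency adjustment (given names conditioned on sex),
    date of birth with day/month-transposition tolerance, sex and locality
    as weak corroborators.  Partial string agreement (a likely typo) keeps
    most of the agreement weight; a partially agreeing date keeps little,
    because near-agreeing dates of *different* people are common while true
    date errors are mostly transpositions or gaps.  The event-after-death
    exclusion condition guards hospital-deaths pairs, and the relatively low
    upper threshold leans on the chain-context QA checks (sex, birth-date
    conflicts) to veto doppelganger merges at link time.
    """
    fields = (
        StrategyField(
            "given_name",
            MatchFunction("given_jw", "string"),
            FieldWeights("given_name", m=0.88, u=0.02, partial_discount=0.65,
                         frequency_mode="chain", conditioning_field="sex"),
        ),
        StrategyField(
            "surname",
            MatchFunction("surname_jw", "string"),
            FieldWeights("surname", m=0.85, u=0.01, partial_discount=0.65,
                         frequency_mode="chain"),
        ),
        StrategyField(
            "sex",
            MatchFunction("sex_exact", "string", agree_threshold=1.0, partial_threshold=1.0),
            FieldWeights("sex", m=0.98, u=0.5),
        ),
        StrategyField(
            "dob",
            MatchFunction("dob_date", "date"),
            FieldWeights("dob", m=0.93, u=1e-4, partial_discount=0.35),
        ),
        StrategyField(
            "locality",
            MatchFunction("locality_str", "string"),
            FieldWeights("locality", m=0.88, u=0.05, partial_discount=0.65),
        ),
    )
    conditions = (
        MatchCondition("event_after_death", "date_after", "event_date", "death_date"),
    )
    return LinkageStrategy(
        strategy_id="default_person_match",
        scope=("*", "*"),
        blocking=(blocking if blocking is not None else default_blocking(),),
        fields=fields,
        conditions=conditions,
        lower=lower,
        upper=upper,
        cardinality=cardinality,
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class Evaluation:
    true_pairs: int
    predicted_pairs: int
    true_positives: int
    precision: Fraction
    recall: Fraction
    f_measure: Fraction
    flags: list

    def as_floats(self) -> dict:
        return {
            "precision": float(self.precision),
            "recall": float(self.recall),
            "f_measure": float(self.f_measure),
            "true_pairs": self.true_pairs,
            "predicted_pairs": self.predicted_pairs,
            "true_positives": self.true_positives,
        }


def _pairs(k: int) -> int:
    return k * (k - 1) // 2


def evaluate(store, truth: dict) -> Evaluation:
    """Pairwise precision / recall / F against the truth partition.

    Counts unordered within-chain record pairs vs unordered same-person
    pairs, over non-deleted records; exact rational arithmetic throughout.
    Undefined precision (no predicted pairs) is reported as 1 with a flag,
    likewise recall when the truth has no co-referent pairs.
    """
    flags = []
    live = [r.record_id for r in store.live_records()]
    for rid in live:
        if rid not in truth:
            raise ValueError(f"truth table missing record: {rid}")
    person_counts: dict = {}
    for rid in live:
        person_counts[truth[rid]] = person_counts.get(truth[rid], 0) + 1
    true_pairs = sum(_pairs(k) for k in person_counts.values())
    predicted_pairs = 0
    true_positives = 0
    for chain in store.active_chains():
        members = [r for r in chain.member_record_ids if r not in store.deleted]
        predicted_pairs += _pairs(len(members))
        cell: dict = {}
        for rid in members:
            cell[truth[rid]] = cell.get(truth[rid], 0) + 1
        true_positives += sum(_pairs(k) for k in cell.values())
    if predicted_pairs == 0:
        precision = Fraction(1)
        flags.append("no_predicted_pairs")
    else:
        precision = Fraction(true_positives, predicted_pairs)
    if true_pairs == 0:
        recall = Fraction(1)
        flags.append("no_true_pairs")
    else:
        recall = Fraction(true_positives, true_pairs)
    if precision + recall == 0:
        f = Fraction(0)
    else:
        f = 2 * precision * recall / (precision + recall)
    return Evaluation(true_pairs, predicted_pairs, true_positives, precision, recall, f, flags)
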