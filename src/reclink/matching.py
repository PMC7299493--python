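"""Match functions, frequency calculations and Fellegi-Sunter weight assembly.

Each strategy field carries a match function (how two values are compared:
string similarity, date with transposition tolerance, numeric tolerance,
location hierarchy) and field weights (the m and u probabilities).  Field
outcomes map to log-base-2 likelihood-ratio weights:

    agree     ->  log2(m / u_eff)
    disagree  ->  log2((1 - m) / (1 - u_eff))
    partial   ->  partial_discount * agreement weight
    missing   ->  0            (absence of evidence is neutral)

where u_eff is the field's u probability, or — when frequency adjustment is
on — the observed relative frequency of the agreeing value clamped below by
a floor.  Rare values therefore earn more agreement weight than common ones.
Frequencies can be counted per record or per chain; chain-based counting
makes the tables invariant to how many event records a person accrues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from ._text import jaro_winkler_cached, soundex
from .profiles import MISSING, StandardisedRecord


class Outcome(str, Enum):
    AGREE = "agree"
    PARTIAL = "partial"
    DISAGREE = "disagree"
    MISSING = "missing"


class StrategyError(Exception):
    pass


# ---------------------------------------------------------------------------
# match functions


@dataclass(frozen=True)
class MatchFunction:
    """Symmetric, deterministic field comparator.

    Parameters by kind:
      string   — agree_threshold (default 0.92), partial_threshold (0.80),
                 Jaro-Winkler similarity.
      date     — allow_transposition (True): day/month swap counts as partial;
                 a single wrong component (year, month or day) is partial.
      numeric  — tolerance (abs difference for agree), partial_tolerance.
      location — level: "exact" compares full values, phonetic-equal values
                 count partial; "phonetic" compares at phonetic-code level.
    """

    function_id: str
    field_kind: str  # string | numeric | date | location
    agree_threshold: float = 0.92
    partial_threshold: float = 0.80
    allow_transposition: bool = True
    tolerance: float = 0.0
    partial_tolerance: Optional[float] = None
    level: str = "exact"

    def validate(self) -> list[str]:
        errs = []
        if self.field_kind not in ("string", "numeric", "date", "location"):
            errs.append(f"{self.function_id}: unknown field kind {self.field_kind!r}")
        if self.field_kind == "string" and not (
            0 <= self.partial_threshold <= self.agree_threshold <= 1
        ):
            errs.append(f"{self.function_id}: need 0 <= partial <= agree <= 1 thresholds")
        if self.field_kind == "numeric" and self.tolerance < 0:
            errs.append(f"{self.function_id}: negative tolerance")
        if self.field_kind == "location" and self.level not in ("exact", "phonetic"):
            errs.append(f"{self.function_id}: unknown hierarchy level {self.level!r}")
        return errs


def _date_parts(v: str) -> tuple:
    parts = v.split("-")
    return tuple(parts + [""] * (3 - len(parts)))


def compare_fields(val_a, val_b, function: MatchFunction) -> Outcome:
    """Compare two standardised values under a match function.

    Missing wins: if either side is the missing marker the outcome is
    ``missing``.  Symmetric in its arguments by construction.
    """
    if val_a is MISSING or val_b is MISSING:
        return Outcome.MISSING
    kind = function.field_kind
    if kind == "string":
        sim = jaro_winkler_cached(str(val_a), str(val_b))
        if sim >= function.agree_threshold:
            return Outcome.AGREE
        if sim >= function.partial_threshold:
            return Outcome.PARTIAL
        return Outcome.DISAGREE
    if kind == "date":
        a, b = str(val_a), str(val_b)
        if a == b:
            return Outcome.AGREE
        ya, ma, da = _date_parts(a)
        yb, mb, db = _date_parts(b)
        if function.allow_transposition and ya == yb and ma == db and da == mb and ma != da:
            return Outcome.PARTIAL  # day/month transposition
        if ("" in (ma, mb, da, db)) and ya == yb:
            # mixed precision: all components present on both sides agree
            if all(x == y for x, y in ((ma, mb), (da, db)) if x and y):
                return Outcome.PARTIAL
        diffs = (ya != yb) + (ma != mb) + (da != db)
        if diffs == 1:
            return Outcome.PARTIAL  # single-component error
        return Outcome.DISAGREE
    if kind == "numeric":
        try:
            diff = abs(float(val_a) - float(val_b))
        except (TypeError, ValueError):
            return Outcome.DISAGREE
        if diff <= function.tolerance:
            return Outcome.AGREE
        if function.partial_tolerance is not None and diff <= function.partial_tolerance:
            return Outcome.PARTIAL
        return Outcome.DISAGREE
    if kind == "location":
        a, b = str(val_a), str(val_b)
        if function.level == "phonetic":
            return Outcome.AGREE if soundex(a) == soundex(b) else Outcome.DISAGREE
        if a == b:
            return Outcome.AGREE
        if soundex(a) == soundex(b):
            return Outcome.PARTIAL
        return Outcome.DISAGREE
    raise StrategyError(f"unknown field kind: {kind}")


# ---------------------------------------------------------------------------
# weights


@dataclass(frozen=True)
class FieldWeights:
    field: str
    m: float
    u: float
    partial_discount: float = 0.5
    frequency_mode: str = "none"  # none | record | chain
    conditioning_field: Optional[str] = None

    def validate(self) -> list[str]:
        errs = []
        if not (0 < self.m < 1 and 0 < self.u < 1):
            errs.append(f"{self.field}: m and u must lie in (0, 1)")
        elif self.m <= self.u:
            errs.append(f"{self.field}: m must exceed u (informative field)")
        if not (0 <= self.partial_discount <= 1):
            errs.append(f"{self.field}: partial_discount outside [0, 1]")
        if self.frequency_mode not in ("none", "record", "chain"):
            errs.append(f"{self.field}: unknown frequency mode {self.frequency_mode!r}")
        return errs


def field_weight(
    outcome: Outcome,
    weights: FieldWeights,
    value_freq: Optional[float] = None,
    freq_floor: float = 1e-6,
) -> float:
    """Log2 likelihood-ratio weight for one field outcome."""
    if outcome == Outcome.MISSING:
        return 0.0
    if weights.frequency_mode != "none" and value_freq is not None:
        u_eff = min(1.0, max(value_freq, freq_floor))
    else:
        u_eff = weights.u
    agree_w = math.log2(weights.m / u_eff)
    if outcome == Outcome.AGREE:
        return agree_w
    if outcome == Outcome.PARTIAL:
        return weights.partial_discount * agree_w
    if u_eff >= 1.0:
        u_eff = 1.0 - 1e-12
    return math.log2((1.0 - weights.m) / (1.0 - u_eff))


# ---------------------------------------------------------------------------
# frequency tables


@dataclass
class FrequencyTable:
    """Relative value frequencies for one field, optionally conditional.

    ``tables`` maps a conditioning value (or None for the unconditional
    table) to {value: relative frequency}; each table sums to 1 over the
    values observed among its counting units.  ``floor`` is the default
    clamp applied to unseen / vanishing frequencies: 1 / (2 x number of
    counting units), which also bounds the weight of singleton values.
    """

    field: str
    mode: str
    conditioning_field: Optional[str]
    tables: dict
    floor: float

    def lookup(self, value, conditioning_value=None) -> float:
        table = self.tables.get(conditioning_value)
        if table is None:
            table = self.tables.get(None, {})
        return max(table.get(value, 0.0), self.floor)


def compute_frequencies(
    store,
    field_name: str,
    mode: str = "record",
    conditioning_field: Optional[str] = None,
) -> FrequencyTable:
    """Tabulate value frequencies over the demographic store.

    record mode: each non-deleted record with a non-missing value counts
    once.  chain mode: each active chain counts once per distinct value it
    contains, so duplicating every record of a chain changes nothing — the
    adjustment the engine relies on for event-based data.  With a
    conditioning field, separate tables are kept per conditioning value
    (units whose conditioning value is missing feed the unconditional
    fallback only).
    """
    if conditioning_field is not None:
        known = set()
        for p in store.profiles.values():
            known.update(fs.name for fs in p.field_specs)
            for fs in p.field_specs:
                known.update(d.name for d in fs.derived_outputs)
        if store.profiles and conditioning_field not in known:
            raise StrategyError(f"conditioning field not in any profile: {conditioning_field}")

    counts: dict = {None: {}}
    n_units: dict = {None: 0}

    def bump(cond, value):
        counts.setdefault(cond, {})
        n_units.setdefault(cond, 0)
        counts[cond][value] = counts[cond].get(value, 0) + 1
        n_units[cond] += 1

    if mode == "record":
        for rec in store.live_records():
            v = rec.get(field_name)
            if v is MISSING:
                continue
            bump(None, v)
            if conditioning_field is not None:
                cv = rec.get(conditioning_field)
                if cv is not MISSING:
                    bump(cv, v)
    elif mode == "chain":
        for chain in store.active_chains():
            members = [store.records[r] for r in chain.member_record_ids if r not in store.deleted]
            values = {rec.get(field_name) for rec in members} - {MISSING}
            conds = {rec.get(conditioning_field) for rec in members} - {MISSING} if conditioning_field else set()
            for v in sorted(values):
                bump(None, v)
                for cv in sorted(conds):
                    bump(cv, v)
    else:
        raise StrategyError(f"unknown frequency mode: {mode}")

    tables = {
        cond: {v: c / n_units[cond] for v, c in table.items()}
        for cond, table in counts.items()
        if n_units[cond] > 0
    }
    total_units = n_units[None]
    floor = 1.0 / (2.0 * total_units) if total_units else 1e-6
    return FrequencyTable(field_name, mode, conditioning_field, tables, floor)


# ---------------------------------------------------------------------------
# match conditions (pair-exclusion predicates)


@dataclass(frozen=True)
class MatchCondition:
    """Boolean exclusion predicate evaluated before scoring.

    kinds:
      date_after  — exclude when ``later_field`` on either record post-dates
                    ``earlier_field`` on the other (e.g. an event recorded
                    after the person's death date).
      fields_differ — exclude when both records carry the field non-missing
                    with unequal values (e.g. restrict a strategy to
                    same-sex pairs).
    """

    condition_id: str
    kind: str
    field_a: str = ""
    field_b: str = ""

    def excludes(self, rec_a: StandardisedRecord, rec_b: StandardisedRecord) -> bool:
        if self.kind == "date_after":
            for r1, r2 in ((rec_a, rec_b), (rec_b, rec_a)):
                later = r1.get(self.field_a)
                earlier = r2.get(self.field_b)
                if later is not MISSING and earlier is not MISSING and str(later) > str(earlier):
                    return True
            return False
        if self.kind == "fields_differ":
            va, vb = rec_a.get(self.field_a), rec_b.get(self.field_a)
            return va is not MISSING and vb is not MISSING and va != vb
        raise StrategyError(f"unknown condition kind: {self.kind}")


# ---------------------------------------------------------------------------
# strategy


@dataclass(frozen=True)
class StrategyField:
    field: str
    function: MatchFunction
    weights: FieldWeights


@dataclass(frozen=True)
class LinkageStrategy:
    strategy_id: str
    scope: tuple = ("*", "*")
    blocking: tuple = ()  # BlockingScheme refs (prep module objects)
    fields: tuple[StrategyField, ...] = ()
    conditions: tuple[MatchCondition, ...] = ()
    lower: float = 0.0
    upper: float = 0.0
    cardinality: str = "none"  # none | 1:1 | 1:N | N:1
    version: int = 1

    def validate(self) -> list[str]:
        errs = []
        if self.lower > self.upper:
            errs.append(f"{self.strategy_id}: lower threshold exceeds upper")
        if self.cardinality not in ("none", "1:1", "1:N", "N:1"):
            errs.append(f"{self.strategy_id}: unknown cardinality {self.cardinality!r}")
        if not self.fields:
            errs.append(f"{self.strategy_id}: no comparison fields")
        for sf in self.fields:
            errs.extend(sf.function.validate())
            errs.extend(sf.weights.validate())
        if self.version < 1:
            errs.append(f"{self.strategy_id}: version must be >= 1")
        return errs


@dataclass
class WeightedPair:
    """A scored candidate pair; the unit the resolution service classifies."""

    record_id_a: str
    record_id_b: str
    strategy_id: str
    run_id: str
    weight: float = 0.0
    outcomes: dict = field(default_factory=dict)  # field -> (outcome, weight)
    excluded_by: Optional[str] = None
    classification: Optional[str] = None
    qa_flags: set = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return self.excluded_by is not None

    def to_dict(self) -> dict:
        return {
            "record_id_a": self.record_id_a,
            "record_id_b": self.record_id_b,
            "strategy_id": self.strategy_id,
            "run_id": self.run_id,
            "weight": self.weight,
            "outcomes": {k: list(v) for k, v in self.outcomes.items()},
            "excluded_by": self.excluded_by,
            "classification": self.classification,
            "qa_flags": sorted(self.qa_flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightedPair":
        pair = cls(
            d["record_id_a"], d["record_id_b"], d["strategy_id"], d["run_id"],
            d.get("weight", 0.0),
        )
        pair.outcomes = {k: tuple(v) for k, v in d.get("outcomes", {}).items()}
        pair.excluded_by = d.get("excluded_by")
        pair.classification = d.get("classification")
        pair.qa_flags = set(d.get("qa_flags", []))
        return pair


def build_frequency_tables(store, strategy: LinkageStrategy) -> dict:
    """Precompute the frequency tables a strategy's fields require."""
    tables = {}
    for sf in strategy.fields:
        if sf.weights.frequency_mode != "none":
            tables[sf.field] = compute_frequencies(
                store, sf.field, sf.weights.frequency_mode, sf.weights.conditioning_field
            )
    return tables


def score_pair(
    rec_a: StandardisedRecord,
    rec_b: StandardisedRecord,
    strategy: LinkageStrategy,
    freq_tables: Optional[dict] = None,
    run_id: str = "adhoc",
) -> WeightedPair:
    """Score one candidate pair under a strategy.

    Match conditions run first; an excluded pair carries the excluding
    condition id and no weight.  Otherwise the overall weight is the exact
    sum of the retained field-wise weights (additivity), and the result is
    symmetric in the two records.
    """
    a, b = (rec_a, rec_b) if rec_a.record_id <= rec_b.record_id else (rec_b, rec_a)
    pair = WeightedPair(a.record_id, b.record_id, strategy.strategy_id, run_id)
    for cond in strategy.conditions:
        if cond.excludes(a, b):
            pair.excluded_by = cond.condition_id
            pair.classification = "excluded"
            return pair
    freq_tables = freq_tables or {}
    total = 0.0
    for sf in strategy.fields:
        va, vb = a.get(sf.field), b.get(sf.field)
        outcome = compare_fields(va, vb, sf.function)
        value_freq = None
        floor = 1e-6
        if sf.weights.frequency_mode != "none" and sf.field in freq_tables:
            table = freq_tables[sf.field]
            floor = table.floor
            if outcome in (Outcome.AGREE, Outcome.PARTIAL):
                cond_val = None
                if sf.weights.conditioning_field:
                    ca = a.get(sf.weights.conditioning_field)
                    cb = b.get(sf.weights.conditioning_field)
                    if ca is not MISSING and ca == cb:
                        cond_val = ca
                # conservative: the commoner of the two values sets u_eff
                value_freq = max(table.lookup(va, cond_val), table.lookup(vb, cond_val))
            else:
                value_freq = None  # disagreement weight uses baseline u
        w = field_weight(outcome, sf.weights, value_freq, floor)
        pair.outcomes[sf.field] = (outcome.value, w)
        total += w
    pair.weight = total
    return pair


class PairScorer:
    """Streaming scorer with per-field value-pair memoisation.

    Linkage runs compare the same (value_a, value_b) combination across many
    record pairs, so each field keeps a cache keyed by the canonical value
    pair (plus the conditioning value where conditional frequencies apply).
    Produces results identical to :func:`score_pair`; the caching is purely
    an evaluation-order optimisation.
    """

    def __init__(self, strategy: LinkageStrategy, freq_tables: Optional[dict] = None):
        errs = strategy.validate()
        if errs:
            raise StrategyError("; ".join(errs))
        self.strategy = strategy
        self.freq_tables = freq_tables or {}
        self._caches: list[dict] = [dict() for _ in strategy.fields]

    def _field_result(self, idx: int, sf: StrategyField, va, vb, cond_val):
        key = (va, vb, cond_val) if va <= vb else (vb, va, cond_val)
        cache = self._caches[idx]
        hit = cache.get(key)
        if hit is not None:
            return hit
        outcome = compare_fields(va, vb, sf.function)
        value_freq = None
        floor = 1e-6
        table = self.freq_tables.get(sf.field)
        if sf.weights.frequency_mode != "none" and table is not None:
            floor = table.floor
            if outcome in (Outcome.AGREE, Outcome.PARTIAL):
                value_freq = max(table.lookup(va, cond_val), table.lookup(vb, cond_val))
        w = field_weight(outcome, sf.weights, value_freq, floor)
        result = (outcome.value, w)
        cache[key] = result
        return result

    def score(
        self,
        rec_a: StandardisedRecord,
        rec_b: StandardisedRecord,
        run_id: str = "adhoc",
    ) -> WeightedPair:
        a, b = (rec_a, rec_b) if rec_a.record_id <= rec_b.record_id else (rec_b, rec_a)
        pair = WeightedPair(a.record_id, b.record_id, self.strategy.strategy_id, run_id)
        for cond in self.strategy.conditions:
            if cond.excludes(a, b):
                pair.excluded_by = cond.condition_id
                pair.classification = "excluded"
                return pair
        total = 0.0
        for idx, sf in enumerate(self.strategy.fields):
            va, vb = a.get(sf.field), b.get(sf.field)
            if va is MISSING or vb is MISSING:
                pair.outcomes[sf.field] = (Outcome.MISSING.value, 0.0)
                continue
            cond_val = None
            if sf.weights.frequency_mode != "none" and sf.weights.conditioning_field:
                ca = a.get(sf.weights.conditioning_field)
                cb = b.get(sf.weights.conditioning_field)
                if ca is not MISSING and ca == cb:
                    cond_val = ca
            result = self._field_result(idx, sf, str(va), str(vb), cond_val)
            pair.outcomes[sf.field] = result
            total += result[1]
        pair.weight = total
        return pair


# ---------------------------------------------------------------------------
# declarative strategy files


def strategy_from_dict(cfg: dict, blocking_lookup=None) -> LinkageStrategy:
    fields = []
    for f in cfg["fields"]:
        fn = f.get("function", {})
        func = MatchFunction(
            function_id=fn.get("id", f"{f['name']}_fn"),
            field_kind=fn.get("kind", "string"),
            agree_threshold=fn.get("agree_threshold", 0.92),
            partial_threshold=fn.get("partial_threshold", 0.80),
            allow_transposition=fn.get("allow_transposition", True),
            tolerance=fn.get("tolerance", 0.0),
            partial_tolerance=fn.get("partial_tolerance"),
            level=fn.get("level", "exact"),
        )
        w = f["weights"]
        weights = FieldWeights(
            field=f["name"],
            m=w["m"],
            u=w["u"],
            partial_discount=w.get("partial_discount", 0.5),
            frequency_mode=w.get("frequency_mode", "none"),
            conditioning_field=w.get("conditioning_field"),
        )
        fields.append(StrategyField(f["name"], func, weights))
    conditions = tuple(
        MatchCondition(c["id"], c["kind"], c.get("field_a", ""), c.get("field_b", ""))
        for c in cfg.get("conditions", [])
    )
    blocking = tuple(
        blocking_lookup[name] for name in cfg.get("blocking", [])
    ) if blocking_lookup else ()
    return LinkageStrategy(
        strategy_id=cfg["strategy_id"],
        scope=tuple(cfg.get("scope", ("*", "*"))),
        blocking=blocking,
        fields=tuple(fields),
        conditions=conditions,
        lower=float(cfg["thresholds"]["lower"]),
        upper=float(cfg["thresholds"]["upper"]),
        cardinality=cfg.get("cardinality", "none"),
        version=int(cfg.get("version", 1)),
    )


def strategy_from_yaml(path, blocking_lookup=None) -> LinkageStrategy:
    import yaml

    with open(path) as fh:
        return strategy_from_dict(yaml.safe_load(fh), blocking_lookup)
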