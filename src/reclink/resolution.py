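"""Resolution: classify weighted pairs, QA-check them, apply cardinality
restrictions, and turn accepted matches into links with immediate merges.

All strategies of a run are pooled before any link is created (the
concurrency contract), so a high-weight link found by one strategy can
never be pre-empted by a lower-weight link from another — the classic
failure mode of strictly sequential linkage passes.  Accepted matches are
processed in descending weight order and each one merges its chains before
the next pair is looked at (the immediacy contract); pairs whose records
already share a chain by then are recorded as redundant rather than
re-linked.

Cardinality restrictions (1:1, 1:N, N:1) are enforced at chain level, not
record level, by a greedy sweep in descending weight; displaced candidates
are demoted to the clerical-review queue rather than discarded, and ties in
weight that contend for the same quota send every tied contender to review
instead of accepting one arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .matching import LinkageStrategy, WeightedPair
from .profiles import MISSING


# ---------------------------------------------------------------------------
# classification


def classify(pair: WeightedPair, strategy: LinkageStrategy) -> str:
    """Threshold classification: match / potential / non-match."""
    if pair.excluded:
        return "excluded"
    if pair.weight >= strategy.upper:
        return "match"
    if pair.weight >= strategy.lower:
        return "potential"
    return "non-match"


# ---------------------------------------------------------------------------
# QA checks (the Checking service)


@dataclass(frozen=True)
class QACheck:
    """Deterministic predicate over a pair and its two chains.

    ``predicate(pair, rec_a, rec_b, chain_records_a, chain_records_b)``
    returns True when the check fires.  ``demote_to_potential`` overrides a
    would-be automatic match down to clerical review; ``block_link`` forces
    non-match.
    """

    check_id: str
    predicate: Callable
    action: str  # demote_to_potential | block_link


def _chain_values(chain_records, field_name):
    return {r.get(field_name) for r in chain_records} - {MISSING}


def _sex_mismatch(pair, rec_a, rec_b, chain_a, chain_b):
    sa, sb = _chain_values(chain_a, "sex"), _chain_values(chain_b, "sex")
    return bool(sa and sb and sa.isdisjoint(sb))


def _death_before_event(pair, rec_a, rec_b, chain_a, chain_b):
    for one, other in ((chain_a, chain_b), (chain_b, chain_a)):
        deaths = _chain_values(one, "death_date")
        events = _chain_values(other, "event_date")
        if deaths and events and min(deaths) < max(events):
            return True
    return False


def _years(values):
    out = set()
    for v in values:
        s = str(v)[:4]
        if s.isdigit():
            out.add(int(s))
    return out


def _implausible_age_gap(pair, rec_a, rec_b, chain_a, chain_b):
    ya, yb = _years(_chain_values(chain_a, "dob")), _years(_chain_values(chain_b, "dob"))
    if not ya or not yb:
        return False
    return min(abs(a - b) for a in ya for b in yb) > 115


def _dates_compatible(da: str, db: str) -> bool:
    if da == db:
        return True
    pa = (str(da).split("-") + ["", ""])[:3]
    pb = (str(db).split("-") + ["", ""])[:3]
    # day/month transposition is a plausible entry error, not a conflict
    return pa[0] == pb[0] and pa[1] == pb[2] and pa[2] == pb[1] and pa[1] != pa[2]


def _dob_conflict(pair, rec_a, rec_b, chain_a, chain_b):
    """No pair of known birth dates across the two chains is compatible.

    A chain accumulates the birth-date evidence of all its records, so a
    high-weight pair whose chains hold irreconcilable dates (not equal, not
    a day/month swap) is suspicious however well the names agree.
    """
    da = _chain_values(chain_a, "dob")
    db = _chain_values(chain_b, "dob")
    if not da or not db:
        return False
    return not any(_dates_compatible(x, y) for x in da for y in db)


def make_intermediate_weight_check(margin: float = 2.0) -> QACheck:
    """Flag matches sitting within ``margin`` above the upper threshold.

    These carry an intermediate weight: strong enough to clear the automatic
    cutoff but close enough to warrant clerical review, so they are demoted.
    The strategy's upper threshold is read off the pair via the strategy
    registry at run time (the predicate receives it through the pair's
    ``_upper`` attribute set by :func:`run_checks`).
    """

    def pred(pair, rec_a, rec_b, chain_a, chain_b):
        upper = getattr(pair, "_upper", None)
        return upper is not None and pair.weight < upper + margin

    return QACheck("intermediate_weight", pred, "demote_to_potential")


def default_checks(intermediate_margin: Optional[float] = None) -> list[QACheck]:
    checks = [
        QACheck("sex_mismatch", _sex_mismatch, "demote_to_potential"),
        QACheck("death_before_event", _death_before_event, "block_link"),
        QACheck("implausible_age_gap", _implausible_age_gap, "demote_to_potential"),
        QACheck("dob_conflict", _dob_conflict, "demote_to_potential"),
    ]
    if intermediate_margin is not None:
        checks.append(make_intermediate_weight_check(intermediate_margin))
    return checks


def run_checks(
    pair: WeightedPair,
    store,
    checks: Iterable[QACheck],
    classification: str,
    upper: Optional[float] = None,
) -> tuple[set, str]:
    """Evaluate QA checks; returns (flags, effective classification).

    Checks only ever weaken a classification: a demotion turns a match into
    a potential, a block forces non-match with the blocking check recorded.
    """
    rec_a = store.records[pair.record_id_a]
    rec_b = store.records[pair.record_id_b]
    chain_a = [store.records[r] for r in store.chains[store.chain_of(pair.record_id_a)].member_record_ids]
    chain_b = [store.records[r] for r in store.chains[store.chain_of(pair.record_id_b)].member_record_ids]
    pair._upper = upper
    flags = set()
    effective = classification
    for check in checks:
        if check.predicate(pair, rec_a, rec_b, chain_a, chain_b):
            flags.add(check.check_id)
            if check.action == "block_link":
                effective = "non-match"
            elif check.action == "demote_to_potential" and effective == "match":
                effective = "potential"
    pair.qa_flags |= flags
    return flags, effective


# ---------------------------------------------------------------------------
# cardinality


def apply_cardinality(
    candidates: list[WeightedPair],
    mode: str,
    chain_of: Callable[[str], int],
) -> tuple[list[WeightedPair], list[WeightedPair]]:
    """Greedy chain-level cardinality restriction.

    Candidates are swept in descending weight.  Under 1:1 each chain on
    either side may appear in one retained candidate; 1:N constrains the
    right side only, N:1 the left.  Equal-weight candidates contending for
    the same quota are all demoted to review.  Returns (retained, demoted).
    """
    if mode == "none":
        return list(candidates), []
    if mode not in ("1:1", "1:N", "N:1"):
        raise ValueError(f"unknown cardinality mode: {mode}")
    constrain_left = mode in ("1:1", "N:1")
    constrain_right = mode in ("1:1", "1:N")
    retained: list[WeightedPair] = []
    demoted: list[WeightedPair] = []
    used_left: set[int] = set()
    used_right: set[int] = set()

    def sides(p):
        return chain_of(p.record_id_a), chain_of(p.record_id_b)

    ordered = sorted(candidates, key=lambda p: (-p.weight, p.record_id_a, p.record_id_b))
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j].weight == ordered[i].weight:
            j += 1
        group = ordered[i:j]
        # within an equal-weight group, find quota contention
        feasible = []
        for p in group:
            la, rb = sides(p)
            if (constrain_left and la in used_left) or (constrain_right and rb in used_right):
                demoted.append(p)
            else:
                feasible.append(p)
        left_claims: dict[int, int] = {}
        right_claims: dict[int, int] = {}
        for p in feasible:
            la, rb = sides(p)
            left_claims[la] = left_claims.get(la, 0) + 1
            right_claims[rb] = right_claims.get(rb, 0) + 1
        for p in feasible:
            la, rb = sides(p)
            contended = (constrain_left and left_claims[la] > 1) or (
                constrain_right and right_claims[rb] > 1
            )
            if contended:
                demoted.append(p)  # tie rule: review arbitrates
            else:
                retained.append(p)
                if constrain_left:
                    used_left.add(la)
                if constrain_right:
                    used_right.add(rb)
        i = j
    return retained, demoted


# ---------------------------------------------------------------------------
# run resolution


@dataclass
class RunReport:
    run_id: str
    links_created: int = 0
    redundant: int = 0
    potential: int = 0
    non_match: int = 0
    excluded: int = 0
    demoted: int = 0
    potentials: list = field(default_factory=list)  # WeightedPairs for review

    @property
    def dispositions(self) -> dict:
        return {
            "link-created": self.links_created,
            "redundant-within-chain": self.redundant,
            "potential": self.potential,
            "non-match": self.non_match,
            "excluded": self.excluded,
            "demoted": self.demoted,
        }


def _strictest_mode(modes: Iterable[str]) -> str:
    modes = set(modes)
    if "1:1" in modes:
        return "1:1"
    one_sided = modes & {"1:N", "N:1"}
    if len(one_sided) == 2:
        return "1:1"  # both sides constrained by different strategies
    if one_sided:
        return one_sided.pop()
    return "none"


def resolve_run(
    store,
    scored_pairs: Iterable[WeightedPair],
    strategies: list[LinkageStrategy],
    run_id: str,
    checks: Optional[list[QACheck]] = None,
    intermediate_margin: Optional[float] = None,
) -> RunReport:
    """Resolve one run's pooled scored pairs into links and potentials.

    The pairs of *all* strategies in the run must be present (pooled) before
    resolution starts.  Processing order is weight-descending with strategy
    declared order, then canonical pair order, breaking ties.  Every scored
    pair ends in exactly one disposition bucket.
    """
    checks = list(checks) if checks is not None else []
    if intermediate_margin is not None:
        checks.append(make_intermediate_weight_check(intermediate_margin))
    strat_by_id = {s.strategy_id: s for s in strategies}
    priority = {s.strategy_id: i for i, s in enumerate(strategies)}
    report = RunReport(run_id)

    matches: list[WeightedPair] = []
    for pair in scored_pairs:
        if pair.excluded:
            pair.classification = "excluded"
            report.excluded += 1
            continue
        strategy = strat_by_id[pair.strategy_id]
        cls = classify(pair, strategy)
        if cls == "potential" and checks:
            # annotate potentials with QA flags for review display; a
            # blocking check downgrades them to non-match outright
            _, cls = run_checks(pair, store, checks, cls, upper=strategy.upper)
        pair.classification = cls
        if cls == "match":
            matches.append(pair)
        elif cls == "potential":
            report.potential += 1
            report.potentials.append(pair)
        else:
            report.non_match += 1

    # chain-level cardinality per dataset-scope pair, strictest declared mode
    def scope_of(pair):
        ds_a = store.records[pair.record_id_a].dataset_id
        ds_b = store.records[pair.record_id_b].dataset_id
        return tuple(sorted((ds_a, ds_b)))

    modes_by_scope: dict = {}
    for s in strategies:
        key = tuple(sorted(s.scope))
        modes_by_scope.setdefault(key, set()).add(s.cardinality)
    retained: list[WeightedPair] = []
    groups: dict = {}
    for pair in matches:
        groups.setdefault(scope_of(pair), []).append(pair)
    for scope, group in groups.items():
        declared = set()
        for skey, modes in modes_by_scope.items():
            if skey == scope or "*" in skey:
                declared |= modes
        mode = _strictest_mode(declared or {"none"})
        kept, demoted = apply_cardinality(group, mode, store.chain_of)
        retained.extend(kept)
        for p in demoted:
            p.classification = "demoted"
            report.demoted += 1
            report.potentials.append(p)

    # weight-descending immediate link creation; merges visible at once
    retained.sort(
        key=lambda p: (-p.weight, priority.get(p.strategy_id, 0), p.record_id_a, p.record_id_b)
    )
    for pair in retained:
        ca = store.chain_of(pair.record_id_a)
        cb = store.chain_of(pair.record_id_b)
        if ca == cb:
            pair.classification = "redundant"
            report.redundant += 1
            store.record_event(
                "link_change",
                {
                    "action": "resolved_by_prior_link",
                    "record_id_a": pair.record_id_a,
                    "record_id_b": pair.record_id_b,
                    "run_id": run_id,
                },
            )
            continue
        if checks:
            # QA runs against the chains as they stand *now*: earlier merges
            # in this run contribute their evidence before this link lands
            _, effective = run_checks(
                pair, store, checks, "match", upper=strat_by_id[pair.strategy_id].upper
            )
            if effective == "potential":
                pair.classification = "demoted"
                report.demoted += 1
                report.potentials.append(pair)
                continue
            if effective == "non-match":
                pair.classification = "non-match"
                report.non_match += 1
                continue
        store.create_link(
            pair.record_id_a,
            pair.record_id_b,
            pair.weight,
            origin="automatic",
            strategy_id=pair.strategy_id,
            run_id=run_id,
        )
        pair.classification = "link-created"
        report.links_created += 1

    # persist the review feed so a queue can be built in a later session
    store.pending_potentials = [p.to_dict() for p in report.potentials]
    store.record_event(
        "run_record",
        {
            "run_id": run_id,
            "strategies": [
                {
                    "strategy_id": s.strategy_id,
                    "version": s.version,
                    "lower": s.lower,
                    "upper": s.upper,
                    "cardinality": s.cardinality,
                    "fields": [
                        {"field": sf.field, "m": sf.weights.m, "u": sf.weights.u,
                         "frequency_mode": sf.weights.frequency_mode}
                        for sf in s.fields
                    ],
                }
                for s in strategies
            ],
            "dispositions": report.dispositions,
        },
    )
    return report
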