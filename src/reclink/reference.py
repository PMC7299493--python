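"""Naive reference scorer: brute-force all-pairs weights from first principles.

This module exists for validation.  It ignores the engine's blocking,
streaming and caching machinery entirely: every in-scope record pair is
enumerated directly and its weight recomputed with inline arithmetic
(explicit log2 likelihood ratios, direct frequency counting).  The engine's
scored-pair set on a store with exhaustive blocking must coincide with this
scorer's output pair-for-pair and weight-for-weight.

Deliberately slow and simple; only ever run on small stores.
"""

from __future__ import annotations

import math
from itertools import combinations

from ._text import jaro_winkler, soundex
from .matching import LinkageStrategy, Outcome
from .profiles import MISSING


def _naive_outcome(va, vb, function) -> str:
    if va is MISSING or vb is MISSING:
        return "missing"
    kind = function.field_kind
    va, vb = str(va), str(vb)
    if kind == "string":
        sim = jaro_winkler(va, vb)  # uncached on purpose
        if sim >= function.agree_threshold:
            return "agree"
        if sim >= function.partial_threshold:
            return "partial"
        return "disagree"
    if kind == "date":
        if va == vb:
            return "agree"
        pa = (va.split("-") + ["", "", ""])[:3]
        pb = (vb.split("-") + ["", "", ""])[:3]
        if (
            function.allow_transposition
            and pa[0] == pb[0]
            and pa[1] == pb[2]
            and pa[2] == pb[1]
            and pa[1] != pa[2]
        ):
            return "partial"
        if "" in (pa[1], pa[2], pb[1], pb[2]) and pa[0] == pb[0]:
            if all(x == y for x, y in ((pa[1], pb[1]), (pa[2], pb[2])) if x and y):
                return "partial"
        if sum(x != y for x, y in zip(pa, pb)) == 1:
            return "partial"
        return "disagree"
    if kind == "numeric":
        diff = abs(float(va) - float(vb))
        if diff <= function.tolerance:
            return "agree"
        if function.partial_tolerance is not None and diff <= function.partial_tolerance:
            return "partial"
        return "disagree"
    if kind == "location":
        if function.level == "phonetic":
            return "agree" if soundex(va) == soundex(vb) else "disagree"
        if va == vb:
            return "agree"
        return "partial" if soundex(va) == soundex(vb) else "disagree"
    raise ValueError(kind)


def _naive_frequencies(store, field_name, mode, conditioning_field):
    """Direct tally of value shares; returns ({cond: {value: freq}}, floor)."""
    units = []
    if mode == "record":
        for rec in store.live_records():
            units.append(([rec.get(field_name)], [rec.get(conditioning_field)] if conditioning_field else []))
    else:
        for chain in store.active_chains():
            recs = [store.records[r] for r in chain.member_record_ids if r not in store.deleted]
            vals = sorted({rec.get(field_name) for rec in recs} - {MISSING})
            conds = sorted({rec.get(conditioning_field) for rec in recs} - {MISSING}) if conditioning_field else []
            for v in vals:
                units.append(([v], conds))
    tables: dict = {None: {}}
    n: dict = {None: 0}
    for values, conds in units:
        for v in values:
            if v is MISSING:
                continue
            tables[None][v] = tables[None].get(v, 0) + 1
            n[None] += 1
            for cv in conds:
                tables.setdefault(cv, {})
                n.setdefault(cv, 0)
                tables[cv][v] = tables[cv].get(v, 0) + 1
                n[cv] += 1
    out = {
        cond: {v: c / n[cond] for v, c in t.items()} for cond, t in tables.items() if n.get(cond)
    }
    floor = 1.0 / (2.0 * n[None]) if n[None] else 1e-6
    return out, floor


def brute_force_scores(store, strategy: LinkageStrategy) -> dict:
    """All-pairs scored weights: {(record_id_a, record_id_b): weight}.

    Excluded pairs map to None.  Pair keys are in canonical (smaller,
    larger) order; scope selectors are honoured.
    """
    freq = {}
    for sf in strategy.fields:
        if sf.weights.frequency_mode != "none":
            freq[sf.field] = _naive_frequencies(
                store, sf.field, sf.weights.frequency_mode, sf.weights.conditioning_field
            )
    sa, sb = strategy.scope

    def in_scope(da, db):
        def ok(x, sel):
            return sel == "*" or x == sel

        return (ok(da, sa) and ok(db, sb)) or (ok(db, sa) and ok(da, sb))

    results = {}
    records = sorted(store.live_records(), key=lambda r: r.record_id)
    for ra, rb in combinations(records, 2):
        if not in_scope(ra.dataset_id, rb.dataset_id):
            continue
        excluded = False
        for cond in strategy.conditions:
            if cond.excludes(ra, rb):
                excluded = True
                break
        if excluded:
            results[(ra.record_id, rb.record_id)] = None
            continue
        total = 0.0
        for sf in strategy.fields:
            va, vb = ra.get(sf.field), rb.get(sf.field)
            outcome = _naive_outcome(va, vb, sf.function)
            if outcome == "missing":
                continue
            m, u = sf.weights.m, sf.weights.u
            if sf.field in freq:
                tables, floor = freq[sf.field]
                if outcome in ("agree", "partial"):
                    cond_val = None
                    if sf.weights.conditioning_field:
                        ca = ra.get(sf.weights.conditioning_field)
                        cb = rb.get(sf.weights.conditioning_field)
                        if ca is not MISSING and ca == cb and ca in tables:
                            cond_val = ca
                    table = tables.get(cond_val, tables[None])
                    fa = max(table.get(str(va), 0.0), floor)
                    fb = max(table.get(str(vb), 0.0), floor)
                    u = min(1.0, max(fa, fb))
            if outcome == "agree":
                total += math.log2(m / u)
            elif outcome == "partial":
                total += sf.weights.partial_discount * math.log2(m / u)
            else:
                total += math.log2((1 - m) / (1 - u))
        results[(ra.record_id, rb.record_id)] = total
    return results
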