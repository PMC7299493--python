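"""Linkage preparation: subset blocking over the demographic store.

A blocking scheme is a union of key definitions; each key is an ordered list
of (field, transform) pairs.  Two records become a candidate pair iff they
agree on every transformed value of at least one key.  Records missing any
field of a key drop out of that key (the union of keys recovers recall);
deleted records never block.  Each unordered pair is emitted exactly once
even when several keys produce it, in canonical (smaller id, larger id)
orientation.

The ``constant`` transform makes a key that puts every in-scope record in
one block — exhaustive all-pairs comparison, the oracle mode used by the
test harness.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Optional

from ._text import soundex
from .profiles import MISSING

TRANSFORMS = ("identity", "phonetic", "first_k_chars", "year_of", "constant")


class BlockingError(Exception):
    pass


@dataclass(frozen=True)
class KeyPart:
    field: str
    transform: str = "identity"
    k: int = 4  # for first_k_chars


@dataclass(frozen=True)
class BlockKey:
    parts: tuple[KeyPart, ...]

    def __post_init__(self):
        object.__setattr__(self, "parts", tuple(self.parts))


@dataclass(frozen=True)
class BlockingScheme:
    scheme_id: str
    keys: tuple[BlockKey, ...]
    scope: tuple = ("*", "*")  # dataset selectors; "*" matches any dataset
    block_ceiling: int = 10_000  # pairs per block before the overflow flag

    def __post_init__(self):
        object.__setattr__(self, "keys", tuple(self.keys))


def exhaustive_scheme(scope=("*", "*"), scheme_id: str = "exhaustive") -> BlockingScheme:
    """All cross pairs in scope: a single constant key."""
    return BlockingScheme(scheme_id, (BlockKey((KeyPart("", "constant"),)),), scope)


def _transform_value(record, part: KeyPart):
    if part.transform == "constant":
        return ""
    v = record.get(part.field)
    if v is MISSING:
        return MISSING
    v = str(v)
    if part.transform == "identity":
        return v
    if part.transform == "phonetic":
        code = soundex(v)
        return code if code else MISSING
    if part.transform == "first_k_chars":
        return v[: part.k]
    if part.transform == "year_of":
        return v[:4] if len(v) >= 4 and v[:4].isdigit() else MISSING
    raise BlockingError(f"unknown transform: {part.transform}")


def key_value(record, key: BlockKey):
    """Transformed key tuple for one record, or MISSING if any part is missing."""
    out = []
    for part in key.parts:
        v = _transform_value(record, part)
        if v is MISSING:
            return MISSING
        out.append(v)
    return tuple(out)


def validate_scheme(scheme: BlockingScheme, store) -> list[str]:
    errs = []
    if not scheme.keys:
        errs.append(f"{scheme.scheme_id}: scheme needs at least one key definition")
    known: set[str] = set()
    for p in store.profiles.values():
        known.update(fs.name for fs in p.field_specs)
        for fs in p.field_specs:
            known.update(d.name for d in fs.derived_outputs)
    for key in scheme.keys:
        for part in key.parts:
            if part.transform not in TRANSFORMS:
                errs.append(f"{scheme.scheme_id}: unknown transform {part.transform!r}")
            if part.transform != "constant" and store.profiles and part.field not in known:
                errs.append(f"{scheme.scheme_id}: unknown field {part.field!r}")
    return errs


def _scope_matches(ds_a: str, ds_b: str, scope: tuple) -> bool:
    sa, sb = scope

    def ok(x, sel):
        return sel == "*" or x == sel

    return (ok(ds_a, sa) and ok(ds_b, sb)) or (ok(ds_b, sa) and ok(ds_a, sb))


def build_blocks(store, scheme: BlockingScheme) -> Iterator[tuple[str, str]]:
    """Stream candidate pairs; each unordered pair exactly once."""
    errs = validate_scheme(scheme, store)
    if errs:
        raise BlockingError("; ".join(errs))
    records = store.live_records()
    in_scope = [
        r
        for r in records
        if scheme.scope == ("*", "*")
        or r.dataset_id in scheme.scope
        or "*" in scheme.scope
    ]
    seen: set[tuple[str, str]] = set()
    for key in scheme.keys:
        blocks: dict = {}
        for rec in in_scope:
            kv = key_value(rec, key)
            if kv is MISSING:
                continue
            blocks.setdefault(kv, []).append(rec)
        for members in blocks.values():
            if len(members) < 2:
                continue
            members.sort(key=lambda r: r.record_id)
            for i in range(len(members)):
                ri = members[i]
                for j in range(i + 1, len(members)):
                    rj = members[j]
                    if not _scope_matches(ri.dataset_id, rj.dataset_id, scheme.scope):
                        continue
                    pair = (ri.record_id, rj.record_id)
                    if pair not in seen:
                        seen.add(pair)
                        yield pair


@dataclass
class BlockHistogram:
    scheme_id: str
    per_key: list  # one {key_value: n_records} dict per key definition
    oversized: list  # (key_index, key_value, pair_count) beyond the ceiling

    def size_counts(self, key_index: int) -> Counter:
        return Counter(self.per_key[key_index].values())


def estimate_block_sizes(store, scheme: BlockingScheme) -> BlockHistogram:
    """Records-per-key-value histogram; flags blocks beyond the pair ceiling."""
    per_key = []
    oversized = []
    for ki, key in enumerate(scheme.keys):
        sizes: dict = {}
        for rec in store.live_records():
            kv = key_value(rec, key)
            if kv is MISSING:
                continue
            sizes[kv] = sizes.get(kv, 0) + 1
        per_key.append(sizes)
        for kv, n in sizes.items():
            pairs = n * (n - 1) // 2
            if pairs > scheme.block_ceiling:
                oversized.append((ki, kv, pairs))
    return BlockHistogram(scheme.scheme_id, per_key, oversized)


def scheme_from_dict(cfg: dict) -> BlockingScheme:
    keys = tuple(
        BlockKey(
            tuple(
                KeyPart(p.get("field", ""), p.get("transform", "identity"), p.get("k", 4))
                for p in key
            )
        )
        for key in cfg["keys"]
    )
    return BlockingScheme(
        scheme_id=cfg["scheme_id"],
        keys=keys,
        scope=tuple(cfg.get("scope", ("*", "*"))),
        block_ceiling=int(cfg.get("block_ceiling", 10_000)),
    )
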