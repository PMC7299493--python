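"""Extraction service: per-request encrypted linkage keys.

An extract releases, for each selected record, the source row id and a
pseudonymised chain key — never any identifying field.  The key is a keyed
pseudorandom function (HMAC-SHA256, truncated to 16 bytes of lowercase hex)
of the record's chain id under a per-request 256-bit secret, so within one
request two records share a key iff they share a chain, while the same
chain yields unrelated keys across requests.
"""

from __future__ import annotations

import hashlib
import hmac
import secrets as _secrets
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

KEY_BYTES = 16  # truncation of the 32-byte HMAC output


class ExtractionError(Exception):
    pass


@dataclass
class ExtractRequest:
    request_id: str
    datasets: tuple = ("*",)  # dataset ids, or "*" for all
    record_filter: Optional[object] = None  # predicate(StandardisedRecord) -> bool
    key_secret: bytes = field(default_factory=lambda: _secrets.token_bytes(32))

    def __post_init__(self):
        if isinstance(self.key_secret, str):
            self.key_secret = self.key_secret.encode()
        if len(self.key_secret) < 16:
            raise ExtractionError("key_secret must provide at least 128 bits")


def linkage_key(chain_id: int, secret: bytes) -> str:
    """Keyed-PRF pseudonym for one chain under one request secret."""
    digest = hmac.new(secret, str(chain_id).encode(), hashlib.sha256).digest()
    return digest[:KEY_BYTES].hex()


def extract(store, request: ExtractRequest) -> pd.DataFrame:
    """Produce the extract table: one (row_id, linkage_key) row per record.

    ``row_id`` is the dataset-qualified source row identifier.  Identifying
    fields are never emitted.  The run is audited with a digest of the
    secret, never the secret itself.  Criteria matching zero records give an
    empty (but well-formed) extract.
    """
    known = set(store.profiles)
    for ds in request.datasets:
        if ds != "*" and known and ds not in known:
            raise ExtractionError(f"unknown dataset in criteria: {ds}")
    rows = []
    for rec in sorted(store.live_records(), key=lambda r: r.record_id):
        if "*" not in request.datasets and rec.dataset_id not in request.datasets:
            continue
        if request.record_filter is not None and not request.record_filter(rec):
            continue
        chain_id = store.chain_of(rec.record_id)
        rows.append(
            {"row_id": rec.record_id, "linkage_key": linkage_key(chain_id, request.key_secret)}
        )
    frame = pd.DataFrame(rows, columns=["row_id", "linkage_key"])
    store.record_event(
        "run_record",
        {
            "action": "extract",
            "request_id": request.request_id,
            "datasets": list(request.datasets),
            "n_rows": len(frame),
            "secret_digest": hashlib.sha256(request.key_secret).hexdigest(),
        },
    )
    return frame


IDENTIFYING_KINDS = ("name", "date", "sex", "address", "locality")


@dataclass
class ExtractVerification:
    ok: bool
    problems: list


def verify_extract(frame: pd.DataFrame, chain_map: dict, store=None) -> ExtractVerification:
    """Check the extract contract against a known record -> chain map.

    Verifies (a) two rows share a linkage key iff they share a chain, and
    (b) no identifying column leaked into the extract schema.
    """
    problems = []
    id_columns = {"row_id", "linkage_key"}
    leaked = [c for c in frame.columns if c not in id_columns]
    if store is not None:
        identifying = set()
        for p in store.profiles.values():
            identifying.update(
                fs.name for fs in p.field_specs if fs.semantic_kind in IDENTIFYING_KINDS
            )
        leaked = [c for c in frame.columns if c in identifying or c not in id_columns]
    for col in leaked:
        problems.append(f"identifying or unexpected column in extract: {col}")
    key_of_chain: dict = {}
    chain_of_key: dict = {}
    for row_id, key in zip(frame["row_id"], frame["linkage_key"]):
        if row_id not in chain_map:
            problems.append(f"row not in truth chain map: {row_id}")
            continue
        chain = chain_map[row_id]
        if chain in key_of_chain and key_of_chain[chain] != key:
            problems.append(f"chain {chain} carries two keys")
        if key in chain_of_key and chain_of_key[key] != chain:
            problems.append(f"key collision across chains: {key}")
        key_of_chain[chain] = key
        chain_of_key[key] = chain
    return ExtractVerification(not problems, problems)
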