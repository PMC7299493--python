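"""The two-database structure: demographic store, links store, and audit log.

Identifying records live in the demographic store; the link graph and the
chain partition (the clusters of records believed to be one person each)
live in the separate links store.  Every mutating operation writes an
append-only :class:`AuditEvent`; replaying the audit log reconstructs the
links store bit-exactly (see :func:`replay_audit`).

Chains behave as a union-find partition with explicit history: a merge
retires the larger-id chain and points it at the survivor, so merge lineage
forms a forest rooted at active chains and the final labelling is
independent of merge order.
"""

from __future__ import annotations

import json
import sqlite3
import time
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .profiles import DatasetProfile, StandardisedRecord

AUDIT_KINDS = (
    "data_change",
    "profile_change",
    "link_change",
    "strategy_change",
    "run_record",
    "review_decision",
)


@dataclass
class Chain:
    chain_id: int
    member_record_ids: set
    created_run_id: str
    status: str = "active"  # active | retired
    successor: Optional[int] = None  # set when retired by a merge


@dataclass(frozen=True)
class Link:
    link_id: int
    record_id_a: str
    record_id_b: str
    weight: float
    origin: str  # automatic | clerical
    strategy_id: str
    run_id: str
    created_at: float


@dataclass(frozen=True)
class AuditEvent:
    event_id: int
    kind: str
    payload: dict
    timestamp: float
    actor: str


@dataclass
class DeletionReport:
    dataset_id: str
    deleted: list = field(default_factory=list)
    unknown: list = field(default_factory=list)
    retired_chains: list = field(default_factory=list)
    splits: list = field(default_factory=list)  # (old_chain, [new_chain_ids])


class StoreError(Exception):
    pass


class LinkageStore:
    """In-memory demographic + links store with audit, persistable to sqlite."""

    def __init__(self, actor: str = "service"):
        self.actor = actor
        self.records: dict[str, StandardisedRecord] = {}
        self.deleted: set[str] = set()
        self.chains: dict[int, Chain] = {}
        self._chain_of: dict[str, int] = {}
        self.links: dict[int, Link] = {}
        self._live_pairs: set[tuple[str, str]] = set()
        self.rejected_chain_pairs: set[tuple[int, int]] = set()  # clerical non-matches
        self.pending_potentials: list[dict] = []  # last run's review feed
        self.events: list[AuditEvent] = []
        self.profiles: dict[str, DatasetProfile] = {}
        self._imports: set[tuple] = set()
        self._next_chain = 1
        self._next_link = 1
        self._next_event = 1
        self._next_run = 1
        self._clock = time.time  # injectable for deterministic persistence tests

    # ---------------------------------------------------------------- audit

    def record_event(self, kind: str, payload: dict, actor: Optional[str] = None) -> int:
        if kind not in AUDIT_KINDS:
            raise StoreError(f"invalid audit kind: {kind}")
        ev = AuditEvent(self._next_event, kind, payload, self._clock(), actor or self.actor)
        self._next_event += 1
        self.events.append(ev)
        return ev.event_id

    def query_events(self, kind: Optional[str] = None, **payload_filter) -> list[AuditEvent]:
        out = []
        for ev in self.events:  # already in sequence order; append-only
            if kind is not None and ev.kind != kind:
                continue
            if any(ev.payload.get(k) != v for k, v in payload_filter.items()):
                continue
            out.append(ev)
        return out

    # ------------------------------------------------------------- importing

    def new_import_run_id(self) -> str:
        rid = f"run{self._next_run:05d}"
        self._next_run += 1
        return rid

    def seen_import(self, import_key: tuple) -> bool:
        return import_key in self._imports

    def add_records(
        self,
        records: Iterable[StandardisedRecord],
        import_key: tuple,
        run_id: str,
        profile: DatasetProfile,
    ) -> None:
        records = list(records)
        for rec in records:
            if rec.record_id in self.records:
                raise StoreError(f"record_id already in store: {rec.record_id}")
        assigned = []
        for rec in records:
            self.records[rec.record_id] = rec
            cid = self._fresh_chain(rec.record_id, run_id)
            assigned.append((rec.record_id, cid))
        self._imports.add(import_key)
        self.profiles[profile.dataset_id] = profile
        self.record_event(
            "data_change",
            {
                "action": "import",
                "dataset_id": profile.dataset_id,
                "profile_version": profile.version,
                "import_key": list(import_key),
                "run_id": run_id,
                "records": assigned,
            },
        )

    # ---------------------------------------------------------------- chains

    def _fresh_chain(self, record_id: str, run_id: str, chain_id: Optional[int] = None) -> int:
        cid = self._next_chain if chain_id is None else chain_id
        self._next_chain = max(self._next_chain, cid) + 1 if chain_id is not None else self._next_chain + 1
        self.chains[cid] = Chain(cid, {record_id}, run_id)
        self._chain_of[record_id] = cid
        return cid

    def assign_initial_chain(self, record_id: str, run_id: str = "manual") -> int:
        """Create a fresh singleton chain for an as-yet unchained record."""
        if record_id in self._chain_of:
            raise StoreError(f"record already chained: {record_id}")
        if record_id not in self.records:
            raise StoreError(f"unknown record: {record_id}")
        return self._fresh_chain(record_id, run_id)

    def chain_of(self, record_id: str) -> int:
        return self._chain_of[record_id]

    def active_chains(self) -> list[Chain]:
        return [c for c in self.chains.values() if c.status == "active"]

    def merge_chains(self, chain_a: int, chain_b: int, cause_link: Optional[Link] = None) -> int:
        """Merge two active chains; the smaller chain_id survives.

        A self-merge is a no-op recorded as a warning event.  The merge is
        visible immediately: all membership queries reflect it before the
        next pair is considered (the immediacy contract).
        """
        if chain_a == chain_b:
            self.record_event(
                "link_change", {"action": "self_merge_noop", "chain": chain_a}
            )
            return chain_a
        ca, cb = self.chains[chain_a], self.chains[chain_b]
        if ca.status != "active" or cb.status != "active":
            raise StoreError("both chains must be active to merge")
        survivor, retired = (ca, cb) if ca.chain_id < cb.chain_id else (cb, ca)
        survivor.member_record_ids |= retired.member_record_ids
        for rid in retired.member_record_ids:
            self._chain_of[rid] = survivor.chain_id
        retired.status = "retired"
        retired.successor = survivor.chain_id
        retired.member_record_ids = set()
        return survivor.chain_id

    # ----------------------------------------------------------------- links

    @staticmethod
    def canonical_pair(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def has_live_link(self, a: str, b: str) -> bool:
        return self.canonical_pair(a, b) in self._live_pairs

    def create_link(
        self,
        record_id_a: str,
        record_id_b: str,
        weight: float,
        origin: str,
        strategy_id: str,
        run_id: str,
        link_id: Optional[int] = None,
        created_at: Optional[float] = None,
    ) -> Link:
        """Create a link, audit it, and immediately merge the two chains."""
        if record_id_a == record_id_b:
            raise StoreError("cannot link a record to itself")
        a, b = self.canonical_pair(record_id_a, record_id_b)
        if (a, b) in self._live_pairs:
            raise StoreError(f"live link already exists: {a} -- {b}")
        for rid in (a, b):
            if rid not in self.records:
                raise StoreError(f"unknown record: {rid}")
            if rid in self.deleted:
                raise StoreError(f"record is deleted: {rid}")
        lid = link_id if link_id is not None else self._next_link
        self._next_link = max(self._next_link, lid) + 1
        link = Link(
            lid, a, b, float(weight), origin, strategy_id, run_id,
            created_at if created_at is not None else self._clock(),
        )
        self.links[lid] = link
        self._live_pairs.add((a, b))
        survivor = self.merge_chains(self._chain_of[a], self._chain_of[b], link)
        self.record_event(
            "link_change",
            {
                "action": "create",
                "link_id": lid,
                "record_id_a": a,
                "record_id_b": b,
                "weight": link.weight,
                "origin": origin,
                "strategy_id": strategy_id,
                "run_id": run_id,
                "created_at": link.created_at,
                "surviving_chain": survivor,
            },
        )
        return link

    def live_links(self) -> list[Link]:
        return [l for l in self.links.values() if self.canonical_pair(l.record_id_a, l.record_id_b) in self._live_pairs]

    # ------------------------------------------------------------- deletions

    def process_deletions(self, dataset_id: str, deleted_row_ids: Iterable[str]) -> DeletionReport:
        """Flag records deleted; re-derive affected chains by connected components.

        Links touching a deleted record die with it; any chain left
        disconnected over its surviving links is split, and a chain whose
        members are all deleted is retired.
        """
        report = DeletionReport(dataset_id)
        target_records = []
        for row_id in deleted_row_ids:
            rid = f"{dataset_id}:{row_id}"
            if rid not in self.records or rid in self.deleted:
                report.unknown.append(row_id)
            else:
                target_records.append(rid)
        affected_chains = {self._chain_of[r] for r in target_records}
        for rid in target_records:
            self.deleted.add(rid)
            report.deleted.append(rid)
        # drop live links touching deleted records
        for (a, b) in list(self._live_pairs):
            if a in self.deleted or b in self.deleted:
                self._live_pairs.discard((a, b))
        # re-derive each affected chain over surviving links
        for cid in sorted(affected_chains):
            chain = self.chains[cid]
            survivors = [r for r in chain.member_record_ids if r not in self.deleted]
            if not survivors:
                chain.status = "retired"
                chain.member_record_ids = set()
                for rid in target_records:
                    self._chain_of.pop(rid, None)
                report.retired_chains.append(cid)
                continue
            components = _components(survivors, self._live_pairs)
            for rid in chain.member_record_ids - set(survivors):
                self._chain_of.pop(rid, None)
            if len(components) == 1:
                chain.member_record_ids = set(components[0])
                continue
            # split: the component containing the smallest record id keeps the
            # chain id; the rest get fresh chains
            components.sort(key=lambda c: min(c))
            chain.member_record_ids = set(components[0])
            new_ids = []
            for comp in components[1:]:
                nid = self._next_chain
                self._next_chain += 1
                self.chains[nid] = Chain(nid, set(comp), chain.created_run_id)
                for rid in comp:
                    self._chain_of[rid] = nid
                new_ids.append(nid)
            report.splits.append((cid, new_ids))
        for rid in target_records:
            if rid in self._chain_of and rid in self.deleted:
                self._chain_of.pop(rid, None)
        self.record_event(
            "data_change",
            {
                "action": "delete",
                "dataset_id": dataset_id,
                "row_ids": sorted(r.split(":", 1)[1] for r in report.deleted),
                "unknown": list(report.unknown),
            },
        )
        return report

    # --------------------------------------------------------------- queries

    def live_records(self) -> list[StandardisedRecord]:
        return [r for rid, r in self.records.items() if rid not in self.deleted]

    def partition(self) -> dict[int, frozenset]:
        """Active chain id -> frozen member set (non-deleted records only)."""
        return {
            c.chain_id: frozenset(c.member_record_ids)
            for c in self.active_chains()
            if c.member_record_ids
        }

    def check_partition_invariant(self) -> None:
        """Active chains partition the non-deleted record universe."""
        seen: dict[str, int] = {}
        for c in self.active_chains():
            for rid in c.member_record_ids:
                if rid in seen:
                    raise StoreError(f"record {rid} in chains {seen[rid]} and {c.chain_id}")
                seen[rid] = c.chain_id
        universe = {rid for rid in self.records if rid not in self.deleted}
        if set(seen) != universe:
            missing = universe - set(seen)
            extra = set(seen) - universe
            raise StoreError(f"partition mismatch; unchained={missing} ghost={extra}")

    def links_fingerprint(self) -> str:
        """Canonical serialisation of the links store (links + partition)."""
        links = sorted(
            (l.link_id, l.record_id_a, l.record_id_b, round(l.weight, 9), l.origin, l.strategy_id, l.run_id)
            for l in self.links.values()
        )
        part = sorted(tuple(sorted(m)) for m in self.partition().values())
        return json.dumps({"links": links, "partition": part})

    # ----------------------------------------------------------- persistence

    def save(self, path) -> None:
        con = sqlite3.connect(str(path))
        try:
            with con:
                con.executescript(
                    """
                    DROP TABLE IF EXISTS records; DROP TABLE IF EXISTS chains;
                    DROP TABLE IF EXISTS links; DROP TABLE IF EXISTS events;
                    DROP TABLE IF EXISTS meta;
                    CREATE TABLE records (record_id TEXT PRIMARY KEY, dataset_id TEXT,
                        values_json TEXT, derived_json TEXT, import_run_id TEXT, deleted INTEGER);
                    CREATE TABLE chains (chain_id INTEGER PRIMARY KEY, members_json TEXT,
                        created_run_id TEXT, status TEXT, successor INTEGER);
                    CREATE TABLE links (link_id INTEGER PRIMARY KEY, a TEXT, b TEXT,
                        weight REAL, origin TEXT, strategy_id TEXT, run_id TEXT,
                        created_at REAL, live INTEGER);
                    CREATE TABLE events (event_id INTEGER PRIMARY KEY, kind TEXT,
                        payload TEXT, timestamp REAL, actor TEXT);
                    CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
                    """
                )
                con.executemany(
                    "INSERT INTO records VALUES (?,?,?,?,?,?)",
                    [
                        (r.record_id, r.dataset_id, json.dumps(r.values), json.dumps(r.derived),
                         r.import_run_id, int(r.record_id in self.deleted))
                        for r in self.records.values()
                    ],
                )
                con.executemany(
                    "INSERT INTO chains VALUES (?,?,?,?,?)",
                    [
                        (c.chain_id, json.dumps(sorted(c.member_record_ids)), c.created_run_id,
                         c.status, c.successor)
                        for c in self.chains.values()
                    ],
                )
                con.executemany(
                    "INSERT INTO links VALUES (?,?,?,?,?,?,?,?,?)",
                    [
                        (l.link_id, l.record_id_a, l.record_id_b, l.weight, l.origin,
                         l.strategy_id, l.run_id, l.created_at,
                         int((l.record_id_a, l.record_id_b) in self._live_pairs))
                        for l in self.links.values()
                    ],
                )
                con.executemany(
                    "INSERT INTO events VALUES (?,?,?,?,?)",
                    [(e.event_id, e.kind, json.dumps(e.payload), e.timestamp, e.actor) for e in self.events],
                )
                meta = {
                    "imports": json.dumps([list(k) for k in self._imports]),
                    "rejected_chain_pairs": json.dumps(sorted(list(p) for p in self.rejected_chain_pairs)),
                    "pending_potentials": json.dumps(self.pending_potentials),
                    "counters": json.dumps(
                        [self._next_chain, self._next_link, self._next_event, self._next_run]
                    ),
                }
                con.executemany("INSERT INTO meta VALUES (?,?)", meta.items())
        finally:
            con.close()

    @classmethod
    def load(cls, path) -> "LinkageStore":
        con = sqlite3.connect(str(path))
        try:
            store = cls()
            for rid, ds, vals, der, run, dele in con.execute("SELECT * FROM records"):
                store.records[rid] = StandardisedRecord(rid, ds, json.loads(vals), json.loads(der), run)
                if dele:
                    store.deleted.add(rid)
            for cid, members, run, status, succ in con.execute("SELECT * FROM chains"):
                ch = Chain(cid, set(json.loads(members)), run, status, succ)
                store.chains[cid] = ch
                if status == "active":
                    for rid in ch.member_record_ids:
                        store._chain_of[rid] = cid
            for lid, a, b, w, origin, sid, rid_, ts, live in con.execute("SELECT * FROM links"):
                store.links[lid] = Link(lid, a, b, w, origin, sid, rid_, ts)
                if live:
                    store._live_pairs.add((a, b))
            for eid, kind, payload, ts, actor in con.execute("SELECT * FROM events"):
                store.events.append(AuditEvent(eid, kind, json.loads(payload), ts, actor))
            meta = dict(con.execute("SELECT * FROM meta"))
            store._imports = {tuple(k) for k in json.loads(meta["imports"])}
            store.rejected_chain_pairs = {tuple(p) for p in json.loads(meta["rejected_chain_pairs"])}
            store.pending_potentials = json.loads(meta["pending_potentials"])
            store._next_chain, store._next_link, store._next_event, store._next_run = json.loads(
                meta["counters"]
            )
            return store
        finally:
            con.close()


def _components(nodes: Iterable[str], edge_set: set[tuple[str, str]]) -> list[list[str]]:
    """Connected components via union-find over the given live-link edges."""
    nodes = list(nodes)
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_set = set(nodes)
    for a, b in edge_set:
        if a in node_set and b in node_set:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for n in nodes:
        groups.setdefault(find(n), []).append(n)
    return list(groups.values())


def replay_audit(events: Iterable[AuditEvent]) -> LinkageStore:
    """Reconstruct the links store from an audit log.

    Imports recreate records with their initial chain assignments from the
    event payload; link-change creations recreate links (and their merges)
    with the original ids, weights and provenance; deletions are re-processed.
    The resulting links store fingerprint is bit-identical to the original's.
    """
    store = LinkageStore(actor="replay")
    for ev in events:
        if ev.kind == "data_change" and ev.payload.get("action") == "import":
            p = ev.payload
            for record_id, cid in p["records"]:
                ds, _, row = record_id.partition(":")
                store.records[record_id] = StandardisedRecord(
                    record_id, ds, {}, {}, p["run_id"]
                )
                store._fresh_chain(record_id, p["run_id"], chain_id=cid)
            store._imports.add(tuple(p["import_key"]))
        elif ev.kind == "data_change" and ev.payload.get("action") == "delete":
            store.process_deletions(ev.payload["dataset_id"], ev.payload["row_ids"])
        elif ev.kind == "link_change" and ev.payload.get("action") == "create":
            p = ev.payload
            store.create_link(
                p["record_id_a"], p["record_id_b"], p["weight"], p["origin"],
                p["strategy_id"], p["run_id"], link_id=p["link_id"],
                created_at=p["created_at"],
            )
    return store
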