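"""Clerical review: de-duplicated cluster queue over potential links.

Potential pairs are lifted to chain level and grouped into connected
components, so a reviewer sees each putative person-cluster once — never
the same chain pair twice in a run.  A cluster whose chains were already
merged by a higher-quality automatic link is suppressed (``resolved_auto``)
unless a QA flag forces it back in front of a reviewer.  Decisions create
clerical links (with immediate merges) or record rejections, and are fully
audited so the run can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .matching import WeightedPair


class ReviewError(Exception):
    pass


@dataclass
class ChainPair:
    chain_a: int
    chain_b: int
    max_weight: float
    pairs: list  # underlying record-level WeightedPairs
    qa_flags: set

    @property
    def key(self) -> tuple[int, int]:
        return (self.chain_a, self.chain_b) if self.chain_a < self.chain_b else (self.chain_b, self.chain_a)


@dataclass
class ReviewCluster:
    cluster_id: int
    chain_ids: set
    chain_pairs: dict  # (chain_a, chain_b) canonical -> ChainPair
    status: str = "open"  # open | resolved_auto | decided
    max_weight: float = 0.0
    decisions: list = field(default_factory=list)


def _lift_to_chains(store, potentials: Iterable[WeightedPair]):
    """Group record-level potentials by current chain pair; drop within-chain
    ones as auto-resolved unless QA-flagged."""
    by_pair: dict = {}
    auto_resolved: list[ChainPair] = []
    for p in potentials:
        ca = store.chain_of(p.record_id_a)
        cb = store.chain_of(p.record_id_b)
        key = (ca, cb) if ca < cb else (cb, ca)
        if ca == cb and not p.qa_flags:
            key = ("auto", ca)
            bucket = by_pair.setdefault(key, ChainPair(ca, cb, p.weight, [], set()))
        else:
            bucket = by_pair.setdefault(key, ChainPair(key[0] if ca != cb else ca,
                                                       key[1] if ca != cb else cb,
                                                       p.weight, [], set()))
        bucket.pairs.append(p)
        bucket.max_weight = max(bucket.max_weight, p.weight)
        bucket.qa_flags |= p.qa_flags
    review_pairs = []
    for key, cp in by_pair.items():
        if key[0] == "auto":
            auto_resolved.append(cp)
        else:
            review_pairs.append(cp)
    return review_pairs, auto_resolved


def _components_of(chain_pairs: list[ChainPair]) -> list[list[ChainPair]]:
    parent: dict[int, int] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for cp in chain_pairs:
        ra, rb = find(cp.chain_a), find(cp.chain_b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[ChainPair]] = {}
    for cp in chain_pairs:
        groups.setdefault(find(cp.chain_a), []).append(cp)
    return list(groups.values())


class ReviewQueue:
    """The run's clerical-review queue: build, decide, summarise."""

    def __init__(self, store, cluster_cap: int = 50):
        self.store = store
        self.cluster_cap = cluster_cap
        self.clusters: dict[int, ReviewCluster] = {}
        self._next_cluster = 1
        self._presented: set[tuple[int, int]] = set()  # chain pairs ever queued

    # ------------------------------------------------------------- building

    def build_queue(self, potentials: Iterable[WeightedPair]) -> list[ReviewCluster]:
        """Connected-component clusters over chain-level potential pairs,
        ordered by descending maximum pair weight."""
        review_pairs, auto_resolved = _lift_to_chains(self.store, potentials)
        # de-duplication across the run: drop chain pairs already presented
        # or already rejected by a reviewer
        rejected = self.store.rejected_chain_pairs
        fresh = [
            cp
            for cp in review_pairs
            if cp.key not in self._presented and cp.key not in rejected
        ]
        built: list[ReviewCluster] = []
        for comp in self._split_oversized(_components_of(fresh)):
            cluster = ReviewCluster(
                cluster_id=self._next_cluster,
                chain_ids={c for cp in comp for c in (cp.chain_a, cp.chain_b)},
                chain_pairs={cp.key: cp for cp in comp},
                max_weight=max(cp.max_weight for cp in comp),
            )
            self._next_cluster += 1
            self.clusters[cluster.cluster_id] = cluster
            for cp in comp:
                self._presented.add(cp.key)
            built.append(cluster)
        for cp in auto_resolved:
            cluster = ReviewCluster(
                cluster_id=self._next_cluster,
                chain_ids={cp.chain_a},
                chain_pairs={},
                status="resolved_auto",
                max_weight=cp.max_weight,
            )
            self._next_cluster += 1
            self.clusters[cluster.cluster_id] = cluster
        built.sort(key=lambda c: -c.max_weight)
        return built

    def _split_oversized(self, components: list[list[ChainPair]]) -> list[list[ChainPair]]:
        """Keep clusters reviewable: oversized components are split by
        dropping their weakest chain pairs until every piece fits the cap."""
        out: list[list[ChainPair]] = []
        stack = list(components)
        while stack:
            comp = stack.pop()
            chains = {c for cp in comp for c in (cp.chain_a, cp.chain_b)}
            if len(chains) <= self.cluster_cap or len(comp) <= 1:
                out.append(comp)
                continue
            comp = sorted(comp, key=lambda cp: cp.max_weight)
            remainder = comp[1:]  # drop the weakest edge and re-component
            stack.extend(_components_of(remainder))
            out.append([comp[0]])  # weakest pair reviewed on its own
        return out

    # ------------------------------------------------------------- deciding

    def decide(
        self,
        cluster_id: int,
        decisions: list[tuple[int, int, str]],
        reviewer: str,
        run_id: str = "review",
    ) -> dict:
        """Apply per-chain-pair verdicts ("accept" / "reject") to a cluster.

        Accepts create clerical links between the chains' representative
        records and merge immediately; rejects are remembered so the pair is
        never re-presented.  Undecided pairs keep the cluster open (partial
        decisions allowed).  Downstream clusters sharing a merged chain are
        rebuilt against the new partition.
        """
        cluster = self.clusters.get(cluster_id)
        if cluster is None:
            raise ReviewError(f"unknown cluster: {cluster_id}")
        if cluster.status != "open":
            raise ReviewError(f"cluster {cluster_id} is not open (status={cluster.status})")
        applied = {"accepted": [], "rejected": [], "already_merged": []}
        for chain_a, chain_b, verdict in decisions:
            key = (chain_a, chain_b) if chain_a < chain_b else (chain_b, chain_a)
            cp = cluster.chain_pairs.get(key)
            if cp is None:
                raise ReviewError(f"chain pair {key} not in cluster {cluster_id}")
            if verdict == "accept":
                rep_a = self._representative(chain_a)
                rep_b = self._representative(chain_b)
                if self.store.chain_of(rep_a) == self.store.chain_of(rep_b):
                    applied["already_merged"].append(key)
                else:
                    self.store.create_link(
                        rep_a, rep_b, cp.max_weight, origin="clerical",
                        strategy_id="clerical", run_id=run_id,
                    )
                    applied["accepted"].append(key)
            elif verdict == "reject":
                self.store.rejected_chain_pairs.add(key)
                applied["rejected"].append(key)
            else:
                raise ReviewError(f"unknown verdict: {verdict}")
            cluster.chain_pairs.pop(key)
            cluster.decisions.append((key, verdict, reviewer))
        self.store.record_event(
            "review_decision",
            {
                "cluster_id": cluster_id,
                "reviewer": reviewer,
                "decisions": [[list(k), v] for k, v, _ in cluster.decisions[-len(decisions):]],
                "applied": {k: [list(x) for x in v] for k, v in applied.items()},
            },
        )
        if not cluster.chain_pairs:
            cluster.status = "decided"
        if applied["accepted"]:
            self._rebuild_downstream({c for pair in applied["accepted"] for c in pair})
        return applied

    def _representative(self, chain_id: int) -> str:
        chain = self.store.chains[chain_id]
        if chain.status != "active":
            chain = self.store.chains[chain.successor]
            while chain.status != "active":
                chain = self.store.chains[chain.successor]
        return min(chain.member_record_ids)

    def _rebuild_downstream(self, merged_chains: set) -> None:
        """Re-evaluate open clusters touching a newly merged chain: their
        remaining potentials are re-lifted against the current partition."""
        for cluster in list(self.clusters.values()):
            if cluster.status != "open" or not (cluster.chain_ids & merged_chains):
                continue
            remaining = [p for cp in cluster.chain_pairs.values() for p in cp.pairs]
            for cp in cluster.chain_pairs.values():
                self._presented.discard(cp.key)
            cluster.chain_pairs = {}
            cluster.status = "decided" if cluster.decisions else "resolved_auto"
            if remaining:
                self.build_queue(remaining)

    # ------------------------------------------------------------- reporting

    def queue_stats(self) -> dict:
        counts = {"open": 0, "resolved_auto": 0, "decided": 0}
        for c in self.clusters.values():
            counts[c.status] = counts.get(c.status, 0) + 1
        counts["total"] = len(self.clusters)
        return counts

    def open_clusters(self) -> list[ReviewCluster]:
        return sorted(
            (c for c in self.clusters.values() if c.status == "open"),
            key=lambda c: -c.max_weight,
        )

    # ------------------------------------------------------------ export/import

    def export_rows(self) -> list[dict]:
        rows = []
        for c in self.open_clusters():
            for key, cp in sorted(c.chain_pairs.items()):
                rows.append(
                    {
                        "cluster_id": c.cluster_id,
                        "chain_a": key[0],
                        "chain_b": key[1],
                        "max_weight": round(cp.max_weight, 6),
                        "qa_flags": ";".join(sorted(cp.qa_flags)),
                        "n_record_pairs": len(cp.pairs),
                    }
                )
        return rows

    def apply_decision_rows(self, rows: Iterable[dict], default_reviewer: str = "cli") -> dict:
        summary = {"accepted": 0, "rejected": 0}
        by_cluster: dict = {}
        for row in rows:
            by_cluster.setdefault(int(row["cluster_id"]), []).append(row)
        for cid, cluster_rows in by_cluster.items():
            decisions = [
                (int(r["chain_a"]), int(r["chain_b"]), r["verdict"]) for r in cluster_rows
            ]
            reviewer = cluster_rows[0].get("reviewer") or default_reviewer
            applied = self.decide(cid, decisions, reviewer)
            summary["accepted"] += len(applied["accepted"])
            summary["rejected"] += len(applied["rejected"])
        return summary
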