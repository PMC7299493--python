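"""End-to-end orchestration: import -> block -> score -> resolve -> review.

The single entry point most callers want is :func:`run_linkage`: it pools
candidate pairs from every strategy's blocking schemes, scores them, and
hands the pooled weighted pairs to the resolution service.  Convenience
wrappers load a synthetic population into a fresh store and run the whole
engine under the default strategy.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .matching import LinkageStrategy, PairScorer, build_frequency_tables
from .prep import build_blocks, exhaustive_scheme
from .profiles import import_dataset
from .resolution import QACheck, RunReport, default_checks, resolve_run
from .review import ReviewQueue
from .stores import LinkageStore
from .synthgen import SyntheticPopulation, default_profiles, default_strategy


def score_run(
    store: LinkageStore,
    strategies: list[LinkageStrategy],
    run_id: str,
    exhaustive: bool = False,
) -> tuple[list, dict]:
    """Score every strategy's candidate pairs; returns (pairs, prescreen).

    Pairs scoring below a strategy's lower threshold cannot influence
    resolution or review, so they are counted (``prescreen`` maps strategy
    id -> discarded non-match count) rather than materialised.  Excluded
    pairs are kept: resolution audits them.
    """
    pooled = []
    prescreen: dict = {}
    for strategy in strategies:
        tables = build_frequency_tables(store, strategy)
        scorer = PairScorer(strategy, tables)
        schemes = strategy.blocking or (exhaustive_scheme(strategy.scope),)
        if exhaustive:
            schemes = (exhaustive_scheme(strategy.scope),)
        seen: set = set()
        dropped = 0
        for scheme in schemes:
            for rid_a, rid_b in build_blocks(store, scheme):
                if (rid_a, rid_b) in seen:
                    continue
                seen.add((rid_a, rid_b))
                pair = scorer.score(store.records[rid_a], store.records[rid_b], run_id)
                if not pair.excluded and pair.weight < strategy.lower:
                    dropped += 1
                    continue
                pooled.append(pair)
        prescreen[strategy.strategy_id] = dropped
    return pooled, prescreen


def run_linkage(
    store: LinkageStore,
    strategies: list[LinkageStrategy],
    run_id: Optional[str] = None,
    checks: Optional[list[QACheck]] = None,
    exhaustive: bool = False,
) -> RunReport:
    """Score and resolve one pooled run over all given strategies."""
    run_id = run_id or store.new_import_run_id()
    pooled, prescreen = score_run(store, strategies, run_id, exhaustive=exhaustive)
    report = resolve_run(store, pooled, strategies, run_id, checks=checks)
    report.non_match += sum(prescreen.values())
    return report


def load_population(pop: SyntheticPopulation, store: Optional[LinkageStore] = None) -> LinkageStore:
    """Import a generated population into a (fresh by default) store."""
    store = store if store is not None else LinkageStore()
    profiles = default_profiles()
    for name, rows in pop.datasets.items():
        if rows:
            import_dataset(store, rows, profiles[name])
    return store


def link_population(
    pop: SyntheticPopulation,
    strategy: Optional[LinkageStrategy] = None,
    checks: Optional[list[QACheck]] = None,
    exhaustive: bool = False,
    with_default_checks: bool = True,
) -> tuple[LinkageStore, RunReport]:
    """Load a synthetic population and run the default (or given) strategy."""
    store = load_population(pop)
    strategy = strategy if strategy is not None else default_strategy()
    if checks is None and with_default_checks:
        checks = default_checks()
    report = run_linkage(store, [strategy], checks=checks, exhaustive=exhaustive)
    return store, report


def review_queue_for(store: LinkageStore, report: RunReport, cluster_cap: int = 50) -> ReviewQueue:
    queue = ReviewQueue(store, cluster_cap=cluster_cap)
    queue.build_queue(report.potentials)
    return queue
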