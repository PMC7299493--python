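"""Classification, QA checks, cardinality restriction, pooled resolution."""

import itertools
import random

import pytest

from reclink.matching import LinkageStrategy, WeightedPair
from reclink.resolution import (
    QACheck,
    apply_cardinality,
    classify,
    default_checks,
    resolve_run,
    run_checks,
)

from conftest import make_store

STRAT = LinkageStrategy("s", fields=(), lower=10.0, upper=20.0)


def wp(a, b, w, strategy="s"):
    return WeightedPair(a, b, strategy, "run", weight=w)


class TestClassify:
    @pytest.mark.parametrize("w,expected", [(25, "match"), (15, "potential"), (5, "non-match"),
                                            (20, "match"), (10, "potential")])
    def test_thresholds(self, w, expected):
        assert classify(wp("a", "b", w), STRAT) == expected


class TestQAChecks:
    def test_sex_mismatch_demotes(self):
        store = make_store([
            {"surname": "Smith", "sex": "F", "dob": "1980-01-01"},
            {"surname": "Smith", "sex": "M", "dob": "1980-01-01"},
        ])
        pair = wp("ds:r001", "ds:r002", 30)
        flags, effective = run_checks(pair, store, default_checks(), "match")
        assert "sex_mismatch" in flags
        assert effective == "potential"

    def test_death_before_event_blocks(self):
        from conftest import person_profile
        from reclink.profiles import FieldSpec, import_dataset
        from reclink.stores import LinkageStore

        store = LinkageStore()
        hosp = person_profile("h", extra=(FieldSpec("event_date", "date", ("trim", "parse_date")),))
        death = person_profile("d", extra=(FieldSpec("death_date", "date", ("trim", "parse_date")),))
        import_dataset(store, [{"row_id": "1", "given_name": "A", "surname": "B", "sex": "F",
                                "dob": "1950-01-01", "locality": "X", "event_date": "2015-06-01"}], hosp)
        import_dataset(store, [{"row_id": "1", "given_name": "A", "surname": "B", "sex": "F",
                                "dob": "1950-01-01", "locality": "X", "death_date": "2010-01-01"}], death)
        pair = wp("h:1", "d:1", 30)
        flags, effective = run_checks(pair, store, default_checks(), "match")
        assert "death_before_event" in flags
        assert effective == "non-match"

    def test_dob_conflict_spares_transpositions(self):
        store = make_store([
            {"surname": "Smith", "dob": "1980-04-12"},
            {"surname": "Smith", "dob": "1980-12-04"},
            {"surname": "Smith", "dob": "1979-06-20"},
        ])
        ok_pair = wp("ds:r001", "ds:r002", 30)
        flags, effective = run_checks(ok_pair, store, default_checks(), "match")
        assert "dob_conflict" not in flags and effective == "match"
        bad_pair = wp("ds:r001", "ds:r003", 30)
        flags, effective = run_checks(bad_pair, store, default_checks(), "match")
        assert "dob_conflict" in flags and effective == "potential"

    def test_no_triggered_checks_leaves_classification(self):
        store = make_store([
            {"surname": "Smith", "sex": "F", "dob": "1980-01-01"},
            {"surname": "Smith", "sex": "F", "dob": "1980-01-01"},
        ])
        pair = wp("ds:r001", "ds:r002", 30)
        flags, effective = run_checks(pair, store, default_checks(), "match")
        assert flags == set() and effective == "match"


def _chain_of_factory(mapping):
    return lambda rid: mapping[rid]


class TestCardinality:
    def test_one_to_one_greedy(self):
        chains = {"a1": 1, "b1": 2, "b2": 3}
        cands = [wp("a1", "b1", 5.0), wp("a1", "b2", 4.0)]
        kept, demoted = apply_cardinality(cands, "1:1", _chain_of_factory(chains))
        assert [(p.record_id_a, p.record_id_b) for p in kept] == [("a1", "b1")]
        assert [(p.record_id_a, p.record_id_b) for p in demoted] == [("a1", "b2")]

    def test_equal_weight_tie_sends_both_to_review(self):
        chains = {"a1": 1, "b1": 2, "b2": 3}
        cands = [wp("a1", "b1", 5.0), wp("a1", "b2", 5.0)]
        kept, demoted = apply_cardinality(cands, "1:1", _chain_of_factory(chains))
        assert kept == []
        assert len(demoted) == 2

    def test_one_to_many_allows_shared_left(self):
        chains = {"a1": 1, "b1": 2, "b2": 3}
        cands = [wp("a1", "b1", 5.0), wp("a1", "b2", 4.0)]
        kept, demoted = apply_cardinality(cands, "1:N", _chain_of_factory(chains))
        assert len(kept) == 2 and demoted == []

    def test_mode_none_is_identity(self):
        cands = [wp("a1", "b1", 5.0), wp("a1", "b2", 4.0)]
        kept, demoted = apply_cardinality(cands, "none", _chain_of_factory({}))
        assert kept == cands and demoted == []

    @staticmethod
    def _oracle_1to1(cands, chain_of):
        """Independent recursive formulation of the greedy-with-tie rule."""
        remaining = sorted(cands, key=lambda p: -p.weight)
        kept, used = [], set()

        def quota_free(p):
            return chain_of(p.record_id_a) not in used and chain_of(p.record_id_b) not in used

        while remaining:
            w = remaining[0].weight
            group = [p for p in remaining if p.weight == w]
            remaining = remaining[len(group):]
            viable = [p for p in group if quota_free(p)]
            for p in viable:
                contenders = [
                    q for q in viable if q is not p and (
                        chain_of(q.record_id_a) == chain_of(p.record_id_a)
                        or chain_of(q.record_id_b) == chain_of(p.record_id_b)
                    )
                ]
                if not contenders:
                    kept.append(p)
            for p in kept:
                used.add(chain_of(p.record_id_a))
                used.add(chain_of(p.record_id_b))
        return {(p.record_id_a, p.record_id_b) for p in kept}

    def test_greedy_matches_enumeration_oracle_and_postcondition(self):
        """1,000 random candidate sets: greedy equals the independent oracle
        on small instances, and no chain ever appears in two retained
        cross-scope matches."""
        rng = random.Random(2024)
        for trial in range(1000):
            n_left, n_right = rng.randint(1, 4), rng.randint(1, 4)
            chain_map = {}
            cands = []
            n_cand = rng.randint(1, 10)
            seen = set()
            for _ in range(n_cand):
                l = f"L{rng.randint(1, n_left)}"
                r = f"R{rng.randint(1, n_right)}"
                if (l, r) in seen:
                    continue
                seen.add((l, r))
                chain_map[l] = int(l[1:])
                chain_map[r] = 100 + int(r[1:])
                cands.append(wp(l, r, float(rng.randint(1, 6))))
            chain_of = _chain_of_factory(chain_map)
            kept, demoted = apply_cardinality(cands, "1:1", chain_of)
            # conservation and 1:1 post-condition
            assert len(kept) + len(demoted) == len(cands)
            used = [chain_of(p.record_id_a) for p in kept] + [
                chain_of(p.record_id_b) for p in kept
            ]
            assert len(used) == len(set(used))
            assert {(p.record_id_a, p.record_id_b) for p in kept} == self._oracle_1to1(
                cands, chain_of
            )


class TestResolveRun:
    def _store3(self):
        return make_store([
            {"row_id": "a", "surname": "Smith", "dob": "1980-01-01"},
            {"row_id": "b", "surname": "Smith", "dob": "1980-01-01"},
            {"row_id": "c", "surname": "Smith", "dob": "1980-01-01"},
        ])

    def test_transitive_triangle_skips_redundant_pair(self):
        """a-b (30) and b-c (28) merge all three; a-c (25) is redundant."""
        store = self._store3()
        pairs = [wp("ds:a", "ds:b", 30), wp("ds:b", "ds:c", 28), wp("ds:a", "ds:c", 25)]
        report = resolve_run(store, pairs, [STRAT], "run1")
        assert report.links_created == 2
        assert report.redundant == 1
        assert len(store.partition()) == 1
        assert any(
            e.payload.get("action") == "resolved_by_prior_link"
            for e in store.query_events("link_change")
        )

    def test_empty_run(self):
        store = self._store3()
        report = resolve_run(store, [], [STRAT], "run1")
        assert report.dispositions == {k: 0 for k in report.dispositions}

    def test_single_match_creates_link_and_merge(self):
        store = self._store3()
        report = resolve_run(store, [wp("ds:a", "ds:b", 30)], [STRAT], "run1")
        assert report.links_created == 1
        assert store.chain_of("ds:a") == store.chain_of("ds:b")

    def test_conservation_every_pair_one_disposition(self):
        store = self._store3()
        pairs = [wp("ds:a", "ds:b", 30), wp("ds:b", "ds:c", 15), wp("ds:a", "ds:c", 5)]
        excluded = wp("ds:a", "ds:b", 0)
        excluded.excluded_by = "cond"
        report = resolve_run(store, pairs + [excluded], [STRAT], "run1")
        assert sum(report.dispositions.values()) == 4
        assert report.excluded == 1 and report.potential == 1 and report.non_match == 1

    def test_order_robustness(self):
        """All arrival orders of a small pair set give the same partition."""
        results = set()
        base = [("ds:a", "ds:b", 30.0), ("ds:b", "ds:c", 28.0), ("ds:a", "ds:c", 12.0)]
        for order in itertools.permutations(base):
            store = self._store3()
            pairs = [wp(a, b, w) for a, b, w in order]
            resolve_run(store, pairs, [STRAT], "run1")
            results.add(frozenset(frozenset(m) for m in store.partition().values()))
        assert len(results) == 1

    def test_pooling_beats_sequencing(self):
        """With two concurrent strategies, the higher-weight link for a chain
        pair wins regardless of which strategy produced it (1:1 scope)."""
        strong = LinkageStrategy("strong", fields=(), lower=10, upper=20, cardinality="1:1",
                                 scope=("ds", "ds2"))
        weak = LinkageStrategy("weak", fields=(), lower=10, upper=20, cardinality="1:1",
                               scope=("ds", "ds2"))
        from conftest import person_profile
        from reclink.profiles import import_dataset

        store = make_store([{"row_id": "a", "surname": "Smith", "dob": "1980-01-01"}])
        import_dataset(store, [
            {"row_id": "x", "given_name": "", "surname": "Smith", "sex": "",
             "dob": "1980-01-01", "locality": ""},
            {"row_id": "y", "given_name": "", "surname": "Smith", "sex": "",
             "dob": "1980-01-01", "locality": ""},
        ], person_profile("ds2"))
        # weak strategy proposes a-y (22), strong proposes a-x (25): pooled
        # resolution must accept a-x and demote a-y under 1:1
        pairs = [wp("ds:a", "ds2:y", 22, "weak"), wp("ds:a", "ds2:x", 25, "strong")]
        report = resolve_run(store, pairs, [weak, strong], "run1")
        assert store.chain_of("ds:a") == store.chain_of("ds2:x")
        assert store.chain_of("ds:a") != store.chain_of("ds2:y")
        assert report.demoted == 1

    def test_run_record_audited_with_parameters(self):
        store = self._store3()
        resolve_run(store, [wp("ds:a", "ds:b", 30)], [STRAT], "run9")
        runs = store.query_events("run_record")
        assert len(runs) == 1
        payload = runs[0].payload
        assert payload["run_id"] == "run9"
        assert payload["strategies"][0]["lower"] == 10.0
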