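# reclink

A self-contained probabilistic record-linkage engine for person-level
administrative and health data.  Linkage units routinely receive datasets —
hospital admissions, death registrations, electoral rolls — that describe
the same people without sharing a unique identifier.  `reclink` connects
the records that belong to one person using the identifying fields the
datasets do carry (given name, surname, sex, date of birth, address
locality), and releases only pseudonymised *linkage keys* to downstream
researchers, never the identifiers themselves.

The package implements the full operational workflow of a linkage unit:

1. **Profiles** — declarative per-dataset "recipes" for cleaning and
   standardising raw fields (case, punctuation, date parsing, phonetic
   codes), applied at import so only standardised values are stored.
2. **Stores** — the two-database separation: a demographic store of
   identifying records and a links store holding the link graph and the
   **chain** partition (a chain is the cluster of records attributed to one
   person).  Every mutation is written to an append-only audit log which
   can be replayed to reconstruct the links store exactly.
3. **Blocking** — union-of-keys subset blocking (e.g. phonetic surname ×
   birth year) to avoid the quadratic all-pairs comparison.
4. **Matching** — Fellegi–Sunter match weights.  For field *i* with
   probabilities *mᵢ* = P(agree | same person) and *uᵢ* = P(agree |
   different people), an agreeing field contributes log₂(mᵢ/uᵢ) and a
   disagreeing field log₂((1−mᵢ)/(1−uᵢ)); the pair weight is the sum.
   When frequency adjustment is on, *uᵢ* is replaced by the observed
   relative frequency of the agreeing value (clamped below by a floor), so
   agreement on a rare surname counts for more than agreement on a common
   one.  Frequencies can be counted per **chain** rather than per record,
   which makes them insensitive to how many event records a person accrues.
5. **Resolution** — all strategies of a run are pooled, pairs above the
   upper threshold become links in descending weight order with immediate
   chain merges, chain-level QA checks (sex conflict, incompatible birth
   dates, death-before-event) veto suspicious merges, and 1:1 / 1:N / N:1
   cardinality restrictions are enforced at chain level.
6. **Review** — pairs with intermediate weights are grouped into
   de-duplicated connected-component clusters for clerical review; decisions
   are applied with immediate merges and full audit.
7. **Extraction** — per-request encrypted linkage keys
   (HMAC-SHA256 of the chain id under a per-request 256-bit secret):
   within one extract, equal keys ⇔ same person; across extracts, keys are
   unlinkable.

A synthetic-population generator with ground truth (`reclink.synthgen`)
and a pairwise precision/recall harness are part of the package, so the
whole engine can be exercised end-to-end without any real data.

## Worked example

```python
from reclink import (PopulationSpec, uniform_corruption, generate, evaluate)
from reclink.pipeline import link_population, review_queue_for

spec = PopulationSpec(n_persons=500, seed=42, mean_events=3.0,
                      corruption=uniform_corruption(0.05))
pop = generate(spec)

store, report = link_population(pop)       # import, block, score, resolve
print(report.dispositions)

result = evaluate(store, pop.truth)        # pairwise metrics vs ground truth
print("precision = %.4f  recall = %.4f  F = %.4f"
      % (float(result.precision), float(result.recall), float(result.f_measure)))

queue = review_queue_for(store, report)    # clerical-review clusters
print(queue.queue_stats())
```

Output:

```
{'link-created': 1076, 'redundant-within-chain': 2172, 'potential': 293,
 'non-match': 10866, 'excluded': 363, 'demoted': 5}
precision = 1.0000  recall = 0.9399  F = 0.9690
{'open': 40, 'resolved_auto': 9, 'decided': 0, 'total': 49}
```

The generated population has 500 persons with a skewed number of hospital
events each (1,489 hospital rows, 129 death registrations) and 5% per-field
corruption.  The engine creates 1,076 automatic links; 2,172 further
candidate pairs are already within a chain when reached (transitivity), 298
intermediate-weight pairs go to clerical review as 40 de-duplicated
clusters, and pairs where a hospital event post-dates the other record's
death date are excluded outright.  Against the ground truth every automatic
link is correct (precision 1.0) and 94% of the true co-referent record
pairs are recovered before any clerical review.

The same engine is scriptable from the shell:

```bash
reclink synth --n-persons 500 --seed 42 --corruption 0.05 --out data/
reclink import --store s.db --profile hospital.yaml --file data/hospital.csv
reclink run --store s.db --default
reclink review export --store s.db --out queue.csv
reclink extract --store s.db --request-id req1 --out keys.csv
```

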