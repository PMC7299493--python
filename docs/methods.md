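# Methods

## The linkage model

`reclink` performs probabilistic record linkage in the Fellegi–Sunter
framework.  Each candidate record pair is compared field by field; field
comparators return one of four ordered outcomes — `agree`, `partial`,
`disagree`, `missing` — and each outcome maps to a log-likelihood-ratio
weight:

| outcome  | weight                              |
|----------|-------------------------------------|
| agree    | log₂(m / u_eff)                     |
| partial  | partial_discount × log₂(m / u_eff)  |
| disagree | log₂((1 − m) / (1 − u_eff))         |
| missing  | 0                                   |

with m = P(outcome agree | records co-referent) and u_eff the probability
of chance agreement.  The pair weight is the exact sum of field weights.
Missing is neutral by design: absence of evidence is not evidence of
absence, and treating it as disagreement would penalise sparse datasets
twice (once through blocking, once through weights).

### Frequency adjustment

With `frequency_mode` set, u_eff for an agreement is the observed relative
frequency of the agreeing value, clamped into [floor, 1] with
floor = 1 / (2 × number of counting units).  The floor bounds the weight a
singleton (or previously unseen) value can earn and avoids log-infinities.
When the two compared values differ (a partial agreement), the *larger* of
the two value frequencies is used — the conservative choice, since the pair
can only be as surprising as its more common spelling.  Disagreements use
the baseline u: a disagreement carries no information about value rarity.

Counting units are records (`record` mode) or chains (`chain` mode): in
chain mode a chain contributes once per distinct value it contains, so the
tables are invariant to how many event records a person has accumulated —
without this, frequent hospital attenders would deflate the apparent rarity
of their own names.  Conditional tables (e.g. given-name frequencies per
sex) are kept alongside an unconditional fallback used whenever the two
records disagree on, or are missing, the conditioning value.

### Comparators

* **string** — Jaro–Winkler similarity (prefix scale 0.1, max prefix 4),
  agree ≥ 0.92, partial ≥ 0.80 by default.  The implementation is verified
  against the standard published comparator values (MARTHA/MARHTA 0.9611,
  DIXON/DICKSONX 0.8133, DUANE/DWAYNE 0.84).
* **date** — exact match agrees; a day/month transposition or a single
  wrong component is partial; mixed-precision dates (1980 vs 1980-04-12)
  whose shared components agree are partial.  Dates are ISO-8601 strings;
  partial dates keep their stated precision and are never imputed.
* **numeric** — |Δ| ≤ tolerance agrees, with an optional partial band.
* **location** — exact value or, at the `phonetic` hierarchy level, equal
  Soundex codes; phonetic-equal values are partial at the exact level.

Phonetic codes use American Soundex with the H/W rule (ASHCRAFT → A261),
both as a derived profile column and as a blocking transform.  The
algorithm name is recorded in the profile so alternatives stay pluggable.

## Standardisation

Profiles declare, per field, a semantic kind and an ordered rule sequence.
All rules are deterministic and idempotent (property-tested): name cleaning
uppercases, collapses hyphens/apostrophes to single spaces and strips other
punctuation; blank input maps to an explicit missing marker (never the
empty string); dates parse day-first for slashed forms.  Address
standardisation is token-level (uppercase, unit/street-number split, a
shipped abbreviation lookup) — deliberate desk-scale normalisation, not
geocoding.

## Blocking

A blocking scheme is a union of keys; each key is a list of
(field, transform) pairs with transforms identity, phonetic,
first_k_chars, year_of, and constant.  A record missing any field of a key
drops out of that key rather than wildcard-matching (wildcards explode
blocks; the union of keys recovers recall).  Every unordered pair is
emitted once, in (smaller id, larger id) orientation.  The `constant`
transform yields exhaustive all-pairs comparison and is the oracle mode
used throughout validation: on small stores the engine's scored pairs are
compared 1:1 against an independent brute-force scorer
(`reclink.reference`), which recomputes weights with inline arithmetic and
its own frequency tally.

## Resolution

All strategies of a run are pooled before any link is created, so a
stronger link found by one strategy can never lose to a weaker link from
another — the failure mode of strictly sequential linkage passes.
Accepted matches are processed in descending weight (ties broken by
strategy declaration order, then pair order); each link merges its chains
immediately, and pairs whose records already share a chain are recorded as
redundant.  The final partition is invariant to input order (permutation-
tested), because merging always keeps the smaller chain id and processing
order is a deterministic sort.

QA checks are evaluated twice: once at classification time to annotate
potentials, and again against the *current* chains immediately before each
link is created, so evidence accumulated by earlier merges in the same run
(a chain's known birth dates, sexes, death dates) can veto a later merge.
Shipped checks: chain-level sex conflict (demote), death before another
record's event date (block), age gap > 115 years (demote), irreconcilable
birth dates — not equal, not a day/month transposition — across the two
chains (demote), and an optional intermediate-weight margin above the upper
threshold.  Demotions feed clerical review; only blocks discard.

Cardinality restrictions (1:1, 1:N, N:1) are enforced at chain level by a
greedy sweep in descending weight.  Displaced candidates are demoted to
review, never deleted, and equal-weight candidates contending for the same
quota are all demoted — review arbitrates rather than the engine accepting
one arbitrarily.  Greedy (not assignment-optimal) resolution is the
declared contract; the review queue is the safety net for its mistakes.
When several pooled strategies declare different modes for one dataset
scope, the strictest applies (1:1 ≻ one-sided ≻ none; two opposite
one-sided modes compose to 1:1).

## Clerical review

Potential pairs are lifted to chain level and clustered by connected
components, so each putative person-group is reviewed once (no chain
appears in two open clusters, and a chain pair is never presented twice in
a run).  Clusters whose chains were already merged by a stronger automatic
link are suppressed unless a QA flag forces them back.  Ordering is by
descending maximum pair weight — the declared choice where no standard
exists.  Components larger than 50 chains are split by repeatedly removing
their weakest chain pair, keeping clusters humanly reviewable.  Decisions
(accept → clerical link + immediate merge; reject → remembered and never
re-presented) are fully audited; replaying the audit log reproduces the
links store bit-exactly.

## Extraction

Linkage keys are a keyed PRF of the chain id: HMAC-SHA256 under a
per-request 256-bit secret, truncated to 16 bytes of lowercase hex.  Within
a request, key equality is exactly chain equality; across requests the
keys are cryptographically unlinkable.  Only (row id, key) columns are
emitted, and the audit trail stores a digest of the secret, never the
secret.  Row-level keys are emitted (one row per record); chain-level
deduplication is the consumer's choice.

## Synthetic study populations

The generator emulates event-based person data: a "hospital" dataset with
a geometric number of events per person (default mean 3, capped at 15) and
a "deaths" dataset covering a fraction (default 0.25) of persons, with
death dates always after the person's last event.  Surnames are drawn
Zipf(1.5) from a shipped 80-name list that includes phonetic variant
families (SMITH/SMYTH, JOHNSON/JOHNSTON); given names are Zipf(1.2) per
sex; birth dates are uniform over 1920–2005; localities uniform over 20
towns.  Corruption operators — one-character typos, Soundex-preserving
vowel substitutions, day/month transpositions, missingness, surname
replacement — are applied independently per field after truth assignment,
each at its own probability (the study condition uses 5% across the
board).  Everything is driven by one mandatory seed; identical specs yield
byte-identical CSV output.

What the generator does *not* emulate: correlated errors (a clerk garbling
a whole row), household/family structure, nickname and transliteration
variation, address histories, or realistic geographic clustering.  Passing
tests therefore demonstrate the engine's mechanics and its behaviour under
independent field noise, not production linkage quality on real data.

## Default strategy parameters

The default person-matching strategy compares given name, surname (both
Jaro–Winkler, chain-based frequencies, given name conditioned on sex), sex
(exact), date of birth (transposition-tolerant), and locality.  m values
(0.85–0.98) reflect a few percent per-field error; u values are the chance
agreement rates implied by the value spaces (0.5 for sex, 10⁻⁴ for full
birth dates, 0.05 for 20 localities).  Date-of-birth partial agreement is
discounted hard (0.35) because near-agreeing dates of different people are
common while true date errors are mostly transpositions; string partials
keep 0.65 of the agreement weight since they are usually typos.  Thresholds
are lower = 7, upper = 12 in log₂ units: the deliberately permissive upper
leans on the chain-context QA checks to veto doppelgänger merges, which
measures better than a high threshold alone (precision ≈ 0.99 at recall ≈
0.93–0.94 under the 5% study condition).  Blocking is a four-key union:
phonetic surname × birth year, phonetic given name × birth year, exact
birth date, phonetic surname × locality (the rescue key for missing birth
dates).

## Problem sizes and numerics

Validation runs use 55-person populations (≈160 records) for exhaustive
oracle comparison, 500 persons (≈1,600 records) for zero-noise exact
recovery, and 2,000 persons (≈6,500 records, ≈190k candidate pairs) for the
noisy condition — large enough for stable pairwise metrics while keeping
the full suite around a quarter of a minute.  Weight comparison against the
brute-force oracle is at 10⁻⁹ absolute; evaluation metrics use exact
rational arithmetic (`fractions.Fraction`) on pair counts, with undefined
precision (no predicted pairs) reported as 1 with an explicit flag.  Pair
scoring memoises per-field value-pair results, which changes evaluation
order but not results (asserted against the uncached path).

## Known limitations

* m/u are user-supplied; there is no EM estimation.
* Greedy cardinality is order-deterministic but not assignment-optimal.
* The review CLI is file-based; there is no interactive interface.
* Single-process, single-writer persistence (one sqlite file).
* The address model is token normalisation only.
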