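# Methods

This note records the models, parameter choices and interpretive decisions
behind `tempomine`, and what the synthetic-corpus tests do and do not show
about real clinical data.

## Corpus model and deduplication

A corpus is an ordered list of note records keyed by `(note_id, line_nbr)`.
The model assumes the warehouse convention in which editing or re-signing a
note re-emits it with the same `note_id` and an incremented `line_nbr`;
"most recent version" is therefore operationalised as *maximal line_nbr
within (patient_id, note_id)*, not maximal timestamp.  When line numbers
tie (possible across malformed extracts), input order decides.  The
canonical seven-column header (`note_id, line_nbr, patient_id, provider_id,
note_type, timestamp, text`) is a documented stand-in for warehouse-specific
header lists; `read_corpus(columns=...)` maps other dialects onto it.

`merge_adjacent` chains a patient's timestamp-sorted notes while each
consecutive gap is ≤ `gap_hours` (default 24 h — "adjacent time periods"
is not a quantified notion, and one calendar day is the natural unit for
nursing documentation).  Merged text is joined with single newlines to
preserve sentence segmentation downstream; the merged record keeps the
earliest timestamp and the first note's identity.  Timestamps are
timezone-naive at minute precision throughout.

## SimHash fingerprints

Width B defaults to 64 bits (32 and 128 supported): 64 bits keeps the
collision probability of unrelated notes negligible at corpus sizes in the
10⁴–10⁵ range while fitting one machine word.  Token hashing uses keyed
blake2b with an explicit integer `hash_seed`, so fingerprints are
reproducible across runs, platforms and Python versions (unlike the
built-in `hash`).  Weighting is raw TF by default; TF-IDF (natural log)
when a corpus-level document-frequency table is supplied — with the
property that a token present in every document weighs exactly zero.
A note section (split on blank lines / `Header:` keywords) can be
fingerprinted instead of the whole document.

Expected behaviour used in tests: unrelated token bags land at mean
Hamming distance B/2; bags sharing ≥ 90 % of weighted tokens land well
below that (locality).

## K-means over fingerprints

Assignment uses squared Euclidean distance between bit vectors and
real-valued per-bit-mean centroids; on binary points this coincides with
Hamming distance when centroids are binary, and it keeps the classical
Lloyd convergence guarantee (the within-cluster objective is non-increasing
per iteration, which the tests assert on every iteration).
Initialisation is deterministic farthest-point seeding from a seeded
random start; an emptied cluster is re-seeded with the globally
worst-fitting point, which cannot increase the objective.  K defaults
to 10.  Cluster *representatives* are always actual input notes (ties
broken toward the lexicographically smallest note id); the final step of
local-representation learning — a human reading and labelling the
representatives — is deliberately out of scope, so the model surfaces
exemplars rather than automating labels.

## Temporal expressions

Three categories, matched with longest-match-wins overlap resolution
(explicit beats implicit beats ordinal on equal length), spans reported as
0-based half-open character offsets:

* **explicit** — ISO dates, bare clock times `HH:MM`, duration phrases
  (`n days/h/hours/weeks/minutes`, normalised to hours: `n days` → 24 n h),
  and the masked de-identification dialect: the literal `DD-MM-YYYY`
  denotes an unknown but fixed reference date (internally pinned to an
  arbitrary epoch so that arithmetic works), and a `+ n` prefix denotes
  that reference date plus n calendar days.
* **implicit_signal** — a cue-word lexicon (before, after, prior to,
  since, then, ...).
* **ordinal** — an ordinal lexicon (first ... tenth, initially, finally).

Both lexicons ship as editable plain-text files; they are deliberately
small stand-ins, not a clinically validated resource, and precision/recall
on real notes will depend on extending them.  Deliberately excluded:
TimeML-style markup emission and machine-learned temporal relation
classification.

## Duration reporting

`duration_between` returns the elapsed time on two scales: `hours` is the
floor of the elapsed whole hours, `days` is the calendar-date difference.
Both choices are forced by the dual reading "2 days or 42 h" for an
interval from 10:02 to 04:26 two days later: 42 h 24 min floors to 42, and
the date difference is 2 even though only 1.77 × 24 h elapsed.  The two
scales intentionally answer different questions (clinical elapsed time vs.
documentation days) and the invariant `days − 1 ≤ hours/24 ≤ days + 1`
ties them together.

## Decomposition and entity clustering

Decomposition excises temporal spans from a sentence; an explicit span
also swallows an immediately preceding connective (`for`, `from`, `to`,
...) so that "fever for 2 days" leaves the sub-expression "fever" rather
than "fever for".  Cue words are excised alone ("hypotension before
intubation" → "hypotension intubation").  Each span becomes one constraint
in span order: duration (hours), anchor_time (datetime/clock), signal or
ordinal (surface string).

"Modified K-medoids" over sub-expressions is interpreted here as **PAM
with deterministic farthest-first initialisation** (first medoid = the
1-medoid optimum, then farthest-first) and Hamming distance over SimHash
fingerprints of the sub-expression token bags.  This interpretation was
chosen because it keeps exemplars real, reuses the package's own embedding
machinery instead of a neural sentence encoder, and is deterministic given
the hash seed; other readings of "modified" are possible.  The greedy
best-swap phase never increases the total within-cluster distance (tested
against the recorded objective history).

Cause attribution uses a single template rule — a condition phrase
preceding "(caused sepsis)" or "caused sepsis" on the note's first line —
matching the documented record format `"<condition> (caused sepsis):
<symptom>, <duration>"`; it is a heuristic, not a relation extractor.

Entity anchors are the note timestamps.  Explicit in-text anchor dates are
carried as constraints but do not override the note time, because masked
dates live on a relative axis that cannot be mixed with real timestamps.

## Sequence database and mining

`build_sequences` produces per-patient ordered `(time_index, itemset)`
lists over the global sorted distinct time points; same-time entities of a
patient merge into one itemset, items within an itemset are stored sorted
for canonical serialisation.  The per-patient and per-time table views are
pivots of one relation and round-trip exactly.  `order_only` mode groups
by per-note order keys instead of timestamps; when per-patient timestamps
are strictly increasing the two modes yield identical pattern sets (mining
only consumes the per-patient chain of itemsets).

PrefixSpan mines single-item chains by recursive projected-database
growth; support is counted at most once per sequence, the standard
semantics (the counting rule matters: `[A,A,A]` supports `[A,A]` once, not
three times).  Default `min_support` is 2 — the smallest value at which a
pattern is shared evidence rather than a single patient's trajectory.
Report ordering is support desc → pattern length desc → lexicographic; the
tie rules are this package's convention.  The optional itemset-element
mode uses exhaustive candidate growth with anti-monotone pruning and
direct containment counting: slower than true bi-directional
projection but transparently complete, and itemset patterns are a
secondary view here.  Out of scope: closed/maximal condensation,
gap-constrained mining, significance testing.

## Synthetic corpus generator

The generator is the package's study-condition definition, not a tuning
knob.  Defaults: 20 patients (50 in the acceptance checks), 3–6 notes per
patient at 6–48 h gaps from a fixed origin, 15 % duplicate rate, a
ten-phrase sepsis symptom vocabulary, and three ordered symptom pairs —
(fever, hypotension), (respiratory failure, hypoxemic respiratory),
(tachypnoea, altered mental status) — each planted independently per
patient with probability 0.9 at strictly increasing note positions.  The
temporal mix is 40 % explicit / 30 % implicit / 30 % ordinal.  Boilerplate
sentences are written to contain *no* temporal vocabulary, and symptom
sentences are templated so that excising the temporal span leaves exactly
the symptom phrase; filler symptoms are drawn only from vocabulary outside
the planted patterns.  These choices make ground truth exact: planted
expression counts, durations, duplicate maps and pattern supports are
recoverable without tolerance.

That exactness is also the generator's limitation: real notes have
misspellings, abbreviations, negation, overlapping temporal phrases and
entity paraphrases that do not reduce to the planted templates.  The
`corrupt` operation injects misspellings and abbreviations (sparing
temporal spans) to probe robustness, but passing the planted-recovery
tests demonstrates correctness of the machinery, not clinical-grade
extraction accuracy.  Corpus-scale results on real data (pattern counts,
top-pattern frequencies) are expressly not reproduced here, since the
source corpora are access-restricted.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (generator, K-means
init, hash keying), and the pipeline manifest hashes every artifact so a
rerun with the same configuration is verifiable byte-for-byte.  The test
suite and the acceptance script use desk-scale problems — 200 random
databases for the mining oracle, 50 patients for planted recovery, 20
planted-partition trials — sizes at which the exhaustive oracles are
feasible and the stochastic checks are already far from their decision
boundaries.
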