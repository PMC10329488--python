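# Methods

This note documents the models and procedures annokit implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the design choices made where the design was genuinely open.

## Text analysis

All tokenized backends share one analyzer modeled on a Lucene-style
standard/stop analyzer: Unicode case-fold, replace every non-alphanumeric
character (including underscore) with a space, split on whitespace, and
remove the classic 33-word English stop list (`a an and are as at be but by
for if in into is it no not of on or such that the their then there these
they this to was will with`). No stemming and no synonym expansion: ontology
labels are short noun phrases, and stemming would merge clinically distinct
tokens (e.g. "ventilated"/"ventilator" vs "ventricular" stems collide under
aggressive stemmers). Only a term's primary label is indexed; metadata
columns are display-only.

## Ranking backends

**Fuzzy (Jaro-Winkler).** Jaro similarity uses the standard definition:
match window `floor(max(|s1|,|s2|)/2) − 1`, greedy left-to-right matching,
transpositions counted as half the number of matched characters out of
sequence order. Two empty strings are defined as identical (similarity 1);
one empty string yields 0. The Winkler prefix boost uses the canonical
defaults — scale 0.1, prefix cap 4, boost threshold 0.7 — and the scale is
restricted to [0, 0.25] so scores stay in [0, 1]. The backend compares
whole case-folded strings without tokenization, since the measure is
character-level. Correctness is checked against an independently written
reference implementation (1000 seeded random pairs, 1e−9 agreement) and
hand-derived textbook values.

**Vector (TF-IDF cosine).** One document per term label. Raw term counts,
smoothed inverse document frequency `idf = ln((1+N)/(1+df)) + 1` (strictly
positive, so a token in every label still contributes), L2-normalized rows
in a scipy CSR matrix; queries are embedded with the index's idf,
out-of-vocabulary tokens dropped. Scores are cosine similarities in [0, 1].
Only documents sharing at least one token are returned, and a query that is
entirely out-of-vocabulary returns an empty result rather than an error.
The matrix is cross-checked against scikit-learn's `TfidfVectorizer` in the
test suite; scikit-learn is deliberately not used as the implementation so
the index structure (vocabulary, idf, postings) stays inspectable and the
cross-check stays independent.

**Fulltext (BM25).** Okapi BM25 with `k1 = 1.2`, `b = 0.75` and
`idf = ln(1 + (N − df + 0.5)/(df + 0.5))` — the ranking family used by
SQLite's FTS5 and Lucene. Each query-token *occurrence* contributes (a
repeated query token weights its term twice). Documents matching no query
token are excluded entirely.

**Determinism.** Every backend orders by descending score with ties broken
by ascending code, so results are reproducible and testable to equality.
Lists are truncated to `min(k, scoreable documents)`. Vector and fulltext
indexes are built on demand and cached in-process, keyed by the ontology's
(version label, term count) fingerprint, so re-ingestion invalidates them;
indexes are cheap to rebuild at the ontology sizes the store targets, so no
on-disk index persistence is implemented.

## Retrieve-then-rerank

The pipeline retrieves `retrieve_k` candidates with one backend, applies a
re-ranker, and truncates to `final_k` (`retrieve_k ≥ final_k` enforced). A
re-ranker is any callable from a `RerankContext` (concept, optional
measurement summary, candidates) to a `RerankResult` that is an exact
permutation of its input — the contract an external LLM re-ranking service
plugin would implement. Remote services are out of scope by design (cost,
nondeterminism); `build_rerank_payload` serializes the context as the
deterministic, round-trip-parseable document such a plugin would consume.

The built-in context re-ranker scores candidate `c` as

    alpha * minmax(retrieval score) + (1 - alpha) * overlap(c)

with `alpha = 0.5` by default. `minmax` normalizes within the candidate
list (all-equal lists normalize to 1). `overlap(c)` is the fraction of the
candidate label's analyzed tokens found in the union of the concept label's
tokens and a context keyword set derived from the measurement summary: the
unit's tokens, the value kind ("numeric"/"textual"), and domain tokens
implied by the unit through a small built-in lexicon (mmHg → arterial,
blood, pressure; cmH2O → airway, pressure, ventilation; bpm → heart, rate,
pulse; ...). The lexicon encodes the observation that a unit of measure
localizes a measurement's physiology, which is exactly what disambiguates
same-label concepts; it is a deliberately small, documented table, not a
learned model, and users can achieve the same effect in a custom re-ranker.

## Observation summaries

A concept is classified **numeric** when at least 90% of its nonempty value
strings parse as finite numbers — real chart data contains sentinel strings
("ERROR", "see note"), so a 100% rule would misclassify genuinely numeric
concepts; below the threshold it is **textual**. Numeric summaries are
equal-width histograms (default 50 bins) over [min, max] with the lowest
bin first; unparseable values are dropped and counted; a degenerate
min = max range becomes a single bin. Textual summaries count exact trimmed
value strings in ascending lexicographic order. Both conserve their totals
by construction and the tests assert it.

Patient series use a half-open window `[anchor, anchor + window_hours)`
(default 96 h) anchored at the patient's earliest observation of the
concept: anchoring at first observation rather than admission needs no
admission table and gives every patient a full window; the half-open edge
makes the boundary case unambiguous (+95 h in, +96 h and +120 h out). The
top-`n` patients (default 5) are those with the most observations of the
concept, ties broken by ascending patient id. Timestamps are ISO 8601;
naive timestamps are assumed UTC.

## Annotation sessions

One annotation per concept, always. Re-annotation replaces the previous
assignment; skipping records that no adequate standard term exists and
clears assignments; `status = annotated` iff assignments are nonempty.
Every assigned (ontology, code) pair must resolve in the store before it is
accepted. Exports are deterministic (session concept order, then assignment
order) and lossless in both CSV (one row per pair, quoted fields, UTF-8)
and JSON (grouped per concept, `schema_version: 1`); import is the exact
inverse, which is also the merge path for exports produced by several
annotators.

## Synthetic data

The generators emulate the shape of a demo-sized ICU extract: a 200-term
ontology, 8 source concepts, 100 patients, observations over a 7-day span.
Defaults worth knowing:

* Ontology labels are clinical-style phrases from a word bank, unique even
  after analysis (no two labels share a token multiset), with ~20%
  near-duplicate distractors created by swapping one token of a true label.
  The ambiguous pair "Mean arterial pressure" / "Mean airway pressure" is
  always present verbatim.
* Two source concepts share the identical label "Mean pressure (MAP)" but
  draw values from N(90, 10) mmHg (arterial-like) and N(12, 3) cmH2O
  (airway-like), both truncated at 0. These distributions are chosen so the
  summaries separate decisively by construction (the observed z-statistic
  is ≈ 250); they are illustrative, not clinical claims. Heart rate is
  N(80, 12) bpm; textual concepts (lung sounds, rhythm) draw from fixed
  categorical distributions.
* Per patient and concept, the observation count is `1 + Poisson(λ)` with
  `λ ~ Uniform(1, 2 · obs_per_patient)` (default mean ≈ 10): the
  between-patient heterogeneity makes the top-5 occurrence ranking
  informative. Exact count ties can still occur — the integer count range
  is far smaller than the squared number of patients — and are resolved by
  the deterministic patient-id tie-break.
* Retrieval queries perturb a true label by exactly one edit (token
  deletion, adjacent-character transposition, or letter-case change).
* Each output file has its own random stream spawned from the master seed
  by a fixed spawn-key index, so identical specs give byte-identical files
  and any one file is reproducible alone.

What the synthetic data does **not** emulate: real release-file metadata
richness, synonym/alternate-description rows, misspelled or abbreviated
source labels beyond single edits, irregular observation cadences,
missing-unit heterogeneity, or inter-concept correlation. Passing tests
demonstrate the algorithms' correctness and the pipeline's invariants on
data with this structure, not mapping accuracy on real EHR extracts.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline at the
default fixture size (200 terms, 100 patients, ~9000 observations, 100
queries), which completes in seconds. Score comparisons in tests use exact
equality where determinism guarantees it and 1e−9 tolerances for floating
point accumulation. The fuzzy backend is pure-Python O(n·m) per string
pair — adequate for interactive queries at the stored ontology sizes;
large production ontologies would motivate a compiled implementation behind
the same interface.

## Known limitations

* Synonyms are not indexed; a terminology's alternate descriptions must be
  flattened into metadata (display-only) or ingested as separate codes.
* BM25 and TF-IDF operate on labels averaging 2–4 tokens; length
  normalization has limited effect at that scale.
* The unit→domain lexicon of the built-in re-ranker covers common ICU units
  only; unlisted units contribute just their own tokens.
* The 96-hour window anchors at first observation; cohorts where admission
  time matters need an external anchor.
* Relative latencies of the three backends depend on implementation and
  hardware and are not a contract of this package.
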