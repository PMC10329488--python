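# annokit

Toolkit for annotating local EHR concepts with standard clinical ontology
codes.

Hospital EHR systems store measurements under locally invented codes
("220052: Mean pressure (MAP)") rather than standard terminology. Multisite
research requires mapping those local concepts onto standard ontologies such
as LOINC, SNOMED CT, ICD-10-CM, or the OMOP vocabulary — a manual, label-
matching-driven process. annokit implements the computational core of that
workflow for annotation tooling:

* **Ontology store** — release tables of any terminology are ingested into a
  single SQLite file under a uniform `(ontology, code, label, metadata)`
  schema via a declarative column map.
* **Three lexical ranking backends** scoring every term against a concept
  label:
  * *fuzzy* — Jaro-Winkler similarity over whole case-folded strings,
    `jw = j + ℓ·p·(1−j)` for Jaro similarity `j ≥ 0.7`, prefix length
    `ℓ ≤ 4`, `p = 0.1`;
  * *vector* — TF-IDF cosine (`tf` raw count, `idf = ln((1+N)/(1+df)) + 1`,
    L2-normalized sparse vectors);
  * *fulltext* — Okapi BM25 over an inverted index
    (`k1 = 1.2`, `b = 0.75`, `idf = ln(1 + (N−df+0.5)/(df+0.5))`).
* **Retrieve-then-rerank** — a high-recall first stage feeds a pluggable
  re-ranker (`RerankContext -> RerankResult`); the deterministic built-in
  re-ranker blends the retrieval score with token overlap against the
  concept label *and keywords derived from the concept's observed
  measurements* (its unit of measure and value kind), which is the signal
  that separates look-alike candidates.
* **Observation summaries** — numeric histograms, alphabetical textual
  tallies, automatic top-5 patient selection, and 96-hour per-patient time
  series from `chartevents`-shaped observation tables. A label like "MAP"
  is ambiguous (mean arterial vs mean airway pressure); values near
  90 mmHg vs 12 cmH2O are not.
* **Annotation sessions** — multi-code and multi-ontology assignments per
  concept, with lossless CSV/JSON export and import.
* **Synthetic fixtures** — seed-deterministic generators for all three
  inputs, so the whole pipeline runs with no licensed or protected data.

## Worked example

Generate a synthetic dataset, build the store, and rank candidates for the
ambiguous concept `220052` ("Mean pressure (MAP)", whose observed values are
arterial-pressure-like) with context re-ranking:

```bash
annokit fixtures --out fix --seed 7
annokit build-ontology --input fix/ontology.csv --ontology-id SYN \
    --version-label v1 --store store.db --metadata-col component
annokit rank --concept-label "Mean pressure (MAP)" --concept-code 220052 \
    --ontology SYN --backend fulltext --top-k 5 --store store.db \
    --rerank context --retrieve-k 20 --observations fix/observations.csv
```

```
rank	ontology	code	label	score	backend
1	SYN	SYN-0000	Mean arterial pressure	1.000000	fulltext
2	SYN	SYN-0001	Mean airway pressure	0.833333	fulltext
3	SYN	SYN-0022	Radial pressure	0.334410	fulltext
4	SYN	SYN-0046	Plasma pressure	0.334410	fulltext
5	SYN	SYN-0060	Peripheral pressure	0.334410	fulltext
```

Both expansions of "MAP" are retrieved, and the re-ranker puts *arterial*
first: the concept's observations (summarized below) carry the unit mmHg,
whose implied domain tokens overlap "arterial pressure" but not "airway".
The scores are the re-ranker's blend of normalized BM25 and token overlap;
1.000000 means both components were maximal. Running the same command for
concept `224697` (same label, cmH2O airway-pressure values) flips the top
two.

```bash
annokit summarize --observations fix/observations.csv --concept 220052
```

prints a JSON summary whose first fields are

```
"kind": "numeric", "n_obs": 1143, "unit": "mmHg", ...
```

— 1143 parsed values, classified numeric, modal unit mmHg — followed by the
50-bin histogram, the mean (~90), and the five patients with the most
observations of this concept.

The same operations are available as a library (`annokit.CandidateRanker`,
`annokit.retrieve_then_rerank`, `annokit.summarize`, ...); see the module
docstrings.

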