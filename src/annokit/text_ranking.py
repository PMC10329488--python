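"""Lexical ranking of ontology terms against free-text concept labels.

Three interchangeable backends score every term of a target ontology against
the label of a local source concept:

``fuzzy``
    Jaro-Winkler similarity between the whole case-folded query and each
    whole case-folded term label.  Character-level, so no tokenization; good
    at typos and word-order-preserving abbreviation.
``vector``
    TF-IDF bag-of-words vectors (raw term frequency, smoothed inverse
    document frequency ``ln((1+N)/(1+df)) + 1``, L2-normalized) compared by
    cosine similarity.
``fulltext``
    Okapi BM25 over an inverted index (``k1 = 1.2``, ``b = 0.75``,
    ``idf = ln(1 + (N - df + 0.5)/(df + 0.5))``), the ranking family used by
    SQLite FTS5 and Lucene.

All backends share one analyzer (Lucene-style: Unicode case fold, every
non-alphanumeric character becomes a space, split on whitespace, drop the
classic 33-word English stop list) and one tie-break: descending score,
then ascending code, so results are fully deterministic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
import numpy as np
import scipy.sparse as sp

from .errors import (
    ConfigurationError,
    EmptyOntologyError,
    ParameterError,
)
from .ontology_store import OntologyStore, OntologyTerm

__all__ = [
    "STOPWORDS",
    "analyze",
    "jaro",
    "jaro_winkler",
    "RankedCandidate",
    "TfidfIndex",
    "InvertedIndex",
    "build_tfidf_index",
    "query_tfidf",
    "build_fulltext_index",
    "query_fulltext",
    "CandidateRanker",
    "BACKENDS",
]

BACKENDS = ("fuzzy", "vector", "fulltext")

#: The classic 33-word Lucene/StopAnalyzer English stop list.
STOPWORDS = frozenset(
    """a an and are as at be but by for if in into is it no not of on or such
    that the their then there these they this to was will with""".split()
)

_NON_WORD = re.compile(r"[\W_]+", re.UNICODE)


def analyze(text: str) -> list[str]:
    """Tokenize ``text`` for indexing and querying.

    Case-folds, replaces every non-alphanumeric character (including
    underscore) with a space, splits on whitespace, and removes stop words.
    Deterministic; the empty string yields an empty token stream.

    >>> analyze("Heart Rate (bpm)")
    ['heart', 'rate', 'bpm']
    """
    return [t for t in _NON_WORD.sub(" ", text.casefold()).split() if t not in STOPWORDS]


# ---------------------------------------------------------------------------
# Jaro / Jaro-Winkler similarity
# ---------------------------------------------------------------------------

def jaro(s1: str, s2: str) -> float:
    """Jaro similarity in [0, 1].

    Characters match when equal and within a sliding window of
    ``floor(max(|s1|, |s2|) / 2) - 1`` positions.  With ``m`` matches and
    ``t`` = half the number of matched characters in different order, the
    similarity is ``(m/|s1| + m/|s2| + (m - t)/m) / 3``; it is 0 when no
    characters match.  Two empty strings are defined to be identical
    (similarity 1) — a documented convention, since the ratio form is
    undefined there.
    """
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(max(len1, len2) // 2 - 1, 0)
    matched1 = [False] * len1
    matched2 = [False] * len2
    m = 0
    for i, ch in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not matched2[j] and s2[j] == ch:
                matched1[i] = matched2[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # count positional mismatches between the two matched subsequences
    k = 0
    mismatches = 0
    for i in range(len1):
        if matched1[i]:
            while not matched2[k]:
                k += 1
            if s1[i] != s2[k]:
                mismatches += 1
            k += 1
    t = mismatches / 2.0
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler(
    s1: str,
    s2: str,
    prefix_scale: float = 0.1,
    max_prefix: int = 4,
    boost_threshold: float = 0.7,
) -> float:
    """Jaro-Winkler similarity: Jaro plus a common-prefix bonus.

    When the Jaro similarity ``j`` reaches ``boost_threshold``, the score
    becomes ``j + l * prefix_scale * (1 - j)`` where ``l`` is the length of
    the common prefix capped at ``max_prefix``.  ``prefix_scale`` must lie in
    [0, 0.25] so the result stays within [0, 1].
    """
    if not 0.0 <= prefix_scale <= 0.25:
        raise ParameterError(f"prefix_scale must be in [0, 0.25], got {prefix_scale}")
    j = jaro(s1, s2)
    if j < boost_threshold:
        return j
    prefix = 0
    for a, b in zip(s1, s2):
        if a != b or prefix >= max_prefix:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1.0 - j)


# ---------------------------------------------------------------------------
# Result and index containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedCandidate:
    """An ontology term with its backend-native score and 1-based rank."""

    term: OntologyTerm
    score: float
    rank: int
    backend: str


@dataclass(frozen=True)
class TfidfIndex:
    """Precomputed TF-IDF document matrix over one ontology's labels."""

    vocabulary: dict[str, int]
    idf: np.ndarray
    doc_vectors: sp.csr_matrix  # rows L2-normalized (or all-zero)
    doc_ids: list[tuple[str, str]]
    terms: list[OntologyTerm]


@dataclass(frozen=True)
class InvertedIndex:
    """Token -> postings structure over one ontology's analyzed labels."""

    postings: dict[str, list[tuple[int, int]]]  # token -> [(doc ordinal, tf)]
    doc_len: np.ndarray
    avg_len: float
    doc_ids: list[tuple[str, str]]
    terms: list[OntologyTerm]


def _top_k(scored: list[tuple[float, OntologyTerm]], k: int, backend: str) -> list[RankedCandidate]:
    """Deterministic top-k: descending score, ties by ascending code."""
    scored.sort(key=lambda sc: (-sc[0], sc[1].code))
    return [
        RankedCandidate(term=term, score=float(score), rank=i + 1, backend=backend)
        for i, (score, term) in enumerate(scored[:k])
    ]


# ---------------------------------------------------------------------------
# Index construction and querying (store-independent once built)
# ---------------------------------------------------------------------------

def _load_terms(store: OntologyStore, ontology_id: str) -> list[OntologyTerm]:
    terms = list(store.iter_terms(ontology_id))
    if not terms:
        raise EmptyOntologyError(f"ontology '{ontology_id}' has no terms to index")
    return terms


def build_tfidf_index(store: OntologyStore, ontology_id: str) -> TfidfIndex:
    """Build the TF-IDF matrix for one ontology (one document per label).

    ``tf`` is the raw in-label token count, ``idf = ln((1+N)/(1+df)) + 1``
    (always positive, so even a token present in every label still carries
    signal), and every nonempty document vector is L2-normalized so cosine
    similarity is a plain dot product.
    """
    terms = _load_terms(store, ontology_id)
    docs = [analyze(t.label) for t in terms]
    vocab = {tok: i for i, tok in enumerate(sorted({t for d in docs for t in d}))}
    n_docs = len(docs)
    df = np.zeros(len(vocab), dtype=np.int64)
    rows, cols, data = [], [], []
    for d, toks in enumerate(docs):
        counts: dict[int, int] = {}
        for tok in toks:
            counts[vocab[tok]] = counts.get(vocab[tok], 0) + 1
        for col in counts:
            df[col] += 1
        rows.extend([d] * len(counts))
        cols.extend(counts.keys())
        data.extend(counts.values())
    idf = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
    mat = sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), (rows, cols)),
        shape=(n_docs, len(vocab)),
    )
    mat = mat.multiply(idf[np.newaxis, :]).tocsr()
    norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
    inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
    mat = sp.diags(inv) @ mat
    return TfidfIndex(
        vocabulary=vocab,
        idf=idf,
        doc_vectors=mat.tocsr(),
        doc_ids=[(t.ontology_id, t.code) for t in terms],
        terms=terms,
    )


def query_tfidf(index: TfidfIndex, query: str, k: int) -> list[RankedCandidate]:
    """Rank documents by cosine similarity to the analyzed query.

    Query tokens absent from the index vocabulary are dropped; a query with
    no in-vocabulary tokens returns an empty list (distinct from an error).
    Only documents sharing at least one token (score > 0) are returned.
    """
    toks = analyze(query)
    qcounts: dict[int, int] = {}
    for tok in toks:
        col = index.vocabulary.get(tok)
        if col is not None:
            qcounts[col] = qcounts.get(col, 0) + 1
    if not qcounts:
        return []
    qvec = np.zeros(len(index.vocabulary))
    for col, tf in qcounts.items():
        qvec[col] = tf * index.idf[col]
    qvec /= np.linalg.norm(qvec)
    scores = index.doc_vectors @ qvec
    scored = [
        (float(scores[d]), index.terms[d])
        for d in np.nonzero(scores > 0)[0]
    ]
    return _top_k(scored, k, "vector")


def build_fulltext_index(store: OntologyStore, ontology_id: str) -> InvertedIndex:
    """Build the inverted index (postings + document lengths) for BM25."""
    terms = _load_terms(store, ontology_id)
    postings: dict[str, list[tuple[int, int]]] = {}
    doc_len = np.zeros(len(terms), dtype=np.int64)
    for d, term in enumerate(terms):
        toks = analyze(term.label)
        doc_len[d] = len(toks)
        counts: dict[str, int] = {}
        for tok in toks:
            counts[tok] = counts.get(tok, 0) + 1
        for tok, tf in counts.items():
            postings.setdefault(tok, []).append((d, tf))
    avg_len = float(doc_len.mean()) if len(terms) else 0.0
    return InvertedIndex(
        postings=postings,
        doc_len=doc_len,
        avg_len=avg_len,
        doc_ids=[(t.ontology_id, t.code) for t in terms],
        terms=terms,
    )


_BM25_K1 = 1.2
_BM25_B = 0.75


def query_fulltext(index: InvertedIndex, query: str, k: int) -> list[RankedCandidate]:
    """Okapi BM25 ranking; documents matching no query token are excluded.

    Each query token occurrence contributes
    ``idf * tf * (k1 + 1) / (tf + k1 * (1 - b + b * dl / avgdl))``, i.e.
    repeated query tokens weight their term proportionally.
    """
    toks = analyze(query)
    if not toks:
        return []
    n_docs = len(index.terms)
    scores: dict[int, float] = {}
    for tok in toks:
        plist = index.postings.get(tok)
        if plist is None:
            continue
        df = len(plist)
        idf = math.log(1.0 + (n_docs - df + 0.5) / (df + 0.5))
        for d, tf in plist:
            denom = tf + _BM25_K1 * (
                1.0 - _BM25_B + _BM25_B * index.doc_len[d] / index.avg_len
            )
            scores[d] = scores.get(d, 0.0) + idf * tf * (_BM25_K1 + 1.0) / denom
    scored = [(s, index.terms[d]) for d, s in scores.items()]
    return _top_k(scored, k, "fulltext")


# ---------------------------------------------------------------------------
# Store-bound ranking facade
# ---------------------------------------------------------------------------

class CandidateRanker:
    """Rank ontology terms against concept labels using a chosen backend.

    Vector and full-text indexes are built on demand and cached per
    ontology; a cache entry is invalidated automatically when the ontology's
    term count or version label changes (i.e. after re-ingestion).
    """

    def __init__(self, store: OntologyStore):
        self.store = store
        self._tfidf: dict[str, tuple[tuple[str, int], TfidfIndex]] = {}
        self._fulltext: dict[str, tuple[tuple[str, int], InvertedIndex]] = {}

    def _fingerprint(self, ontology_id: str) -> tuple[str, int]:
        ont = self.store.get_ontology(ontology_id)
        return (ont.version_label, ont.term_count)

    def tfidf_index(self, ontology_id: str) -> TfidfIndex:
        fp = self._fingerprint(ontology_id)
        cached = self._tfidf.get(ontology_id)
        if cached is None or cached[0] != fp:
            self._tfidf[ontology_id] = (fp, build_tfidf_index(self.store, ontology_id))
        return self._tfidf[ontology_id][1]

    def fulltext_index(self, ontology_id: str) -> InvertedIndex:
        fp = self._fingerprint(ontology_id)
        cached = self._fulltext.get(ontology_id)
        if cached is None or cached[0] != fp:
            self._fulltext[ontology_id] = (fp, build_fulltext_index(self.store, ontology_id))
        return self._fulltext[ontology_id][1]

    def rank_fuzzy(self, query: str, ontology_id: str, k: int) -> list[RankedCandidate]:
        """Jaro-Winkler over whole case-folded strings, every term scored.

        ``k`` larger than the term count simply returns all terms ranked.
        """
        q = query.casefold()
        terms = _load_terms(self.store, ontology_id)
        scored = [(jaro_winkler(q, t.label.casefold()), t) for t in terms]
        return _top_k(scored, k, "fuzzy")

    def rank_candidates(
        self,
        concept,
        ontology_id: str,
        backend: str,
        k: int,
    ) -> list[RankedCandidate]:
        """Dispatch to the chosen backend using the concept's label as query.

        ``concept`` may be a ``SourceConcept`` (its ``label`` is used) or a
        plain string.
        """
        query = getattr(concept, "label", concept)
        if backend == "fuzzy":
            return self.rank_fuzzy(query, ontology_id, k)
        if backend == "vector":
            return query_tfidf(self.tfidf_index(ontology_id), query, k)
        if backend == "fulltext":
            return query_fulltext(self.fulltext_index(ontology_id), query, k)
        raise ConfigurationError(
            f"unknown backend '{backend}'; expected one of {BACKENDS}"
        )
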