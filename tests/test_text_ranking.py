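"""Analyzer, similarity measures, and the three ranking backends."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annokit.errors import ConfigurationError, EmptyOntologyError, ParameterError
from annokit.text_ranking import (
    BACKENDS,
    analyze,
    build_fulltext_index,
    build_tfidf_index,
    jaro,
    jaro_winkler,
    query_fulltext,
    query_tfidf,
)
from conftest import ONTOLOGY_ID
from reference_similarity import reference_jaro_winkler

# ---------------------------------------------------------------------------
# Analyzer
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Heart Rate (bpm)", ["heart", "rate", "bpm"]),
        ("", []),
        ("the of", []),  # "of" is a stop word, "the" is a stop word
        ("Systolic Blood-Pressure!", ["systolic", "blood", "pressure"]),
        ("SpO2 (%)", ["spo2"]),
        ("a An AND with", []),
    ],
)
def test_analyze(text, expected):
    assert analyze(text) == expected


def test_analyze_is_idempotent_on_its_own_output():
    toks = analyze("Left Lower Lobe (LLL) lung sounds")
    assert analyze(" ".join(toks)) == toks


# ---------------------------------------------------------------------------
# Jaro / Jaro-Winkler
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "s1,s2,expected",
    [
        ("MARTHA", "MARHTA", 0.9444444444444445),  # m=6, t=1, by hand
        ("abc", "abc", 1.0),
        ("abc", "xyz", 0.0),
        ("", "", 1.0),  # documented convention
        ("", "a", 0.0),
    ],
)
def test_jaro_known_values(s1, s2, expected):
    assert jaro(s1, s2) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "s1,s2,expected",
    [
        ("MARTHA", "MARHTA", 0.9611111111111111),  # 0.9444 + 3*0.1*(1-0.9444)
        ("DWAYNE", "DUANE", 0.84),  # jaro 0.8222, prefix length 1
        ("x", "x", 1.0),
    ],
)
def test_jaro_winkler_known_values(s1, s2, expected):
    assert jaro_winkler(s1, s2) == pytest.approx(expected, abs=1e-12)


def test_jaro_winkler_rejects_out_of_range_prefix_scale():
    with pytest.raises(ParameterError):
        jaro_winkler("a", "b", prefix_scale=0.3)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.text(alphabet="abcdefg ", max_size=20),
    st.text(alphabet="abcdefg ", max_size=20),
)
def test_similarity_invariants(s1, s2):
    """Symmetry, bounds, identity, and the Winkler boost direction."""
    j = jaro(s1, s2)
    jw = jaro_winkler(s1, s2)
    assert 0.0 <= j <= 1.0
    assert 0.0 <= jw <= 1.0
    assert j == pytest.approx(jaro(s2, s1), abs=1e-12)
    assert jw == pytest.approx(jaro_winkler(s2, s1), abs=1e-12)
    assert jw >= j - 1e-12
    if s1 == s2:
        assert j == 1.0


def test_jaro_winkler_matches_independent_reference():
    """Oracle equivalence on 1000 seeded random string pairs."""
    rng = random.Random(20230708)
    alphabet = "abcdefghij -"
    for _ in range(1000):
        s1 = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 20)))
        s2 = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 20)))
        assert abs(jaro_winkler(s1, s2) - reference_jaro_winkler(s1, s2)) < 1e-9


# ---------------------------------------------------------------------------
# TF-IDF backend
# ---------------------------------------------------------------------------


def test_tfidf_idf_closed_forms(store_factory):
    one_doc = store_factory([("c1", "heart rate")], ontology_id="ONE")
    idx = build_tfidf_index(one_doc, "ONE")
    # N = df = 1 for every token: idf = ln(2/2) + 1 = 1
    assert np.allclose(idx.idf, 1.0)

    uni = store_factory(
        [("c1", "heart rate"), ("c2", "heart sounds"), ("c3", "heart output")],
        ontology_id="UNI",
    )
    idx = build_tfidf_index(uni, "UNI")
    assert idx.idf[idx.vocabulary["heart"]] == pytest.approx(1.0)  # df = N
    assert idx.idf[idx.vocabulary["rate"]] > 1.0


def test_tfidf_matches_hand_computation(store_factory):
    """3-doc toy corpus weights equal tf * (ln((1+N)/(1+df)) + 1), L2-normed."""
    st_ = store_factory(
        [("c1", "heart rate"), ("c2", "respiratory rate"), ("c3", "heart sounds")],
        ontology_id="TOY3",
    )
    idx = build_tfidf_index(st_, "TOY3")
    idf = {tok: math.log(4 / (1 + df)) + 1 for tok, df in
           [("heart", 2), ("rate", 2), ("respiratory", 1), ("sounds", 1)]}
    for tok, expected in idf.items():
        assert idx.idf[idx.vocabulary[tok]] == pytest.approx(expected)
    # doc c1 = (heart, rate): both weights idf/sqrt(2*idf^2) since idfs equal
    row = idx.doc_vectors[0].toarray().ravel()
    expected = idf["heart"] / math.sqrt(2 * idf["heart"] ** 2)
    assert row[idx.vocabulary["heart"]] == pytest.approx(expected)
    assert row[idx.vocabulary["rate"]] == pytest.approx(expected)


def test_tfidf_matches_sklearn(store):
    """Cross-check the whole matrix against scikit-learn's vectorizer."""
    sklearn_text = pytest.importorskip("sklearn.feature_extraction.text")
    idx = build_tfidf_index(store, ONTOLOGY_ID)
    labels = [t.label for t in idx.terms]
    vec = sklearn_text.TfidfVectorizer(analyzer=analyze, norm="l2", smooth_idf=True)
    ref = vec.fit_transform(labels)
    # align columns by token
    order = [idx.vocabulary[tok] for tok in vec.get_feature_names_out()]
    ours = idx.doc_vectors[:, order]
    assert np.allclose(ours.toarray(), ref.toarray(), atol=1e-9)


def test_tfidf_doc_vectors_unit_norm(store):
    idx = build_tfidf_index(store, ONTOLOGY_ID)
    norms = np.sqrt(np.asarray(idx.doc_vectors.multiply(idx.doc_vectors).sum(axis=1)).ravel())
    nonzero = norms[norms > 0]
    assert np.allclose(nonzero, 1.0, atol=1e-9)


def test_tfidf_query_behaviour(store_factory):
    st_ = store_factory(
        [("c1", "heart rate"), ("c2", "respiratory rate"), ("c3", "heart sounds")],
        ontology_id="TOY3",
    )
    idx = build_tfidf_index(st_, "TOY3")
    # exact unique label ranks first with cosine 1
    res = query_tfidf(idx, "respiratory rate", 3)
    assert res[0].term.code == "c2"
    assert res[0].score == pytest.approx(1.0)
    # out-of-vocabulary query: empty result, not an error
    assert query_tfidf(idx, "zzz qqq", 3) == []
    # brute-force cosine oracle for "heart"
    res = query_tfidf(idx, "heart", 3)
    dense = idx.doc_vectors.toarray()
    q = np.zeros(dense.shape[1])
    q[idx.vocabulary["heart"]] = 1.0
    scores = dense @ q
    expected = sorted(
        [(s, idx.terms[d].code) for d, s in enumerate(scores) if s > 0],
        key=lambda sc: (-sc[0], sc[1]),
    )
    assert [(c.score, c.term.code) for c in res] == pytest.approx(expected)


def test_empty_ontology_cannot_be_indexed(tmp_path):
    # every row is skipped (empty labels), leaving an ontology with no terms
    from annokit.ontology_store import OntologyStore

    path = tmp_path / "empty.csv"
    path.write_text("code,label\nc1,\nc2,\n", encoding="utf-8")
    with OntologyStore() as st_:
        report = st_.ingest_ontology(path, {"code": "code", "label": "label"}, "EMPTY")
        assert report.n_ingested == 0 and report.n_skipped == 2
        with pytest.raises(EmptyOntologyError):
            build_tfidf_index(st_, "EMPTY")
        with pytest.raises(EmptyOntologyError):
            build_fulltext_index(st_, "EMPTY")


# ---------------------------------------------------------------------------
# BM25 backend
# ---------------------------------------------------------------------------


def test_inverted_index_structure(store_factory):
    st_ = store_factory(
        [("c1", "heart rate"), ("c2", "heart sounds")], ontology_id="TWO"
    )
    idx = build_fulltext_index(st_, "TWO")
    assert len(idx.postings["heart"]) == 2
    # doc_len equals analyzed token count; postings tf sums to doc_len
    for d in range(2):
        total = sum(tf for tok in idx.postings for dd, tf in idx.postings[tok] if dd == d)
        assert total == idx.doc_len[d]
    assert idx.avg_len == pytest.approx(2.0)


def test_fulltext_doc_len_applies_analyzer(store_factory):
    st_ = store_factory([("c1", "heart rate (bpm)")], ontology_id="ONE")
    idx = build_fulltext_index(st_, "ONE")
    assert idx.doc_len[0] == 3


def _brute_bm25(labels, query_tokens, k1=1.2, b=0.75):
    docs = [analyze(lbl) for lbl in labels]
    n = len(docs)
    avg = sum(len(d) for d in docs) / n
    scores = []
    for d in docs:
        s = 0.0
        for tok in query_tokens:
            tf = d.count(tok)
            if tf == 0:
                continue
            df = sum(1 for dd in docs if tok in dd)
            idf = math.log(1 + (n - df + 0.5) / (df + 0.5))
            s += idf * tf * (k1 + 1) / (tf + k1 * (1 - b + b * len(d) / avg))
        scores.append(s)
    return scores


def test_bm25_matches_brute_force(store_factory):
    labels = ["heart rate", "respiratory rate", "heart sounds", "blood pressure"]
    st_ = store_factory(list(zip("c1 c2 c3 c4".split(), labels)), ontology_id="FOUR")
    idx = build_fulltext_index(st_, "FOUR")
    res = query_fulltext(idx, "heart rate", 4)
    brute = _brute_bm25(labels, ["heart", "rate"])
    expected = sorted(
        [(s, code) for s, code in zip(brute, "c1 c2 c3 c4".split()) if s > 0],
        key=lambda sc: (-sc[0], sc[1]),
    )
    assert [(c.score, c.term.code) for c in res] == pytest.approx(expected)
    # a doc containing every query token beats every non-matching doc
    assert res[0].term.code == "c1"
    assert all(c.term.code != "c4" for c in res)  # zero-match docs excluded


def test_bm25_single_rare_token(store_factory):
    st_ = store_factory(
        [("c1", "heart rate"), ("c2", "blood pressure"), ("c3", "lung sounds")],
        ontology_id="RARE",
    )
    idx = build_fulltext_index(st_, "RARE")
    res = query_fulltext(idx, "pressure", 3)
    assert len(res) == 1 and res[0].term.code == "c2"


def test_bm25_stopword_only_query_is_empty(store_factory):
    st_ = store_factory([("c1", "heart rate")], ontology_id="ONE")
    idx = build_fulltext_index(st_, "ONE")
    assert query_fulltext(idx, "the of and", 3) == []


# ---------------------------------------------------------------------------
# Fuzzy backend and dispatch
# ---------------------------------------------------------------------------


def test_rank_fuzzy_identity_and_truncation(store_factory):
    st_ = store_factory(
        [("c1", "Heart rate"), ("c2", "Blood pressure"), ("c3", "Lung sounds")],
        ontology_id="TOY",
    )
    from annokit.text_ranking import CandidateRanker

    ranker = CandidateRanker(st_)
    res = ranker.rank_fuzzy("Heart rate", "TOY", 1)
    assert res[0].term.code == "c1" and res[0].score == pytest.approx(1.0)
    # k beyond the term count returns everything ranked
    assert len(ranker.rank_fuzzy("heart", "TOY", 5)) == 3


def test_rank_fuzzy_equals_brute_force(ranker, store):
    res = ranker.rank_fuzzy("heart rate", ONTOLOGY_ID, 10)
    brute = sorted(
        (
            (jaro_winkler("heart rate", t.label.casefold()), t.code)
            for t in store.iter_terms(ONTOLOGY_ID)
        ),
        key=lambda sc: (-sc[0], sc[1]),
    )[:10]
    assert [(c.score, c.term.code) for c in res] == pytest.approx(brute)


def test_rank_candidates_dispatch(ranker):
    for backend in BACKENDS:
        res = ranker.rank_candidates("heart rate", ONTOLOGY_ID, backend, 5)
        assert res and all(c.backend == backend for c in res)
        assert [c.rank for c in res] == list(range(1, len(res) + 1))
        assert all(res[i].score >= res[i + 1].score for i in range(len(res) - 1))
    with pytest.raises(ConfigurationError):
        ranker.rank_candidates("x", ONTOLOGY_ID, "semantic", 5)


def test_ambiguous_concept_retrieved_by_all_backends(ranker):
    """Both expansions of the ambiguous "MAP" concept appear in the top 5."""
    wanted = {"Mean arterial pressure", "Mean airway pressure"}
    for backend in BACKENDS:
        res = ranker.rank_candidates("Mean pressure (MAP)", ONTOLOGY_ID, backend, 5)
        labels = {c.term.label for c in res}
        assert wanted <= labels, f"{backend} missed {wanted - labels}"


def test_equal_scores_break_ties_by_ascending_code(store_factory):
    st_ = store_factory(
        [("b2", "heart rate"), ("a1", "heart rate")], ontology_id="TIE"
    )
    idx = build_fulltext_index(st_, "TIE")
    res = query_fulltext(idx, "heart", 2)
    assert [c.term.code for c in res] == ["a1", "b2"]
    assert res[0].score == pytest.approx(res[1].score)
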