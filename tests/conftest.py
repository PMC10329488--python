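"""Shared fixtures: one synthetic dataset (seed 7) reused across the suite."""

import csv

import pytest

from annokit import observation_context as obs
from annokit.fixtures import FixtureSpec, write_fixture_set
from annokit.ontology_store import OntologyStore
from annokit.text_ranking import CandidateRanker

ONTOLOGY_ID = "SYN"


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec()  # defaults: 200 terms, 8 concepts, 100 patients, seed 7


@pytest.fixture(scope="session")
def fixture_paths(fixture_spec, tmp_path_factory):
    return write_fixture_set(fixture_spec, tmp_path_factory.mktemp("fixtures"))


@pytest.fixture(scope="session")
def store(fixture_paths):
    st = OntologyStore()
    st.ingest_ontology(
        fixture_paths["ontology"],
        {"code": "code", "label": "label", "component": "component", "system": "system"},
        ONTOLOGY_ID,
        "v1",
    )
    yield st
    st.close()


@pytest.fixture(scope="session")
def ranker(store):
    return CandidateRanker(store)


@pytest.fixture(scope="session")
def observations(fixture_paths):
    return obs.load_observations(fixture_paths["observations"])


@pytest.fixture
def store_factory(tmp_path):
    """Build an in-memory store from (code, label) rows via a real CSV file."""
    opened = []

    def make(rows, ontology_id="TOY", version="v1"):
        path = tmp_path / f"{ontology_id}_{len(opened)}.csv"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "label"])
            writer.writerows(rows)
        st = OntologyStore()
        st.ingest_ontology(path, {"code": "code", "label": "label"}, ontology_id, version)
        opened.append(st)
        return st

    yield make
    for st in opened:
        st.close()
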