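"""SQLite-backed store for clinical ontology terms.

Release tables from different terminology systems (LOINC, SNOMED CT,
ICD-10-CM, OMOP, ...) ship with different column layouts.  The store
normalizes them into a single uniform schema — ``(ontology_id, code, label,
metadata)`` — so the search and annotation layers never see release-specific
structure.  The mapping from a release file's columns onto that schema is
supplied declaratively by the caller (``column_map``), which is how new
terminologies are supported without code changes.

Schema (one SQLite file, UTF-8 text throughout)::

    ontologies(id TEXT PRIMARY KEY, version_label TEXT, position INTEGER)
    terms(ontology_id TEXT, code TEXT, label TEXT, metadata TEXT(JSON),
          PRIMARY KEY (ontology_id, code))

Labels are stored verbatim — no case folding or trimming at rest — so that
what the annotator sees is exactly what the release file said.  Codes are
case-sensitive identifiers.
"""

from __future__ import annotations

import json
import sqlite3
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .errors import (
    DuplicateCodeError,
    InputError,
    SchemaError,
    TermNotFoundError,
    UnknownOntologyError,
)

__all__ = [
    "Ontology",
    "OntologyTerm",
    "IngestReport",
    "OntologyStore",
    "detect_delimiter",
]


@dataclass(frozen=True)
class Ontology:
    """One ingested terminology system."""

    id: str
    version_label: str
    term_count: int


@dataclass(frozen=True)
class OntologyTerm:
    """One code + primary description record, with display metadata."""

    ontology_id: str
    code: str
    label: str
    metadata: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class IngestReport:
    """Outcome of one ingestion: the resulting ontology plus row accounting."""

    ontology: Ontology
    n_ingested: int
    n_skipped: int


def detect_delimiter(header_line: str) -> str:
    """Delimited-text inputs are comma- or tab-separated; a tab anywhere in
    the header line wins (release exports never tab-pad a comma header)."""
    return "\t" if "\t" in header_line else ","


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"input file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise InputError(f"input file is empty: {path}")
    sep = detect_delimiter(header)
    # keep_default_na=False: empty cells stay "", labels stay verbatim strings
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")


class OntologyStore:
    """Open (or create) a single-file relational term store.

    Parameters
    ----------
    path:
        Filesystem path of the SQLite database, or ``":memory:"`` for an
        ephemeral store.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._create_schema()

    def _create_schema(self) -> None:
        with self._conn:
            self._conn.execute(
                "CREATE TABLE IF NOT EXISTS ontologies ("
                " id TEXT PRIMARY KEY,"
                " version_label TEXT NOT NULL,"
                " position INTEGER NOT NULL)"
            )
            self._conn.execute(
                "CREATE TABLE IF NOT EXISTS terms ("
                " ontology_id TEXT NOT NULL REFERENCES ontologies(id),"
                " code TEXT NOT NULL,"
                " label TEXT NOT NULL,"
                " metadata TEXT NOT NULL DEFAULT '{}',"
                " PRIMARY KEY (ontology_id, code))"
            )

    # -- lifecycle -----------------------------------------------------------

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "OntologyStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- ingestion -----------------------------------------------------------

    def ingest_ontology(
        self,
        table_path: str | Path,
        column_map: Mapping[str, str],
        ontology_id: str,
        version_label: str = "",
    ) -> IngestReport:
        """Load one release table into the store under ``ontology_id``.

        ``column_map`` maps source column names to roles: exactly one column
        must map to ``"code"`` and one to ``"label"``; every other entry
        names a metadata attribute stored alongside the term (in mapping
        order).  Rows with an empty (or whitespace-only) code or label are
        skipped and counted.  A duplicate code within the file rejects the
        whole file.  Re-ingesting an existing ontology id replaces its terms.
        """
        frame = _read_delimited(table_path)

        roles = Counter(column_map.values())
        if roles.get("code", 0) != 1 or roles.get("label", 0) != 1:
            raise SchemaError(
                "column_map must assign exactly one 'code' and one 'label' column"
            )
        missing = [col for col in column_map if col not in frame.columns]
        if missing:
            raise SchemaError(
                f"mapped column(s) absent from header of {table_path}: {missing}"
            )

        code_col = next(c for c, r in column_map.items() if r == "code")
        label_col = next(c for c, r in column_map.items() if r == "label")
        meta_cols = [(c, r) for c, r in column_map.items() if r not in ("code", "label")]

        rows: list[tuple[str, str, str]] = []
        n_skipped = 0
        for rec in frame.itertuples(index=False):
            rec = rec._asdict() if hasattr(rec, "_asdict") else dict(zip(frame.columns, rec))
            code = rec[code_col]
            label = rec[label_col]
            if not str(code).strip() or not str(label).strip():
                n_skipped += 1
                continue
            metadata = {role: str(rec[col]) for col, role in meta_cols}
            rows.append((str(code), str(label), json.dumps(metadata, ensure_ascii=False)))

        counts = Counter(code for code, _, _ in rows)
        dupes = sorted(code for code, n in counts.items() if n > 1)
        if dupes:
            raise DuplicateCodeError(
                f"duplicate codes in {table_path} for ontology '{ontology_id}': {dupes}",
                codes=dupes,
            )

        with self._conn:
            cur = self._conn.execute(
                "SELECT position FROM ontologies WHERE id = ?", (ontology_id,)
            ).fetchone()
            if cur is None:
                nxt = self._conn.execute(
                    "SELECT COALESCE(MAX(position), -1) + 1 FROM ontologies"
                ).fetchone()[0]
                self._conn.execute(
                    "INSERT INTO ontologies (id, version_label, position) VALUES (?, ?, ?)",
                    (ontology_id, version_label, nxt),
                )
            else:
                self._conn.execute(
                    "UPDATE ontologies SET version_label = ? WHERE id = ?",
                    (version_label, ontology_id),
                )
            self._conn.execute("DELETE FROM terms WHERE ontology_id = ?", (ontology_id,))
            self._conn.executemany(
                "INSERT INTO terms (ontology_id, code, label, metadata) VALUES (?, ?, ?, ?)",
                [(ontology_id, c, l, m) for c, l, m in rows],
            )

        ontology = Ontology(ontology_id, version_label, len(rows))
        return IngestReport(ontology=ontology, n_ingested=len(rows), n_skipped=n_skipped)

    # -- lookups -------------------------------------------------------------

    def has_ontology(self, ontology_id: str) -> bool:
        row = self._conn.execute(
            "SELECT 1 FROM ontologies WHERE id = ?", (ontology_id,)
        ).fetchone()
        return row is not None

    def get_ontology(self, ontology_id: str) -> Ontology:
        row = self._conn.execute(
            "SELECT id, version_label FROM ontologies WHERE id = ?", (ontology_id,)
        ).fetchone()
        if row is None:
            raise UnknownOntologyError(f"unknown ontology: '{ontology_id}'")
        return Ontology(row[0], row[1], self.term_count(ontology_id))

    def term_count(self, ontology_id: str) -> int:
        return self._conn.execute(
            "SELECT COUNT(*) FROM terms WHERE ontology_id = ?", (ontology_id,)
        ).fetchone()[0]

    def get_term(self, ontology_id: str, code: str) -> OntologyTerm:
        """Exact, case-sensitive lookup of one term.

        An unknown ontology id and an unknown code raise distinct errors so
        configuration mistakes are not mistaken for missing codes.
        """
        if not self.has_ontology(ontology_id):
            raise UnknownOntologyError(f"unknown ontology: '{ontology_id}'")
        row = self._conn.execute(
            "SELECT code, label, metadata FROM terms WHERE ontology_id = ? AND code = ?",
            (ontology_id, code),
        ).fetchone()
        if row is None:
            raise TermNotFoundError(f"no term '{code}' in ontology '{ontology_id}'")
        return OntologyTerm(ontology_id, row[0], row[1], json.loads(row[2]))

    def list_ontologies(self) -> list[Ontology]:
        rows = self._conn.execute(
            "SELECT id, version_label FROM ontologies ORDER BY position"
        ).fetchall()
        return [Ontology(oid, ver, self.term_count(oid)) for oid, ver in rows]

    def iter_terms(self, ontology_id: str) -> Iterator[OntologyTerm]:
        """All terms of one ontology in ascending code order (deterministic)."""
        if not self.has_ontology(ontology_id):
            raise UnknownOntologyError(f"unknown ontology: '{ontology_id}'")
        cur = self._conn.execute(
            "SELECT code, label, metadata FROM terms WHERE ontology_id = ? ORDER BY code",
            (ontology_id,),
        )
        for code, label, metadata in cur:
            yield OntologyTerm(ontology_id, code, label, json.loads(metadata))
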