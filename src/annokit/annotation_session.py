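"""Annotation workflow state: concept queue, assignments, export/import.

A session holds one annotation record per source concept.  An annotation
maps the concept to one or more (ontology, code) pairs — multiple codes
when no single term covers the concept, and pairs from different
terminologies simultaneously when desired.  Re-annotating replaces the
previous assignment (interactive correction semantics); a concept with no
adequate standard term is marked skipped instead.

Exports are deterministic and lossless: CSV writes one row per (concept,
assignment) pair, JSON groups assignments per concept under a versioned
schema; ``import_annotations`` is the exact inverse of either format, which
is also how independently produced exports can be merged.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    InputError,
    NotFoundError,
    ParseError,
    SchemaError,
    ValidationError,
)
from .ontology_store import OntologyStore, detect_delimiter
from .text_ranking import BACKENDS

__all__ = [
    "SourceConcept",
    "Annotation",
    "Config",
    "Session",
    "create_session",
    "annotate",
    "skip",
    "export_annotations",
    "import_annotations",
]

SCHEMA_VERSION = 1

_CSV_HEADER = ["concept_code", "status", "annotated_at", "ontology_id", "ontology_code"]
_STATUSES = ("pending", "annotated", "skipped")


@dataclass(frozen=True)
class SourceConcept:
    """A local EHR concept (opaque code + free-text label) awaiting mapping."""

    code: str
    label: str
    value_kind: str = "unknown"  # numeric | textual | unknown


@dataclass(frozen=True)
class Annotation:
    """The (possibly multi-code, multi-ontology) mapping of one concept."""

    concept_code: str
    assignments: tuple[tuple[str, str], ...] = ()
    status: str = "pending"
    annotated_at: str | None = None  # ISO 8601, set when status becomes annotated


@dataclass
class Config:
    """Launch configuration (YAML on disk, keys exactly as the field names)."""

    ontology_ids: list[str]
    backend: str = "fulltext"
    top_k: int = 10
    retrieve_k: int = 50
    window_hours: float = 96.0
    top_n_patients: int = 5
    store_path: str | None = None
    concepts_path: str | None = None
    observations_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.ontology_ids:
            raise ConfigurationError("config must name at least one ontology id")
        if self.backend not in BACKENDS:
            raise ConfigurationError(
                f"unknown backend '{self.backend}'; expected one of {BACKENDS}"
            )
        if self.retrieve_k < self.top_k:
            raise ConfigurationError(
                f"retrieve_k ({self.retrieve_k}) must be >= top_k ({self.top_k})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        path = Path(path)
        if not path.is_file():
            raise InputError(f"config file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config root must be a mapping: {path}")
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "ontology_ids" not in raw:
            raise ConfigurationError("config must define ontology_ids")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class Session:
    """Ordered concept queue plus one annotation per concept."""

    concepts: list[SourceConcept]
    annotations: dict[str, Annotation]
    config: Config
    cursor: int = 0


# ---------------------------------------------------------------------------
# Session operations
# ---------------------------------------------------------------------------

def create_session(
    concepts_path: str | Path,
    config: Config,
    store: OntologyStore | None = None,
) -> Session:
    """Read the source-concept table and start a fresh session.

    The table must have ``code`` and ``label`` columns; duplicate concept
    codes reject the file.  When a store is supplied (or reachable through
    ``config.store_path``), every configured ontology must already be
    ingested.
    """
    path = Path(concepts_path)
    if not path.is_file():
        raise InputError(f"concepts file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise InputError(f"concepts file is empty: {path}")
    sep = detect_delimiter(header)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in ("code", "label"):
        if col not in frame.columns:
            raise SchemaError(f"concepts file lacks required column '{col}': {path}")
    if len(frame) == 0:
        raise InputError(f"concepts file has no rows: {path}")
    dupes = sorted(frame["code"][frame["code"].duplicated()].unique())
    if dupes:
        raise ValidationError(f"duplicate concept code(s) in {path}: {dupes}")

    owns_store = False
    if store is None and config.store_path:
        store = OntologyStore(config.store_path)
        owns_store = True
    try:
        if store is not None:
            for oid in config.ontology_ids:
                if not store.has_ontology(oid):
                    raise ConfigurationError(
                        f"configured ontology '{oid}' is not in the store"
                    )
    finally:
        if owns_store and store is not None:
            store.close()

    concepts = [
        SourceConcept(code=row.code, label=row.label)
        for row in frame.itertuples(index=False)
    ]
    annotations = {c.code: Annotation(concept_code=c.code) for c in concepts}
    return Session(concepts=concepts, annotations=annotations, config=config)


def annotate(
    session: Session,
    concept_code: str,
    assignments: Sequence[tuple[str, str]],
    store: OntologyStore,
    now: datetime | None = None,
) -> Session:
    """Assign one or more resolvable (ontology, code) pairs to a concept.

    Replaces any previous annotation.  Every pair must resolve through the
    store's ``get_term``; an empty assignment list is an error (use
    :func:`skip` to record that no adequate term exists).
    """
    if concept_code not in session.annotations:
        raise NotFoundError(f"concept '{concept_code}' is not in this session")
    pairs = [(str(o), str(c)) for o, c in assignments]
    if not pairs:
        raise ValidationError("empty assignments: use skip() to mark a concept unmappable")
    seen = set()
    for pair in pairs:
        if pair in seen:
            raise ValidationError(f"duplicate assignment {pair}")
        seen.add(pair)
        try:
            store.get_term(*pair)
        except NotFoundError as exc:
            raise ValidationError(f"unresolvable assignment {pair}: {exc}") from exc
    stamp = (now or datetime.now(timezone.utc)).isoformat()
    session.annotations[concept_code] = Annotation(
        concept_code=concept_code,
        assignments=tuple(pairs),
        status="annotated",
        annotated_at=stamp,
    )
    return session


def skip(session: Session, concept_code: str) -> Session:
    """Mark a concept as having no adequate standard term; clears assignments."""
    if concept_code not in session.annotations:
        raise NotFoundError(f"concept '{concept_code}' is not in this session")
    session.annotations[concept_code] = Annotation(
        concept_code=concept_code, status="skipped"
    )
    return session


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def _ordered_annotations(session: Session) -> list[Annotation]:
    return [session.annotations[c.code] for c in session.concepts]


def export_annotations(session: Session, path: str | Path, format: str = "csv") -> Path:
    """Write the session's annotations to ``path`` (partial sessions allowed).

    CSV: one row per (concept, assignment) pair; pending/skipped concepts
    get one marker row with empty assignment columns.  JSON: one record per
    concept with its assignment list, under a ``schema_version`` field.
    Ordering follows the session's concept order, then assignment order.
    """
    path = Path(path)
    annotations = _ordered_annotations(session)
    if format == "csv":
        try:
            fh = open(path, "w", encoding="utf-8", newline="")
        except OSError as exc:
            raise InputError(f"cannot write to {path}: {exc}") from exc
        with fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
            writer.writerow(_CSV_HEADER)
            for ann in annotations:
                stamp = ann.annotated_at or ""
                if ann.assignments:
                    for oid, code in ann.assignments:
                        writer.writerow([ann.concept_code, ann.status, stamp, oid, code])
                else:
                    writer.writerow([ann.concept_code, ann.status, stamp, "", ""])
    elif format == "json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "annotations": [
                {
                    "concept_code": ann.concept_code,
                    "status": ann.status,
                    "annotated_at": ann.annotated_at,
                    "assignments": [
                        {"ontology_id": oid, "code": code} for oid, code in ann.assignments
                    ],
                }
                for ann in annotations
            ],
        }
        try:
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(doc, fh, indent=2, ensure_ascii=False)
                fh.write("\n")
        except OSError as exc:
            raise InputError(f"cannot write to {path}: {exc}") from exc
    else:
        raise ConfigurationError(f"unknown export format '{format}' (csv or json)")
    return path


def _import_csv(path: Path) -> dict[str, Annotation]:
    out: dict[str, Annotation] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if header != _CSV_HEADER:
            raise ParseError(f"{path}: line 1: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_CSV_HEADER):
                raise ParseError(f"{path}: line {lineno}: expected {len(_CSV_HEADER)} fields")
            concept_code, status, stamp, oid, code = row
            if status not in _STATUSES:
                raise ParseError(f"{path}: line {lineno}: unknown status '{status}'")
            prev = out.get(concept_code)
            assignments = list(prev.assignments) if prev else []
            if oid or code:
                assignments.append((oid, code))
            out[concept_code] = Annotation(
                concept_code=concept_code,
                assignments=tuple(assignments),
                status=status,
                annotated_at=stamp or None,
            )
    return out


def _import_json(path: Path) -> dict[str, Annotation]:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, dict) or "annotations" not in doc:
        raise ParseError(f"{path}: record 1: missing 'annotations' key")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(
            f"{path}: unsupported schema_version {doc.get('schema_version')!r}"
        )
    out: dict[str, Annotation] = {}
    for i, rec in enumerate(doc["annotations"], start=1):
        try:
            out[rec["concept_code"]] = Annotation(
                concept_code=rec["concept_code"],
                assignments=tuple(
                    (a["ontology_id"], a["code"]) for a in rec["assignments"]
                ),
                status=rec["status"],
                annotated_at=rec["annotated_at"],
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: record {i}: malformed annotation ({exc})") from exc
        if rec["status"] not in _STATUSES:
            raise ParseError(f"{path}: record {i}: unknown status '{rec['status']}'")
    return out


def import_annotations(path: str | Path, format: str | None = None) -> dict[str, Annotation]:
    """Read annotations back from an export; lossless inverse of export.

    ``format`` is inferred from the file suffix when omitted (.json vs
    anything else = CSV).
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"annotation file not found: {path}")
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        return _import_json(path)
    if format == "csv":
        return _import_csv(path)
    raise ConfigurationError(f"unknown import format '{format}' (csv or json)")
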