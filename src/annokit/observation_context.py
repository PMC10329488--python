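"""Summaries of observed measurement data used to disambiguate concepts.

A local concept code such as "MAP" is ambiguous from its label alone (mean
arterial pressure? mean airway pressure?), but the values recorded against
it usually are not: arterial pressures cluster near 90 mmHg, airway
pressures near 12 cmH2O.  This module computes the aggregations an
annotator would look at:

* a numeric value distribution (equal-width histogram, lowest value on the
  left);
* an alphabetical histogram of textual values;
* per-patient time series over a fixed-length window (default 96 hours),
  with the top-5 patients by occurrence count selected automatically.

Observation tables are delimited text with columns
``concept_code, patient_id, timestamp, value, unit`` — the shape of
MIMIC-IV ``chartevents``/``labevents`` extracts.  Timestamps are ISO 8601;
naive timestamps are assumed UTC.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, NotFoundError, SummaryError
from .ontology_store import detect_delimiter

__all__ = [
    "Observation",
    "ConceptSummary",
    "PatientSeries",
    "load_observations",
    "for_concept",
    "classify_value_kind",
    "summarize",
    "summarize_numeric",
    "summarize_textual",
    "select_top_patients",
    "extract_patient_series",
]

OBSERVATION_COLUMNS = ("concept_code", "patient_id", "timestamp", "value", "unit")

#: Fraction of nonempty values that must parse as finite numbers for a
#: concept to be classified numeric.  Real chart data is noisy ("ERROR",
#: "see note"), so a strict 100% rule would misclassify numeric concepts.
NUMERIC_FRACTION_THRESHOLD = 0.9

DEFAULT_WINDOW_HOURS = 96.0
DEFAULT_TOP_N_PATIENTS = 5
DEFAULT_N_BINS = 50


@dataclass(frozen=True)
class Observation:
    """One measurement event for a concept."""

    concept_code: str
    patient_id: str
    timestamp: datetime
    raw_value: str
    unit: str = ""


@dataclass(frozen=True)
class ConceptSummary:
    """Aggregate description of one concept's observed values.

    For ``kind == "numeric"``, ``bin_edges``/``counts`` describe an
    equal-width histogram over [vmin, vmax]; ``n_obs`` counts the parsed
    values and ``n_unparseable`` the dropped ones.  For ``kind ==
    "textual"``, ``values`` lists (value, count) pairs in ascending
    lexicographic order and ``n_obs`` is their total.  ``unit`` is the modal
    nonempty unit string (ties to the lexicographically smallest).
    """

    concept_code: str
    kind: str  # "numeric" | "textual"
    n_obs: int
    unit: str = ""
    # numeric part
    bin_edges: tuple[float, ...] = ()
    counts: tuple[int, ...] = ()
    vmin: float | None = None
    vmax: float | None = None
    mean: float | None = None
    sd: float | None = None
    n_unparseable: int = 0
    # textual part
    values: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class PatientSeries:
    """One patient's in-window numeric observations for a concept."""

    patient_id: str
    points: tuple[tuple[datetime, float], ...]
    occurrence_count: int  # all of the patient's observations, not only in-window


# ---------------------------------------------------------------------------
# Loading and helpers
# ---------------------------------------------------------------------------

def load_observations(path: str | Path) -> list[Observation]:
    """Read an observation table (CSV or TSV, header required)."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"observation file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise InputError(f"observation file is empty: {path}")
    sep = detect_delimiter(header)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in OBSERVATION_COLUMNS if c not in frame.columns and c != "unit"]
    if missing:
        raise InputError(f"observation file lacks required column(s): {missing}")
    if "unit" not in frame.columns:
        frame["unit"] = ""
    stamps = pd.to_datetime(frame["timestamp"], utc=True, format="ISO8601")
    return [
        Observation(
            concept_code=row.concept_code,
            patient_id=row.patient_id,
            timestamp=ts.to_pydatetime(),
            raw_value=row.value,
            unit=row.unit,
        )
        for row, ts in zip(frame.itertuples(index=False), stamps)
    ]


def for_concept(observations: Iterable[Observation], concept_code: str) -> list[Observation]:
    """Filter an observation sequence down to one concept code."""
    return [o for o in observations if o.concept_code == concept_code]


def _parse_number(raw: str) -> float | None:
    try:
        v = float(raw)
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def _modal_unit(observations: Sequence[Observation]) -> str:
    units = Counter(o.unit for o in observations if o.unit)
    if not units:
        return ""
    # ties resolved toward the lexicographically smallest unit
    top_count = max(units.values())
    return min(u for u, c in units.items() if c == top_count)


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------

def classify_value_kind(observations: Sequence[Observation]) -> str:
    """Decide whether a concept's values are numeric or textual.

    Numeric iff at least 90% of the nonempty raw value strings parse as
    finite decimal numbers.  A concept with no nonempty values is textual.
    """
    if not observations:
        raise InputError("cannot classify an empty observation sequence")
    nonempty = [o.raw_value for o in observations if o.raw_value.strip()]
    if not nonempty:
        return "textual"
    n_numeric = sum(1 for v in nonempty if _parse_number(v) is not None)
    return "numeric" if n_numeric / len(nonempty) >= NUMERIC_FRACTION_THRESHOLD else "textual"


def summarize_numeric(
    observations: Sequence[Observation], n_bins: int = DEFAULT_N_BINS
) -> ConceptSummary:
    """Equal-width histogram over the full value range, lowest bin first.

    Unparseable values are dropped and counted in ``n_unparseable``.  When
    every parsed value is identical the histogram degenerates to a single
    bin [v, v] holding the full count.
    """
    if not observations:
        raise InputError("cannot summarize an empty observation sequence")
    parsed = np.array(
        [v for o in observations if (v := _parse_number(o.raw_value)) is not None]
    )
    n_unparseable = len(observations) - len(parsed)
    if len(parsed) == 0:
        raise SummaryError("no observation value parses as a number")
    vmin, vmax = float(parsed.min()), float(parsed.max())
    if vmin == vmax:
        edges = np.array([vmin, vmax])
        counts = np.array([len(parsed)])
    else:
        counts, edges = np.histogram(parsed, bins=n_bins, range=(vmin, vmax))
    return ConceptSummary(
        concept_code=observations[0].concept_code,
        kind="numeric",
        n_obs=int(len(parsed)),
        unit=_modal_unit(observations),
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        vmin=vmin,
        vmax=vmax,
        mean=float(parsed.mean()),
        sd=float(parsed.std(ddof=1)) if len(parsed) > 1 else 0.0,
        n_unparseable=n_unparseable,
    )


def summarize_textual(observations: Sequence[Observation]) -> ConceptSummary:
    """Count exact (whitespace-trimmed) value strings, alphabetical order."""
    if not observations:
        raise InputError("cannot summarize an empty observation sequence")
    tally = Counter(o.raw_value.strip() for o in observations)
    return ConceptSummary(
        concept_code=observations[0].concept_code,
        kind="textual",
        n_obs=len(observations),
        unit=_modal_unit(observations),
        values=tuple(sorted(tally.items())),
    )


def summarize(
    observations: Sequence[Observation], n_bins: int = DEFAULT_N_BINS
) -> ConceptSummary:
    """Classify the concept's value kind and dispatch to the right summary."""
    kind = classify_value_kind(observations)
    if kind == "numeric":
        return summarize_numeric(observations, n_bins=n_bins)
    return summarize_textual(observations)


# ---------------------------------------------------------------------------
# Patient-level series
# ---------------------------------------------------------------------------

def select_top_patients(
    observations: Sequence[Observation], n: int = DEFAULT_TOP_N_PATIENTS
) -> list[str]:
    """Patients ranked by occurrence count for this concept.

    Descending count, ties by ascending patient id; at most ``n`` ids (all
    distinct patients when fewer exist).
    """
    if not observations:
        raise InputError("cannot rank patients of an empty observation sequence")
    tally = Counter(o.patient_id for o in observations)
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return [pid for pid, _ in ranked[:n]]


def extract_patient_series(
    observations: Sequence[Observation],
    patient_id: str,
    window_hours: float = DEFAULT_WINDOW_HOURS,
) -> PatientSeries:
    """One patient's numeric points inside a fixed window.

    The window is the half-open interval ``[anchor, anchor + window_hours)``
    anchored at the patient's earliest observation of this concept, so an
    observation exactly ``window_hours`` after the first is excluded.
    Values that do not parse as numbers are omitted from the points;
    ``occurrence_count`` still counts every observation of the patient.
    """
    mine = [o for o in observations if o.patient_id == patient_id]
    if not mine:
        raise NotFoundError(f"patient '{patient_id}' has no observations for this concept")
    anchor = min(o.timestamp for o in mine)
    end = anchor + timedelta(hours=window_hours)
    points = sorted(
        (o.timestamp, v)
        for o in mine
        if anchor <= o.timestamp < end and (v := _parse_number(o.raw_value)) is not None
    )
    return PatientSeries(
        patient_id=patient_id,
        points=tuple(points),
        occurrence_count=len(mine),
    )
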