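"""Synthetic ontologies, source concepts, and observation tables.

Real inputs to the toolkit are licensed terminology releases and protected
EHR extracts, neither of which can ship with the package.  This module
generates structurally faithful synthetic stand-ins for all three, so every
other module is exercisable end-to-end with no external data:

* a mini ontology whose labels are clinical-style phrases built from a word
  bank, salted with near-duplicate distractors (sharing at least one token
  with a true label) and containing the classic ambiguous pair
  "Mean arterial pressure" / "Mean airway pressure" verbatim;
* a source-concept table including two concepts that share the identical
  terse label "Mean pressure (MAP)" but draw their observed values from
  different distributions (arterial-like ~N(90, 10) mmHg vs airway-like
  ~N(12, 3) cmH2O), so the measurement summaries — not the labels — are
  what disambiguates them;
* an observation table in the five-column chartevents shape, ~100 patients
  (mirroring a demo-sized ICU extract) with per-patient occurrence counts
  heterogeneous enough that the top-5 patient ranking is almost surely
  untied;
* perturbed retrieval queries (one edit per query) paired with their true
  codes, for recall measurements.

Everything is driven by one master seed.  Each output file uses its own
pseudo-random stream spawned from the master seed by a fixed spawn-key
index (0 = ontology, 1 = concepts, 2 = observations, 3 = queries), so any
single file is reproducible without generating the others.  Identical specs
yield byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .text_ranking import analyze

__all__ = [
    "FixtureSpec",
    "ConceptPlan",
    "generate_mini_ontology",
    "generate_source_concepts",
    "generate_observations",
    "generate_queries",
    "write_fixture_set",
]

_STREAMS = {"ontology": 0, "concepts": 1, "observations": 2, "queries": 3}

_ADJECTIVES = [
    "systolic", "diastolic", "peak", "left", "right", "upper", "lower",
    "central", "peripheral", "inspiratory", "expiratory", "serum", "ionized",
    "total", "venous", "capillary", "tympanic", "axillary", "basal", "residual",
]
_MEASURES = [
    "pressure", "rate", "volume", "temperature", "saturation", "output",
    "sodium", "potassium", "glucose", "lactate", "creatinine", "hemoglobin",
    "bilirubin", "albumin", "calcium", "magnesium", "oxygen", "flow",
    "resistance", "compliance",
]
_SITES = [
    "heart", "lung", "blood", "radial", "femoral", "brachial", "core", "skin",
    "cerebral", "renal", "hepatic", "gastric", "urine", "plasma",
]
_UNIT_SUFFIXES = ["(bpm)", "(mmHg)", "(%)", "(mmol/L)", "(mg/dL)", "(cmH2O)", "(L/min)", ""]

_WORD_BANK = _ADJECTIVES + _MEASURES + _SITES

# 7-day observation span starting at a fixed instant (naive = UTC by
# convention of the loader)
_T0 = datetime(2023, 1, 1, 0, 0, 0)
_SPAN_SECONDS = 7 * 24 * 3600


@dataclass(frozen=True)
class FixtureSpec:
    """Fully parameterized description of one synthetic dataset."""

    n_terms: int = 200
    n_concepts: int = 8
    n_patients: int = 100
    obs_per_patient: int = 10  # mean of the per-patient count distribution
    seed: int = 7
    ambiguous_pairs: tuple = (
        (
            "Mean arterial pressure",
            "Mean airway pressure",
            ("normal", 90.0, 10.0),
            ("normal", 12.0, 3.0),
        ),
    )


@dataclass(frozen=True)
class ConceptPlan:
    """What to generate for one source concept."""

    code: str
    label: str
    kind: str  # numeric | textual
    unit: str = ""
    dist: tuple = ()  # ("normal", mean, sd) for numeric concepts
    categories: tuple = ()  # ((value, probability), ...) for textual concepts


def _rng(spec: FixtureSpec, stream: str) -> np.random.Generator:
    key = _STREAMS[stream]
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

def _dedup_key(label: str) -> tuple:
    return tuple(sorted(analyze(label)))


def _has_repeats(label: str) -> bool:
    toks = analyze(label)
    return len(toks) != len(set(toks))


def generate_mini_ontology(spec: FixtureSpec, path: str | Path) -> Path:
    """Write a synthetic ontology table (columns: code,label,component,system).

    Labels are unique even after analysis (no two share the same token
    multiset), so exact-label queries have a single best answer under every
    backend.  Roughly a fifth of the terms are near-duplicate distractors
    derived from an existing label by swapping one token.
    """
    if spec.n_terms < 20:
        raise ParameterError(f"n_terms must be >= 20 to host the required structure, got {spec.n_terms}")
    rng = _rng(spec, "ontology")
    labels: list[str] = []
    seen: set[tuple] = set()

    def _try_add(label: str) -> bool:
        key = _dedup_key(label)
        if not key or key in seen or _has_repeats(label):
            return False
        seen.add(key)
        labels.append(label)
        return True

    for pair in spec.ambiguous_pairs:
        for lbl in pair[:2]:
            _try_add(lbl)

    n_distractors = max(1, spec.n_terms // 5)
    n_core = spec.n_terms - n_distractors
    while len(labels) < n_core:
        pattern = int(rng.integers(0, 4))
        site = _SITES[rng.integers(len(_SITES))]
        adj = _ADJECTIVES[rng.integers(len(_ADJECTIVES))]
        meas = _MEASURES[rng.integers(len(_MEASURES))]
        suffix = _UNIT_SUFFIXES[rng.integers(len(_UNIT_SUFFIXES))]
        if pattern == 0:
            label = f"{site} {meas}"
        elif pattern == 1:
            label = f"{adj} {site} {meas}"
        elif pattern == 2:
            label = f"{adj} {meas} {suffix}".strip()
        else:
            label = f"{site} {adj} {meas} {suffix}".strip()
        _try_add(label[0].upper() + label[1:])

    n_protected = sum(len(pair[:2]) for pair in spec.ambiguous_pairs)
    while len(labels) < spec.n_terms:
        # distractor: mutate one token of a non-ambiguous multi-token label
        src = labels[int(rng.integers(n_protected, n_core))]
        toks = src.split()
        if len(toks) < 2:
            continue
        i = int(rng.integers(len(toks)))
        toks[i] = _WORD_BANK[rng.integers(len(_WORD_BANK))]
        label = " ".join(toks)
        _try_add(label[0].upper() + label[1:])

    rows = []
    for i, label in enumerate(labels):
        toks = analyze(label)
        rows.append(
            {
                "code": f"SYN-{i:04d}",
                "label": label,
                "component": toks[0] if toks else "",
                "system": _SITES[rng.integers(len(_SITES))],
            }
        )
    frame = pd.DataFrame(rows)
    path = Path(path)
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Source concepts
# ---------------------------------------------------------------------------

def _base_plans(spec: FixtureSpec) -> list[ConceptPlan]:
    pair = spec.ambiguous_pairs[0]
    return [
        ConceptPlan("220045", "Heart rate", "numeric", "bpm", ("normal", 80.0, 12.0)),
        # two concepts with the identical ambiguous label, different physiology
        ConceptPlan("220052", "Mean pressure (MAP)", "numeric", "mmHg", pair[2]),
        ConceptPlan("224697", "Mean pressure (MAP)", "numeric", "cmH2O", pair[3]),
        ConceptPlan(
            "224969", "LLL lung sounds", "textual", "",
            categories=(
                ("Absent", 0.10), ("Clear", 0.45), ("Coarse", 0.15),
                ("Diminished", 0.25), ("Wheezes", 0.05),
            ),
        ),
        ConceptPlan("220210", "Respiratory rate", "numeric", "insp/min", ("normal", 18.0, 4.0)),
        ConceptPlan("223761", "Temperature", "numeric", "°C", ("normal", 37.0, 0.6)),
        ConceptPlan("220621", "Glucose", "numeric", "mg/dL", ("normal", 110.0, 30.0)),
        ConceptPlan(
            "224650", "Heart rhythm", "textual", "",
            categories=(("AFib", 0.15), ("Paced", 0.10), ("Sinus", 0.70), ("SVT", 0.05)),
        ),
    ]


def generate_source_concepts(spec: FixtureSpec, path: str | Path) -> list[ConceptPlan]:
    """Write the source-concept table (columns: code,label); return the plans."""
    if spec.n_concepts < 4:
        raise ParameterError(
            "n_concepts must be >= 4 (heart rate, the ambiguous pair, one textual concept)"
        )
    rng = _rng(spec, "concepts")
    plans = _base_plans(spec)[: spec.n_concepts]
    while len(plans) < spec.n_concepts:
        i = len(plans)
        adj = _ADJECTIVES[rng.integers(len(_ADJECTIVES))]
        meas = _MEASURES[rng.integers(len(_MEASURES))]
        mu = float(np.round(rng.uniform(5.0, 200.0), 1))
        plans.append(
            ConceptPlan(
                f"extra_{i:03d}", f"{adj} {meas}".capitalize(), "numeric", "",
                ("normal", mu, max(1.0, 0.15 * mu)),
            )
        )
    frame = pd.DataFrame({"code": [p.code for p in plans], "label": [p.label for p in plans]})
    frame.to_csv(Path(path), index=False, lineterminator="\n")
    return plans


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

def generate_observations(
    spec: FixtureSpec, plans: list[ConceptPlan], path: str | Path
) -> Path:
    """Write the observation table for the given concept plans.

    Per patient and concept, the observation count is ``1 + Poisson(lam)``
    with ``lam ~ Uniform(1, 2 * obs_per_patient)`` drawn per patient —
    the between-patient heterogeneity keeps occurrence-count ranks distinct
    with high probability.  Numeric values follow the plan's distribution
    (truncated at 0); textual values follow the plan's categorical
    distribution.  Timestamps are uniform over a 7-day span per patient.
    """
    if not plans:
        raise ParameterError("plans must be nonempty")
    rng = _rng(spec, "observations")
    patients = [f"P{i:03d}" for i in range(spec.n_patients)]
    records: list[tuple[str, str, str, str, str]] = []
    for plan in plans:
        for pid in patients:
            lam = rng.uniform(1.0, 2.0 * spec.obs_per_patient)
            n = 1 + int(rng.poisson(lam))
            offsets = np.sort(rng.uniform(0.0, _SPAN_SECONDS, size=n)).astype(int)
            if plan.kind == "numeric":
                _, mu, sd = plan.dist
                vals = np.maximum(rng.normal(mu, sd, size=n), 0.0)
                rendered = [f"{v:.1f}" for v in vals]
            else:
                cats = [c for c, _ in plan.categories]
                probs = [p for _, p in plan.categories]
                rendered = [str(v) for v in rng.choice(cats, size=n, p=probs)]
            for off, val in zip(offsets, rendered):
                stamp = (_T0 + timedelta(seconds=int(off))).isoformat()
                records.append((plan.code, pid, stamp, val, plan.unit))
    frame = pd.DataFrame(
        records, columns=["concept_code", "patient_id", "timestamp", "value", "unit"]
    )
    path = Path(path)
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Retrieval queries
# ---------------------------------------------------------------------------

def _perturb_label(label: str, rng: np.random.Generator) -> str:
    """Apply exactly one edit: token deletion, adjacent-character
    transposition, or letter case change."""
    ops = []
    toks = label.split()
    if len(toks) >= 2:
        ops.append("delete")
    swap_positions = [i for i in range(len(label) - 1) if label[i] != label[i + 1]]
    if swap_positions:
        ops.append("transpose")
    alpha_positions = [i for i, ch in enumerate(label) if ch.isalpha()]
    if alpha_positions:
        ops.append("case")
    if not ops:
        return label
    op = ops[int(rng.integers(len(ops)))]
    if op == "delete":
        i = int(rng.integers(len(toks)))
        return " ".join(toks[:i] + toks[i + 1 :])
    if op == "transpose":
        i = swap_positions[int(rng.integers(len(swap_positions)))]
        return label[:i] + label[i + 1] + label[i] + label[i + 2 :]
    i = alpha_positions[int(rng.integers(len(alpha_positions)))]
    return label[:i] + label[i].swapcase() + label[i + 1 :]


def generate_queries(
    spec: FixtureSpec, ontology_path: str | Path, n_queries: int = 100
) -> list[tuple[str, str]]:
    """Single-edit perturbed queries paired with their true term codes."""
    frame = pd.read_csv(ontology_path, dtype=str, keep_default_na=False)
    rng = _rng(spec, "queries")
    n_terms = len(frame)
    replace = n_queries > n_terms
    idx = rng.choice(n_terms, size=n_queries, replace=replace)
    out = []
    for i in idx:
        label = frame["label"].iloc[int(i)]
        code = frame["code"].iloc[int(i)]
        out.append((_perturb_label(label, rng), code))
    return out


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def write_fixture_set(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write ontology, concepts, observations, queries, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ontology = generate_mini_ontology(spec, outdir / "ontology.csv")
    plans = generate_source_concepts(spec, outdir / "concepts.csv")
    observations = generate_observations(spec, plans, outdir / "observations.csv")
    queries = generate_queries(spec, ontology)
    queries_path = outdir / "queries.tsv"
    with open(queries_path, "w", encoding="utf-8") as fh:
        fh.write("query\ttrue_code\n")
        for q, c in queries:
            fh.write(f"{q}\t{c}\n")
    manifest = dict(asdict(spec))
    manifest["files"] = {
        "ontology": ontology.name,
        "concepts": "concepts.csv",
        "observations": observations.name,
        "queries": queries_path.name,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return {
        "ontology": ontology,
        "concepts": outdir / "concepts.csv",
        "observations": observations,
        "queries": queries_path,
        "manifest": manifest_path,
    }
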