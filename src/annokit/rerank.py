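"""Retrieve-then-rerank pipeline for candidate ontology terms.

A cheap, high-recall first stage (any backend of
:mod:`annokit.text_ranking`) retrieves ``retrieve_k`` candidates; a
re-ranker then permutes them and the list is truncated to ``final_k``.

The re-ranker is a plain callable contract — ``RerankContext ->
RerankResult`` — so an external model (e.g. a hosted LLM re-ranking
endpoint) can be plugged in.  Two re-rankers ship with the package:

``rerank_identity``
    Keeps the first-stage order; the pipeline default, so re-ranking is
    effectively disabled unless requested.
``rerank_context_overlap``
    A deterministic re-ranker that blends the (min-max normalized)
    first-stage score with a token-overlap score against the concept label
    *plus keywords derived from the concept's observed measurements* —
    its unit of measure and value kind.  Units carry domain information
    (mmHg points at vascular pressures, cmH2O at airway pressures), which
    is exactly the signal that disambiguates look-alike candidates.

Every re-ranker must return an exact permutation of its input candidates
with ranks re-assigned 1..n.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

from .errors import ParameterError, ValidationError
from .observation_context import ConceptSummary
from .text_ranking import CandidateRanker, RankedCandidate, analyze

__all__ = [
    "RerankContext",
    "RerankResult",
    "Reranker",
    "rerank_identity",
    "rerank_context_overlap",
    "make_context_overlap_reranker",
    "build_rerank_payload",
    "parse_rerank_payload",
    "retrieve_then_rerank",
    "UNIT_DOMAIN_KEYWORDS",
]


@dataclass(frozen=True)
class RerankContext:
    """Everything a re-ranker may look at: the concept, its measurement
    summary (if any), and the first-stage candidates in rank order."""

    concept: object  # SourceConcept (needs .code and .label)
    candidates: tuple[RankedCandidate, ...]
    summary: ConceptSummary | None = None


@dataclass(frozen=True)
class RerankResult:
    """A permutation of the input candidates with fresh consecutive ranks."""

    candidates: tuple[RankedCandidate, ...]
    reranker_id: str


Reranker = Callable[[RerankContext], RerankResult]


def _reassign(ordered: Sequence[RankedCandidate], scores: Sequence[float]) -> tuple[RankedCandidate, ...]:
    return tuple(
        replace(c, rank=i + 1, score=float(s))
        for i, (c, s) in enumerate(zip(ordered, scores))
    )


def _check_permutation(context: RerankContext, result: RerankResult) -> None:
    before = sorted((c.term.ontology_id, c.term.code) for c in context.candidates)
    after = sorted((c.term.ontology_id, c.term.code) for c in result.candidates)
    if before != after:
        raise ValidationError(
            f"reranker '{result.reranker_id}' did not return a permutation of its input"
        )


# ---------------------------------------------------------------------------
# Built-in re-rankers
# ---------------------------------------------------------------------------

def rerank_identity(context: RerankContext) -> RerankResult:
    """Keep the first-stage order (re-ranking disabled)."""
    return RerankResult(candidates=tuple(context.candidates), reranker_id="identity")


#: Small built-in lexicon mapping measurement-unit tokens (as produced by
#: the analyzer) to the clinical-domain tokens they imply.  Used only by the
#: context-overlap re-ranker; extend by passing ``extra_keywords``.
UNIT_DOMAIN_KEYWORDS: dict[str, tuple[str, ...]] = {
    "mmhg": ("arterial", "blood", "pressure"),
    "cmh2o": ("airway", "pressure", "ventilation"),
    "bpm": ("heart", "rate", "pulse"),
    "insp": ("respiratory", "rate", "breath"),
    "min": (),
    "c": ("temperature",),
    "f": ("temperature",),
    "mmol": ("serum", "concentration"),
    "mg": ("serum", "concentration"),
    "dl": (),
    "l": (),
    "g": (),
}


def _context_keywords(summary: ConceptSummary | None) -> set[str]:
    if summary is None:
        return set()
    keywords: set[str] = {summary.kind}
    for tok in analyze(summary.unit):
        keywords.add(tok)
        keywords.update(UNIT_DOMAIN_KEYWORDS.get(tok, ()))
    return keywords


def rerank_context_overlap(context: RerankContext, alpha: float = 0.5) -> RerankResult:
    """Blend first-stage score with token overlap against concept + context.

    New score = ``alpha * minmax(first-stage score) + (1 - alpha) * overlap``
    where ``overlap`` is the fraction of the candidate label's analyzed
    tokens found in the union of the concept label's tokens and the context
    keyword set (unit tokens, unit-implied domain tokens, value kind).  When
    all first-stage scores are equal, their normalized value is defined as
    1.  Ties are broken by ascending code.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    cands = context.candidates
    if not cands:
        return RerankResult(candidates=(), reranker_id="context_overlap")
    raw = [c.score for c in cands]
    lo, hi = min(raw), max(raw)
    if hi > lo:
        normed = [(s - lo) / (hi - lo) for s in raw]
    else:
        normed = [1.0] * len(raw)
    reference = set(analyze(getattr(context.concept, "label", str(context.concept))))
    reference |= _context_keywords(context.summary)
    blended = []
    for c, ns in zip(cands, normed):
        toks = analyze(c.term.label)
        overlap = sum(1 for t in toks if t in reference) / len(toks) if toks else 0.0
        blended.append(alpha * ns + (1.0 - alpha) * overlap)
    order = sorted(range(len(cands)), key=lambda i: (-blended[i], cands[i].term.code))
    result = RerankResult(
        candidates=_reassign([cands[i] for i in order], [blended[i] for i in order]),
        reranker_id="context_overlap",
    )
    _check_permutation(context, result)
    return result


def make_context_overlap_reranker(alpha: float = 0.5) -> Reranker:
    """Bind ``alpha`` so the result satisfies the plain re-ranker contract."""
    return lambda context: rerank_context_overlap(context, alpha=alpha)


# ---------------------------------------------------------------------------
# Payload serialization for external re-rankers
# ---------------------------------------------------------------------------

_PAYLOAD_HEADER = "annokit-rerank-payload\tv1"


def build_rerank_payload(context: RerankContext) -> str:
    """Serialize a rerank context as a deterministic tab-separated document.

    This is the document an external re-ranking service plugin would
    consume: the concept, the measurement summary when available, and the
    candidates in first-stage rank order.  ``parse_rerank_payload`` is its
    inverse for the fields it carries.
    """
    concept = context.concept
    lines = [_PAYLOAD_HEADER]
    lines.append(f"concept\t{getattr(concept, 'code', '')}\t{getattr(concept, 'label', str(concept))}")
    s = context.summary
    if s is not None:
        def _g(x):
            return "" if x is None else f"{x:g}"

        fields = [f"kind={s.kind}", f"n_obs={s.n_obs}", f"unit={s.unit}"]
        if s.kind == "numeric":
            fields += [f"min={_g(s.vmin)}", f"max={_g(s.vmax)}",
                       f"mean={_g(s.mean)}", f"sd={_g(s.sd)}"]
        else:
            top = ", ".join(f"{v} ({c})" for v, c in s.values[:10])
            fields.append(f"values={top}")
        lines.append("summary\t" + "\t".join(fields))
    for c in context.candidates:
        lines.append(
            f"candidate\t{c.rank}\t{c.term.ontology_id}\t{c.term.code}\t{c.term.label}"
        )
    return "\n".join(lines) + "\n"


def parse_rerank_payload(text: str) -> dict:
    """Parse a payload back into its concept and candidate identifiers."""
    lines = text.splitlines()
    if not lines or lines[0] != _PAYLOAD_HEADER:
        raise ValidationError("not an annokit rerank payload (bad header line)")
    out: dict = {"concept_code": None, "concept_label": None, "has_summary": False, "candidates": []}
    for ln in lines[1:]:
        kind, _, rest = ln.partition("\t")
        if kind == "concept":
            code, _, label = rest.partition("\t")
            out["concept_code"], out["concept_label"] = code, label
        elif kind == "summary":
            out["has_summary"] = True
        elif kind == "candidate":
            rank, ontology_id, code, label = rest.split("\t", 3)
            out["candidates"].append(
                {"rank": int(rank), "ontology_id": ontology_id, "code": code, "label": label}
            )
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def retrieve_then_rerank(
    ranker: CandidateRanker,
    concept,
    ontology_id: str,
    backend: str,
    retrieve_k: int,
    reranker: Reranker,
    final_k: int,
    summary: ConceptSummary | None = None,
) -> list[RankedCandidate]:
    """High-recall retrieval followed by re-ranking, truncated to ``final_k``.

    With the identity re-ranker this reduces exactly to plain
    ``rank_candidates`` truncated to ``final_k``.  An empty retrieval
    short-circuits: the re-ranker is never invoked.
    """
    if retrieve_k < final_k:
        raise ParameterError(
            f"retrieve_k ({retrieve_k}) must be >= final_k ({final_k})"
        )
    first = ranker.rank_candidates(concept, ontology_id, backend, retrieve_k)
    if not first:
        return []
    context = RerankContext(concept=concept, candidates=tuple(first), summary=summary)
    result = reranker(context)
    _check_permutation(context, result)
    return [replace(c, rank=i + 1) for i, c in enumerate(result.candidates[:final_k])]
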