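"""End-to-end orchestration: extract -> graph -> disambiguate -> complete -> evaluate.

The functions here are the library surface behind the command-line
interface; each takes and returns plain package objects so a notebook or
test can run any prefix of the pipeline directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chunker import TextChunk
from .completion import (
    CompletionCandidate,
    ConsensusPolicy,
    UNANIMITY,
    VerificationRecord,
    complete_graph,
)
from .disambiguation import MergeDecision, apply_merges, candidate_pairs, resolve_pair
from .evaluation import PhraseMatchReport, phrase_prf
from .extraction import (
    AnnotatedChunk,
    ExtractionResult,
    FewShotBlock,
    extract_vanilla,
    ner_two_step,
    re_two_step,
)
from .gateway import Backend, GenerationSettings, PromptTemplate, TranscriptLog
from .graph import KnowledgeGraph, Provenance, TripleRecord
from .schema import Schema

__all__ = [
    "PipelineResult",
    "extract_corpus",
    "build_graph",
    "disambiguate_graph",
    "complete_and_verify",
    "evaluate_extraction",
    "run_full_pipeline",
]


@dataclass
class PipelineResult:
    graph: KnowledgeGraph
    ner_results: list[ExtractionResult] = field(default_factory=list)
    re_results: list[ExtractionResult] = field(default_factory=list)
    merge_decisions: list[MergeDecision] = field(default_factory=list)
    merge_report: dict = field(default_factory=dict)
    completion_ledger: list[VerificationRecord] = field(default_factory=list)
    reports: dict[str, PhraseMatchReport] = field(default_factory=dict)


def extract_corpus(
    chunks: list[TextChunk],
    schema: Schema,
    backend: Backend,
    method: str = "two_step",
    shots_ner: FewShotBlock | None = None,
    shots_re: FewShotBlock | None = None,
    settings: GenerationSettings = GenerationSettings(),
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> tuple[list[ExtractionResult], list[ExtractionResult]]:
    """Run NER and RE over every chunk with the chosen prompting method."""
    if method not in ("two_step", "vanilla"):
        raise ValueError("method must be 'two_step' or 'vanilla'")
    ner_results, re_results = [], []
    for chunk in chunks:
        if method == "two_step":
            ner_results.append(
                ner_two_step(chunk, schema, shots_ner, backend, settings, templates, log)
            )
            re_results.append(
                re_two_step(chunk, schema, shots_re, backend, settings, templates, log)
            )
        else:
            ner_results.append(
                extract_vanilla(chunk, schema, "ner", shots_ner, backend, settings, templates, log)
            )
            re_results.append(
                extract_vanilla(chunk, schema, "re", shots_re, backend, settings, templates, log)
            )
    return ner_results, re_results


def build_graph(
    schema: Schema,
    re_results: list[ExtractionResult],
    ner_results: list[ExtractionResult] | None = None,
    doc_of_chunk: dict[str, str] | None = None,
) -> KnowledgeGraph:
    """Assemble extraction output into a validated graph.

    RE triples define the edges; NER entities (when given) are registered
    too so that isolated mentions survive into the graph.
    """
    kg = KnowledgeGraph(schema=schema)
    for result in ner_results or []:
        for surface, type_name in result.entities:
            if schema.entity_type(type_name):
                kg.ensure_entity(surface, type_name)
    for result in re_results:
        triples = []
        for head, relation, tail in result.triples:
            spec = schema.relation_type(relation)
            if spec is None:
                continue
            head_id = kg.ensure_entity(head, spec.source_type)
            tail_id = kg.ensure_entity(tail, spec.target_type)
            triples.append(
                TripleRecord(
                    head=head_id,
                    relation=spec.name,
                    tail=tail_id,
                    provenance=Provenance(
                        source_doc=(doc_of_chunk or {}).get(result.chunk_id, ""),
                        chunk_id=result.chunk_id,
                        stage="extraction",
                        session_ref=f"re:{result.chunk_id}",
                    ),
                )
            )
        kg.add_triples(triples)
    return kg


def disambiguate_graph(
    kg: KnowledgeGraph,
    backend: Backend,
    threshold: float = 0.3,
    mode: str = "pairs",
    settings: GenerationSettings = GenerationSettings(),
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> tuple[KnowledgeGraph, list[MergeDecision], dict]:
    """Nominate candidate duplicates, adjudicate each, and merge."""
    decisions = [
        resolve_pair((a, b), kg, backend, settings, score, templates, log)
        for a, b, score in candidate_pairs(kg, threshold, mode)
    ]
    merged, report = apply_merges(kg, decisions)
    return merged, decisions, report


def complete_and_verify(
    kg: KnowledgeGraph,
    seeds: list[CompletionCandidate],
    backend: Backend,
    policy: ConsensusPolicy = UNANIMITY,
    settings: GenerationSettings = GenerationSettings(),
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> tuple[list[TripleRecord], list[VerificationRecord]]:
    return complete_graph(
        kg, seeds, backend, settings, policy, templates=templates, log=log
    )


def evaluate_extraction(
    ner_results: list[ExtractionResult],
    re_results: list[ExtractionResult],
    gold: dict[str, AnnotatedChunk],
) -> dict[str, PhraseMatchReport]:
    """Phrase-level P/R/F1 for both tasks against chunk-keyed gold."""
    pred_ner = {r.chunk_id: r.entities for r in ner_results}
    pred_re = {r.chunk_id: r.triples for r in re_results}
    gold_ner = {cid: g.entities for cid, g in gold.items()}
    gold_re = {cid: g.triples for cid, g in gold.items()}
    return {
        "ner": phrase_prf(pred_ner, gold_ner, "ner"),
        "re": phrase_prf(pred_re, gold_re, "re"),
    }


def run_full_pipeline(
    chunks: list[TextChunk],
    schema: Schema,
    backend: Backend,
    gold: dict[str, AnnotatedChunk] | None = None,
    seeds: list[CompletionCandidate] | None = None,
    method: str = "two_step",
    threshold: float = 0.3,
    policy: ConsensusPolicy = UNANIMITY,
    settings: GenerationSettings = GenerationSettings(),
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> PipelineResult:
    """Extraction through completion in one call; evaluates when gold given."""
    ner_results, re_results = extract_corpus(
        chunks, schema, backend, method, settings=settings, templates=templates, log=log
    )
    kg = build_graph(schema, re_results, ner_results)
    kg, decisions, merge_report = disambiguate_graph(
        kg, backend, threshold, settings=settings, templates=templates, log=log
    )
    ledger: list[VerificationRecord] = []
    if seeds:
        _, ledger = complete_and_verify(
            kg, seeds, backend, policy, settings, templates, log
        )
    result = PipelineResult(
        graph=kg,
        ner_results=ner_results,
        re_results=re_results,
        merge_decisions=decisions,
        merge_report=merge_report,
        completion_ledger=ledger,
    )
    if gold is not None:
        result.reports = evaluate_extraction(ner_results, re_results, gold)
    return result
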