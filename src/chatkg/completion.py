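"""Knowledge-graph completion with triple cyclic verification.

Completion mines assertions the extraction stage never saw, by asking the
model three kinds of question about a candidate triple (h, r, t):

* triple classification — "h <r> t? Please answer true or false";
* relation prediction — choose r between h and t from a closed option list;
* link prediction — predict t from (h, r) and h from (r, t).

A generative model will happily answer all of these, including for
assertions it invented. *Cyclic verification* exploits the redundancy: the
same triple is posed as every applicable question and each check casts a
vote (classification votes iff "true", relation prediction iff it returns
r, link prediction iff it returns the held-out endpoint). A consensus
policy decides acceptance from the votes; the default demands unanimity
over {classify, relation, link_tail}, which maximizes precision of the
accepted set — the point of the mechanism is hallucination control, so a
triple the model cannot re-derive from every direction does not enter the
graph.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from ._text import normalize_label, normalize_surface, verbalize_label
from .gateway import (
    Backend,
    ChatSession,
    GenerationSettings,
    PromptTemplate,
    TranscriptLog,
    chat,
    render_prompt,
)
from .graph import KnowledgeGraph, Provenance, TripleRecord
from .schema import RELATION_PREDICTION_OPTIONS
from .templates import get_template

__all__ = [
    "CompletionCandidate",
    "VerificationRecord",
    "ConsensusPolicy",
    "UNANIMITY",
    "MAJORITY",
    "classify_triple",
    "predict_relation",
    "predict_link",
    "cyclic_verify",
    "complete_graph",
]

logger = logging.getLogger(__name__)

ALL_CHECKS = ("classify", "relation", "link_tail", "link_head")


@dataclass(frozen=True)
class ConsensusPolicy:
    name: str
    required_votes: int
    applicable_checks: tuple[str, ...] = ("classify", "relation", "link_tail")

    def __post_init__(self) -> None:
        unknown = set(self.applicable_checks) - set(ALL_CHECKS)
        if unknown:
            raise ValueError(f"unknown checks: {sorted(unknown)}")
        if not 1 <= self.required_votes <= len(self.applicable_checks):
            raise ValueError("require 1 <= required_votes <= |applicable_checks|")


#: Default: all three primary checks must agree (link_head stays optional).
UNANIMITY = ConsensusPolicy("unanimity", 3)
MAJORITY = ConsensusPolicy("majority", 2)
POLICIES = {
    "unanimity": UNANIMITY,
    "majority": MAJORITY,
    "any": ConsensusPolicy("any", 1),
    "unanimity4": ConsensusPolicy("unanimity4", 4, ALL_CHECKS),
}


@dataclass(frozen=True)
class CompletionCandidate:
    """A triple proposal with at most one unknown field before resolution."""

    head: str = ""
    relation: str = ""
    tail: str = ""
    origin: str = "seed"

    def missing_field(self) -> str | None:
        empty = [f for f, v in (("head", self.head), ("relation", self.relation), ("tail", self.tail)) if not v]
        if len(empty) > 1:
            raise ValueError(f"candidate has {len(empty)} empty fields; at most one allowed")
        return empty[0] if empty else None


@dataclass
class VerificationRecord:
    triple: tuple[str, str, str]
    checks: dict = field(default_factory=dict)  # check name -> raw outcome
    votes_passed: int = 0
    accepted: bool = False
    policy: str = ""

    def to_dict(self) -> dict:
        return {
            "triple": list(self.triple),
            "checks": dict(self.checks),
            "votes_passed": self.votes_passed,
            "accepted": self.accepted,
            "policy": self.policy,
        }


# ---------------------------------------------------------------------------
# the three tasks

def classify_triple(
    triple: tuple[str, str, str],
    backend: Backend,
    settings: GenerationSettings = GenerationSettings(),
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> bool:
    """True/false verdict on a fully specified triple.

    Parsed case-insensitively; anything that is not an unambiguous "true"
    is conservatively false (with a warning for genuinely odd answers).
    """
    head, relation, tail = triple
    session = ChatSession(id=f"tc:{head}|{relation}|{tail}", meta={"task": "triple_classification"})
    prompt = render_prompt(
        get_template("triple_classification", templates),
        {"head": head, "relation_text": verbalize_label(relation), "tail": tail},
    )
    response, _ = chat(session, prompt, backend, settings, log)
    has_true = re.search(r"\btrue\b", response, re.I)
    has_false = re.search(r"\bfalse\b", response, re.I)
    if has_true and not has_false:
        return True
    if not has_false:
        logger.warning("unparseable classification answer %r; treating as false", response)
    return False


def predict_relation(
    head: str,
    tail: str,
    options: tuple[str, ...] | list[str] = RELATION_PREDICTION_OPTIONS,
    backend: Backend | None = None,
    settings: GenerationSettings = GenerationSettings(),
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> str:
    """Predict the relation between two entities from a closed option list.

    The answer must name a member of ``options``: exact (normalized) match
    first, else the longest option found as a substring of the response.
    Anything else yields "" with a warning — the vocabulary is closed.
    """
    if not options:
        raise ValueError("options must be non-empty")
    session = ChatSession(id=f"rp:{head}|{tail}", meta={"task": "relation_prediction"})
    prompt = render_prompt(
        get_template("relation_prediction", templates),
        {"head": head, "tail": tail, "options": ", ".join(f"'{o}'" for o in options)},
    )
    response, _ = chat(session, prompt, backend, settings, log)
    answer = normalize_label(response.strip().strip("'\"."))
    for option in options:
        if normalize_label(option) == answer:
            return option
    norm_response = normalize_label(response)
    hits = [o for o in options if normalize_label(o) in norm_response]
    if hits:
        return max(hits, key=lambda o: len(normalize_label(o)))
    logger.warning("relation answer %r matches no option", response)
    return ""


def predict_link(
    head: str = "",
    relation: str = "",
    tail: str = "",
    backend: Backend | None = None,
    settings: GenerationSettings = GenerationSettings(),
    target_hint: str = "disease",
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> str:
    """Predict the missing endpoint of a triple; exactly one must be empty.

    ``target_hint`` names the kind of entity asked for ("... what
    disease?"); pass the schema type's description for non-disease slots.
    """
    if bool(head) == bool(tail):
        raise ValueError("exactly one of head/tail must be empty")
    if not relation:
        raise ValueError("relation is required for link prediction")
    direction = "tail" if head else "head"
    session = ChatSession(id=f"lp-{direction}:{head or tail}|{relation}", meta={"task": "link_prediction"})
    if direction == "tail":
        prompt = render_prompt(
            get_template("link_prediction_tail", templates),
            {"head": head, "relation_text": verbalize_label(relation), "target_hint": target_hint},
        )
    else:
        prompt = render_prompt(
            get_template("link_prediction_head", templates),
            {"tail": tail, "relation_text": verbalize_label(relation), "target_hint": target_hint},
        )
    response, _ = chat(session, prompt, backend, settings, log)
    answer = response.strip().splitlines()[0].strip().strip("'\".") if response.strip() else ""
    if normalize_surface(answer) in ("", "none", "unknown", "empty"):
        return ""
    return answer


# ---------------------------------------------------------------------------
# cyclic verification

def cyclic_verify(
    candidate: tuple[str, str, str],
    backend: Backend,
    settings: GenerationSettings = GenerationSettings(),
    policy: ConsensusPolicy = UNANIMITY,
    options: tuple[str, ...] | list[str] = RELATION_PREDICTION_OPTIONS,
    target_hint: str = "disease",
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
    source_hint: str | None = None,
) -> VerificationRecord:
    """Cross-check one fully specified triple with every applicable task.

    Each check votes independently; a failed or unparseable check is a
    non-vote, never an error. ``accepted`` follows deterministically from
    the votes and the policy.
    """
    head, relation, tail = candidate
    if not (head and relation and tail):
        raise ValueError("cyclic verification needs a fully specified triple")
    record = VerificationRecord(triple=candidate, policy=policy.name)
    votes = 0
    for check in policy.applicable_checks:
        if check == "classify":
            verdict = classify_triple(candidate, backend, settings, templates, log)
            record.checks["classify"] = verdict
            votes += int(verdict)
        elif check == "relation":
            predicted = predict_relation(head, tail, options, backend, settings, templates, log)
            record.checks["relation"] = predicted
            votes += int(bool(predicted) and normalize_label(predicted) == normalize_label(relation))
        elif check == "link_tail":
            predicted = predict_link(
                head=head, relation=relation, backend=backend, settings=settings,
                target_hint=target_hint, templates=templates, log=log,
            )
            record.checks["link_tail"] = predicted
            votes += int(bool(predicted) and normalize_surface(predicted) == normalize_surface(tail))
        elif check == "link_head":
            predicted = predict_link(
                tail=tail, relation=relation, backend=backend, settings=settings,
                target_hint=source_hint or target_hint, templates=templates, log=log,
            )
            record.checks["link_head"] = predicted
            votes += int(bool(predicted) and normalize_surface(predicted) == normalize_surface(head))
    record.votes_passed = votes
    record.accepted = votes >= policy.required_votes
    return record


def complete_graph(
    kg: KnowledgeGraph,
    seeds: list[CompletionCandidate],
    backend: Backend,
    settings: GenerationSettings = GenerationSettings(),
    policy: ConsensusPolicy = UNANIMITY,
    options: tuple[str, ...] | list[str] | None = None,
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> tuple[list[TripleRecord], list[VerificationRecord]]:
    """Resolve seeds, verify each cyclically, and store the accepted ones.

    Each seed's missing field (if any) is filled by the matching task,
    then the full triple runs through :func:`cyclic_verify`. Only accepted
    triples enter the graph (status ``verified``); the full ledger of
    verification records — accepted or not — is returned alongside.
    Unresolvable seeds (empty prediction) are recorded and skipped.
    """
    if options is None:
        options = tuple(kg.schema.relation_type_names()) or RELATION_PREDICTION_OPTIONS
    accepted_triples: list[TripleRecord] = []
    ledger: list[VerificationRecord] = []
    for seed in seeds:
        missing = seed.missing_field()
        head, relation, tail = seed.head, seed.relation, seed.tail
        if missing == "relation":
            relation = predict_relation(head, tail, options, backend, settings, templates, log)
        elif missing in ("head", "tail"):
            hint = _endpoint_hint(kg, relation, missing)
            predicted = predict_link(
                head=head, relation=relation, tail=tail, backend=backend,
                settings=settings, target_hint=hint, templates=templates, log=log,
            )
            if missing == "head":
                head = predicted
            else:
                tail = predicted
        if not (head and relation and tail):
            ledger.append(
                VerificationRecord(
                    triple=(seed.head, seed.relation, seed.tail),
                    checks={"resolution": "failed"},
                    policy=policy.name,
                )
            )
            continue
        record = cyclic_verify(
            (head, relation, tail), backend, settings, policy, options,
            _endpoint_hint(kg, relation, "tail"), templates, log,
            source_hint=_endpoint_hint(kg, relation, "head"),
        )
        ledger.append(record)
        if not record.accepted:
            continue
        rel_spec = kg.schema.relation_type(relation)
        if rel_spec is None:
            record.checks["stored"] = "skipped: relation not in typed schema"
            continue
        head_id = _register(kg, head, rel_spec.source_type)
        tail_id = _register(kg, tail, rel_spec.target_type)
        triple = TripleRecord(
            head=head_id,
            relation=rel_spec.name,
            tail=tail_id,
            status="verified",
            provenance=Provenance(stage="completion", session_ref=f"kgc:{head}|{relation}|{tail}"),
        )
        added, _rejected = kg.add_triples([triple])
        if added:
            accepted_triples.append(triple)
    return accepted_triples, ledger


def _endpoint_hint(kg: KnowledgeGraph, relation: str, which: str) -> str:
    """Human phrasing of the entity kind a link question asks for."""
    spec = kg.schema.relation_type(relation) if relation else None
    if spec is None:
        return "disease"
    type_name = spec.source_type if which == "head" else spec.target_type
    return verbalize_label(type_name)


def _register(kg: KnowledgeGraph, surface: str, type_name: str) -> str:
    """Match an answer to an existing entity by normalized surface, else
    auto-register it flagged for review — completion mines new knowledge."""
    existing = kg.entity_by_surface(surface)
    if existing is not None:
        return existing.id
    eid = kg.ensure_entity(surface, type_name)
    kg.entities[eid].attributes.setdefault("reviewed", "false")
    return eid
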