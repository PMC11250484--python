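"""Two-step and single-shot ("vanilla") information extraction over chunks.

The two-step protocol first asks *which* entity types (or relation types)
a chunk contains, then issues one follow-up query per confirmed type to
pull out the instances; the chunk text travels only in the step-1 prompt
because the chat session carries the history. Decomposing the task this
way bounds each answer to a single type, which makes the responses short,
parseable, and attributable: a type missed in step 1 costs exactly that
type's items and nothing else.

Call-count law (asserted by tests): two-step NER issues ``1 + (number of
types reported present)`` backend calls, two-step RE ``1 + (number of
relations reported present)``, and the vanilla prompts exactly 1. When
step 1 reports nothing, step 2 is skipped entirely.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from ._text import normalize_label, normalize_surface
from .gateway import (
    Backend,
    ChatSession,
    GenerationSettings,
    PromptTemplate,
    TranscriptLog,
    chat,
    render_prompt,
)
from .chunker import TextChunk
from .schema import Schema
from .templates import get_template

__all__ = [
    "ExtractionResult",
    "AnnotatedChunk",
    "FewShotBlock",
    "ner_two_step",
    "re_two_step",
    "extract_vanilla",
    "build_fewshot_block",
]

_BULLET = re.compile(r"^\s*(?:[-*•]+|\d+[.)])\s*")
_PAIR = re.compile(r"\(([^(),]+),([^()]+)\)")
_TRIPLE = re.compile(r"\(([^(),]+),([^(),]+),([^()]+)\)")
_NONE_RE = re.compile(r"^\s*(none|no .*|n/?a)\s*\.?\s*$", re.I)


@dataclass
class ExtractionResult:
    """Entities and triples extracted from one chunk, plus parse failures."""

    chunk_id: str
    entities: list[tuple[str, str]] = field(default_factory=list)  # (surface, type)
    triples: list[tuple[str, str, str]] = field(default_factory=list)  # (h, r, t)
    parse_failures: list[str] = field(default_factory=list)
    sessions: list[ChatSession] = field(default_factory=list)

    def add_entity(self, surface: str, type_name: str) -> None:
        key = (normalize_surface(surface), normalize_label(type_name))
        if key[0] and key not in self._entity_keys():
            self.entities.append((surface.strip(), type_name))

    def add_triple(self, head: str, relation: str, tail: str) -> None:
        key = (normalize_surface(head), normalize_label(relation), normalize_surface(tail))
        if all(key) and key not in self._triple_keys():
            self.triples.append((head.strip(), relation, tail.strip()))

    def _entity_keys(self) -> set[tuple[str, str]]:
        return {(normalize_surface(s), normalize_label(t)) for s, t in self.entities}

    def _triple_keys(self) -> set[tuple[str, str, str]]:
        return {
            (normalize_surface(h), normalize_label(r), normalize_surface(t))
            for h, r, t in self.triples
        }

    def to_dict(self) -> dict:
        return {
            "chunk_id": self.chunk_id,
            "entities": [list(e) for e in self.entities],
            "triples": [list(t) for t in self.triples],
            "parse_failures": list(self.parse_failures),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ExtractionResult":
        return cls(
            chunk_id=data["chunk_id"],
            entities=[tuple(e) for e in data.get("entities", [])],
            triples=[tuple(t) for t in data.get("triples", [])],
            parse_failures=list(data.get("parse_failures", [])),
        )


@dataclass(frozen=True)
class AnnotatedChunk:
    """A gold-annotated chunk, the unit few-shot examples are drawn from."""

    chunk_id: str
    text: str
    entities: tuple[tuple[str, str], ...] = ()
    triples: tuple[tuple[str, str, str], ...] = ()


@dataclass(frozen=True)
class FewShotBlock:
    """Balanced positive/negative worked examples prepended to a prompt.

    A *negative* example is a chunk whose expected answer is explicitly
    empty (``None``) — the minimal counterpart to a positive example in an
    extraction task, where the null answer is a real and frequent outcome.
    """

    k: int
    examples: tuple[tuple[str, str], ...]  # (input excerpt, expected answer)
    seed: int

    def render(self) -> str:
        if not self.examples:
            return ""
        parts = [f"Here are {len(self.examples)} examples."]
        for i, (excerpt, answer) in enumerate(self.examples, 1):
            parts.append(f"Example {i}:\nText: {excerpt}\nAnswer: {answer}")
        return "\n".join(parts) + "\nNow the task.\n"


# ---------------------------------------------------------------------------
# response parsing

def parse_type_list(response: str, valid_names: list[str]) -> tuple[list[str], bool]:
    """Names from ``valid_names`` reported present in a step-1 answer.

    Returns (present types in ``valid_names`` order, parse ok). A response
    is unparseable when it neither matches any valid name nor says none.
    """
    if _NONE_RE.match(response.strip()):
        return [], True
    by_key = {normalize_label(n): n for n in valid_names}
    found: set[str] = set()
    for token in re.split(r"[,;\n]+", response):
        token = _BULLET.sub("", token).strip().strip(".")
        key = normalize_label(token)
        if key in by_key:
            found.add(by_key[key])
    ordered = [n for n in valid_names if n in found]
    return ordered, bool(ordered)


def parse_entity_lines(
    response: str, schema: Schema, requested_type: str
) -> tuple[list[tuple[str, str]], list[str]]:
    """Parse ``Type: e1; e2`` lines; a bare list falls to the requested type.

    Lines claiming a type the schema does not declare are dropped and
    recorded as failures.
    """
    entities: list[tuple[str, str]] = []
    failures: list[str] = []
    for line in response.splitlines():
        line = _BULLET.sub("", line).strip()
        if not line or _NONE_RE.match(line):
            continue
        type_name, _, rest = line.partition(":")
        if rest and schema.entity_type(type_name.strip()):
            declared = schema.entity_type(type_name.strip()).name
            surfaces = rest
        elif rest and _looks_like_label(type_name):
            failures.append(line)  # claims an undeclared type
            continue
        else:
            declared, surfaces = requested_type, line
        for surface in surfaces.split(";"):
            surface = surface.strip().strip(".")
            if surface and not _NONE_RE.match(surface):
                entities.append((surface, declared))
    return entities, failures


def _looks_like_label(text: str) -> bool:
    return bool(re.fullmatch(r"[A-Za-z_][A-Za-z0-9_ -]{0,40}", text.strip()))


def parse_pair_lines(response: str) -> tuple[list[tuple[str, str]], list[str]]:
    """Parse ``(head, tail)`` pairs; malformed non-empty lines are failures."""
    pairs: list[tuple[str, str]] = []
    failures: list[str] = []
    for line in response.splitlines():
        stripped = _BULLET.sub("", line).strip()
        if not stripped or _NONE_RE.match(stripped):
            continue
        found = _PAIR.findall(stripped)
        if not found:
            failures.append(stripped)
            continue
        for h, t in found:
            pairs.append((h.strip(), t.strip()))
    return pairs, failures


def parse_triple_lines(
    response: str, schema: Schema
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Parse ``(head, relation, tail)`` lines against the schema's labels."""
    triples: list[tuple[str, str, str]] = []
    failures: list[str] = []
    for line in response.splitlines():
        stripped = _BULLET.sub("", line).strip()
        if not stripped or _NONE_RE.match(stripped):
            continue
        found = _TRIPLE.findall(stripped)
        if not found:
            failures.append(stripped)
            continue
        for h, r, t in found:
            r = r.strip()
            rel = schema.relation_type(r)
            if rel is None and not schema.has_relation_label(r):
                failures.append(stripped)
                continue
            triples.append((h.strip(), rel.name if rel else r, t.strip()))
    return triples, failures


# ---------------------------------------------------------------------------
# extraction operations

def ner_two_step(
    chunk: TextChunk,
    schema: Schema,
    shots: FewShotBlock | None,
    backend: Backend,
    settings: GenerationSettings = GenerationSettings(),
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> ExtractionResult:
    """Two-step NER: one type-presence call, then one call per present type."""
    if not schema.entity_types:
        raise ValueError("schema declares no entity types")
    result = ExtractionResult(chunk_id=chunk.id)
    session = ChatSession(id=f"ner:{chunk.id}", meta={"chunk_id": chunk.id, "task": "ner"})
    result.sessions.append(session)
    step1 = render_prompt(
        get_template("ner_step1", templates),
        {
            "text": chunk.text,
            "entity_types": ", ".join(schema.entity_type_names()),
            "shots": shots.render() if shots else "",
        },
        key_extra={"chunk_id": chunk.id},
    )
    response, _ = chat(session, step1, backend, settings, log)
    present, ok = parse_type_list(response, schema.entity_type_names())
    if not ok:
        result.parse_failures.append(response)
        return result
    for type_name in present:
        step2 = render_prompt(
            get_template("ner_step2", templates),
            {"entity_type": type_name},
            key_extra={"chunk_id": chunk.id},
        )
        response2, _ = chat(session, step2, backend, settings, log)
        entities, failures = parse_entity_lines(response2, schema, type_name)
        for surface, tname in entities:
            result.add_entity(surface, tname)
        result.parse_failures.extend(failures)
    return result


def re_two_step(
    chunk: TextChunk,
    schema: Schema,
    shots: FewShotBlock | None,
    backend: Backend,
    settings: GenerationSettings = GenerationSettings(),
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> ExtractionResult:
    """Two-step RE: relation-presence call, then one pair-listing call per
    confirmed relation; output triples all bear step-1-confirmed relations."""
    if not schema.relation_types:
        raise ValueError("schema declares no relation types")
    result = ExtractionResult(chunk_id=chunk.id)
    session = ChatSession(id=f"re:{chunk.id}", meta={"chunk_id": chunk.id, "task": "re"})
    result.sessions.append(session)
    step1 = render_prompt(
        get_template("re_step1", templates),
        {
            "text": chunk.text,
            "relation_types": ", ".join(schema.relation_type_names()),
            "shots": shots.render() if shots else "",
        },
        key_extra={"chunk_id": chunk.id},
    )
    response, _ = chat(session, step1, backend, settings, log)
    present, ok = parse_type_list(response, schema.relation_type_names())
    if not ok:
        result.parse_failures.append(response)
        return result
    for relation in present:
        step2 = render_prompt(
            get_template("re_step2", templates),
            {"relation": relation},
            key_extra={"chunk_id": chunk.id},
        )
        response2, _ = chat(session, step2, backend, settings, log)
        pairs, failures = parse_pair_lines(response2)
        result.parse_failures.extend(failures)
        spec = schema.relation_type(relation)
        for head, tail in pairs:
            result.add_triple(head, relation, tail)
            result.add_entity(head, spec.source_type)
            result.add_entity(tail, spec.target_type)
    return result


def extract_vanilla(
    chunk: TextChunk,
    schema: Schema,
    mode: str,
    shots: FewShotBlock | None,
    backend: Backend,
    settings: GenerationSettings = GenerationSettings(),
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> ExtractionResult:
    """Single-call baseline: one prompt asks for everything at once."""
    if mode not in ("ner", "re"):
        raise ValueError("mode must be 'ner' or 're'")
    result = ExtractionResult(chunk_id=chunk.id)
    session = ChatSession(
        id=f"vanilla-{mode}:{chunk.id}", meta={"chunk_id": chunk.id, "task": f"vanilla_{mode}"}
    )
    result.sessions.append(session)
    if mode == "ner":
        prompt = render_prompt(
            get_template("vanilla_ner", templates),
            {
                "text": chunk.text,
                "entity_types": ", ".join(schema.entity_type_names()),
                "shots": shots.render() if shots else "",
            },
            key_extra={"chunk_id": chunk.id},
        )
        response, _ = chat(session, prompt, backend, settings, log)
        if not response.strip() or response.strip() == "(empty)":
            result.parse_failures.append(response)
            return result
        entities, failures = parse_entity_lines(response, schema, requested_type="")
        for surface, tname in entities:
            if schema.entity_type(tname):
                result.add_entity(surface, tname)
            else:
                failures.append(f"{tname}: {surface}")
        result.parse_failures.extend(failures)
    else:
        prompt = render_prompt(
            get_template("vanilla_re", templates),
            {
                "text": chunk.text,
                "relation_types": ", ".join(schema.relation_type_names()),
                "shots": shots.render() if shots else "",
            },
            key_extra={"chunk_id": chunk.id},
        )
        response, _ = chat(session, prompt, backend, settings, log)
        if not response.strip() or response.strip() == "(empty)":
            result.parse_failures.append(response)
            return result
        triples, failures = parse_triple_lines(response, schema)
        result.parse_failures.extend(failures)
        for head, relation, tail in triples:
            spec = schema.relation_type(relation)
            result.add_triple(head, relation, tail)
            if spec is not None:
                result.add_entity(head, spec.source_type)
                result.add_entity(tail, spec.target_type)
    return result


# ---------------------------------------------------------------------------
# few-shot construction

def serialize_ner_answer(chunk: AnnotatedChunk) -> str:
    if not chunk.entities:
        return "None"
    by_type: dict[str, list[str]] = {}
    for surface, tname in chunk.entities:
        by_type.setdefault(tname, []).append(surface)
    return "\n".join(f"{t}: {'; '.join(es)}" for t, es in by_type.items())


def serialize_re_answer(chunk: AnnotatedChunk) -> str:
    if not chunk.triples:
        return "None"
    return "\n".join(f"({h}, {r}, {t})" for h, r, t in chunk.triples)


def build_fewshot_block(
    gold: list[AnnotatedChunk], k: int, seed: int, task: str = "ner"
) -> FewShotBlock:
    """Sample a balanced few-shot block from gold-annotated chunks.

    Positives are chunks with at least one gold item for ``task``;
    negatives are chunks with none, serialized with the explicit empty
    answer. Sampling is deterministic under ``seed``; an insufficient pool
    raises with the exact deficit.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return FewShotBlock(k=0, examples=(), seed=seed)
    serialize = serialize_ner_answer if task == "ner" else serialize_re_answer
    has_items = (
        (lambda c: bool(c.entities)) if task == "ner" else (lambda c: bool(c.triples))
    )
    positives = sorted((c for c in gold if has_items(c)), key=lambda c: c.chunk_id)
    negatives = sorted((c for c in gold if not has_items(c)), key=lambda c: c.chunk_id)
    n_pos = (k + 1) // 2
    n_neg = k // 2
    if len(positives) < n_pos or len(negatives) < n_neg:
        raise ValueError(
            f"insufficient gold for {k}-shot block: need {n_pos} positive "
            f"(have {len(positives)}) and {n_neg} negative (have {len(negatives)})"
        )
    rng = random.Random(seed)
    chosen = rng.sample(positives, n_pos) + rng.sample(negatives, n_neg)
    rng.shuffle(chosen)
    return FewShotBlock(
        k=k,
        examples=tuple((c.text, serialize(c)) for c in chosen),
        seed=seed,
    )
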