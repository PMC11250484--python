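"""Duplicate-entity detection and merging.

Triples mined from different documents inevitably name the same concept
with different surfaces ("Heart Failure" vs "Congestive Heart Failure").
Candidates are nominated structurally — Jaccard similarity between head
entities' outgoing-triple neighborhoods — and adjudicated by the model,
then merged transitively.

Two similarity modes exist. The default compares the sets of (relation,
tail) pairs: J = |pairs_A ∩ pairs_B| / |pairs_A ∪ pairs_B|. A "literal"
mode computes |R_A ∩ R_B ∩ T_A ∩ T_B| / |R_A ∪ R_B ∪ T_A ∪ T_B| over the
raw relation and tail sets; because relation labels and entity ids are
disjoint vocabularies, its numerator is empty on ordinary graphs, so it is
kept only for fidelity experiments and the pair mode is the default.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx

from ._text import normalize_surface
from .gateway import (
    Backend,
    ChatSession,
    GenerationSettings,
    PromptTemplate,
    TranscriptLog,
    chat,
    render_prompt,
)
from .graph import KnowledgeGraph, TripleRecord
from .templates import get_template

__all__ = [
    "EntityProfile",
    "MergeDecision",
    "entity_profile",
    "jaccard_similarity",
    "candidate_pairs",
    "resolve_pair",
    "apply_merges",
]

logger = logging.getLogger(__name__)

_CANONICAL = re.compile(r"canonical\s*[:=]\s*(.+)", re.I)
_MERGE_HINT = re.compile(r"\b(same entity|are the same|merge|identical entity)\b", re.I)
_DISTINCT_HINT = re.compile(r"\b(different entit|distinct|not the same|are different)\b", re.I)


@dataclass(frozen=True)
class EntityProfile:
    """Outgoing-triple neighborhood of a head entity."""

    entity: str
    relations: frozenset[str]
    tails: frozenset[str]
    pairs: frozenset[tuple[str, str]]


@dataclass
class MergeDecision:
    pair: tuple[str, str]  # entity ids
    score: float
    verdict: str  # "merge" | "distinct"
    rationale: str = ""
    canonical: str = ""

    def __post_init__(self) -> None:
        if self.verdict == "merge" and not self.canonical:
            raise ValueError("merge verdict requires a canonical surface")


def entity_profile(kg: KnowledgeGraph, entity_id: str) -> EntityProfile:
    """Relations, tails and (relation, tail) pairs where the entity is head."""
    if entity_id not in kg.entities:
        raise KeyError(f"unknown entity id {entity_id!r}")
    pairs = {(t.relation, t.tail) for t in kg.outgoing(entity_id)}
    return EntityProfile(
        entity=entity_id,
        relations=frozenset(r for r, _ in pairs),
        tails=frozenset(t for _, t in pairs),
        pairs=frozenset(pairs),
    )


def jaccard_similarity(a: EntityProfile, b: EntityProfile, mode: str = "pairs") -> float:
    """Jaccard similarity of two head-entity profiles, in [0, 1].

    Empty-over-empty is 0 by convention: two entities about which nothing
    is asserted are not evidence for a merge.
    """
    if mode == "pairs":
        union = a.pairs | b.pairs
        if not union:
            return 0.0
        return len(a.pairs & b.pairs) / len(union)
    if mode == "literal":
        union = a.relations | b.relations | a.tails | b.tails
        if not union:
            return 0.0
        inter = a.relations & b.relations & a.tails & b.tails
        return len(inter) / len(union)
    raise ValueError(f"unknown similarity mode {mode!r}")


def candidate_pairs(
    kg: KnowledgeGraph, threshold: float = 0.3, mode: str = "pairs"
) -> list[tuple[str, str, float]]:
    """All unordered head-entity pairs scoring >= threshold, ranked.

    Descending by score; ties broken lexicographically by the pair's
    surfaces so the ordering is deterministic.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    heads = sorted({t.head for t in kg.triples})
    profiles = {h: entity_profile(kg, h) for h in heads}
    out: list[tuple[str, str, float]] = []
    for i, a in enumerate(heads):
        for b in heads[i + 1 :]:
            score = jaccard_similarity(profiles[a], profiles[b], mode)
            if score >= threshold:
                first, second = sorted((a, b), key=lambda e: kg.entities[e].surface)
                out.append((first, second, score))
    out.sort(key=lambda r: (-r[2], kg.entities[r[0]].surface, kg.entities[r[1]].surface))
    return out


def _format_triples(kg: KnowledgeGraph, entity_id: str) -> str:
    lines = [
        f"({kg.entities[t.head].surface}, {t.relation}, {kg.entities[t.tail].surface})"
        for t in sorted(kg.outgoing(entity_id), key=kg.triple_key)
    ]
    return "\n".join(lines) if lines else "(no triples)"


def resolve_pair(
    pair: tuple[str, str],
    kg: KnowledgeGraph,
    backend: Backend,
    settings: GenerationSettings = GenerationSettings(),
    score: float = 0.0,
    templates: dict[str, PromptTemplate] | None = None,
    log: TranscriptLog | None = None,
) -> MergeDecision:
    """Ask the model whether two candidate entities are the same.

    The prompt embeds both entities' triples. An unparseable verdict falls
    back to "distinct" with a logged warning — a missed merge is cheaper
    than a wrong one.
    """
    a_id, b_id = sorted(pair, key=lambda e: kg.entities[e].surface)
    ea, eb = kg.entities[a_id], kg.entities[b_id]
    session = ChatSession(id=f"ed:{a_id}|{b_id}", meta={"task": "disambiguation"})
    prompt = render_prompt(
        get_template("disambiguation", templates),
        {
            "entity_a": ea.surface,
            "entity_b": eb.surface,
            "triples_a": _format_triples(kg, a_id),
            "triples_b": _format_triples(kg, b_id),
        },
    )
    response, _ = chat(session, prompt, backend, settings, log)

    merge_hit = bool(_MERGE_HINT.search(response))
    distinct_hit = bool(_DISTINCT_HINT.search(response))
    if merge_hit and not distinct_hit:
        verdict = "merge"
    elif distinct_hit and not merge_hit:
        verdict = "distinct"
    else:
        logger.warning("unparseable disambiguation verdict for (%s, %s)", a_id, b_id)
        verdict = "distinct"

    canonical = ""
    if verdict == "merge":
        m = _CANONICAL.search(response)
        if m:
            canonical = m.group(1).strip().strip("\"'.")
        if not canonical:
            # fall back to the better-supported surface
            na = sum(1 for _ in kg.outgoing(a_id))
            nb = sum(1 for _ in kg.outgoing(b_id))
            canonical = ea.surface if na >= nb else eb.surface
    return MergeDecision(
        pair=(a_id, b_id), score=score, verdict=verdict, rationale=response, canonical=canonical
    )


def apply_merges(
    kg: KnowledgeGraph, decisions: list[MergeDecision]
) -> tuple[KnowledgeGraph, dict]:
    """Union merge verdicts transitively and rewrite the graph.

    Entity identity is an equivalence relation, so pairwise merge verdicts
    are closed under connected components. Each component keeps one
    survivor carrying the canonical surface; every other surface becomes
    an alias, triples are rewritten to the survivor id, and (h, r, t)
    duplicates (and self-loops created by the rewrite) are dropped.
    """
    merged_pairs = [d for d in decisions if d.verdict == "merge"]
    graph = nx.Graph()
    for d in merged_pairs:
        a, b = d.pair
        if a not in kg.entities or b not in kg.entities:
            raise KeyError(f"merge decision references unknown entity: {d.pair}")
        graph.add_edge(a, b)

    report: dict = {"components": [], "conflicts": [], "dropped_triples": 0}
    remap: dict[str, str] = {}
    new_kg = kg.copy()

    for component in sorted(nx.connected_components(graph), key=min):
        members = sorted(component)
        canonicals = sorted(
            {d.canonical for d in merged_pairs if set(d.pair) <= component and d.canonical}
        )
        if len(canonicals) == 1:
            canonical = canonicals[0]
        else:
            # conflict: pick the surface supported by the most triples
            def support(eid: str) -> int:
                return sum(1 for t in kg.triples if t.head == eid or t.tail == eid)

            best = sorted(members, key=lambda e: (-support(e), kg.entities[e].surface))[0]
            canonical = kg.entities[best].surface
            report["conflicts"].append({"members": members, "canonicals": canonicals})
            logger.warning("conflicting canonical names in component %s", members)

        survivor_id = next(
            (m for m in members if normalize_surface(kg.entities[m].surface) == normalize_surface(canonical)),
            members[0],
        )
        survivor = new_kg.entities[survivor_id]
        survivor.surface = canonical
        for m in members:
            if m == survivor_id:
                continue
            other = new_kg.entities.pop(m)
            survivor.aliases |= {other.surface} | other.aliases
            survivor.attributes = {**other.attributes, **survivor.attributes}
            remap[m] = survivor_id
        survivor.aliases.discard(survivor.surface)
        report["components"].append(
            {"members": members, "survivor": survivor_id, "canonical": canonical}
        )

    rewritten: list[TripleRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for t in new_kg.triples:
        head = remap.get(t.head, t.head)
        tail = remap.get(t.tail, t.tail)
        if head == tail:
            report["dropped_triples"] += 1
            continue
        nt = TripleRecord(
            head=head, relation=t.relation, tail=tail, provenance=t.provenance, status=t.status
        )
        key = new_kg.triple_key(nt)
        if key in seen:
            report["dropped_triples"] += 1
            continue
        seen.add(key)
        rewritten.append(nt)
    new_kg.triples = rewritten
    return new_kg, report
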