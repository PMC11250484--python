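"""Synthetic fixtures: truth graph, templated corpus, gold, scripted backend.

The reference corpus behind this pipeline is private, so every stage is
exercised against generated stand-ins instead: a schema-conformant truth
graph, a corpus of templated sentences realizing its triples, per-chunk
gold annotations, and a :class:`~chatkg.gateway.BackendScript` that
answers every extraction / disambiguation / completion prompt with the
gold content degraded by controllable error rates.

Error model:

* ``miss_rate`` — each gold entity/triple is independently omitted from
  the scripted step-2 answers (and a step-1 type is reported present only
  while at least one of its items survives), so measured recall at miss
  rate ``m`` is binomially distributed around ``1 - m``;
* ``halluc_rate`` — spurious items with in-vocabulary types/relations but
  novel surfaces are injected into answers and into the completion seed
  list. Hallucinated completion seeds get *no* script entries, so every
  cyclic check falls to the default response and fails — the scripted
  model of a hallucination that cannot be re-derived.
* ``alias_rate`` — a fraction of head entities acquire a duplicate
  surface used for some of their sentences, giving disambiguation a known
  ground truth. Aliases are only given to heads with 2-5 outgoing triples
  and exactly two triples are re-realized under the alias, so the
  alias/canonical pair-Jaccard is 2/k >= 0.4, safely above the default
  candidate threshold.

Everything is a pure function of (schema, spec): the same seed yields the
same graph, corpus, and script, bit for bit.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field

from ._text import verbalize_label, word_count
from .chunker import TextChunk
from .completion import CompletionCandidate
from .extraction import AnnotatedChunk
from .gateway import BackendScript
from .graph import KnowledgeGraph, Provenance, TripleRecord
from .schema import Schema

__all__ = ["FixtureSpec", "Fixture", "generate_truth_graph", "generate_corpus_and_script"]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_entities_per_type: int = 4
    n_triples: int = 80
    chunk_words: tuple[int, int] = (500, 700)
    alias_rate: float = 0.0
    miss_rate: float = 0.0
    halluc_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alias_rate", "miss_rate", "halluc_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_entities_per_type <= 0 or self.n_triples <= 0:
            raise ValueError("entity and triple counts must be positive")
        lo, hi = self.chunk_words
        if not 0 < lo <= hi:
            raise ValueError("chunk_words must be a positive (min, max) range")


@dataclass
class Fixture:
    """Everything one offline run needs."""

    spec: FixtureSpec
    truth: KnowledgeGraph
    alias_map: dict[str, str]  # entity id -> alias surface
    chunks: list[TextChunk] = field(default_factory=list)
    gold: dict[str, AnnotatedChunk] = field(default_factory=dict)
    script: BackendScript = field(default_factory=BackendScript)
    completion_seeds: list[CompletionCandidate] = field(default_factory=list)
    hallucinated_seeds: list[CompletionCandidate] = field(default_factory=list)

    @property
    def all_seeds(self) -> list[CompletionCandidate]:
        return self.completion_seeds + self.hallucinated_seeds


def _entity_surface(type_name: str, index: int) -> str:
    return f"{verbalize_label(type_name)} {index:02d}"


def generate_truth_graph(
    schema: Schema, spec: FixtureSpec
) -> tuple[KnowledgeGraph, dict[str, str]]:
    """Build a schema-conformant truth graph plus the alias ground truth.

    Every entity participates in at least one triple (a coverage pass
    links each entity through some relation its type can take part in),
    then random endpoint-valid triples fill up to ``n_triples``.
    """
    rng = random.Random(spec.seed)
    kg = KnowledgeGraph(schema=schema)
    # only types some relation can touch: an entity type outside every
    # relation signature (the reference schema's Cause type, for instance)
    # could never be realized as a triple endpoint or a corpus sentence
    connected = {rt.source_type for rt in schema.relation_types} | {
        rt.target_type for rt in schema.relation_types
    }
    ids_by_type: dict[str, list[str]] = {}
    for et in schema.entity_types:
        if et.name not in connected:
            continue
        ids_by_type[et.name] = [
            kg.ensure_entity(_entity_surface(et.name, i), et.name)
            for i in range(1, spec.n_entities_per_type + 1)
        ]

    keys: set[tuple[str, str, str]] = set()
    triples: list[TripleRecord] = []

    def try_add(head: str, rel: str, tail: str) -> bool:
        if head == tail:
            return False
        t = TripleRecord(head=head, relation=rel, tail=tail,
                         provenance=Provenance(source_doc="synth", stage="extraction"))
        key = kg.triple_key(t)
        if key in keys:
            return False
        keys.add(key)
        triples.append(t)
        return True

    # coverage: each entity appears in >= 1 triple
    for et in schema.entity_types:
        usable = [
            rt for rt in schema.relation_types
            if et.name in (rt.source_type, rt.target_type)
        ]
        if not usable:
            continue  # isolated type: schema gives it no relation to live in
        for eid in ids_by_type[et.name]:
            if any(eid in (t.head, t.tail) for t in triples):
                continue
            for _ in range(100):
                rt = rng.choice(usable)
                if et.name == rt.source_type:
                    partner = rng.choice(ids_by_type[rt.target_type])
                    if try_add(eid, rt.name, partner):
                        break
                else:
                    partner = rng.choice(ids_by_type[rt.source_type])
                    if try_add(partner, rt.name, eid):
                        break

    if len(triples) > spec.n_triples:
        raise ValueError(
            f"n_triples={spec.n_triples} too small to cover all "
            f"{len(kg.entities)} entities (coverage needs {len(triples)})"
        )
    attempts = 0
    while len(triples) < spec.n_triples:
        attempts += 1
        if attempts > 200 * spec.n_triples:
            raise ValueError(
                f"cannot realize {spec.n_triples} distinct endpoint-valid triples "
                f"with {spec.n_entities_per_type} entities per type"
            )
        rt = rng.choice(schema.relation_types)
        try_add(
            rng.choice(ids_by_type[rt.source_type]),
            rt.name,
            rng.choice(ids_by_type[rt.target_type]),
        )
    kg.triples = triples

    alias_map: dict[str, str] = {}
    if spec.alias_rate > 0:
        out_degree = Counter(t.head for t in triples)
        head_ids = sorted(out_degree)
        eligible = [h for h in head_ids if 2 <= out_degree[h] <= 5]
        n_alias = min(len(eligible), round(spec.alias_rate * len(head_ids)))
        for eid in rng.sample(eligible, n_alias) if n_alias else []:
            alias_map[eid] = f"syn {kg.entities[eid].surface}"
    return kg, alias_map


def _sentence(schema: Schema, head: str, relation: str, tail: str) -> str:
    # one fixed template per relation keeps gold alignment trivial
    return f"The record states that {head} {verbalize_label(relation)} {tail}."


def generate_corpus_and_script(
    kg: KnowledgeGraph,
    alias_map: dict[str, str],
    spec: FixtureSpec,
) -> Fixture:
    """Realize the truth graph as chunks + gold and script every prompt.

    Each triple becomes one templated sentence placed in some chunk; for
    aliased heads, two of their sentences are additionally re-realized
    under the alias surface. The script answers extraction prompts with
    the per-chunk gold (degraded per the spec's error rates), merges for
    the true alias pairs, and the four completion checks for seed triples
    whose (h,r) / (h,t) / (r,t) projections are unique — the uniqueness
    guard keeps single-answer link/relation prompts unambiguous.
    """
    schema = kg.schema
    rng = random.Random(spec.seed + 1)
    err = random.Random(spec.seed + 2)

    surface = lambda eid: kg.entities[eid].surface  # noqa: E731
    type_of = lambda eid: kg.entities[eid].type  # noqa: E731

    # ---- realizations: (head surface, relation, tail surface, head type, tail type)
    realizations: list[tuple[str, str, str, str, str]] = []
    for t in kg.triples:
        realizations.append(
            (surface(t.head), t.relation, surface(t.tail), type_of(t.head), type_of(t.tail))
        )
    for eid, alias in sorted(alias_map.items()):
        own = [t for t in kg.triples if t.head == eid][:2]
        for t in own:
            realizations.append(
                (alias, t.relation, surface(t.tail), type_of(t.head), type_of(t.tail))
            )
    rng.shuffle(realizations)

    # ---- pack sentences into chunks
    chunks: list[TextChunk] = []
    gold: dict[str, AnnotatedChunk] = {}
    buf: list[tuple[str, str, str, str, str]] = []
    buf_words = 0
    target = rng.randint(*spec.chunk_words)

    def flush() -> None:
        nonlocal buf, buf_words, target
        if not buf:
            return
        cid = f"synth-c{len(chunks):04d}"
        text = " ".join(_sentence(schema, h, r, t) for h, r, t, _, _ in buf)
        entities: list[tuple[str, str]] = []
        triples: list[tuple[str, str, str]] = []
        for h, r, t, ht, tt in buf:
            if (h, ht) not in entities:
                entities.append((h, ht))
            if (t, tt) not in entities:
                entities.append((t, tt))
            if (h, r, t) not in triples:
                triples.append((h, r, t))
        chunks.append(TextChunk(id=cid, doc_id="synth", text=text, word_count=word_count(text)))
        gold[cid] = AnnotatedChunk(
            chunk_id=cid, text=text, entities=tuple(entities), triples=tuple(triples)
        )
        buf, buf_words = [], 0
        target = rng.randint(*spec.chunk_words)

    for real in realizations:
        words = word_count(_sentence(schema, real[0], real[1], real[2]))
        if buf and buf_words + words > target:
            flush()
        buf.append(real)
        buf_words += words
    flush()

    # ---- script the extraction prompts
    script = BackendScript(default_response="unknown")
    entity_type_list = ", ".join(schema.entity_type_names())
    relation_type_list = ", ".join(schema.relation_type_names())
    phantom = 0

    for chunk in chunks:
        g = gold[chunk.id]
        kept_entities = [e for e in g.entities if err.random() >= spec.miss_rate]
        if err.random() < spec.halluc_rate:
            phantom += 1
            kept_entities.append(
                (f"phantom finding {phantom:02d}", err.choice(schema.entity_type_names()))
            )
        types_present = [
            et.name for et in schema.entity_types
            if any(t == et.name for _, t in kept_entities)
        ]
        script.add(
            "ner_step1",
            {"entity_types": entity_type_list},
            ", ".join(types_present) if types_present else "None",
            chunk_id=chunk.id,
        )
        ner_lines = []
        for tname in types_present:
            members = "; ".join(s for s, t in kept_entities if t == tname)
            line = f"{tname}: {members}"
            ner_lines.append(line)
            script.add("ner_step2", {"entity_type": tname}, line, chunk_id=chunk.id)
        script.add(
            "vanilla_ner",
            {"entity_types": entity_type_list},
            "\n".join(ner_lines) if ner_lines else "None",
            chunk_id=chunk.id,
        )

        kept_triples = [t for t in g.triples if err.random() >= spec.miss_rate]
        if err.random() < spec.halluc_rate:
            phantom += 1
            rt = err.choice(schema.relation_types)
            kept_triples.append(
                (
                    f"phantom {verbalize_label(rt.source_type)} {phantom:02d}",
                    rt.name,
                    f"phantom {verbalize_label(rt.target_type)} {phantom:02d}",
                )
            )
        rels_present = [
            rt.name for rt in schema.relation_types
            if any(r == rt.name for _, r, _ in kept_triples)
        ]
        script.add(
            "re_step1",
            {"relation_types": relation_type_list},
            ", ".join(rels_present) if rels_present else "None",
            chunk_id=chunk.id,
        )
        for rel in rels_present:
            pairs = "\n".join(f"({h}, {t})" for h, r, t in kept_triples if r == rel)
            script.add("re_step2", {"relation": rel}, pairs, chunk_id=chunk.id)
        script.add(
            "vanilla_re",
            {"relation_types": relation_type_list},
            "\n".join(f"({h}, {r}, {t})" for h, r, t in kept_triples) or "None",
            chunk_id=chunk.id,
        )

    # ---- script the true alias merges
    for eid, alias in sorted(alias_map.items()):
        canonical = surface(eid)
        a, b = sorted((canonical, alias))
        script.add(
            "disambiguation",
            {"entity_a": a, "entity_b": b},
            f"A and B refer to the same entity. Canonical: {canonical}",
        )

    # ---- completion seeds and their scripted checks
    # Greedy selection keeps every seed's (h,r), (h,t) and (r,t) projections
    # unique among the seeds, so each single-answer link/relation prompt has
    # exactly one correct scripted completion.
    used_hr: set[tuple[str, str]] = set()
    used_ht: set[tuple[str, str]] = set()
    used_rt: set[tuple[str, str]] = set()
    completion_seeds: list[CompletionCandidate] = []
    for t in sorted(kg.triples, key=kg.triple_key):
        h, r, tl = surface(t.head), t.relation, surface(t.tail)
        if (h, r) in used_hr or (h, tl) in used_ht or (r, tl) in used_rt:
            continue
        used_hr.add((h, r))
        used_ht.add((h, tl))
        used_rt.add((r, tl))
        rv = verbalize_label(r)
        script.add("triple_classification", {"head": h, "relation_text": rv, "tail": tl}, "True")
        script.add("relation_prediction", {"head": h, "tail": tl}, r)
        script.add("link_prediction_tail", {"head": h, "relation_text": rv}, tl)
        script.add("link_prediction_head", {"tail": tl, "relation_text": rv}, h)
        completion_seeds.append(CompletionCandidate(head=h, relation=r, tail=tl, origin="truth"))

    hallucinated_seeds: list[CompletionCandidate] = []
    if spec.halluc_rate > 0 and completion_seeds:
        n_halluc = max(1, round(spec.halluc_rate * len(completion_seeds)))
        for i in range(n_halluc):
            rt = err.choice(schema.relation_types)
            hallucinated_seeds.append(
                CompletionCandidate(
                    head=f"spurious {verbalize_label(rt.source_type)} {i:02d}",
                    relation=rt.name,
                    tail=f"spurious {verbalize_label(rt.target_type)} {i:02d}",
                    origin="hallucination",
                )
            )

    return Fixture(
        spec=spec,
        truth=kg,
        alias_map=dict(alias_map),
        chunks=chunks,
        gold=gold,
        script=script,
        completion_seeds=completion_seeds,
        hallucinated_seeds=hallucinated_seeds,
    )
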