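"""In-memory knowledge graph store: entities, triples, validation, statistics.

Triple identity is the normalized (head surface, relation, tail surface)
tuple — case-folded, whitespace-collapsed, outer punctuation stripped — so
re-extracting the same assertion from two documents stores it once. Entity
ids are the normalized surface form, which makes ids stable across
serialization and keeps surface-level identity and id-level identity in
lock-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from ._text import normalize_label, normalize_surface
from .schema import Schema, validate_schema

__all__ = [
    "Provenance",
    "TripleRecord",
    "EntityRecord",
    "KnowledgeGraph",
    "TRIPLE_STATUSES",
]

TRIPLE_STATUSES = ("extracted", "completed", "verified", "refined", "rejected")


@dataclass(frozen=True)
class Provenance:
    """Where an assertion came from: document, chunk, pipeline stage, chat."""

    source_doc: str = ""
    chunk_id: str = ""
    stage: str = "extraction"  # "extraction" | "completion"
    session_ref: str = ""


@dataclass(frozen=True)
class TripleRecord:
    """A directed head -(relation)-> tail assertion between entity ids."""

    head: str
    relation: str
    tail: str
    provenance: Provenance = Provenance()
    status: str = "extracted"


@dataclass
class EntityRecord:
    id: str
    surface: str
    type: str
    attributes: dict[str, str] = field(default_factory=dict)
    aliases: set[str] = field(default_factory=set)


def entity_id_for(surface: str) -> str:
    """Entity id derived from a surface form (normalized surface)."""
    return normalize_surface(surface)


@dataclass
class KnowledgeGraph:
    schema: Schema
    entities: dict[str, EntityRecord] = field(default_factory=dict)
    triples: list[TripleRecord] = field(default_factory=list)

    # -- entities --------------------------------------------------------

    def ensure_entity(self, surface: str, type_name: str) -> str:
        """Register (or fetch) the entity for ``surface``; returns its id.

        The type must be declared in the schema. A surface already stored
        keeps its original type and casing; later sightings only confirm it.
        """
        eid = entity_id_for(surface)
        if not eid:
            raise ValueError("entity surface is empty after normalization")
        if eid in self.entities:
            return eid
        spec = self.schema.entity_type(type_name)
        if spec is None:
            raise ValueError(f"entity type {type_name!r} not declared in schema")
        self.entities[eid] = EntityRecord(id=eid, surface=surface.strip(), type=spec.name)
        return eid

    def entity_by_surface(self, surface: str) -> EntityRecord | None:
        return self.entities.get(entity_id_for(surface))

    # -- triples ---------------------------------------------------------

    def triple_key(self, t: TripleRecord) -> tuple[str, str, str]:
        head = self.entities[t.head].surface if t.head in self.entities else t.head
        tail = self.entities[t.tail].surface if t.tail in self.entities else t.tail
        return (normalize_surface(head), normalize_label(t.relation), normalize_surface(tail))

    def triple_keys(self) -> set[tuple[str, str, str]]:
        return {self.triple_key(t) for t in self.triples}

    def add_triples(
        self, triples: Iterable[TripleRecord]
    ) -> tuple[int, list[tuple[TripleRecord, str]]]:
        """Store triples, skipping (h, r, t) duplicates; idempotent.

        Returns (count newly stored, per-triple rejection records). A triple
        is rejected — not raised — when its relation label is unknown to the
        schema, an endpoint is unregistered, or head == tail.
        """
        existing = self.triple_keys()
        added = 0
        rejected: list[tuple[TripleRecord, str]] = []
        for t in triples:
            if t.head not in self.entities:
                rejected.append((t, f"unknown head entity id {t.head!r}"))
                continue
            if t.tail not in self.entities:
                rejected.append((t, f"unknown tail entity id {t.tail!r}"))
                continue
            if not self.schema.has_relation_label(t.relation):
                rejected.append((t, f"unknown relation label {t.relation!r}"))
                continue
            if t.head == t.tail:
                rejected.append((t, "head and tail are the same entity"))
                continue
            key = self.triple_key(t)
            if key in existing:
                continue
            existing.add(key)
            self.triples.append(t)
            added += 1
        return added, rejected

    def outgoing(self, entity_id: str) -> Iterator[TripleRecord]:
        return (t for t in self.triples if t.head == entity_id)

    def incoming(self, entity_id: str) -> Iterator[TripleRecord]:
        return (t for t in self.triples if t.tail == entity_id)

    # -- statistics ------------------------------------------------------

    def stats(self) -> dict:
        """Per-entity-type entity and triple counts.

        Triple convention: a triple contributes to the tally of every
        distinct entity type among its two endpoints (once per type, even
        when head and tail share a type). The convention is spelled out in
        the returned header so exported tables are self-describing.
        """
        per_type: dict[str, dict[str, int]] = {
            et.name: {"entities": 0, "triples": 0} for et in self.schema.entity_types
        }
        for e in self.entities.values():
            per_type.setdefault(e.type, {"entities": 0, "triples": 0})
            per_type[e.type]["entities"] += 1
        for t in self.triples:
            types = {self.entities[t.head].type, self.entities[t.tail].type}
            for ty in types:
                per_type.setdefault(ty, {"entities": 0, "triples": 0})
                per_type[ty]["triples"] += 1
        return {
            "convention": "a triple is counted once per distinct endpoint entity type",
            "total_entities": len(self.entities),
            "total_triples": len(self.triples),
            "per_type": per_type,
        }

    # -- validation ------------------------------------------------------

    def validate(self) -> list[str]:
        """Structural violations of the graph (empty == valid)."""
        violations = validate_schema(self.schema)
        for eid, e in self.entities.items():
            if not e.surface.strip():
                violations.append(f"entity {eid!r} has an empty surface")
            if self.schema.entity_type(e.type) is None:
                violations.append(f"entity {eid!r} has undeclared type {e.type!r}")
            if e.surface in e.aliases:
                violations.append(f"entity {eid!r} lists its own surface as an alias")
        seen: set[tuple[str, str, str]] = set()
        for t in self.triples:
            if t.head not in self.entities:
                violations.append(f"dangling head id {t.head!r}")
                continue
            if t.tail not in self.entities:
                violations.append(f"dangling tail id {t.tail!r}")
                continue
            if t.head == t.tail:
                violations.append(f"self-loop on entity {t.head!r}")
            if not self.schema.has_relation_label(t.relation):
                violations.append(f"triple with unknown relation {t.relation!r}")
            if t.status not in TRIPLE_STATUSES:
                violations.append(f"triple with unknown status {t.status!r}")
            key = self.triple_key(t)
            if key in seen:
                violations.append(f"duplicate triple {key}")
            seen.add(key)
        return violations

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": self.schema.to_dict(),
            "entities": [
                {
                    "id": e.id,
                    "surface": e.surface,
                    "type": e.type,
                    "attributes": dict(sorted(e.attributes.items())),
                    "aliases": sorted(e.aliases),
                }
                for e in sorted(self.entities.values(), key=lambda e: e.id)
            ],
            "triples": [
                {
                    "head": t.head,
                    "relation": t.relation,
                    "tail": t.tail,
                    "status": t.status,
                    "provenance": {
                        "source_doc": t.provenance.source_doc,
                        "chunk_id": t.provenance.chunk_id,
                        "stage": t.provenance.stage,
                        "session_ref": t.provenance.session_ref,
                    },
                }
                for t in sorted(self.triples, key=self.triple_key)
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "KnowledgeGraph":
        kg = cls(schema=Schema.from_dict(data["schema"]))
        for e in data.get("entities", []):
            kg.entities[e["id"]] = EntityRecord(
                id=e["id"],
                surface=e["surface"],
                type=e["type"],
                attributes=dict(e.get("attributes", {})),
                aliases=set(e.get("aliases", [])),
            )
        for t in data.get("triples", []):
            prov = t.get("provenance", {})
            kg.triples.append(
                TripleRecord(
                    head=t["head"],
                    relation=t["relation"],
                    tail=t["tail"],
                    status=t.get("status", "extracted"),
                    provenance=Provenance(
                        source_doc=prov.get("source_doc", ""),
                        chunk_id=prov.get("chunk_id", ""),
                        stage=prov.get("stage", "extraction"),
                        session_ref=prov.get("session_ref", ""),
                    ),
                )
            )
        return kg

    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(
            schema=self.schema,
            entities={
                eid: replace(e, attributes=dict(e.attributes), aliases=set(e.aliases))
                for eid, e in self.entities.items()
            },
            triples=list(self.triples),
        )
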