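"""Corpus readers and graph writers.

Covers three I/O surfaces:

* benchmark corpora in the two common BioRED distribution dialects —
  PubTator text and BioC XML — restricted to the four benchmark entity
  classes (D)isease, (G)ene, (C)hemical, (V)ariant and the corpus's eight
  undirected relation labels;
* lossless dump/load of a :class:`~chatkg.graph.KnowledgeGraph` as JSON or
  CSV;
* Neo4j bulk-import export (node CSV + edge CSV + idempotent Cypher
  loader).

All writers order their output deterministically so exports diff cleanly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .graph import KnowledgeGraph
from .schema import Schema

__all__ = [
    "AnnotatedDocument",
    "read_biored",
    "write_pubtator",
    "write_triples",
    "read_triples",
    "export_neo4j",
    "BIORED_ENTITY_TYPES",
    "BIORED_RELATION_TYPES",
]

#: BioRED entity classes, long dialect names mapped to the short letters.
BIORED_ENTITY_TYPES = {
    "DiseaseOrPhenotypicFeature": "D",
    "GeneOrGeneProduct": "G",
    "ChemicalEntity": "C",
    "SequenceVariant": "V",
    "D": "D",
    "G": "G",
    "C": "C",
    "V": "V",
}

#: The corpus's eight undirected relation labels.
BIORED_RELATION_TYPES = {
    "Association",
    "Positive_Correlation",
    "Negative_Correlation",
    "Bind",
    "Cotreatment",
    "Comparison",
    "Drug_Interaction",
    "Conversion",
}


@dataclass
class AnnotatedDocument:
    """One benchmark document with phrase-level entity and relation gold."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    mentions: list[dict] = field(default_factory=list)  # start,end,text,type,norm_type,concept
    relations_raw: list[tuple[str, str, str]] = field(default_factory=list)  # (type, id1, id2)
    issues: list[str] = field(default_factory=list)

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()

    @property
    def entities(self) -> list[tuple[str, str]]:
        """Unique (surface, normalized type) pairs, in first-mention order."""
        seen, out = set(), []
        for m in self.mentions:
            key = (m["text"], m["norm_type"])
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    @property
    def relations(self) -> list[tuple[str, str, str]]:
        """(endpoint surface, relation, endpoint surface) with the undirected
        pair stored in canonical (lexicographic concept-id) endpoint order."""
        surface_of = {}
        for m in self.mentions:
            surface_of.setdefault(m["concept"], m["text"])
        out = []
        for rel, id1, id2 in self.relations_raw:
            a, b = sorted((id1, id2))
            out.append((surface_of.get(a, a), rel, surface_of.get(b, b)))
        return out


def read_biored(
    path: str | Path, dialect: str = "pubtator", errors: list[str] | None = None
) -> list[AnnotatedDocument]:
    """Parse a BioRED-style corpus file.

    Malformed records are reported (into ``errors`` and the owning
    document's ``issues``) and parsing continues; unknown entity-type tags
    are kept but flagged.
    """
    if dialect == "pubtator":
        return _read_pubtator(Path(path), errors if errors is not None else [])
    if dialect == "bioc_xml":
        return _read_bioc(Path(path), errors if errors is not None else [])
    raise ValueError(f"unknown dialect {dialect!r}")


def _norm_entity_type(raw: str, doc: AnnotatedDocument) -> str:
    norm = BIORED_ENTITY_TYPES.get(raw)
    if norm is None:
        doc.issues.append(f"unknown entity type tag {raw!r}")
        return raw
    return norm


def _read_pubtator(path: Path, errors: list[str]) -> list[AnnotatedDocument]:
    docs: dict[str, AnnotatedDocument] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "|t|" in line or "|a|" in line:
                doc_id, kind, text = line.split("|", 2)
                doc = docs.setdefault(doc_id, AnnotatedDocument(doc_id=doc_id))
                if kind == "t":
                    doc.title = text
                else:
                    doc.abstract = text
                continue
            fields = line.split("\t")
            doc = docs.get(fields[0])
            if doc is None:
                errors.append(f"line {lineno}: annotation before any title line")
                continue
            try:
                if len(fields) >= 6 and fields[1].isdigit() and fields[2].isdigit():
                    start, end = int(fields[1]), int(fields[2])
                    doc.mentions.append(
                        {
                            "start": start,
                            "end": end,
                            "text": fields[3],
                            "type": fields[4],
                            "norm_type": _norm_entity_type(fields[4], doc),
                            "concept": fields[5],
                        }
                    )
                elif len(fields) >= 4:
                    rel = fields[1]
                    if rel not in BIORED_RELATION_TYPES:
                        doc.issues.append(f"unknown relation type {rel!r}")
                    doc.relations_raw.append((rel, fields[2], fields[3]))
                else:
                    raise ValueError("too few fields")
            except (ValueError, IndexError) as err:
                msg = f"line {lineno}: malformed record ({err}): {line[:80]}"
                errors.append(msg)
                doc.issues.append(msg)
    return [docs[k] for k in docs]


def _read_bioc(path: Path, errors: list[str]) -> list[AnnotatedDocument]:
    tree = etree.parse(str(path))
    docs: list[AnnotatedDocument] = []
    for dnode in tree.findall(".//document"):
        doc_id = (dnode.findtext("id") or "").strip()
        doc = AnnotatedDocument(doc_id=doc_id)
        for passage in dnode.findall("passage"):
            ptype = None
            for infon in passage.findall("infon"):
                if infon.get("key") == "type":
                    ptype = (infon.text or "").strip()
            text = (passage.findtext("text") or "").strip()
            if ptype == "title":
                doc.title = text
            else:
                doc.abstract = f"{doc.abstract} {text}".strip()
            for ann in passage.findall("annotation"):
                infons = {i.get("key"): (i.text or "").strip() for i in ann.findall("infon")}
                loc = ann.find("location")
                start = int(loc.get("offset")) if loc is not None else 0
                length = int(loc.get("length")) if loc is not None else 0
                raw_type = infons.get("type", "")
                doc.mentions.append(
                    {
                        "start": start,
                        "end": start + length,
                        "text": (ann.findtext("text") or "").strip(),
                        "type": raw_type,
                        "norm_type": _norm_entity_type(raw_type, doc),
                        "concept": infons.get("identifier", ann.get("id", "")),
                    }
                )
        for rel in dnode.findall("relation"):
            infons = {i.get("key"): (i.text or "").strip() for i in rel.findall("infon")}
            rtype = infons.get("type", "")
            if rtype not in BIORED_RELATION_TYPES:
                doc.issues.append(f"unknown relation type {rtype!r}")
            doc.relations_raw.append(
                (rtype, infons.get("entity1", ""), infons.get("entity2", ""))
            )
        docs.append(doc)
    return docs


def write_pubtator(docs: list[AnnotatedDocument], path: str | Path) -> None:
    """Serialize documents back to PubTator text (round-trip safe)."""
    lines: list[str] = []
    for doc in docs:
        lines.append(f"{doc.doc_id}|t|{doc.title}")
        lines.append(f"{doc.doc_id}|a|{doc.abstract}")
        for m in sorted(doc.mentions, key=lambda m: (m["start"], m["end"])):
            lines.append(
                f"{doc.doc_id}\t{m['start']}\t{m['end']}\t{m['text']}\t{m['type']}\t{m['concept']}"
            )
        for rel, id1, id2 in doc.relations_raw:
            lines.append(f"{doc.doc_id}\t{rel}\t{id1}\t{id2}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# graph dump / load

_ENTITY_COLUMNS = ("id", "surface", "type", "aliases", "attributes")
_TRIPLE_COLUMNS = (
    "head", "relation", "tail", "status", "source_doc", "chunk_id", "stage", "session_ref",
)
_ALIAS_SEP = "|"


def _join_aliases(aliases) -> str:
    # escape the separator so an alias containing '|' survives round-trip
    return _ALIAS_SEP.join(a.replace("\\", "\\\\").replace(_ALIAS_SEP, "\\|") for a in aliases)


def _split_aliases(joined: str) -> list[str]:
    out: list[str] = []
    buf: list[str] = []
    i = 0
    while i < len(joined):
        c = joined[i]
        if c == "\\" and i + 1 < len(joined):
            buf.append(joined[i + 1])
            i += 2
            continue
        if c == _ALIAS_SEP:
            if buf:
                out.append("".join(buf))
                buf = []
            i += 1
            continue
        buf.append(c)
        i += 1
    if buf:
        out.append("".join(buf))
    return out


def write_triples(kg: KnowledgeGraph, path: str | Path, format: str = "json") -> None:
    """Dump the graph losslessly.

    JSON writes one ``{schema, entities, triples}`` document. CSV writes a
    directory with ``schema.json``, ``entities.csv`` and ``triples.csv``
    (fixed, documented columns; aliases ``|``-separated inside a quoted
    field, attributes as embedded JSON).
    """
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(kg.to_dict(), indent=1, ensure_ascii=False), encoding="utf-8"
        )
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    path.mkdir(parents=True, exist_ok=True)
    data = kg.to_dict()
    (path / "schema.json").write_text(
        json.dumps(data["schema"], indent=1, ensure_ascii=False), encoding="utf-8"
    )
    with open(path / "entities.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL, lineterminator="\n")
        writer.writerow(_ENTITY_COLUMNS)
        for e in data["entities"]:
            writer.writerow(
                [
                    e["id"],
                    e["surface"],
                    e["type"],
                    _join_aliases(e["aliases"]),
                    json.dumps(e["attributes"], sort_keys=True, ensure_ascii=False),
                ]
            )
    with open(path / "triples.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL, lineterminator="\n")
        writer.writerow(_TRIPLE_COLUMNS)
        for t in data["triples"]:
            p = t["provenance"]
            writer.writerow(
                [
                    t["head"], t["relation"], t["tail"], t["status"],
                    p["source_doc"], p["chunk_id"], p["stage"], p["session_ref"],
                ]
            )


def read_triples(path: str | Path, format: str | None = None) -> KnowledgeGraph:
    """Load a graph written by :func:`write_triples`.

    Unknown relation labels are an error naming every offender: a dump
    must agree with its own schema.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.is_dir() else "json"
    if format == "json":
        kg = KnowledgeGraph.from_dict(json.loads(path.read_text(encoding="utf-8")))
    elif format == "csv":
        schema = Schema.from_dict(
            json.loads((path / "schema.json").read_text(encoding="utf-8"))
        )
        data: dict = {"schema": schema.to_dict(), "entities": [], "triples": []}
        with open(path / "entities.csv", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                data["entities"].append(
                    {
                        "id": row["id"],
                        "surface": row["surface"],
                        "type": row["type"],
                        "aliases": _split_aliases(row["aliases"]),
                        "attributes": json.loads(row["attributes"] or "{}"),
                    }
                )
        with open(path / "triples.csv", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                data["triples"].append(
                    {
                        "head": row["head"],
                        "relation": row["relation"],
                        "tail": row["tail"],
                        "status": row["status"],
                        "provenance": {
                            "source_doc": row["source_doc"],
                            "chunk_id": row["chunk_id"],
                            "stage": row["stage"],
                            "session_ref": row["session_ref"],
                        },
                    }
                )
        kg = KnowledgeGraph.from_dict(data)
    else:
        raise ValueError(f"unknown format {format!r}")

    unknown = sorted(
        {t.relation for t in kg.triples if not kg.schema.has_relation_label(t.relation)}
    )
    if unknown:
        raise ValueError(f"dump contains relation labels unknown to its schema: {unknown}")
    return kg


# ---------------------------------------------------------------------------
# Neo4j export

_CYPHER = """\
// Idempotent loader for the exported graph (neo4j-shell / cypher-shell).
CREATE CONSTRAINT entity_id IF NOT EXISTS
FOR (e:Entity) REQUIRE e.id IS UNIQUE;

LOAD CSV WITH HEADERS FROM 'file:///nodes.csv' AS row
MERGE (e:Entity {{id: row.id}})
SET e.surface = row.surface,
    e.type = row.type,
    e.aliases = CASE WHEN row.aliases = '' THEN [] ELSE split(row.aliases, '{sep}') END;

LOAD CSV WITH HEADERS FROM 'file:///edges.csv' AS row
MATCH (h:Entity {{id: row.head}})
MATCH (t:Entity {{id: row.tail}})
MERGE (h)-[r:REL {{relation: row.relation}}]->(t)
SET r.status = row.status;
"""


def export_neo4j(kg: KnowledgeGraph, outdir: str | Path) -> dict[str, Path]:
    """Write ``nodes.csv``, ``edges.csv`` and an idempotent ``load.cypher``.

    Output ordering is deterministic (entities by id, edges by triple
    key); the Cypher script MERGEs, so re-running it changes nothing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = outdir / "nodes.csv"
    edges = outdir / "edges.csv"
    cypher = outdir / "load.cypher"
    with open(nodes, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL, lineterminator="\n")
        writer.writerow(["id", "surface", "type", "aliases"])
        for e in sorted(kg.entities.values(), key=lambda e: e.id):
            writer.writerow([e.id, e.surface, e.type, _join_aliases(sorted(e.aliases))])
    with open(edges, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL, lineterminator="\n")
        writer.writerow(["head", "relation", "tail", "status"])
        for t in sorted(kg.triples, key=kg.triple_key):
            writer.writerow([t.head, t.relation, t.tail, t.status])
    cypher.write_text(_CYPHER.format(sep=_ALIAS_SEP), encoding="utf-8")
    return {"nodes": nodes, "edges": edges, "cypher": cypher}
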