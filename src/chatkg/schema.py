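"""Knowledge-graph schema: entity types, relation types, and label vocabularies.

A schema declares what a graph may contain: entity types (each with named
attributes), directed relation types constrained to (source type, target
type) endpoint pairs, and free-standing label vocabularies used by
completion tasks whose option lists are broader than the typed relation
schema (e.g. the 14-label relation-prediction option list).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from ._text import normalize_label

__all__ = [
    "AttributeSpec",
    "EntityTypeSpec",
    "RelationTypeSpec",
    "Schema",
    "validate_schema",
    "load_schema",
    "save_schema",
    "heart_failure_schema",
    "RELATION_PREDICTION_OPTIONS",
]

#: Closed option list offered to the relation-prediction completion task.
RELATION_PREDICTION_OPTIONS: tuple[str, ...] = (
    "causes",
    "is_associated_with",
    "increases_risk_of",
    "diagnosed_as",
    "diagnosed_using",
    "symptoms_include",
    "treated_with",
    "prevented_by",
    "causes_side_effects_of",
    "affects",
    "leads_to",
    "caused_by",
    "affects_prognosis",
    "affects_mortality",
)


@dataclass(frozen=True)
class AttributeSpec:
    """A named attribute of an entity type (e.g. ``Name``, kind ``string``)."""

    name: str
    value_kind: str = "string"  # "string" | "number"
    description: str = ""


@dataclass(frozen=True)
class EntityTypeSpec:
    name: str
    attributes: tuple[AttributeSpec, ...] = (AttributeSpec("Name"),)
    description: str = ""


@dataclass(frozen=True)
class RelationTypeSpec:
    """Directed relation type; endpoints name declared entity types."""

    name: str
    source_type: str
    target_type: str
    description: str = ""


@dataclass
class Schema:
    entity_types: list[EntityTypeSpec] = field(default_factory=list)
    relation_types: list[RelationTypeSpec] = field(default_factory=list)
    #: named lists of extra relation labels usable by completion prompts
    vocabularies: dict[str, list[str]] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------

    def entity_type(self, name: str) -> EntityTypeSpec | None:
        key = normalize_label(name)
        for et in self.entity_types:
            if normalize_label(et.name) == key:
                return et
        return None

    def relation_type(self, name: str) -> RelationTypeSpec | None:
        key = normalize_label(name)
        for rt in self.relation_types:
            if normalize_label(rt.name) == key:
                return rt
        return None

    def entity_type_names(self) -> list[str]:
        return [et.name for et in self.entity_types]

    def relation_type_names(self) -> list[str]:
        return [rt.name for rt in self.relation_types]

    def known_relation_labels(self) -> set[str]:
        """Normalized labels valid as a triple's relation: schema relations
        plus every registered vocabulary label."""
        labels = {normalize_label(rt.name) for rt in self.relation_types}
        for vocab in self.vocabularies.values():
            labels.update(normalize_label(v) for v in vocab)
        return labels

    def has_relation_label(self, label: str) -> bool:
        return normalize_label(label) in self.known_relation_labels()

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "entity_types": [
                {
                    "name": et.name,
                    "description": et.description,
                    "attributes": [
                        {
                            "name": a.name,
                            "value_kind": a.value_kind,
                            "description": a.description,
                        }
                        for a in et.attributes
                    ],
                }
                for et in self.entity_types
            ],
            "relation_types": [
                {
                    "name": rt.name,
                    "source_type": rt.source_type,
                    "target_type": rt.target_type,
                    "description": rt.description,
                }
                for rt in self.relation_types
            ],
            "vocabularies": {k: list(v) for k, v in self.vocabularies.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Schema":
        return cls(
            entity_types=[
                EntityTypeSpec(
                    name=et["name"],
                    description=et.get("description", ""),
                    attributes=tuple(
                        AttributeSpec(
                            name=a["name"],
                            value_kind=a.get("value_kind", "string"),
                            description=a.get("description", ""),
                        )
                        for a in et.get("attributes", [{"name": "Name"}])
                    ),
                )
                for et in data.get("entity_types", [])
            ],
            relation_types=[
                RelationTypeSpec(
                    name=rt["name"],
                    source_type=rt["source_type"],
                    target_type=rt["target_type"],
                    description=rt.get("description", ""),
                )
                for rt in data.get("relation_types", [])
            ],
            vocabularies={
                k: list(v) for k, v in data.get("vocabularies", {}).items()
            },
        )


def validate_schema(schema: Schema) -> list[str]:
    """Check schema invariants; returns violation messages (empty == valid).

    Violations are data, not exceptions: a generated schema is expected to
    be imperfect and the caller decides how to react.
    """
    violations: list[str] = []
    seen_types: set[str] = set()
    for et in schema.entity_types:
        if not et.name.strip():
            violations.append("entity type with empty name")
            continue
        key = normalize_label(et.name)
        if key in seen_types:
            violations.append(f"duplicate entity type name: {et.name!r}")
        seen_types.add(key)
        if not et.attributes:
            violations.append(f"entity type {et.name!r} declares no attributes")
        attr_names = [a.name for a in et.attributes]
        for a in et.attributes:
            if not a.name.strip():
                violations.append(f"entity type {et.name!r} has an unnamed attribute")
            if a.value_kind not in ("string", "number"):
                violations.append(
                    f"attribute {et.name}.{a.name}: unknown value kind {a.value_kind!r}"
                )
        if len(set(attr_names)) != len(attr_names):
            violations.append(f"entity type {et.name!r} has duplicate attribute names")

    seen_rels: set[str] = set()
    for rt in schema.relation_types:
        if not rt.name.strip():
            violations.append("relation type with empty name")
            continue
        key = normalize_label(rt.name)
        if key in seen_rels:
            violations.append(f"duplicate relation type name: {rt.name!r}")
        # entity and relation names live in separate namespaces: the reference
        # schema itself uses "Cause" as both an entity type and a relation
        seen_rels.add(key)
        if schema.entity_type(rt.source_type) is None:
            violations.append(
                f"relation {rt.name!r}: undeclared source type {rt.source_type!r}"
            )
        if schema.entity_type(rt.target_type) is None:
            violations.append(
                f"relation {rt.name!r}: undeclared target type {rt.target_type!r}"
            )

    for vocab_name, labels in schema.vocabularies.items():
        for label in labels:
            if not str(label).strip():
                violations.append(f"vocabulary {vocab_name!r} contains an empty label")
    return violations


def load_schema(path: str | Path) -> Schema:
    """Read a schema from YAML or JSON (by extension; YAML reads JSON too)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return Schema.from_dict(data or {})


def save_schema(schema: Schema, path: str | Path) -> None:
    path = Path(path)
    data = schema.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2, ensure_ascii=False)
        else:
            yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


def _simple_type(name: str, noun: str, extra: Iterable[AttributeSpec] = ()) -> EntityTypeSpec:
    attrs = (
        AttributeSpec("Name", "string", f"Name of the {noun}"),
        AttributeSpec("Description", "string", f"Description of the {noun}"),
        *extra,
    )
    return EntityTypeSpec(name=name, attributes=attrs, description=noun.capitalize())


def heart_failure_schema() -> Schema:
    """The 12-entity-type / 10-relation-type heart-failure schema.

    This is the default schema shipped with the package: every entity type
    carries Name and Description string attributes (Medication additionally
    Dosage), and relations fan out from Disease (plus RiskFactor-causes-
    Disease). The relation-prediction option vocabulary is registered
    alongside the typed relations.
    """
    entity_types = [
        _simple_type("Disease", "disease"),
        _simple_type("Cause", "cause"),
        _simple_type("RiskFactor", "risk factor"),
        _simple_type("Symptom", "symptom"),
        _simple_type("Sign", "sign"),
        _simple_type("LaboratoryTest", "laboratory test"),
        _simple_type("ImagingTest", "imaging test"),
        _simple_type("Complication", "complication"),
        _simple_type(
            "Medication",
            "medication",
            (AttributeSpec("Dosage", "string", "Dosage of the medication"),),
        ),
        _simple_type("InterventionalTherapy", "interventional therapy"),
        _simple_type("SurgicalTherapy", "surgical therapy"),
        _simple_type("Prognosis", "prognosis"),
    ]
    relation_types = [
        RelationTypeSpec("Cause", "RiskFactor", "Disease", "Risk factor causes disease"),
        RelationTypeSpec("ManifestsAsSymptom", "Disease", "Symptom", "Disease manifests as symptom"),
        RelationTypeSpec("ManifestsAsSign", "Disease", "Sign", "Disease manifests as sign"),
        RelationTypeSpec("DiagnosedByLab", "Disease", "LaboratoryTest", "Disease diagnosed by laboratory test"),
        RelationTypeSpec("DiagnosedByImg", "Disease", "ImagingTest", "Disease diagnosed by imaging test"),
        RelationTypeSpec("LeadsTo", "Disease", "Complication", "Disease leads to complication"),
        RelationTypeSpec("TreatedByMedication", "Disease", "Medication", "Disease treated by medication"),
        RelationTypeSpec("TreatedByIntervention", "Disease", "InterventionalTherapy", "Disease treated by interventional therapy"),
        RelationTypeSpec("TreatedBySurgery", "Disease", "SurgicalTherapy", "Disease treated by surgical therapy"),
        RelationTypeSpec("PrognosisOfDisease", "Disease", "Prognosis", "Prognosis of disease"),
    ]
    return Schema(
        entity_types=entity_types,
        relation_types=relation_types,
        vocabularies={"relation_prediction": list(RELATION_PREDICTION_OPTIONS)},
    )
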