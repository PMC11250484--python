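"""Built-in prompt templates for every pipeline task.

Templates are data: a deployment can override any of them with a
``*.tmpl`` file (YAML header + body, see :func:`chatkg.gateway.load_template`).
The defaults are the heart-failure instantiation; slot values — entity and
relation type lists, chunk text, few-shot blocks — carry everything
disease-specific.

Answer-format contract (what the response parsers accept): entity answers
are line-oriented ``TypeName: entity 1; entity 2`` lists, relation-pair
answers are ``(head, tail)`` lines, vanilla triples are ``(head, relation,
tail)`` lines; ``None`` means nothing found. Parsers tolerate bullets and
numbering. BIO tagging is deliberately never requested: phrase strings are
the unit of annotation.
"""

from __future__ import annotations

from .gateway import PromptTemplate

__all__ = ["DEFAULT_TEMPLATES", "get_template"]


def _t(id: str, body: str, slots: tuple[str, ...], key_slots: tuple[str, ...] | None = None,
       task: str | None = None) -> PromptTemplate:
    return PromptTemplate(id=id, task=task or id, body=body, slots=slots, key_slots=key_slots)


DEFAULT_TEMPLATES: dict[str, PromptTemplate] = {
    t.id: t
    for t in [
        _t(
            "schema_design",
            "I want you to act as an experienced clinician and knowledge engineer.\n"
            "We are building a knowledge graph for {{disease}}. Work step by step:\n"
            "1. List the entity types needed to describe {{disease}} (diagnosis, "
            "treatment, prognosis), each with named string attributes.\n"
            "2. List the relation types between those entity types, each with a "
            "source entity type and a target entity type.\n"
            "Answer in YAML with top-level keys entity_types and relation_types.",
            slots=("disease",),
        ),
        _t(
            "ner_step1",
            "{{shots}}The entity types of interest are: [{{entity_types}}].\n"
            "Which of these entity types appear in the following text? "
            "Answer with a comma-separated list of type names, or None if no "
            "listed type appears.\n\nText: {{text}}",
            slots=("text", "entity_types", "shots"),
            key_slots=("entity_types",),
        ),
        _t(
            "ner_step2",
            "List every {{entity_type}} entity mentioned in the text above.\n"
            "Answer on one line in the form '{{entity_type}}: entity 1; entity 2; "
            "...', or None if there is none.",
            slots=("entity_type",),
        ),
        _t(
            "re_step1",
            "{{shots}}The relation types of interest are: [{{relation_types}}].\n"
            "Which of these relation types are expressed in the following text? "
            "Answer with a comma-separated list of relation names, or None.\n\n"
            "Text: {{text}}",
            slots=("text", "relation_types", "shots"),
            key_slots=("relation_types",),
        ),
        _t(
            "re_step2",
            "List every pair of entities in the text above that is connected by "
            "the relation {{relation}}.\nAnswer with one '(head entity, tail "
            "entity)' pair per line, or None.",
            slots=("relation",),
        ),
        _t(
            "vanilla_ner",
            "{{shots}}Extract all entities of the types [{{entity_types}}] from "
            "the following text.\nAnswer one line per type present, in the form "
            "'TypeName: entity 1; entity 2; ...'.\n\nText: {{text}}",
            slots=("text", "entity_types", "shots"),
            key_slots=("entity_types",),
        ),
        _t(
            "vanilla_re",
            "{{shots}}Extract all (head entity, relation, tail entity) triples "
            "from the following text, using only the relation types "
            "[{{relation_types}}].\nAnswer with one '(head entity, relation, "
            "tail entity)' triple per line, or None.\n\nText: {{text}}",
            slots=("text", "relation_types", "shots"),
            key_slots=("relation_types",),
        ),
        _t(
            "disambiguation",
            "Entity A is \"{{entity_a}}\", which appears in the triples:\n"
            "{{triples_a}}\nEntity B is \"{{entity_b}}\", which appears in the "
            "triples:\n{{triples_b}}\nBased on your medical expertise, do A and "
            "B refer to the same entity? Answer 'same entity' or 'different "
            "entities' and explain briefly. If they are the same, end with "
            "'Canonical: <preferred name>'.",
            slots=("entity_a", "entity_b", "triples_a", "triples_b"),
            key_slots=("entity_a", "entity_b"),
        ),
        _t(
            "triple_classification",
            "Based on the medical knowledge of cardiovascular specialists, "
            "{{head}} {{relation_text}} {{tail}}? Please answer true or false.",
            slots=("head", "relation_text", "tail"),
        ),
        _t(
            "relation_prediction",
            "What is the medical relation between {{head}} and {{tail}}? Please "
            "select the best answer based on your medical expertise from the "
            "following option list: [{{options}}].",
            slots=("head", "tail", "options"),
            key_slots=("head", "tail"),
        ),
        _t(
            "link_prediction_tail",
            "{{head}} {{relation_text}} what {{target_hint}}?",
            slots=("head", "relation_text", "target_hint"),
            key_slots=("head", "relation_text"),
        ),
        _t(
            "link_prediction_head",
            "What {{target_hint}} {{relation_text}} {{tail}}?",
            slots=("tail", "relation_text", "target_hint"),
            key_slots=("tail", "relation_text"),
        ),
    ]
}


def get_template(task: str, overrides: dict[str, PromptTemplate] | None = None) -> PromptTemplate:
    if overrides and task in overrides:
        return overrides[task]
    return DEFAULT_TEMPLATES[task]
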