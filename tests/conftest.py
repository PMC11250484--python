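import random

import pytest

from chatkg import (
    FixtureSpec,
    KnowledgeGraph,
    TripleRecord,
    generate_corpus_and_script,
    generate_truth_graph,
    heart_failure_schema,
)


@pytest.fixture(scope="session")
def hf_schema():
    return heart_failure_schema()


@pytest.fixture(scope="session")
def closure_fixture(hf_schema):
    """Zero-error fixture with aliases: the master integration input."""
    spec = FixtureSpec(seed=11, n_entities_per_type=4, n_triples=80, alias_rate=0.2)
    truth, alias_map = generate_truth_graph(hf_schema, spec)
    return generate_corpus_and_script(truth, alias_map, spec)


def random_graph(schema, seed: int, n_per_type: int = 3, n_triples: int = 25) -> KnowledgeGraph:
    """Small random endpoint-valid graph for oracle comparisons."""
    rng = random.Random(seed)
    kg = KnowledgeGraph(schema=schema)
    ids = {
        et.name: [
            kg.ensure_entity(f"{et.name.lower()} {i}", et.name)
            for i in range(n_per_type)
        ]
        for et in schema.entity_types
    }
    triples = []
    for _ in range(n_triples * 4):
        if len(triples) >= n_triples:
            break
        rt = rng.choice(schema.relation_types)
        h = rng.choice(ids[rt.source_type])
        t = rng.choice(ids[rt.target_type])
        if h != t:
            triples.append(TripleRecord(head=h, relation=rt.name, tail=t))
    kg.add_triples(triples)
    return kg
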