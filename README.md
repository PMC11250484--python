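# chatkg

Building a disease-specific medical knowledge graph by hand is slow: annotators
read hundreds of guideline and consensus documents and mark up every entity
(diseases, symptoms, medications, tests, ...) and every relation between them.
`chatkg` implements an alternative construction pipeline in which a chat-style
large language model does the first pass and deterministic machinery keeps it
honest. It is written for biomedical NLP practitioners who want to build — and,
crucially, *test offline* — an LLM-driven knowledge-graph pipeline for a
disease of their choice; the shipped default schema is the heart-failure one
(12 entity types, 10 relation types).

## The pipeline

1. **Schema and store.** A typed schema (entity types with attributes,
   relation types with endpoint constraints) guards a triple store of
   (h, r, t) assertions. Triple identity is the normalized surface tuple, so
   re-extraction across documents deduplicates automatically.
2. **Chunking.** Long documents are split into 500–700-word chunks, cutting
   only at paragraph breaks, sentence terminators or line breaks (in that
   order of preference).
3. **Two-step extraction.** Rather than asking for everything at once
   ("vanilla" prompting, also provided as a baseline), each chunk `x` is
   processed in two chat steps: step 1 asks *which* entity types (for NER) or
   relation types `r ∈ R` (for RE) the chunk contains, step 2 issues one
   follow-up per confirmed type to list its instances. For RE this factors as

   p((h,r,t) | x, q) = p(r | x, q₁) · p((h,t) | q_r)

   where q₁ is built from the full relation set R and each q_r rides on the
   session history, so the chunk text is sent only once. The protocol obeys a
   call-count law — 1 + (#types present) calls — and confines a step-1 miss to
   exactly one type.
4. **Entity disambiguation.** Candidate duplicates ("Heart Failure" vs
   "Congestive Heart Failure") are nominated structurally by Jaccard
   similarity of head-entity neighborhoods, J(A,B) = |shared|/|union| over the
   (relation, tail) pairs of A and B, then adjudicated by the model and merged
   transitively.
5. **Cyclically verified completion.** New candidate triples are posed to the
   model as three independent tasks — true/false classification, relation
   prediction from a closed 14-label option list, and link prediction in both
   directions — and accepted only when a consensus policy (default: unanimity)
   is met. A hallucinated assertion that cannot be re-derived from every
   direction never enters the graph.
6. **Evaluation.** Extraction is scored at the phrase level ("100 mg" is one
   item, not two tokens): precision, recall, F1 per task. Expert-consensus
   gold follows the 2-of-3 majority rule, with pairwise Cohen's kappa for
   agreement.

Every stage talks to the model through one gateway, and the gateway accepts a
**scripted backend**: a deterministic response table generated together with a
synthetic truth graph, corpus and gold annotations. With controllable miss /
hallucination / alias rates, the whole pipeline becomes a pure function of
(schema, seed) — no API key, no network, bit-for-bit reproducible.

## Worked example

Generate a zero-error synthetic world with planted duplicate surfaces, run the
full pipeline against its scripted backend, and check recovery:

```python
from chatkg import (FixtureSpec, ScriptedBackend, generate_corpus_and_script,
                    generate_truth_graph, heart_failure_schema, run_full_pipeline)

schema = heart_failure_schema()
spec = FixtureSpec(seed=11, n_entities_per_type=4, n_triples=80, alias_rate=0.2)
truth, aliases = generate_truth_graph(schema, spec)
fx = generate_corpus_and_script(truth, aliases, spec)
result = run_full_pipeline(fx.chunks, schema, ScriptedBackend(fx.script),
                           gold=fx.gold, seeds=fx.all_seeds)
print(f"chunks: {len(fx.chunks)}   planted aliases: {len(aliases)}")
print(f"recovered graph: {len(result.graph.entities)} entities, "
      f"{len(result.graph.triples)} triples "
      f"(truth: {len(truth.entities)} / {len(truth.triples)})")
merges = sum(d.verdict == "merge" for d in result.merge_decisions)
print(f"merges applied: {merges} of {len(result.merge_decisions)} candidates")
for task, rep in result.reports.items():
    print(f"{task.upper()}: P={rep.precision:.3f} R={rep.recall:.3f} F1={rep.f1:.3f}")
```

prints

```
chunks: 2   planted aliases: 2
recovered graph: 44 entities, 80 triples (truth: 44 / 80)
merges applied: 2 of 10 candidates
NER: P=1.000 R=1.000 F1=1.000
RE: P=1.000 R=1.000 F1=1.000
```

Both planted aliases were found by the Jaccard filter and confirmed by the
(scripted) model; the other 8 structurally similar candidate pairs were
correctly left distinct; the recovered graph equals the truth graph exactly,
so phrase-level precision and recall are both 1. Raising `miss_rate` or
`halluc_rate` degrades these numbers in the predicted, binomial way — that
contrast is what the test suite asserts.

The same run is available from the shell:

```bash
chatkg fixtures --seed 11 --alias-rate 0.2 --out fx
chatkg extract --chunks fx/chunks.jsonl --script fx/script.json --out run
chatkg disambiguate --graph run/graph.json --script fx/script.json --out run
chatkg complete --graph run/graph.json --seeds fx/seeds.jsonl --script fx/script.json --out run
chatkg evaluate --ner run/ner.jsonl --re run/re.jsonl --gold fx/gold.jsonl --out run
chatkg export --graph run/graph.json --out run/neo4j
```

Each stage writes a manifest and skips itself when its inputs are unchanged. A
live chat-completion endpoint can replace the script (`--backend` block in the
`chatkg full` config); the library code is identical either way.

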