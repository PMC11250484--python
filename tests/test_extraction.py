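"""Two-step / vanilla extraction: call counts, parsing, few-shot sampling."""

import pytest

from chatkg import (
    AnnotatedChunk,
    BackendScript,
    FixtureSpec,
    ScriptedBackend,
    TextChunk,
    build_fewshot_block,
    extract_vanilla,
    generate_corpus_and_script,
    generate_truth_graph,
    ner_two_step,
    re_two_step,
)
from chatkg.evaluation import phrase_prf


CHUNK = TextChunk(
    id="c1",
    doc_id="doc",
    text="Heart failure manifests as dyspnea. Heart failure is treated by captopril.",
    word_count=12,
)


def entity_type_key(schema):
    return ", ".join(schema.entity_type_names())


def relation_type_key(schema):
    return ", ".join(schema.relation_type_names())


class TestNerTwoStep:
    def _backend(self, schema):
        script = BackendScript()
        script.add("ner_step1", {"entity_types": entity_type_key(schema)},
                   "Disease, Symptom", chunk_id="c1")
        script.add("ner_step2", {"entity_type": "Disease"},
                   "Disease: heart failure", chunk_id="c1")
        script.add("ner_step2", {"entity_type": "Symptom"},
                   "Symptom: dyspnea", chunk_id="c1")
        return ScriptedBackend(script)

    def test_one_plus_types_present_calls(self, hf_schema):
        backend = self._backend(hf_schema)
        result = ner_two_step(CHUNK, hf_schema, None, backend)
        assert backend.n_calls == 1 + 2
        assert set(result.entities) == {("heart failure", "Disease"), ("dyspnea", "Symptom")}
        assert result.parse_failures == []

    def test_step1_none_skips_step2(self, hf_schema):
        script = BackendScript()
        script.add("ner_step1", {"entity_types": entity_type_key(hf_schema)}, "None", chunk_id="c1")
        backend = ScriptedBackend(script)
        result = ner_two_step(CHUNK, hf_schema, None, backend)
        assert backend.n_calls == 1
        assert result.entities == [] and result.parse_failures == []

    def test_unparseable_step1_recorded_and_skipped(self, hf_schema):
        script = BackendScript(default_response="I cannot help with that")
        backend = ScriptedBackend(script)
        result = ner_two_step(CHUNK, hf_schema, None, backend)
        assert backend.n_calls == 1
        assert result.entities == []
        assert result.parse_failures == ["I cannot help with that"]

    def test_undeclared_type_in_step2_dropped(self, hf_schema):
        script = BackendScript()
        script.add("ner_step1", {"entity_types": entity_type_key(hf_schema)},
                   "Disease", chunk_id="c1")
        script.add("ner_step2", {"entity_type": "Disease"},
                   "Alien: zork\nDisease: heart failure", chunk_id="c1")
        result = ner_two_step(CHUNK, hf_schema, None, ScriptedBackend(script))
        assert result.entities == [("heart failure", "Disease")]
        assert result.parse_failures == ["Alien: zork"]


class TestReTwoStep:
    def test_worked_example(self, hf_schema):
        script = BackendScript()
        script.add("re_step1", {"relation_types": relation_type_key(hf_schema)},
                   "TreatedByMedication", chunk_id="c1")
        script.add("re_step2", {"relation": "TreatedByMedication"},
                   "(heart failure, captopril)", chunk_id="c1")
        backend = ScriptedBackend(script)
        result = re_two_step(CHUNK, hf_schema, None, backend)
        assert backend.n_calls == 2
        assert result.triples == [("heart failure", "TreatedByMedication", "captopril")]
        # endpoints auto-registered with schema-implied types
        assert ("heart failure", "Disease") in result.entities
        assert ("captopril", "Medication") in result.entities

    def test_empty_step1_no_step2_calls(self, hf_schema):
        script = BackendScript()
        script.add("re_step1", {"relation_types": relation_type_key(hf_schema)},
                   "None", chunk_id="c1")
        backend = ScriptedBackend(script)
        result = re_two_step(CHUNK, hf_schema, None, backend)
        assert backend.n_calls == 1
        assert result.triples == []

    def test_three_relations_three_step2_calls(self, hf_schema):
        script = BackendScript()
        script.add("re_step1", {"relation_types": relation_type_key(hf_schema)},
                   "TreatedByMedication, ManifestsAsSymptom, LeadsTo", chunk_id="c1")
        script.add("re_step2", {"relation": "TreatedByMedication"},
                   "(heart failure, captopril)", chunk_id="c1")
        script.add("re_step2", {"relation": "ManifestsAsSymptom"},
                   "(heart failure, dyspnea)", chunk_id="c1")
        script.add("re_step2", {"relation": "LeadsTo"},
                   "(heart failure, renal failure)", chunk_id="c1")
        backend = ScriptedBackend(script)
        result = re_two_step(CHUNK, hf_schema, None, backend)
        assert backend.n_calls == 1 + 3
        assert len(result.triples) == 3

    def test_bad_pair_list_fails_only_that_relation(self, hf_schema):
        script = BackendScript()
        script.add("re_step1", {"relation_types": relation_type_key(hf_schema)},
                   "TreatedByMedication, ManifestsAsSymptom", chunk_id="c1")
        script.add("re_step2", {"relation": "TreatedByMedication"},
                   "pairs: heart failure together with captopril", chunk_id="c1")
        script.add("re_step2", {"relation": "ManifestsAsSymptom"},
                   "(heart failure, dyspnea)", chunk_id="c1")
        result = re_two_step(CHUNK, hf_schema, None, ScriptedBackend(script))
        assert result.triples == [("heart failure", "ManifestsAsSymptom", "dyspnea")]
        assert len(result.parse_failures) == 1


class TestVanilla:
    def test_single_call_and_parser_equivalence(self, hf_schema):
        script = BackendScript()
        script.add("vanilla_ner", {"entity_types": entity_type_key(hf_schema)},
                   "Disease: heart failure\nSymptom: dyspnea", chunk_id="c1")
        backend = ScriptedBackend(script)
        result = extract_vanilla(CHUNK, hf_schema, "ner", None, backend)
        assert backend.n_calls == 1
        two_step = TestNerTwoStep()._backend(hf_schema)
        reference = ner_two_step(CHUNK, hf_schema, None, two_step)
        assert set(result.entities) == set(reference.entities)

    def test_empty_response_is_one_failure(self, hf_schema):
        script = BackendScript(default_response="")
        result = extract_vanilla(CHUNK, hf_schema, "re", None, ScriptedBackend(script))
        assert result.triples == []
        assert len(result.parse_failures) == 1

    def test_malformed_line_among_valid_lines(self, hf_schema):
        script = BackendScript()
        script.add(
            "vanilla_re",
            {"relation_types": relation_type_key(hf_schema)},
            "(heart failure, TreatedByMedication, captopril)\n"
            "this line is not a triple\n"
            "(heart failure, ManifestsAsSymptom, dyspnea)",
            chunk_id="c1",
        )
        result = extract_vanilla(CHUNK, hf_schema, "re", None, ScriptedBackend(script))
        assert len(result.triples) == 2
        assert result.parse_failures == ["this line is not a triple"]

    def test_unknown_relation_in_triple_rejected(self, hf_schema):
        script = BackendScript()
        script.add(
            "vanilla_re",
            {"relation_types": relation_type_key(hf_schema)},
            "(a, Summons, b)",
            chunk_id="c1",
        )
        result = extract_vanilla(CHUNK, hf_schema, "re", None, ScriptedBackend(script))
        assert result.triples == []
        assert len(result.parse_failures) == 1


class TestFewShot:
    def _gold(self):
        chunks = []
        for i in range(8):
            chunks.append(
                AnnotatedChunk(
                    chunk_id=f"p{i}", text=f"positive text {i}",
                    entities=((f"entity {i}", "Disease"),),
                    triples=((f"entity {i}", "LeadsTo", f"comp {i}"),),
                )
            )
        for i in range(8):
            chunks.append(AnnotatedChunk(chunk_id=f"n{i}", text=f"negative text {i}"))
        return chunks

    def test_balanced_and_deterministic(self):
        gold = self._gold()
        block = build_fewshot_block(gold, k=6, seed=123, task="ner")
        again = build_fewshot_block(gold, k=6, seed=123, task="ner")
        assert block == again
        assert block.k == 6 and len(block.examples) == 6
        positives = [e for e in block.examples if e[1] != "None"]
        negatives = [e for e in block.examples if e[1] == "None"]
        assert len(positives) == len(negatives) == 3

    def test_answers_use_template_answer_format(self):
        block = build_fewshot_block(self._gold(), k=2, seed=0, task="re")
        positive = next(a for _, a in block.examples if a != "None")
        assert positive.startswith("(") and positive.endswith(")")
        rendered = block.render()
        assert "Example 1:" in rendered and "Answer:" in rendered

    def test_zero_shot_is_empty(self):
        block = build_fewshot_block(self._gold(), k=0, seed=0)
        assert block.examples == () and block.render() == ""

    def test_insufficient_pool_states_deficit(self):
        with pytest.raises(ValueError, match="need 9 positive"):
            build_fewshot_block(self._gold(), k=18, seed=0, task="ner")


class TestErrorIsolation:
    def test_type_dropped_in_step1_zeroes_only_that_type(self, hf_schema):
        """Step decomposition isolates errors: removing one type from every
        step-1 answer drives that type's recall to 0 and leaves others at 1."""
        spec = FixtureSpec(seed=5, n_entities_per_type=4, n_triples=60)
        truth, amap = generate_truth_graph(hf_schema, spec)
        fx = generate_corpus_and_script(truth, amap, spec)
        for key, resp in list(fx.script.entries.items()):
            if key[0] == "ner_step1":
                kept = [t for t in resp.split(", ") if t != "Symptom"]
                fx.script.entries[key] = ", ".join(kept) if kept else "None"
        backend = ScriptedBackend(fx.script)
        results = [ner_two_step(c, hf_schema, None, backend) for c in fx.chunks]
        pred = {r.chunk_id: r.entities for r in results}
        gold_sym = {
            cid: [e for e in g.entities if e[1] == "Symptom"] for cid, g in fx.gold.items()
        }
        gold_rest = {
            cid: [e for e in g.entities if e[1] != "Symptom"] for cid, g in fx.gold.items()
        }
        assert phrase_prf(pred, gold_sym, "ner").recall == 0.0
        assert phrase_prf(
            {c: [e for e in es if e[1] != "Symptom"] for c, es in pred.items()},
            gold_rest,
            "ner",
        ).recall == 1.0
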