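"""Completion tasks and the cyclic-verification consensus machinery."""

from itertools import product

import pytest

from chatkg import (
    BackendScript,
    CompletionCandidate,
    ConsensusPolicy,
    KnowledgeGraph,
    ScriptedBackend,
    classify_triple,
    complete_graph,
    cyclic_verify,
    predict_link,
    predict_relation,
)
from chatkg.completion import ALL_CHECKS
from chatkg.schema import RELATION_PREDICTION_OPTIONS

TRIPLE = ("hypertension", "increases_risk_of", "heart failure")


def worked_example_script() -> BackendScript:
    script = BackendScript()
    script.add(
        "triple_classification",
        {"head": "hypertension", "relation_text": "increases risk of", "tail": "heart failure"},
        "True",
    )
    script.add(
        "relation_prediction",
        {"head": "hypertension", "tail": "heart failure"},
        "increases_risk_of",
    )
    script.add(
        "link_prediction_tail",
        {"head": "hypertension", "relation_text": "increases risk of"},
        "heart failure",
    )
    script.add(
        "link_prediction_head",
        {"tail": "heart failure", "relation_text": "increases risk of"},
        "hypertension",
    )
    return script


class TestClassifyTriple:
    def test_scripted_true(self):
        assert classify_triple(TRIPLE, ScriptedBackend(worked_example_script())) is True

    @pytest.mark.parametrize("answer,expected", [
        ("False", False),
        ("false.", False),
        ("TRUE", True),
        ("maybe", False),           # conservative parse
        ("true or false?", False),  # ambiguous -> false
    ])
    def test_parse_is_conservative(self, answer, expected):
        backend = ScriptedBackend(BackendScript(default_response=answer))
        assert classify_triple(TRIPLE, backend) is expected


class TestPredictRelation:
    def test_worked_example(self):
        backend = ScriptedBackend(worked_example_script())
        assert (
            predict_relation("hypertension", "heart failure", backend=backend)
            == "increases_risk_of"
        )

    def test_answer_outside_closed_list_is_empty(self):
        backend = ScriptedBackend(BackendScript(default_response="definitely_frobnicates"))
        assert predict_relation("a", "b", backend=backend) == ""

    def test_label_embedded_in_prose_extracted(self):
        backend = ScriptedBackend(
            BackendScript(
                default_response="Based on my expertise the answer is increases_risk_of, "
                "since hypertension affects cardiac load."
            )
        )
        # longest-match oracle over the options list
        expected = max(
            (o for o in RELATION_PREDICTION_OPTIONS
             if o.replace("_", " ") in "based on my expertise the answer is increases risk of since hypertension affects cardiac load"),
            key=len,
        )
        got = predict_relation("a", "b", backend=backend)
        assert got == expected == "increases_risk_of"

    def test_empty_options_rejected(self):
        with pytest.raises(ValueError):
            predict_relation("a", "b", options=(), backend=None)


class TestPredictLink:
    def test_tail_direction(self):
        backend = ScriptedBackend(worked_example_script())
        assert (
            predict_link(head="hypertension", relation="increases_risk_of", backend=backend)
            == "heart failure"
        )

    def test_head_direction(self):
        backend = ScriptedBackend(worked_example_script())
        assert (
            predict_link(tail="heart failure", relation="increases_risk_of", backend=backend)
            == "hypertension"
        )

    def test_empty_answer_gives_empty(self):
        backend = ScriptedBackend(BackendScript(default_response="none"))
        assert predict_link(head="x", relation="causes", backend=backend) == ""

    def test_requires_exactly_one_endpoint(self):
        with pytest.raises(ValueError):
            predict_link(head="a", tail="b", relation="causes", backend=None)


def script_for_pattern(pattern: dict) -> BackendScript:
    """Script in which each check independently agrees or disagrees."""
    script = BackendScript()
    rv = "increases risk of"
    script.add(
        "triple_classification",
        {"head": TRIPLE[0], "relation_text": rv, "tail": TRIPLE[2]},
        "True" if pattern["classify"] else "False",
    )
    script.add(
        "relation_prediction",
        {"head": TRIPLE[0], "tail": TRIPLE[2]},
        "increases_risk_of" if pattern["relation"] else "caused_by",
    )
    script.add(
        "link_prediction_tail",
        {"head": TRIPLE[0], "relation_text": rv},
        TRIPLE[2] if pattern["link_tail"] else "aortic stenosis",
    )
    script.add(
        "link_prediction_head",
        {"tail": TRIPLE[2], "relation_text": rv},
        TRIPLE[0] if pattern["link_head"] else "obesity",
    )
    return script


class TestCyclicVerify:
    def test_consistent_script_unanimity_four_checks(self):
        policy = ConsensusPolicy("unanimity4", 4, ALL_CHECKS)
        record = cyclic_verify(TRIPLE, ScriptedBackend(worked_example_script()), policy=policy)
        assert record.votes_passed == 4 and record.accepted

    def test_relation_disagreement_breaks_unanimity(self):
        pattern = {"classify": True, "relation": False, "link_tail": True, "link_head": True}
        record = cyclic_verify(TRIPLE, ScriptedBackend(script_for_pattern(pattern)))
        assert record.votes_passed == 2 and not record.accepted

    def test_all_sixteen_patterns_match_vote_arithmetic(self):
        """Enumerate every agree/disagree combination of the four checks."""
        for bits in product([True, False], repeat=4):
            pattern = dict(zip(ALL_CHECKS, bits))
            backend = ScriptedBackend(script_for_pattern(pattern))
            for required in (1, 2, 3, 4):
                policy = ConsensusPolicy(f"v{required}", required, ALL_CHECKS)
                record = cyclic_verify(TRIPLE, ScriptedBackend(script_for_pattern(pattern)), policy=policy)
                assert record.votes_passed == sum(bits)
                assert record.accepted == (sum(bits) >= required)

    def test_acceptance_monotone_in_required_votes(self):
        for bits in product([True, False], repeat=4):
            pattern = dict(zip(ALL_CHECKS, bits))
            accepted = [
                cyclic_verify(
                    TRIPLE,
                    ScriptedBackend(script_for_pattern(pattern)),
                    policy=ConsensusPolicy(f"v{r}", r, ALL_CHECKS),
                ).accepted
                for r in (1, 2, 3, 4)
            ]
            # once rejected at some strictness, rejected at every stricter one
            for earlier, later in zip(accepted, accepted[1:]):
                assert earlier or not later

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            ConsensusPolicy("bad", 4)  # only 3 applicable checks by default
        with pytest.raises(ValueError):
            ConsensusPolicy("bad", 0)


class TestCompleteGraph:
    def test_accepted_triples_enter_graph_verified(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        script = BackendScript()
        rv = "cause"
        script.add("triple_classification",
                   {"head": "smoking", "relation_text": rv, "tail": "heart failure"}, "True")
        script.add("relation_prediction", {"head": "smoking", "tail": "heart failure"}, "Cause")
        script.add("link_prediction_tail", {"head": "smoking", "relation_text": rv}, "heart failure")
        seeds = [CompletionCandidate(head="smoking", relation="Cause", tail="heart failure")]
        accepted, ledger = complete_graph(kg, seeds, ScriptedBackend(script))
        assert len(accepted) == 1
        assert kg.triples[0].status == "verified"
        assert kg.triples[0].provenance.stage == "completion"
        assert kg.entities[accepted[0].head].type == "RiskFactor"
        assert len(ledger) == 1 and ledger[0].accepted

    def test_never_stores_rejected_triple(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        seeds = [CompletionCandidate(head="ghost", relation="Cause", tail="phantom")]
        accepted, ledger = complete_graph(kg, seeds, ScriptedBackend(BackendScript()))
        assert accepted == [] and kg.triples == []
        assert len(ledger) == 1 and not ledger[0].accepted

    def test_empty_seed_list_is_noop(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        accepted, ledger = complete_graph(kg, [], ScriptedBackend(BackendScript()))
        assert accepted == [] and ledger == []

    def test_unresolvable_seed_recorded_and_skipped(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        seeds = [CompletionCandidate(head="smoking", relation="Cause", tail="")]
        accepted, ledger = complete_graph(kg, seeds, ScriptedBackend(BackendScript(default_response="none")))
        assert accepted == []
        assert ledger[0].checks.get("resolution") == "failed"

    def test_missing_relation_resolved_then_verified(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        script = BackendScript()
        rv = "cause"
        script.add("relation_prediction", {"head": "smoking", "tail": "heart failure"}, "Cause")
        script.add("triple_classification",
                   {"head": "smoking", "relation_text": rv, "tail": "heart failure"}, "True")
        script.add("link_prediction_tail", {"head": "smoking", "relation_text": rv}, "heart failure")
        seeds = [CompletionCandidate(head="smoking", tail="heart failure")]
        accepted, _ = complete_graph(kg, seeds, ScriptedBackend(script))
        assert len(accepted) == 1
        assert kg.triples[0].relation == "Cause"
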