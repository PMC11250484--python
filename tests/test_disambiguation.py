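"""Jaccard profiles, candidate ranking, adjudication, and merging."""

import pytest
from hypothesis import given, settings, strategies as st

from chatkg import (
    BackendScript,
    KnowledgeGraph,
    MergeDecision,
    ScriptedBackend,
    TripleRecord,
    apply_merges,
    candidate_pairs,
    entity_profile,
    jaccard_similarity,
    resolve_pair,
)
from chatkg.disambiguation import EntityProfile

from conftest import random_graph


def brute_force_profile(kg, eid):
    rels, tails, pairs = set(), set(), set()
    for t in kg.triples:
        if t.head == eid:
            rels.add(t.relation)
            tails.add(t.tail)
            pairs.add((t.relation, t.tail))
    return rels, tails, pairs


class TestEntityProfile:
    def test_no_outgoing_triples_empty_sets(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        eid = kg.ensure_entity("isolated", "Disease")
        profile = entity_profile(kg, eid)
        assert profile.relations == profile.tails == profile.pairs == frozenset()

    def test_fanout_counts(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        d = kg.ensure_entity("hf", "Disease")
        m1 = kg.ensure_entity("m1", "Medication")
        m2 = kg.ensure_entity("m2", "Medication")
        kg.add_triples([
            TripleRecord(d, "TreatedByMedication", m1),
            TripleRecord(d, "TreatedByMedication", m2),
        ])
        profile = entity_profile(kg, d)
        assert profile.relations == {"TreatedByMedication"}
        assert profile.tails == {m1, m2}
        assert len(profile.pairs) == 2

    def test_unknown_entity_raises(self, hf_schema):
        with pytest.raises(KeyError):
            entity_profile(KnowledgeGraph(schema=hf_schema), "ghost")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_scan_oracle(self, hf_schema, seed):
        kg = random_graph(hf_schema, seed)
        for eid in kg.entities:
            profile = entity_profile(kg, eid)
            rels, tails, pairs = brute_force_profile(kg, eid)
            assert (profile.relations, profile.tails, profile.pairs) == (rels, tails, pairs)


def profile_from_pairs(name, pairs):
    return EntityProfile(
        entity=name,
        relations=frozenset(r for r, _ in pairs),
        tails=frozenset(t for _, t in pairs),
        pairs=frozenset(pairs),
    )


class TestJaccard:
    def test_identical_nonempty_profiles_score_one(self):
        p = profile_from_pairs("a", {("r1", "t1"), ("r2", "t2")})
        assert jaccard_similarity(p, p) == 1.0

    def test_disjoint_profiles_score_zero(self):
        a = profile_from_pairs("a", {("r1", "t1")})
        b = profile_from_pairs("b", {("r2", "t2")})
        assert jaccard_similarity(a, b) == 0.0

    def test_worked_one_third(self):
        a = profile_from_pairs("a", {("treated_with", "d1"), ("causes", "s1")})
        b = profile_from_pairs("b", {("treated_with", "d1"), ("causes", "s2")})
        assert jaccard_similarity(a, b) == pytest.approx(1 / 3)

    def test_both_empty_zero_by_convention(self):
        a = profile_from_pairs("a", set())
        b = profile_from_pairs("b", set())
        assert jaccard_similarity(a, b) == 0.0
        assert jaccard_similarity(a, b, "literal") == 0.0

    def test_literal_mode_set_algebra(self):
        # shared token must appear in both relation sets AND both tail sets
        a = profile_from_pairs("a", {("x", "x"), ("r", "t1")})
        b = profile_from_pairs("b", {("x", "x"), ("r", "t2")})
        # R_A∩R_B∩T_A∩T_B = {x}; union = {x, r, t1, t2}
        assert jaccard_similarity(a, b, "literal") == pytest.approx(1 / 4)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.sets(st.tuples(st.sampled_from("rst"), st.sampled_from("abcd")), max_size=6),
        st.sets(st.tuples(st.sampled_from("rst"), st.sampled_from("abcd")), max_size=6),
        st.sampled_from(["pairs", "literal"]),
    )
    def test_symmetry_and_bounds(self, pa, pb, mode):
        a, b = profile_from_pairs("a", pa), profile_from_pairs("b", pb)
        s = jaccard_similarity(a, b, mode)
        assert 0.0 <= s <= 1.0
        assert s == jaccard_similarity(b, a, mode)


class TestCandidatePairs:
    def test_threshold_zero_is_exhaustive(self, hf_schema):
        kg = random_graph(hf_schema, 1, n_per_type=2, n_triples=12)
        heads = {t.head for t in kg.triples}
        k = len(heads)
        assert len(candidate_pairs(kg, 0.0)) == k * (k - 1) // 2

    def test_threshold_one_only_profile_identical(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        a = kg.ensure_entity("hf", "Disease")
        b = kg.ensure_entity("chf", "Disease")
        c = kg.ensure_entity("htn", "Disease")
        m = kg.ensure_entity("captopril", "Medication")
        s = kg.ensure_entity("dyspnea", "Symptom")
        kg.add_triples([
            TripleRecord(a, "TreatedByMedication", m),
            TripleRecord(b, "TreatedByMedication", m),
            TripleRecord(c, "ManifestsAsSymptom", s),
        ])
        pairs = candidate_pairs(kg, 1.0)
        assert [(p[0], p[1]) for p in pairs] == [("chf", "hf")]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_pairs_oracle(self, hf_schema, seed):
        kg = random_graph(hf_schema, seed)
        got = candidate_pairs(kg, 0.3)
        heads = sorted({t.head for t in kg.triples})
        expected = set()
        for i, a in enumerate(heads):
            for b in heads[i + 1:]:
                s = jaccard_similarity(entity_profile(kg, a), entity_profile(kg, b))
                if s >= 0.3:
                    expected.add(frozenset((a, b)))
        assert {frozenset((a, b)) for a, b, _ in got} == expected
        scores = [s for _, _, s in got]
        assert scores == sorted(scores, reverse=True)


class TestResolvePair:
    def _kg(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        hf = kg.ensure_entity("Heart Failure", "Disease")
        chf = kg.ensure_entity("Congestive Heart Failure", "Disease")
        af = kg.ensure_entity("Atrial Fibrillation", "Disease")
        vf = kg.ensure_entity("Ventricular Fibrillation", "Disease")
        m = kg.ensure_entity("digoxin", "Medication")
        kg.add_triples([
            TripleRecord(hf, "TreatedByMedication", m),
            TripleRecord(chf, "TreatedByMedication", m),
            TripleRecord(af, "TreatedByMedication", m),
            TripleRecord(vf, "TreatedByMedication", m),
        ])
        return kg, hf, chf, af, vf

    def test_scripted_merge_and_distinct(self, hf_schema):
        kg, hf, chf, af, vf = self._kg(hf_schema)
        script = BackendScript()
        script.add(
            "disambiguation",
            {"entity_a": "Congestive Heart Failure", "entity_b": "Heart Failure"},
            "They are the same entity: both describe the heart failing to pump "
            "blood effectively. Canonical: Heart Failure",
        )
        script.add(
            "disambiguation",
            {"entity_a": "Atrial Fibrillation", "entity_b": "Ventricular Fibrillation"},
            "These are different entities: arrhythmias of different chambers.",
        )
        backend = ScriptedBackend(script)
        merge = resolve_pair((hf, chf), kg, backend)
        assert merge.verdict == "merge" and merge.canonical == "Heart Failure"
        distinct = resolve_pair((af, vf), kg, backend)
        assert distinct.verdict == "distinct"

    def test_gibberish_is_conservative_distinct(self, hf_schema):
        kg, hf, chf, *_ = self._kg(hf_schema)
        backend = ScriptedBackend(BackendScript(default_response="purple monkey dishwasher"))
        decision = resolve_pair((hf, chf), kg, backend)
        assert decision.verdict == "distinct"

    def test_merge_without_canonical_uses_better_supported_surface(self, hf_schema):
        kg, hf, chf, *_ = self._kg(hf_schema)
        s = kg.ensure_entity("edema", "Symptom")
        kg.add_triples([TripleRecord(hf, "ManifestsAsSymptom", s)])
        backend = ScriptedBackend(BackendScript(default_response="Clearly the same entity."))
        decision = resolve_pair((hf, chf), kg, backend)
        assert decision.verdict == "merge"
        assert decision.canonical == "Heart Failure"  # 2 triples vs 1


class TestApplyMerges:
    def test_shared_triple_collapses(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        a = kg.ensure_entity("HF", "Disease")
        b = kg.ensure_entity("CHF", "Disease")
        m = kg.ensure_entity("captopril", "Medication")
        kg.add_triples([
            TripleRecord(a, "TreatedByMedication", m),
            TripleRecord(b, "TreatedByMedication", m),
        ])
        decision = MergeDecision(pair=(a, b), score=1.0, verdict="merge", canonical="HF")
        merged, report = apply_merges(kg, [decision])
        assert len(merged.entities) == len(kg.entities) - 1
        assert len(merged.triples) == len(kg.triples) - 1
        assert merged.entities["hf"].aliases == {"CHF"}
        assert merged.validate() == []

    def test_empty_decision_list_is_identity(self, hf_schema):
        kg = random_graph(hf_schema, 3)
        merged, _ = apply_merges(kg, [])
        assert merged.to_dict() == kg.to_dict()

    def test_chain_merges_transitively(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        ids = [kg.ensure_entity(n, "Disease") for n in ("A1", "B1", "C1")]
        m = kg.ensure_entity("drug", "Medication")
        kg.add_triples([TripleRecord(i, "TreatedByMedication", m) for i in ids])
        decisions = [
            MergeDecision(pair=(ids[0], ids[1]), score=1.0, verdict="merge", canonical="A1"),
            MergeDecision(pair=(ids[1], ids[2]), score=1.0, verdict="merge", canonical="A1"),
        ]
        merged, _ = apply_merges(kg, decisions)
        survivors = [e for e in merged.entities.values() if e.type == "Disease"]
        assert len(survivors) == 1
        assert survivors[0].surface == "A1"
        assert survivors[0].aliases == {"B1", "C1"}

    def test_conflicting_canonicals_resolved_and_logged(self, hf_schema):
        kg = KnowledgeGraph(schema=hf_schema)
        ids = [kg.ensure_entity(n, "Disease") for n in ("A1", "B1", "C1")]
        m = kg.ensure_entity("drug", "Medication")
        s = kg.ensure_entity("sx", "Symptom")
        kg.add_triples(
            [TripleRecord(i, "TreatedByMedication", m) for i in ids]
            + [TripleRecord(ids[1], "ManifestsAsSymptom", s)]
        )
        decisions = [
            MergeDecision(pair=(ids[0], ids[1]), score=1.0, verdict="merge", canonical="A1"),
            MergeDecision(pair=(ids[1], ids[2]), score=1.0, verdict="merge", canonical="C1"),
        ]
        merged, report = apply_merges(kg, decisions)
        assert len(report["conflicts"]) == 1
        survivors = [e for e in merged.entities.values() if e.type == "Disease"]
        assert survivors[0].surface == "B1"  # most triple support

    @pytest.mark.parametrize("seed", range(3))
    def test_never_increases_counts_and_stays_valid(self, hf_schema, seed):
        kg = random_graph(hf_schema, seed)
        heads = sorted({t.head for t in kg.triples})[:4]
        decisions = [
            MergeDecision(
                pair=(heads[i], heads[i + 1]), score=0.5, verdict="merge",
                canonical=kg.entities[heads[i]].surface,
            )
            for i in range(len(heads) - 1)
        ]
        merged, _ = apply_merges(kg, decisions)
        assert len(merged.entities) <= len(kg.entities)
        assert len(merged.triples) <= len(kg.triples)
        assert merged.validate() == []
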