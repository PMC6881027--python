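"""Terminology store: loading, subsumption, term index, ICD-10 resolution."""

import json
import random

import pytest

from ddidetect.ontology import (
    Ontology,
    OntologyError,
    Predicate,
    Relation,
    build_term_index,
    load_ontology,
    normalize_term,
    ontology_from_dict,
)


def brute_force_descendants(relations, concept_id):
    """Independent DFS over raw relation records (reflexive closure)."""
    edges = {}
    for rel in relations:
        if rel.predicate is Predicate.IS_A:
            edges.setdefault(rel.object, []).append(rel.subject)
    seen = {concept_id}
    stack = [concept_id]
    while stack:
        for child in edges.get(stack.pop(), ()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    return seen


def _mini(concepts, relations, icd10=None):
    return ontology_from_dict(
        {
            "concepts": [
                {"id": cid, "category": "diagnosis", "descriptions": [[cid.lower(), "de"]]}
                for cid in concepts
            ],
            "relations": [
                {"subject": a, "predicate": "is_a", "object": b} for a, b in relations
            ],
            "icd10_map": icd10 or {},
        }
    )


class TestLoading:
    def test_fixture_parent_cardinalities(self, onto):
        """21 bone-condition and 13 drug-class subclasses under the two parents."""
        assert len(onto.descendants("M0006E0")) == 22
        assert len(onto.descendants("E003230")) == 14

    def test_empty_ontology_is_valid(self):
        onto = ontology_from_dict({"concepts": [], "relations": [], "icd10_map": {}})
        assert onto.concepts == {}

    def test_is_a_cycle_rejected(self):
        with pytest.raises(OntologyError, match="IS_A cycle"):
            _mini(["A", "B"], [("A", "B"), ("B", "A")])

    def test_dangling_relation_endpoint_rejected(self):
        with pytest.raises(OntologyError, match="unknown concept"):
            _mini(["A"], [("A", "B")])

    def test_concept_without_description_rejected(self):
        with pytest.raises(OntologyError, match="no descriptions"):
            ontology_from_dict(
                {"concepts": [{"id": "A", "category": "diagnosis", "descriptions": []}]}
            )

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_ontology(tmp_path / "nope.json")

    def test_malformed_json_reported(self, tmp_path):
        p = tmp_path / "broken.json"
        p.write_text("{not json", encoding="utf-8")
        with pytest.raises(OntologyError, match="not valid JSON"):
            load_ontology(p)

    def test_roundtrip_from_file(self, tmp_path, onto):
        doc = {
            "concepts": [
                {
                    "id": c.id,
                    "category": c.category.value,
                    "descriptions": [list(d) for d in c.descriptions],
                }
                for c in onto.concepts.values()
            ],
            "relations": [
                {"subject": r.subject, "predicate": r.predicate.value, "object": r.object}
                for r in onto.relations
            ],
            "icd10_map": {k: [v[0], v[1]] for k, v in onto.icd10_map.items()},
        }
        p = tmp_path / "onto.json"
        p.write_text(json.dumps(doc, ensure_ascii=False), encoding="utf-8")
        reloaded = load_ontology(p)
        assert set(reloaded.concepts) == set(onto.concepts)


class TestSubsumption:
    def test_descendants_of_leaf_is_itself(self, onto):
        assert onto.descendants("P000002") == {"P000002"}

    def test_has_index_reflexive(self, onto):
        for cid in list(onto.concepts)[:10]:
            assert onto.has_index(cid, cid)

    def test_has_index_examples(self, onto):
        assert onto.has_index("P000002", "E003230")
        assert onto.has_index("M0006E0", "M0006E0")
        assert not onto.has_index("E003230", "M0006E0")

    def test_unknown_id_raises(self, onto):
        with pytest.raises(KeyError):
            onto.descendants("ZZZZ")
        with pytest.raises(KeyError):
            onto.has_index("ZZZZ", "M0006E0")

    def test_descendants_match_brute_force_on_random_dags(self):
        """Index-based closure equals DFS over raw records on 50 random DAGs."""
        rng = random.Random(2024)
        for _ in range(50):
            n = rng.randint(2, 40)
            ids = [f"C{i:03d}" for i in range(n)]
            # edges only from higher to lower index: acyclic by construction
            rel = []
            for i in range(1, n):
                for j in range(i):
                    if rng.random() < 0.15:
                        rel.append((ids[i], ids[j]))
            onto = _mini(ids, rel)
            for cid in ids:
                assert onto.descendants(cid) == brute_force_descendants(
                    onto.relations, cid
                )

    def test_transitivity_on_fixture(self, onto):
        ids = list(onto.concepts)
        for a in ids:
            for b in onto.descendants(a):
                for c in onto.descendants(b):
                    assert onto.has_index(c, a)


class TestTermIndex:
    def test_virtual_synonym_basis(self, onto, resources):
        """Two different terms of one concept map to the same concept id set."""
        index = resources.term_index
        heart = index.lookup("heart")
        cardiac = index.lookup("cardiac")
        assert heart and heart & cardiac

    def test_empty_ontology_empty_index(self):
        onto = ontology_from_dict({"concepts": []})
        index = build_term_index(onto, lambda w: [normalize_term(w)])
        assert index.descriptions == {}

    def test_absent_stem_lookup_empty(self, resources):
        assert resources.term_index.lookup("xylophon") == set()

    def test_umlaut_folding(self):
        assert normalize_term("Refluxösophagitis") == "refluxoesophagitis"
        assert normalize_term("Säure") == "saeure"


class TestICD10:
    def test_resolve_known_code(self, onto):
        label, ids = onto.resolve_icd10("M82.02")
        assert label == "Osteoporosis in multiple myelomatosis: Upper arm"
        assert ids == ["M0006E0", "T000439", "GA00026", "M000E3C"]

    def test_case_folding(self, onto):
        assert onto.resolve_icd10("m82.02") == onto.resolve_icd10("M82.02")

    def test_modifier_letter_stripped(self, onto):
        assert onto.resolve_icd10("M81.9G") == onto.resolve_icd10("M81.9")

    def test_unknown_code_is_not_found(self, onto):
        assert onto.resolve_icd10("Z99.9") is None

    def test_malformed_code_raises(self, onto):
        with pytest.raises(ValueError):
            onto.resolve_icd10("12.3")
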