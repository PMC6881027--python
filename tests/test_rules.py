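"""Rules engine: WHO T-score interpretation, rule loading and evaluation."""

import itertools
import random

import pytest

from ddidetect.graph import Certainty, ConceptGraph, ConceptMention, NumericFinding
from ddidetect.ontology import ontology_from_dict
from ddidetect.rules import (
    RuleError,
    WHOThresholds,
    evaluate_rule,
    interpret_tscore,
    run_rules,
    rules_from_dict,
)

OSTEO = "M0006E0"
OSTEOPENIA = "M002BF8"
PPI = "E003230"


def _finding(value):
    return NumericFinding(name_concept="W000F9D", value=value, char_span=(0, 5))


class TestWHOInterpretation:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (-2.7, OSTEO),
            (-2.5, OSTEO),  # band edge belongs to osteoporosis
            (-2.4999, OSTEOPENIA),
            (-1.5, OSTEOPENIA),
            (-1.0, None),  # band edge belongs to normal
            (-1.0001, OSTEOPENIA),
            (0.5, None),
        ],
    )
    def test_bands(self, value, expected):
        assert interpret_tscore(_finding(value)) == expected

    def test_wrong_name_concept_rejected(self):
        bad = NumericFinding(name_concept="XXXX", value=-3.0, char_span=(0, 1))
        with pytest.raises(ValueError):
            interpret_tscore(bad)

    def test_configurable_edges(self):
        thresholds = WHOThresholds(osteoporosis_max=-3.0, normal_min=-2.0)
        assert interpret_tscore(_finding(-2.5), thresholds) == OSTEOPENIA


class TestRuleLoading:
    def test_default_rule_shape(self, default_rules):
        assert len(default_rules) == 1
        rule = default_rules[0]
        assert rule.trigger == PPI
        referenced = rule.condition.referenced_concepts()
        assert referenced == {OSTEO, OSTEOPENIA}

    def test_unknown_concept_rejected(self, onto):
        raw = {
            "rules": [
                {"id": "bad", "trigger": "XXXX", "condition": {"has_index": OSTEO}}
            ]
        }
        with pytest.raises(RuleError, match="unknown concept"):
            rules_from_dict(raw, onto)

    def test_empty_rules_file(self, onto):
        assert rules_from_dict({}, onto) == []

    def test_malformed_condition_rejected(self, onto):
        raw = {"rules": [{"id": "bad", "trigger": PPI, "condition": {"all": []}}]}
        with pytest.raises(RuleError):
            rules_from_dict(raw, onto)


def _graph(doc_id, *mentions, findings=()):
    return ConceptGraph(doc_id=doc_id, mentions=list(mentions), findings=list(findings))


def _m(cid, pos=0, negated=False, speculated=False):
    return ConceptMention(
        concept_id=cid,
        token_span=(pos, pos),
        negated=negated,
        certainty=Certainty.SPECULATED if speculated else Certainty.ASSERTED,
    )


class TestRuleEvaluation:
    def test_fires_on_subclass_pair(self, onto, default_rules):
        graph = _graph("d1", _m("P000002", 0), _m(OSTEOPENIA, 5))
        event = evaluate_rule(default_rules[0], graph, onto)
        assert event is not None
        assert event.trigger_mention.concept_id == "P000002"
        assert {m.concept_id for m in event.supporting_mentions} == {OSTEOPENIA}

    def test_negated_condition_blocks_event(self, onto, default_rules):
        graph = _graph("d1", _m("P000002", 0), _m(OSTEO, 5, negated=True))
        assert evaluate_rule(default_rules[0], graph, onto) is None

    def test_speculated_mentions_excluded_by_default(self, onto, default_rules):
        graph = _graph("d1", _m("P000002", 0), _m(OSTEO, 5, speculated=True))
        assert evaluate_rule(default_rules[0], graph, onto) is None
        assert (
            evaluate_rule(default_rules[0], graph, onto, include_speculated=True)
            is not None
        )

    def test_missing_trigger_no_event(self, onto, default_rules):
        graph = _graph("d1", _m(OSTEO, 0))
        assert evaluate_rule(default_rules[0], graph, onto) is None

    def test_subsumption_completeness(self, onto, default_rules):
        """Any descendant substituted for its parent never changes firing."""
        osteo_ids = sorted(onto.descendants(OSTEO) | onto.descendants(OSTEOPENIA))
        ppi_ids = sorted(onto.descendants(PPI))
        for bone, drug in itertools.product(osteo_ids, ppi_ids):
            graph = _graph("d", _m(drug, 0), _m(bone, 7))
            assert evaluate_rule(default_rules[0], graph, onto) is not None, (bone, drug)

    def test_first_trigger_in_document_order_recorded(self, onto, default_rules):
        graph = _graph("d1", _m("P000003", 9), _m("P000002", 2), _m(OSTEO, 5))
        event = evaluate_rule(default_rules[0], graph, onto)
        assert event.trigger_mention.concept_id == "P000002"


class TestBruteForceEquivalence:
    def test_condition_tree_matches_truth_table(self):
        """Engine evaluation equals exhaustive truth-table evaluation."""
        onto = ontology_from_dict(
            {
                "concepts": [
                    {"id": c, "category": "diagnosis", "descriptions": [[c, "de"]]}
                    for c in ["T", "A", "B", "C"]
                ],
                "relations": [
                    {"subject": "B", "predicate": "is_a", "object": "A"},
                ],
            }
        )
        raw = {
            "rules": [
                {
                    "id": "r",
                    "trigger": "T",
                    "condition": {
                        "any": [
                            {"all": [{"has_index": "A"}, {"has_index": "C"}]},
                            {"not": {"has_index": "C"}},
                        ]
                    },
                }
            ]
        }
        rule = rules_from_dict(raw, onto)[0]

        def brute(present):
            has = lambda anc: any(
                anc == c or (anc == "A" and c == "B") for c in present
            )
            return (has("A") and has("C")) or not has("C")

        rng = random.Random(7)
        universe = ["A", "B", "C"]
        for _ in range(100):
            present = [c for c in universe if rng.random() < 0.5]
            mentions = [_m("T", 0)] + [
                _m(c, i + 1) for i, c in enumerate(present)
            ]
            graph = _graph("d", *mentions)
            fired = evaluate_rule(rule, graph, onto) is not None
            assert fired == brute(present), present


class TestRunRules:
    def test_per_document_composition(self, onto, default_rules):
        graphs = [
            _graph("a", _m("P000002", 0), _m(OSTEO, 3)),
            _graph("b", _m(OSTEO, 0)),
            _graph("c", _m("P000002", 0)),
        ]
        events = run_rules(default_rules, graphs, onto)
        assert set(events) == {"a"}
        assert len(events["a"]) == 1

    def test_empty_input(self, onto, default_rules):
        assert run_rules(default_rules, [], onto) == {}

    def test_deterministic(self, onto, default_rules):
        graphs = [_graph("a", _m("P000002", 0), _m(OSTEO, 3))]
        assert run_rules(default_rules, graphs, onto) == run_rules(
            default_rules, graphs, onto
        )
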