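"""Declarative rules engine over concept graphs.

Rules are trigger-event modules in a small YAML dialect: a trigger concept
(any mention taxonomically subsumed under it fires the rule), a boolean
condition tree whose leaves are subsumption tests (``has_index``) or numeric
finding predicates, and an action (emit a clinical event or a derived
concept). Negated mentions never satisfy a rule; hedged (speculated)
mentions are excluded by default as well.

The bone-density interpretation follows the WHO definition: T-score at or
below -2.5 SD → osteoporosis, between -2.5 and -1.0 → osteopenia, at or
above -1.0 → normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .graph import ConceptGraph, ConceptMention, NumericFinding
from .ontology import Ontology

__all__ = [
    "ClinicalEvent",
    "Condition",
    "FindingPredicate",
    "HasIndex",
    "Rule",
    "RuleError",
    "WHOThresholds",
    "evaluate_rule",
    "interpret_tscore",
    "load_rules",
    "run_rules",
]

OSTEOPOROSIS = "M0006E0"
OSTEOPENIA = "M002BF8"
PPI = "E003230"
TSCORE_CONCEPT = "W000F9D"


class RuleError(ValueError):
    """Raised for malformed rule files or references to unknown concepts."""


@dataclass(frozen=True)
class WHOThresholds:
    """Band edges of the WHO bone-density classification, in SD units."""

    osteoporosis_max: float = -2.5  # T <= this -> osteoporosis
    normal_min: float = -1.0  # T >= this -> normal
    osteoporosis_concept: str = OSTEOPOROSIS
    osteopenia_concept: str = OSTEOPENIA


def interpret_tscore(
    finding: NumericFinding, thresholds: WHOThresholds | None = None
) -> str | None:
    """Map a T-score finding onto a diagnosis concept per the WHO bands.

    Returns the osteoporosis concept for values at or below -2.5 SD, the
    osteopenia concept strictly between -2.5 and -1.0, and None otherwise.
    """
    thresholds = thresholds or WHOThresholds()
    if finding.name_concept != TSCORE_CONCEPT:
        raise ValueError(
            f"interpret_tscore expects a {TSCORE_CONCEPT} finding, "
            f"got {finding.name_concept!r}"
        )
    if finding.value <= thresholds.osteoporosis_max:
        return thresholds.osteoporosis_concept
    if finding.value < thresholds.normal_min:
        return thresholds.osteopenia_concept
    return None


# ------------------------------------------------------------------ conditions
class Condition:
    """Base class of condition-tree nodes."""

    def evaluate(
        self,
        mentions: list[ConceptMention],
        findings: list[NumericFinding],
        onto: Ontology,
    ) -> tuple[bool, list[ConceptMention]]:
        raise NotImplementedError

    def referenced_concepts(self) -> set[str]:
        return set()


@dataclass(frozen=True)
class HasIndex(Condition):
    """True iff some eligible mention is subsumed under ``ancestor``."""

    ancestor: str

    def evaluate(self, mentions, findings, onto):
        support = [m for m in mentions if onto.has_index(m.concept_id, self.ancestor)]
        return (bool(support), support)

    def referenced_concepts(self):
        return {self.ancestor}


_COMPARATORS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
}


@dataclass(frozen=True)
class FindingPredicate(Condition):
    """True iff some numeric finding of ``name_concept`` satisfies the comparison."""

    name_concept: str
    comparator: str
    threshold: float

    def evaluate(self, mentions, findings, onto):
        cmp = _COMPARATORS[self.comparator]
        hit = any(
            f.name_concept == self.name_concept and cmp(f.value, self.threshold)
            for f in findings
        )
        return (hit, [])

    def referenced_concepts(self):
        return {self.name_concept}


@dataclass(frozen=True)
class BooleanNode(Condition):
    op: str  # all | any | not
    children: tuple[Condition, ...]

    def evaluate(self, mentions, findings, onto):
        results = [c.evaluate(mentions, findings, onto) for c in self.children]
        support = [m for ok, sup in results for m in sup if ok]
        if self.op == "all":
            return (all(ok for ok, _ in results), support)
        if self.op == "any":
            return (any(ok for ok, _ in results), support)
        return (not results[0][0], [])

    def referenced_concepts(self):
        out: set[str] = set()
        for c in self.children:
            out |= c.referenced_concepts()
        return out


def _parse_condition(node) -> Condition:
    if not isinstance(node, dict) or len(node) != 1:
        raise RuleError(f"malformed condition node: {node!r}")
    key, value = next(iter(node.items()))
    if key in ("all", "any"):
        if not isinstance(value, list) or not value:
            raise RuleError(f"{key!r} requires a non-empty list of children")
        return BooleanNode(op=key, children=tuple(_parse_condition(c) for c in value))
    if key == "not":
        return BooleanNode(op="not", children=(_parse_condition(value),))
    if key == "has_index":
        if not isinstance(value, str):
            raise RuleError(f"has_index requires a concept id, got {value!r}")
        return HasIndex(ancestor=value)
    if key == "finding":
        try:
            return FindingPredicate(
                name_concept=value["name"],
                comparator=value["op"],
                threshold=float(value["value"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise RuleError(f"malformed finding predicate {value!r}: {exc}") from exc
    raise RuleError(f"unknown condition type {key!r}")


# ------------------------------------------------------------------------ rule
@dataclass(frozen=True)
class Rule:
    id: str
    trigger: str
    condition: Condition
    action: str = "emit_event"  # emit_event | emit_concept
    emit_concept: str | None = None
    description: str = ""

    def validate(self, onto: Ontology) -> None:
        unknown = sorted(
            cid
            for cid in {self.trigger, *self.condition.referenced_concepts()}
            | ({self.emit_concept} if self.emit_concept else set())
            if cid not in onto.concepts
        )
        if unknown:
            raise RuleError(f"rule {self.id!r}: unknown concept ids {unknown}")


@dataclass(frozen=True)
class ClinicalEvent:
    """A fired rule for one document, with the mentions that justified it."""

    doc_id: str
    rule_id: str
    trigger_mention: ConceptMention
    supporting_mentions: tuple[ConceptMention, ...] = ()


def load_rules(path: str | Path, onto: Ontology) -> list[Rule]:
    """Load and validate rules from the YAML dialect."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return rules_from_dict(raw or {}, onto)


def rules_from_dict(raw: dict, onto: Ontology) -> list[Rule]:
    rules: list[Rule] = []
    for rec in raw.get("rules", []) or []:
        try:
            rule = Rule(
                id=rec["id"],
                trigger=rec["trigger"],
                condition=_parse_condition(rec["condition"]),
                action=rec.get("action", "emit_event"),
                emit_concept=rec.get("emit_concept"),
                description=rec.get("description", ""),
            )
        except KeyError as exc:
            raise RuleError(f"rule record {rec!r} missing field {exc}") from exc
        if rule.action not in ("emit_event", "emit_concept"):
            raise RuleError(f"rule {rule.id!r}: unknown action {rule.action!r}")
        rule.validate(onto)
        rules.append(rule)
    return rules


def evaluate_rule(
    rule: Rule,
    graph: ConceptGraph,
    onto: Ontology,
    include_speculated: bool = False,
) -> ClinicalEvent | None:
    """Evaluate one rule against one concept graph.

    The rule fires iff some eligible (non-negated, asserted) mention is
    subsumed under the trigger concept and the condition tree holds over the
    remaining eligible mentions and the numeric findings. The first
    qualifying trigger mention in document order is recorded.
    """
    eligible = [
        m for m in graph.mentions if m.is_positive(include_speculated=include_speculated)
    ]
    triggers = [m for m in eligible if onto.has_index(m.concept_id, rule.trigger)]
    if not triggers:
        return None
    triggers.sort(key=lambda m: m.token_span)
    for trig in triggers:
        others = [m for m in eligible if m is not trig]
        ok, support = rule.condition.evaluate(others, graph.findings, onto)
        if ok:
            return ClinicalEvent(
                doc_id=graph.doc_id,
                rule_id=rule.id,
                trigger_mention=trig,
                supporting_mentions=tuple(support),
            )
    return None


def run_rules(
    rules: Iterable[Rule],
    graphs: Iterable[ConceptGraph],
    onto: Ontology,
    include_speculated: bool = False,
) -> dict[str, list[ClinicalEvent]]:
    """Evaluate all rules on all graphs; deterministic (doc_id, rule_id) order."""
    out: dict[str, list[ClinicalEvent]] = {}
    rules = sorted(rules, key=lambda r: r.id)
    for graph in sorted(graphs, key=lambda g: g.doc_id):
        events = []
        for rule in rules:
            event = evaluate_rule(rule, graph, onto, include_speculated)
            if event is not None:
                events.append(event)
        if events:
            out[graph.doc_id] = events
    return out
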