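# File formats

## Ontology JSON

```json
{
  "concepts": [
    {"id": "M0006E0", "category": "diagnosis",
     "descriptions": [["Osteoporose", "de"], ["osteoporosis", "en"]]}
  ],
  "relations": [
    {"subject": "O000001", "predicate": "is_a", "object": "M0006E0"},
    {"subject": "E003230", "predicate": "semantic",
     "semantic_label": "is contraindication of", "object": "M0006E0"}
  ],
  "icd10_map": {"M81.9": ["Osteoporose", ["M0006E0"]]}
}
```

Categories: diagnosis, morphology, treatment, procedure, agent,
microbiology, function, material, topography, linker, measurement.
Predicates: `is_a` (must form a DAG), `part_of`, `semantic` (free label).
ICD-10 keys are canonical `LNN` or `LNN.N(N)` forms. Validation errors name
the offending record.

## Concept-graph XML (version 1.0)

```xml
<conceptGraph docId="D0001" version="1.0">
  <provenance><item name="pipeline_version" value="0.1.0"/></provenance>
  <tokens>
    <token surface="Osteoporose" start="6" end="17"><stem>osteoporose</stem></token>
  </tokens>
  <mentions>
    <mention concept="M0006E0" first="1" last="1" negated="false"
             certainty="asserted" source="text"/>
  </mentions>
  <findings>
    <finding name="W000F9D" value="-2.7" start="28" end="41"/>
  </findings>
</conceptGraph>
```

Token spans are 0-based half-open character offsets; mention spans are
inclusive token indices. `source` is one of text, icd10, ner_rule,
trade_name. Serialization round-trips losslessly and is byte-deterministic.

## Lexicons (TSV, `#` comments)

- `drug_db.tsv`: trade_name, agent, concept_id
- `abbreviations.tsv`: abbreviation, expansion
- `negation_triggers.tsv`: phrase, kind (pre_neg | post_neg | hedge)
- `ocr_confusions.tsv`: pattern_a, pattern_b, substitution_weight
- `stems_extra.tsv` / `stopwords.tsv`: one or more normalized word forms per line

## Rules YAML

```yaml
rules:
  - id: ppi-osteoporosis-ddi
    trigger: E003230
    condition:
      any: [{has_index: M0006E0}, {has_index: M002BF8}]
    action: emit_event
```

Condition nodes: `all`, `any`, `not`, `has_index: <concept>`, and
`finding: {name: W000F9D, op: "<=", value: -2.5}`.

## Corpus and results

Letters: JSONL with `doc_id` and `text`. Gold standard: TSV with `doc_id`,
`has_osteo`, `has_ppi`, `has_event` (0/1). Events: TSV with `doc_id`,
`rule_id`, `trigger_concept`, `support_concepts`. Evaluation reports: TSV
and Markdown in the three-column layout.
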