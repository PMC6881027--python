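# ddidetect

Knowledge-based detection of drug-disease interactions (DDIs) in free-text
German hospital discharge letters.

Clinical narratives mention the facts that matter for medication safety —
diagnoses, bone-density measurements, drug prescriptions — in free text,
inconsistently, abbreviated, misspelled, and sometimes corrupted by OCR. This
package implements the classic knowledge-based recipe for finding a specific
clinical event in such text without any training data, at the example of the
relative contraindication **proton-pump inhibitor (PPI) use in a patient with
osteoporosis or osteopenia**:

1. **A local terminology/ontology** — concepts with multilingual descriptions
   connected by taxonomic (`is a`), partonomic and semantic relations. The
   taxonomy answers subsumption queries (`hasIndex`), so a rule can say
   "anything under *PPI*" instead of enumerating thirteen agents. A bundled
   synthetic miniature terminology (65 concepts, including 21 osteoporosis and
   13 PPI subclasses) stands in for a commercial nomenclature.
2. **An NLP pipeline** — tokenization; German stemming with compound-noun
   splitting (*Protonenpumpeninhibitor* → *proton·pumpe·inhibitor*);
   abbreviation expansion (*PPI* ≡ *Protonenpumpeninhibitor*); spell
   correction by weighted edit distance in which OCR-typical confusions
   (h↔n, rn↔m, l↔1, O↔0) and dropped vowels (*prtone-pmp inhbtor*) are cheap;
   concept matching with *virtual synonyms* (*cardiac infarction* ≡ *heart
   infarction* because *heart*/*cardiac* describe one concept);
   ontology-path disambiguation; and negation/hedge detection (*no signs of
   osteoporosis*). Pattern-based NER extracts ICD-10 codes (resolved to
   pre-coordinated concept lists), T-score measurements and drug trade names.
   The output per letter is an XML **concept graph**.
3. **A rules engine** — declarative trigger/condition rules over concept
   graphs. The default rule fires on any mention subsumed under *PPI*
   (`E003230`) when another eligible mention is subsumed under *osteoporosis*
   (`M0006E0`) or *osteopenia* (`M002BF8`). T-scores are interpreted by the
   WHO definition (T ≤ −2.5 → osteoporosis; −2.5 < T < −1.0 → osteopenia)
   and fed back as derived concepts.

Detection is scored per document as precision `P = TP/(TP+FP)`, recall
`R = TP/(TP+FN)` and `F = 2PR/(P+R)`, with exact (Clopper–Pearson) binomial
confidence intervals from beta quantiles. Because real discharge letters are
not shareable, a **synthetic corpus generator** produces German-style letters
with known document-level ground truth, configurable prevalences, expression
channels (diagnosis term, ICD-10 code, or T-score line), negated and hedged
distractor sentences, and OCR noise.

## Worked example

Generate 200 letters, annotate them, run the default rule and score against
the generated gold standard:

```bash
ddidetect simulate --seed 42 --out demo
ddidetect annotate --in demo/letters.jsonl --out demo/graphs
ddidetect run-rules --graphs demo/graphs --out demo/events.tsv
ddidetect evaluate --gold demo/gold.tsv --graphs demo/graphs \
    --events demo/events.tsv --out demo/report
```

which prints (seed 42, default generator parameters):

```
Metric                Osteoporosis/osteopenia  PPI                    Osteoporosis/osteopenia and PPI
True positives        129                      15                     12
False positives       0                        0                      0
False negatives       0                        0                      0
True negatives        71                       185                    188
Recall (%)            100.00 (97.18-100.00)    100.00 (78.20-100.00)  100.00 (73.54-100.00)
Precision (%)         100.00 (97.18-100.00)    100.00 (78.20-100.00)  100.00 (73.54-100.00)
F-Score (%)           100.00                   100.00                 100.00
```

Reading: of the 200 letters, 129 carried the bone condition and 15 a PPI
(12 both); at the default noise levels every document label was recovered,
so all confusion matrices are diagonal and every F-score is 100%. The
parenthesized ranges are exact 95% binomial confidence intervals — wide for
the event column because only 12 documents carry the combined event. Higher
OCR rates or counting hedged mentions as positives (see
`include_speculated`) degrade precision, which is how the false-positive
mechanism of real letters (prevention recommendations that mention
osteoporosis without a diagnosis) can be studied.

The same steps are available as a library:

```python
from ddidetect import annotate, load_default_resources

resources = load_default_resources()
graph = annotate("demo", "Medikation: Pantozol 40 mg. DXA T-Score: -2.7", resources)
print(graph.positive_concepts())   # {'P000002', 'W000F9D', 'M0006E0'}
```

## Layout

- `src/ddidetect/ontology.py` — terminology store, subsumption, ICD-10 map
- `src/ddidetect/stemming.py` — German stemming, compound splitting, spell correction
- `src/ddidetect/pipeline.py` — annotation pipeline (matching, disambiguation, negation)
- `src/ddidetect/entities.py` — ICD-10 / T-score / trade-name extraction
- `src/ddidetect/rules.py` — rules engine and WHO T-score interpretation
- `src/ddidetect/corpus.py` — synthetic letter generator and corpus statistics
- `src/ddidetect/evaluation.py` — confusion matrices, metrics, exact CIs, reports
- `src/ddidetect/data/` — synthetic terminology fixture, lexicons, default rules
- `docs/methods.md` — models, parameters, design decisions and limitations
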