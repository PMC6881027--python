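# Methods

This note documents the models and procedures implemented in `ddidetect`,
the tunable parameters and their defaults, what the synthetic data does and
does not emulate, and the numerical and design choices made where more than
one defensible option existed.

## Terminology and subsumption

The terminology is a set of concepts, each with one or more descriptions
(term plus language tag) and a category (diagnosis, agent, measurement,
topography, linker, …), connected by `is_a`, `part_of` and free semantic
relations. The `is_a` subgraph must be a directed acyclic graph; this is
checked at load time and a cycle aborts loading with the offending path.

`descendants(x)` is the reflexive transitive closure of reverse `is_a`
edges; `has_index(found, ancestor)` tests membership in it. **Subsumption is
reflexive by design**: a letter that literally says "PPI" must satisfy a
rule whose trigger is the PPI parent concept itself. Reflexivity can be
switched off per query (`descendants(..., reflexive=False)`) for callers
that need proper descendants.

Terms are normalized before indexing: lower-cased, German umlauts folded
(ä→ae, ö→oe, ü→ue, ß→ss). This makes indexing robust to the common typing
and OCR variants of German clinical text.

The bundled `wnc_mini.json` is a *synthetic miniature* terminology built for
testing and simulation: 65 concepts, of which 21 osteoporosis subclasses
(one nested two levels deep), 13 PPI agents, distractor diagnoses and drugs,
and an ICD-10 map of 11 codes. Every ICD-10 label is phrased so that
re-annotating the label text through the pipeline reproduces exactly the
concept list mapped to the code (the "label feedback" invariant).

## Stemming and compound splitting

Stemming is deliberately shallow: a fixed inflectional suffix list (-en,
-es, -er, -e, -n, -s, longest first, preferring a result present in the stem
lexicon) rather than a full morphological analyzer. Compound nouns are
decomposed greedily left-to-right over the stem lexicon, allowing the German
linking morphemes -s, -n, -en, -es, -e between parts; minimum part length 3.
If no decomposition exists, the suffix-stripped whole word is the stem. The
stem lexicon is the normalized description vocabulary of the loaded
terminology plus trade names and a small supplementary list of compound
parts. Because both the description index and the letter tokens pass through
the same stemmer, exact description terms always match regardless of how
aggressive the stemming is; inflectional robustness beyond that is
best-effort.

Full syntactic parsing is intentionally omitted: the detection task consumes
stems, labels and spans only. This is a simplification relative to a
full-scale clinical NLP engine.

## Spell correction

A token whose stems are unknown to the lexicon (length ≥ 4, not a recognized
abbreviation) is corrected to the vocabulary entry with minimal weighted
edit distance, where

- substitutions listed in the OCR confusion table (h↔n, rn↔m, l↔1, O↔0,
  multi-character pairs allowed) cost **0.5**,
- insertion of a vowel present in the target but dropped in the source costs
  **0.5** (the "prtone-pmp inhbtor" contraction pattern),
- all other edits cost **1.0**.

The acceptance threshold is ≤ 1 for words of up to 6 characters and ≤ 2
otherwise. Ties are never resolved by guessing: the word stays unchanged and
the degenerate case is recorded. A stopword list of common German function
and template words shields ordinary prose from accidental correction.

## Concept matching and virtual synonyms

Matching is longest-match left-to-right over token stem sequences. A
multi-stem description matches when each of its stems is matched in order,
either literally or by a stem that is a *one-word description of a common
concept* — the virtual-synonym mechanism that makes "cardiac infarction"
equal to "heart infarction". Restricting virtual synonymy to one-word
descriptions prevents a description's own parts (e.g. "infarction" inside
"heart infarction") from becoming synonyms of each other. A description may
start or end inside a compound token, so "Altersosteoporose" can satisfy a
description beginning at its second stem. All concepts of an ambiguous span
are emitted as parallel mentions.

Disambiguation keeps, for each ambiguous span, the candidate with the
strictly shortest relation path (any predicate, ≤ 3 edges) to an unambiguous
mention within 10 tokens; with no path or a tie, all interpretations are
kept. The path bound and window are package choices — defensible but not
canonical — and are configurable (`PipelineConfig.disamb_max_path`,
`disamb_window`).

## Negation and hedging

Trigger-based, sentence-bounded scope (sentences end at `.!?;` or a line
break). A pre-trigger (kein/keine/ohne/nicht/no/without/"no signs of", …)
negates a mention if at most **5 tokens** intervene; the post-trigger
"ausgeschlossen" negates any preceding mention of its sentence. Hedge
triggers (Verdacht auf, möglich, Prävention, Prophylaxe, Risiko, suspected,
…) set certainty to *speculated* instead; negation wins over hedging. The
window of 5 is a package choice, configurable via
`PipelineConfig.negation_window`.

Negated mentions never count toward document-level positives or rule
satisfaction. Speculated mentions are excluded by default as well
(`include_speculated=False`): prevention-recommendation sentences are a
documented false-positive source, and excluding hedged mentions is the
conservative default. The flag exists precisely so the precision cost of the
opposite choice can be measured.

## Entity extraction

- **ICD-10**: `[A-Z][0-9]{2}(\.[0-9]{1,2})?` word-bounded, optional trailing
  German modifier letter (stripped). Dot-less matches preceded by the word
  "Vitamin" are rejected ("Vitamin B12"). Codes resolve to a label and a
  pre-coordinated concept list; code-derived mentions take precedence over
  free-text mentions on overlapping spans, because a code carries a unique
  label while free text may be ambiguous.
- **T-scores**: keyword `T-Score` (case-insensitive; the dialect `T-Wert` is
  also accepted) with optional `:`/`=` and a signed decimal with comma or
  point. A keyword without a parseable number is skipped with a logged
  warning. All findings are kept; the WHO interpretation uses the **minimum**
  (worst-site) value, mirroring clinical convention — configurable in
  principle, deliberate as a default.
- **Trade names**: whole-token matches against the drug lexicon (a bundled
  36-entry TSV standing in for a licensed national drug database) emit the
  active agent's concept. Compound-split stems never fire, so "Pantozolin"
  does not match "Pantozol".

## WHO bone-density rule

T ≤ −2.5 SD → osteoporosis; −2.5 < T < −1.0 → osteopenia; T ≥ −1.0 →
normal. The −2.5 edge belongs to osteoporosis ("2.5 SD or more below the
young-adult mean") and −1.0 to normal. Both edges live in configuration
(`WHOThresholds`) and the band tests pin them exactly.

## Rules engine

Rules are YAML records: a trigger concept, a boolean condition tree
(`all`/`any`/`not` over `has_index` and numeric finding predicates) and an
action. A rule fires iff some eligible mention is subsumed under the trigger
and the condition holds over the remaining eligible mentions and findings;
the first qualifying trigger mention in document order is recorded together
with the supporting mentions. The engine is a minimal stand-in for a
medical-logic-module language: the trigger/`hasIndex` semantics are kept,
the surrounding standards machinery (institution mapping, full syntax) is
out of scope.

## Synthetic corpus

Each letter realizes its gold record (`has_osteo`, `has_ppi`,
`has_event = has_osteo ∧ has_ppi`) through randomly chosen expression
channels. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_docs` | 200 | letters per corpus (desk scale) |
| `prev_osteo` | 0.672 | bone-condition prevalence (reference cohort rate) |
| `prev_ppi` | 0.075 | PPI prevalence (reference cohort rate) |
| `p_icd_code` | 1/3 | weight of the ICD-code channel; the remainder splits evenly between diagnosis term and T-score line (the true channel mix of real letters is unknown, so near-uniform) |
| `p_abbrev` | 0.30 | PPI expressed as the bare abbreviation |
| `p_negation` | 0.30 | negated target sentence in a negative letter |
| `p_hedge_distractor` | 0.20 | hedged prevention-recommendation sentence in an osteo-negative letter |
| `ocr_rate` | 0.001 | per-character confusion probability (h→n, m→rn, l→1); digits exempt |

Positive T-score channels draw T ~ U(−3.5, −1.1) (one decimal), covering
both WHO bands; letters without that channel carry a normal-range DXA line
(T ~ U(−0.8, 1.5)) with probability 0.7. Generation uses a single
`random.Random(seed)` stream, so corpora are byte-identical across runs and
platforms.

What the generator does **not** emulate: real clinical prose and its length
(≈ 60 tokens per synthetic letter versus ≈ 1000 in real discharge letters),
laboratory panels beyond T-scores, temporal structure, de-identification
artifacts, and the true expression-channel mix. Perfect scores on the
noise-free synthetic corpus therefore demonstrate internal consistency of
pipeline, rules and gold labels — not expected performance on real letters,
where vocabulary coverage and unmodeled phrasing dominate.

## Evaluation

Document-level confusion matrices over the full corpus universe, per column
(bone condition / PPI / combined event). Precision, recall, F as usual;
undefined metrics (zero denominator) are reported as an explicit `n/a`,
never coerced to 0 or 1. Confidence intervals are two-sided Clopper–Pearson
from beta quantiles (`low = B(α/2; k, n−k+1)`, `high = B(1−α/2; k+1, n−k)`,
with k = 0 → low = 0 and k = n → high = 1), cross-checked in the tests
against an independent bisection on the binomial CDF to 1e−9. Report
percentages are rounded half-up to two decimals.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the end-to-end pipeline on
200-letter corpora, parameter-recovery checks on 2000 letters, taxonomy
equivalence on 50 random DAGs of up to 40 nodes, and CI equivalence on 1000
random (k, n) with n ≤ 3000 — sizes chosen to exercise every code path while
keeping a full run in well under a minute on one CPU.

## Known limitations

- Disambiguation uses graph distance only; no statistical sense inventory.
- Negation scope is window- and sentence-based; long-range or coordinated
  scopes ("weder … noch") are not modeled.
- The spell corrector searches the whole vocabulary per unknown token
  (length-filtered); adequate at desk scale, an index would be needed for
  large vocabularies.
- The drug lexicon resolves trade names only; dose/frequency parsing and
  ATC assignment are out of scope.
- Mention-level (span) evaluation and significance testing between systems
  are out of scope; scoring is document-level only.
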