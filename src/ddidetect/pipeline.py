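"""NLP annotation pipeline: from letter text to a concept graph.

Stages, in order: tokenization → stemming with German compound splitting →
abbreviation expansion → OCR-aware spell correction → concept matching with
virtual synonyms → entity extraction (ICD-10, T-scores, trade names) →
measurement interpretation (WHO bone-density rule) → ontology-based
disambiguation → negation and hedge detection. The pipeline is a pure
function of (text, ontology, lexicons, configuration): annotating the same
letter twice yields byte-identical XML.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

from . import entities
from .graph import Certainty, ConceptGraph, ConceptMention, MentionSource, Token
from .ontology import Ontology, TermIndex, normalize_term
from .rules import WHOThresholds, interpret_tscore

__all__ = [
    "NegationTrigger",
    "PipelineConfig",
    "annotate",
    "detect_negation",
    "disambiguate",
    "expand_abbreviations",
    "match_concepts",
    "tokenize",
]

# number (sign included) | word incl. hyphenated compound | any other glyph
_TOKEN = re.compile(r"[+-]?\d+(?:[.,]\d+)?|[^\W\d_]\w*(?:-\w+)*|\S")

_SENTENCE_END = {".", "!", "?", ";"}


@dataclass
class PipelineConfig:
    """Tunable bounds of the pipeline (all defaults documented in docs/methods.md)."""

    negation_window: int = 5  # max intervening tokens between trigger and mention
    disamb_window: int = 10  # token distance searched for disambiguating context
    disamb_max_path: int = 3  # max relation-path length (any predicate)
    correct_spelling: bool = True
    min_correction_length: int = 4
    who: WHOThresholds = field(default_factory=WHOThresholds)


def tokenize(text: str) -> list[Token]:
    """Split text into offset-preserving tokens.

    Punctuation is split off; hyphenated compounds ("T-Score", "prtone-pmp")
    stay single tokens; signed decimals ("-2.7", "-2,7") are one token.
    """
    return [
        Token(surface=m.group(0), start=m.start(), end=m.end())
        for m in _TOKEN.finditer(text)
    ]


def stem_tokens(tokens: list[Token], stemmer) -> None:
    for tok in tokens:
        if any(ch.isalpha() for ch in tok.surface):
            tok.stems = stemmer.stem_word(tok.surface)
        else:
            tok.stems = [normalize_term(tok.surface)]


def expand_abbreviations(
    tokens: list[Token], abbrev_lexicon: dict[str, str], stemmer
) -> list[Token]:
    """Add the expansion's stems as an alternative reading of matching tokens.

    Lookup is by exact surface first, then case-folded; offsets and the
    original stems are untouched, so "PPI" and "Protonenpumpeninhibitor"
    are detected identically downstream.
    """
    folded = {normalize_term(k): v for k, v in abbrev_lexicon.items()}
    for tok in tokens:
        expansion = abbrev_lexicon.get(tok.surface) or folded.get(
            normalize_term(tok.surface)
        )
        if expansion is None:
            continue
        stems: list[str] = []
        for word in expansion.split():
            stems.extend(stemmer.stem_word(word))
        if stems and stems not in tok.alt_stems and stems != tok.stems:
            tok.alt_stems.append(stems)
            tok.labels.add("ABBREV")
    return tokens


def correct_tokens(tokens: list[Token], corrector, stemmer, config: PipelineConfig) -> None:
    """Spell-correct alphabetic tokens whose stems are unknown to the lexicon."""
    for tok in tokens:
        if len(tok.surface) < config.min_correction_length:
            continue
        if not any(ch.isalpha() for ch in tok.surface):
            continue
        if tok.alt_stems:  # recognized abbreviation
            continue
        norm = normalize_term(tok.surface)
        if norm in corrector.vocabulary:
            continue
        if all(stem in stemmer.lexicon for stem in tok.stems):
            continue
        corrected = corrector.correct(tok.surface)
        if corrected is None:
            continue
        tok.corrected_from = tok.surface
        tok.labels.add("CORRECTED")
        tok.stems = stemmer.stem_word(corrected)


# ------------------------------------------------------------------ matching
def _match_description(
    tokens: list[Token],
    start_tok: int,
    alt: list[str],
    offset: int,
    desc: tuple[str, ...],
    index: TermIndex,
) -> int | None:
    """Try to match description stems from (token, alternative, stem offset).

    Consecutive description stems consume consecutive token stems; each later
    token may contribute via any of its alternative readings. Returns the
    last token index of the match, or None.
    """

    def rec(ti: int, cur: list[str], pos: int, di: int) -> int | None:
        if di == len(desc):
            return ti
        if pos >= len(cur):
            tj = ti + 1
            if tj >= len(tokens):
                return None
            for nxt in tokens[tj].alternatives():
                hit = rec(tj, nxt, 0, di)
                if hit is not None:
                    return hit
            return None
        if index.stems_match(desc[di], cur[pos]):
            return rec(ti, cur, pos + 1, di + 1)
        return None

    return rec(start_tok, alt, offset, 0)


def match_concepts(
    tokens: list[Token], index: TermIndex, onto: Ontology | None = None
) -> list[ConceptMention]:
    """Longest-match, left-to-right concept matching with virtual synonyms.

    A multi-stem description matches when each of its stems is matched in
    order by token stems, either literally or by a stem that is a one-word
    description of a common concept (virtual synonymy). Every concept of an
    ambiguous matched span yields its own mention.
    """
    mentions: list[ConceptMention] = []
    i, n = 0, len(tokens)
    while i < n:
        hits: list[tuple[int, int, set[str]]] = []  # (last_token, desc_len, ids)
        for alt in tokens[i].alternatives():
            for offset, stem in enumerate(alt):
                seen: set[tuple[str, ...]] = set()
                first_stems = [stem, *sorted(index.synonym_mates(stem))]
                for fs in first_stems:
                    for desc, ids in index.by_first.get(fs, ()):
                        if desc in seen or not index.stems_match(desc[0], stem):
                            continue
                        seen.add(desc)
                        last = _match_description(tokens, i, alt, offset, desc, index)
                        if last is not None:
                            hits.append((last, len(desc), ids))
        if not hits:
            i += 1
            continue
        max_last = max(h[0] for h in hits)
        max_len = max(h[1] for h in hits if h[0] == max_last)
        span_ids: set[str] = set()
        for last, dlen, ids in hits:
            if last == max_last and dlen == max_len:
                span_ids |= ids
        for cid in sorted(span_ids):
            mentions.append(ConceptMention(concept_id=cid, token_span=(i, max_last)))
        i = max_last + 1
    return mentions


# -------------------------------------------------------------- disambiguation
def disambiguate(
    mentions: list[ConceptMention],
    onto: Ontology,
    window: int = 10,
    max_path: int = 3,
) -> list[ConceptMention]:
    """Resolve ambiguous spans via shortest relation paths to nearby context.

    For each span carrying several candidate concepts, the candidate with the
    strictly shortest relation path (any predicate, at most ``max_path``
    edges) to an unambiguous mention within ``window`` tokens is kept; with
    no such path, or on a tie, all interpretations are used in parallel.
    """
    spans: dict[tuple[int, int], list[ConceptMention]] = {}
    passthrough: list[ConceptMention] = []
    for m in mentions:
        if m.source is MentionSource.TEXT:
            spans.setdefault(m.token_span, []).append(m)
        else:
            passthrough.append(m)
    graph = onto.relation_graph()
    context = [
        ms[0] for span, ms in spans.items() if len({m.concept_id for m in ms}) == 1
    ]
    out: list[ConceptMention] = list(passthrough)
    for span, ms in spans.items():
        if len({m.concept_id for m in ms}) == 1:
            out.extend(ms)
            continue
        neighbours = [
            c
            for c in context
            if _span_distance(span, c.token_span) <= window
        ]
        scores: dict[str, int] = {}
        for m in ms:
            best = None
            for c in neighbours:
                try:
                    d = nx.shortest_path_length(graph, m.concept_id, c.concept_id)
                except (nx.NetworkXNoPath, nx.NodeNotFound):
                    continue
                if d <= max_path and (best is None or d < best):
                    best = d
            if best is not None:
                scores[m.concept_id] = best
        if scores:
            best_score = min(scores.values())
            winners = [cid for cid, s in scores.items() if s == best_score]
            if len(winners) == 1:
                out.extend(m for m in ms if m.concept_id == winners[0])
                continue
        out.extend(ms)
    return out


def _span_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    if b[0] > a[1]:
        return b[0] - a[1]
    if a[0] > b[1]:
        return a[0] - b[1]
    return 0


# ------------------------------------------------------------------- negation
@dataclass(frozen=True)
class NegationTrigger:
    """A (possibly multi-word) trigger phrase with its kind.

    kind: ``pre_neg`` negates a following mention, ``post_neg`` a preceding
    one (German "ausgeschlossen"), ``hedge`` marks a following mention as
    speculated.
    """

    phrase: tuple[str, ...]
    kind: str  # pre_neg | post_neg | hedge


def _sentence_ids(tokens: list[Token], text: str) -> list[int]:
    ids: list[int] = []
    current = 0
    for i, tok in enumerate(tokens):
        ids.append(current)
        if tok.surface in _SENTENCE_END:
            current += 1
        elif i + 1 < len(tokens) and "\n" in text[tok.end : tokens[i + 1].start]:
            current += 1
    return ids


def detect_negation(
    tokens: list[Token],
    mentions: list[ConceptMention],
    trigger_lexicon: list[NegationTrigger],
    text: str = "",
    window: int = 5,
) -> list[ConceptMention]:
    """Set negation/certainty flags using sentence-bounded trigger scopes.

    A mention is negated when a pre-trigger ends within ``window`` intervening
    tokens before it in the same sentence, or a post-trigger follows it in the
    sentence; hedge triggers set certainty to speculated instead. Negation
    wins over hedging.
    """
    if not text and tokens:
        text = " " * tokens[-1].end
    sent = _sentence_ids(tokens, text)
    norm = [normalize_term(t.surface) for t in tokens]
    occurrences: list[tuple[int, int, str]] = []
    for trig in trigger_lexicon:
        k = len(trig.phrase)
        for i in range(len(tokens) - k + 1):
            if tuple(norm[i : i + k]) == trig.phrase:
                occurrences.append((i, i + k - 1, trig.kind))
    out: list[ConceptMention] = []
    for m in mentions:
        first, last = m.token_span
        negated = m.negated
        certainty = m.certainty
        for ts, te, kind in occurrences:
            same_sentence = sent[ts] == sent[first]
            if kind in ("pre_neg", "hedge"):
                if same_sentence and te < first and (first - te - 1) <= window:
                    if kind == "pre_neg":
                        negated = True
                    else:
                        certainty = Certainty.SPECULATED
            elif kind == "post_neg":
                if sent[ts] == sent[last] and ts > last:
                    negated = True
        out.append(
            ConceptMention(
                concept_id=m.concept_id,
                token_span=m.token_span,
                negated=negated,
                certainty=certainty if not negated else certainty,
                source=m.source,
            )
        )
    return out


# ------------------------------------------------------------------- annotate
def annotate(
    doc_id: str,
    text: str,
    resources,
    config: PipelineConfig | None = None,
) -> ConceptGraph:
    """Run the full pipeline on one letter and return its concept graph.

    ``resources`` bundles the ontology, term index, stemmer, lexicons and
    drug database (see :class:`ddidetect.resources.Resources`). Deterministic
    for fixed inputs and configuration.
    """
    config = config or PipelineConfig()
    graph = ConceptGraph(doc_id=doc_id, provenance=dict(resources.provenance))
    if not text:
        return graph
    tokens = tokenize(text)
    stem_tokens(tokens, resources.stemmer)
    expand_abbreviations(tokens, resources.abbreviations, resources.stemmer)
    if config.correct_spelling:
        correct_tokens(tokens, resources.corrector, resources.stemmer, config)
    graph.tokens = tokens

    mentions = match_concepts(tokens, resources.term_index, resources.ontology)

    # ICD-10 codes: resolved labels contribute their pre-coordinated concepts;
    # code-derived mentions take precedence over free-text mentions on
    # conflicting spans.
    icd_mentions: list[ConceptMention] = []
    icd_spans: list[tuple[int, int]] = []
    for code, (cstart, cend) in entities.extract_icd10(text):
        resolved = resources.ontology.resolve_icd10(code)
        if resolved is None:
            continue
        _label, concept_ids = resolved
        tok_span = _char_to_token_span(tokens, cstart, cend)
        if tok_span is None:
            continue
        icd_spans.append(tok_span)
        for cid in concept_ids:
            icd_mentions.append(
                ConceptMention(concept_id=cid, token_span=tok_span, source=MentionSource.ICD10)
            )
    if icd_spans:
        mentions = [
            m
            for m in mentions
            if not any(_span_distance(m.token_span, s) == 0 for s in icd_spans)
        ]
    mentions.extend(icd_mentions)

    graph.findings = entities.extract_tscores(text)
    mentions.extend(
        entities.resolve_trade_names(tokens, resources.drug_db, resources.ontology)
    )

    # WHO interpretation of the worst (minimum) T-score of the letter
    derived: list[ConceptMention] = []
    if graph.findings:
        worst = min(graph.findings, key=lambda f: f.value)
        concept = interpret_tscore(worst, config.who)
        if concept is not None:
            tok_span = _char_to_token_span(tokens, *worst.char_span)
            if tok_span is not None:
                derived.append(
                    ConceptMention(
                        concept_id=concept, token_span=tok_span, source=MentionSource.NER_RULE
                    )
                )

    mentions = disambiguate(
        mentions, resources.ontology, config.disamb_window, config.disamb_max_path
    )
    mentions = detect_negation(
        tokens, mentions, resources.negation_triggers, text, config.negation_window
    )
    mentions.extend(derived)
    mentions.sort(key=lambda m: (m.token_span, m.source.value, m.concept_id))
    graph.mentions = mentions
    return graph


def _char_to_token_span(
    tokens: list[Token], start: int, end: int
) -> tuple[int, int] | None:
    covered = [i for i, t in enumerate(tokens) if t.start < end and t.end > start]
    if not covered:
        return None
    return (covered[0], covered[-1])
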