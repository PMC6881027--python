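"""Pattern-based entity extraction: ICD-10 codes, T-scores, drug trade names.

Regular-expression named entity recognition feeding concepts and numeric
findings into the concept graph. ICD-10 codes follow the German "LNN.NN"
surface form with an optional certainty modifier letter (stripped); T-score
lines accept comma or point decimals; trade names are resolved to their
active-agent concepts through a drug lexicon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .graph import ConceptMention, MentionSource, NumericFinding, Token
from .ontology import Ontology, OntologyError, normalize_term

__all__ = [
    "DrugLexiconEntry",
    "TSCORE_CONCEPT",
    "extract_icd10",
    "extract_tscores",
    "resolve_trade_names",
]

logger = logging.getLogger(__name__)

#: terminology concept for the bone-density T-score measurement
TSCORE_CONCEPT = "W000F9D"

# letter + two digits + optional .N(N) + optional modifier letter, word-bounded
_ICD10 = re.compile(r"\b([A-Z][0-9]{2}(?:\.[0-9]{1,2})?)([A-Z]?)\b")
# keyword then optional separator then signed decimal (comma or point)
_TSCORE = re.compile(
    r"(T-?(?:Score|Wert))\s*[:=]?\s*([+-]?\d+(?:[.,]\d+)?)",
    re.IGNORECASE,
)
_TSCORE_KEYWORD = re.compile(r"T-?(?:Score|Wert)\s*[:=]?", re.IGNORECASE)


def extract_icd10(text: str) -> list[tuple[str, tuple[int, int]]]:
    """All non-overlapping ICD-10 codes with character spans, left to right.

    Dot-less vitamin designations ("Vitamin B12") are rejected by a context
    guard on the preceding word; the trailing German modifier letter is kept
    out of the returned code.
    """
    out: list[tuple[str, tuple[int, int]]] = []
    for match in _ICD10.finditer(text):
        code = match.group(1)
        preceding = text[: match.start()].rstrip()
        prev_word = preceding.split()[-1] if preceding.split() else ""
        if "." not in code and normalize_term(prev_word) in {"vitamin", "vit", "vit."}:
            continue
        out.append((code, (match.start(1), match.end(1))))
    return out


def extract_tscores(text: str) -> list[NumericFinding]:
    """T-score findings (concept W000F9D) from keyword + signed decimal.

    A keyword followed by something unparseable as a number is skipped with
    a logged warning rather than raising.
    """
    findings: list[NumericFinding] = []
    matched_starts = set()
    for match in _TSCORE.finditer(text):
        value = float(match.group(2).replace(",", "."))
        findings.append(
            NumericFinding(
                name_concept=TSCORE_CONCEPT,
                value=value,
                char_span=(match.start(), match.end()),
            )
        )
        matched_starts.add(match.start())
    for kw in _TSCORE_KEYWORD.finditer(text):
        if kw.start() not in matched_starts:
            tail = text[kw.end() : kw.end() + 12].strip()
            logger.warning("T-score keyword without parseable value: %r ...", tail[:12])
    return findings


@dataclass(frozen=True)
class DrugLexiconEntry:
    """One trade-name row of the drug lexicon."""

    trade_name_stem: str
    agent_name: str
    agent_concept: str


def load_drug_db(rows: Iterable[Sequence[str]], onto: Ontology) -> list[DrugLexiconEntry]:
    """Validate (trade_name, agent, concept_id) rows against the ontology."""
    entries: list[DrugLexiconEntry] = []
    for row in rows:
        trade, agent, concept = row[0], row[1], row[2]
        if concept not in onto.concepts:
            raise OntologyError(
                f"drug lexicon entry {trade!r}: unknown agent concept {concept!r}"
            )
        entries.append(
            DrugLexiconEntry(
                trade_name_stem=normalize_term(trade),
                agent_name=agent,
                agent_concept=concept,
            )
        )
    return entries


def resolve_trade_names(
    tokens: list[Token],
    drug_db: list[DrugLexiconEntry],
    onto: Ontology,
) -> list[ConceptMention]:
    """Label trade-name tokens and emit mentions of the active-agent concept.

    Matching is token-bounded: the whole normalized surface (or stem) must
    equal a trade-name stem; substrings never fire.
    """
    by_stem = {e.trade_name_stem: e for e in drug_db}
    mentions: list[ConceptMention] = []
    for i, tok in enumerate(tokens):
        # whole-token matching only: a trade name is not a compound part
        candidates = {normalize_term(tok.surface)}
        if len(tok.stems) == 1:
            candidates.add(tok.stems[0])
        entry = next((by_stem[c] for c in sorted(candidates) if c in by_stem), None)
        if entry is None:
            continue
        tok.labels.add("TRADE_NAME")
        mentions.append(
            ConceptMention(
                concept_id=entry.agent_concept,
                token_span=(i, i),
                source=MentionSource.TRADE_NAME,
            )
        )
    return mentions
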