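"""The concept graph: machine-readable annotation result for one document.

Holds the token layer (offsets, stems, labels), concept mentions with
negation and certainty flags, numeric findings (e.g. T-scores) and
provenance. Serializes to a versioned XML dialect and re-parses losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from lxml import etree

__all__ = [
    "Certainty",
    "ConceptGraph",
    "ConceptMention",
    "MentionSource",
    "NumericFinding",
    "Token",
]

SCHEMA_VERSION = "1.0"


class Certainty(str, Enum):
    ASSERTED = "asserted"
    SPECULATED = "speculated"


class MentionSource(str, Enum):
    TEXT = "text"
    ICD10 = "icd10"
    NER_RULE = "ner_rule"
    TRADE_NAME = "trade_name"


@dataclass
class Token:
    surface: str
    start: int
    end: int
    stems: list[str] = field(default_factory=list)
    #: alternative stem sequences (abbreviation expansions)
    alt_stems: list[list[str]] = field(default_factory=list)
    labels: set[str] = field(default_factory=set)
    corrected_from: str | None = None

    def alternatives(self) -> list[list[str]]:
        return [self.stems] + self.alt_stems


@dataclass
class ConceptMention:
    concept_id: str
    token_span: tuple[int, int]  # (first, last) token index, inclusive
    negated: bool = False
    certainty: Certainty = Certainty.ASSERTED
    source: MentionSource = MentionSource.TEXT

    def is_positive(self, include_speculated: bool = False) -> bool:
        """Whether this mention may count toward document-level positives."""
        if self.negated:
            return False
        return include_speculated or self.certainty is Certainty.ASSERTED

    def negate(self) -> "ConceptMention":
        return replace(self, negated=True)


@dataclass
class NumericFinding:
    name_concept: str
    value: float
    char_span: tuple[int, int]


@dataclass
class ConceptGraph:
    doc_id: str
    tokens: list[Token] = field(default_factory=list)
    mentions: list[ConceptMention] = field(default_factory=list)
    findings: list[NumericFinding] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    # ------------------------------------------------------------- queries
    def positive_concepts(self, include_speculated: bool = False) -> set[str]:
        """Concept ids of mentions eligible as document-level positives."""
        return {
            m.concept_id
            for m in self.mentions
            if m.is_positive(include_speculated=include_speculated)
        }

    def mention_char_span(self, mention: ConceptMention) -> tuple[int, int]:
        first, last = mention.token_span
        return (self.tokens[first].start, self.tokens[last].end)

    # ----------------------------------------------------------------- XML
    def to_xml(self) -> bytes:
        root = etree.Element("conceptGraph", docId=self.doc_id, version=SCHEMA_VERSION)
        prov = etree.SubElement(root, "provenance")
        for key in sorted(self.provenance):
            etree.SubElement(prov, "item", name=key, value=self.provenance[key])
        toks = etree.SubElement(root, "tokens")
        for tok in self.tokens:
            el = etree.SubElement(
                toks, "token", surface=tok.surface, start=str(tok.start), end=str(tok.end)
            )
            if tok.corrected_from is not None:
                el.set("correctedFrom", tok.corrected_from)
            if tok.labels:
                el.set("labels", ",".join(sorted(tok.labels)))
            for stem in tok.stems:
                etree.SubElement(el, "stem").text = stem
            for alt in tok.alt_stems:
                alt_el = etree.SubElement(el, "alt")
                for stem in alt:
                    etree.SubElement(alt_el, "stem").text = stem
        mens = etree.SubElement(root, "mentions")
        for m in self.mentions:
            etree.SubElement(
                mens,
                "mention",
                concept=m.concept_id,
                first=str(m.token_span[0]),
                last=str(m.token_span[1]),
                negated="true" if m.negated else "false",
                certainty=m.certainty.value,
                source=m.source.value,
            )
        finds = etree.SubElement(root, "findings")
        for f in self.findings:
            etree.SubElement(
                finds,
                "finding",
                name=f.name_concept,
                value=repr(f.value),
                start=str(f.char_span[0]),
                end=str(f.char_span[1]),
            )
        return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)

    @classmethod
    def from_xml(cls, data: bytes) -> "ConceptGraph":
        root = etree.fromstring(data)
        if root.tag != "conceptGraph":
            raise ValueError(f"unexpected root element {root.tag!r}")
        graph = cls(doc_id=root.get("docId", ""))
        prov = root.find("provenance")
        if prov is not None:
            for item in prov.findall("item"):
                graph.provenance[item.get("name", "")] = item.get("value", "")
        toks = root.find("tokens")
        if toks is not None:
            for el in toks.findall("token"):
                tok = Token(
                    surface=el.get("surface", ""),
                    start=int(el.get("start", "0")),
                    end=int(el.get("end", "0")),
                    stems=[s.text or "" for s in el.findall("stem")],
                    alt_stems=[
                        [s.text or "" for s in alt.findall("stem")]
                        for alt in el.findall("alt")
                    ],
                    corrected_from=el.get("correctedFrom"),
                )
                labels = el.get("labels")
                if labels:
                    tok.labels = set(labels.split(","))
                graph.tokens.append(tok)
        mens = root.find("mentions")
        if mens is not None:
            for el in mens.findall("mention"):
                graph.mentions.append(
                    ConceptMention(
                        concept_id=el.get("concept", ""),
                        token_span=(int(el.get("first", "0")), int(el.get("last", "0"))),
                        negated=el.get("negated") == "true",
                        certainty=Certainty(el.get("certainty", "asserted")),
                        source=MentionSource(el.get("source", "text")),
                    )
                )
        finds = root.find("findings")
        if finds is not None:
            for el in finds.findall("finding"):
                graph.findings.append(
                    NumericFinding(
                        name_concept=el.get("name", ""),
                        value=float(el.get("value", "nan")),
                        char_span=(int(el.get("start", "0")), int(el.get("end", "0"))),
                    )
                )
        return graph
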