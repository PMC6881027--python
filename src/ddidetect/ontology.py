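"""Local terminology store with taxonomic subsumption and ICD-10 resolution.

A stand-in for a full terminology server: concepts carry multilingual
descriptions and typed relations (taxonomic ``is a``, partonomic
``is part of`` and free semantic links such as ``is contraindication of``).
The store answers subsumption queries (``has_index``), builds a stem-level
term index used for concept matching, and resolves ICD-10 codes to textual
labels plus pre-coordinated concept lists.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable

import networkx as nx

__all__ = [
    "Category",
    "Concept",
    "Ontology",
    "OntologyError",
    "Predicate",
    "Relation",
    "TermIndex",
    "load_ontology",
    "normalize_term",
]


class OntologyError(ValueError):
    """Raised when an ontology file violates the schema or its invariants."""


class Category(str, Enum):
    DIAGNOSIS = "diagnosis"
    MORPHOLOGY = "morphology"
    TREATMENT = "treatment"
    PROCEDURE = "procedure"
    AGENT = "agent"
    MICROBIOLOGY = "microbiology"
    FUNCTION = "function"
    MATERIAL = "material"
    TOPOGRAPHY = "topography"
    LINKER = "linker"
    MEASUREMENT = "measurement"


class Predicate(str, Enum):
    IS_A = "is_a"
    PART_OF = "part_of"
    SEMANTIC = "semantic"


# ä→ae etc. before casefold so OCR/typing variants index identically
_UMLAUTS = str.maketrans(
    {"ä": "ae", "ö": "oe", "ü": "ue", "Ä": "ae", "Ö": "oe", "Ü": "ue", "ß": "ss"}
)


def normalize_term(term: str) -> str:
    """Lower-case a term and fold German umlauts (ä→ae, ö→oe, ü→ue, ß→ss)."""
    return term.translate(_UMLAUTS).lower()


@dataclass(frozen=True)
class Concept:
    """A terminology concept: identifier, descriptions (term, language), category."""

    id: str
    descriptions: tuple[tuple[str, str], ...]
    category: Category

    def terms(self) -> list[str]:
        return [t for t, _lang in self.descriptions]


@dataclass(frozen=True)
class Relation:
    subject: str
    predicate: Predicate
    object: str
    semantic_label: str | None = None


_ICD10_CANON = re.compile(r"^[A-Z][0-9]{2}(?:\.[0-9]{1,2})?$")


@dataclass
class Ontology:
    """Concept store with an IS_A taxonomy index and an ICD-10 code map."""

    concepts: dict[str, Concept]
    relations: list[Relation]
    icd10_map: dict[str, tuple[str, list[str]]]
    _children: dict[str, list[str]] = field(default_factory=dict, repr=False)
    _graph: "nx.DiGraph | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ checks
    def validate(self) -> None:
        for cid, c in self.concepts.items():
            if not cid:
                raise OntologyError("empty concept id")
            if cid != c.id:
                raise OntologyError(f"concept key {cid!r} != id {c.id!r}")
            if not c.descriptions:
                raise OntologyError(f"concept {cid!r} has no descriptions")
        isa = nx.DiGraph()
        children: dict[str, list[str]] = {}
        for rel in self.relations:
            for endpoint in (rel.subject, rel.object):
                if endpoint not in self.concepts:
                    raise OntologyError(
                        f"relation {rel.subject} {rel.predicate.value} {rel.object}: "
                        f"unknown concept {endpoint!r}"
                    )
            if rel.predicate is Predicate.IS_A:
                isa.add_edge(rel.subject, rel.object)
                children.setdefault(rel.object, []).append(rel.subject)
        if not nx.is_directed_acyclic_graph(isa):
            cycle = nx.find_cycle(isa)
            path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"IS_A cycle: {path}")
        for code, (label, ids) in self.icd10_map.items():
            if not _ICD10_CANON.match(code):
                raise OntologyError(f"icd10_map key {code!r} is not canonical")
            for cid in ids:
                if cid not in self.concepts:
                    raise OntologyError(f"icd10 code {code}: unknown concept {cid!r}")
        self._children = children
        # undirected relation graph (any predicate), used by disambiguation
        g = nx.Graph()
        g.add_nodes_from(self.concepts)
        g.add_edges_from((r.subject, r.object) for r in self.relations)
        self._graph = g

    # --------------------------------------------------------------- taxonomy
    def descendants(self, concept_id: str, reflexive: bool = True) -> set[str]:
        """All concepts reachable via reverse IS_A edges.

        With ``reflexive=True`` (default) the concept itself is included, so a
        mention of the parent term satisfies subsumption under itself.
        """
        if concept_id not in self.concepts:
            raise KeyError(f"unknown concept {concept_id!r}")
        out: set[str] = {concept_id} if reflexive else set()
        stack = list(self._children.get(concept_id, ()))
        while stack:
            node = stack.pop()
            if node in out:
                continue
            out.add(node)
            stack.extend(self._children.get(node, ()))
        return out

    def has_index(self, found: str, ancestor: str) -> bool:
        """True iff ``found`` is taxonomically subsumed under ``ancestor``.

        Reflexive: ``has_index(x, x)`` is true, so the literal parent term
        (e.g. "PPI") triggers rules phrased over the parent concept.
        """
        if found not in self.concepts:
            raise KeyError(f"unknown concept {found!r}")
        return found in self.descendants(ancestor)

    def relation_graph(self) -> "nx.Graph":
        assert self._graph is not None
        return self._graph

    # ----------------------------------------------------------------- ICD-10
    def resolve_icd10(self, code: str) -> tuple[str, list[str]] | None:
        """Resolve an ICD-10 code to (label, concept ids); None if unknown.

        Codes are canonicalized (upper case, German modifier letters such as
        the trailing G/V/A stripped) before lookup. A syntactically malformed
        code raises ``ValueError``.
        """
        canon = code.strip().upper()
        canon = re.sub(r"[A-Z]$", "", canon) if len(canon) > 3 else canon
        if not _ICD10_CANON.match(canon):
            raise ValueError(f"malformed ICD-10 code {code!r}")
        return self.icd10_map.get(canon)


class TermIndex:
    """Stemmed description index over an ontology.

    ``descriptions`` maps a stem tuple to the concept ids sharing that stemmed
    description; ``unigram`` maps single stems to concepts for which the stem
    constitutes a complete one-word description. The latter is the basis of
    virtual synonymy: two stems are interchangeable inside a longer
    description whenever they are one-word descriptions of a common concept
    (the classic "heart"/"cardiac" → "cardiac infarction" case).
    """

    def __init__(self) -> None:
        self.descriptions: dict[tuple[str, ...], set[str]] = {}
        self.unigram: dict[str, set[str]] = {}
        self._mates: dict[str, set[str]] = {}
        self.by_first: dict[str, list[tuple[tuple[str, ...], set[str]]]] = {}

    def add(self, stems: tuple[str, ...], concept_id: str) -> None:
        if not stems:
            return
        self.descriptions.setdefault(stems, set()).add(concept_id)
        if len(stems) == 1:
            self.unigram.setdefault(stems[0], set()).add(concept_id)

    def lookup(self, stem: str) -> set[str]:
        """Concepts having ``stem`` as a complete one-word description."""
        return self.unigram.get(stem, set())

    def freeze(self) -> None:
        for stems, ids in self.descriptions.items():
            self.by_first.setdefault(stems[0], []).append((stems, ids))
        mates: dict[str, set[str]] = {}
        concept_stems: dict[str, set[str]] = {}
        for stem, ids in self.unigram.items():
            for cid in ids:
                concept_stems.setdefault(cid, set()).add(stem)
        for stem, ids in self.unigram.items():
            m: set[str] = set()
            for cid in ids:
                m |= concept_stems[cid]
            m.discard(stem)
            mates[stem] = m
        self._mates = mates

    def synonym_mates(self, stem: str) -> set[str]:
        """Stems virtually synonymous with ``stem`` (share a one-word concept)."""
        return self._mates.get(stem, set())

    def stems_match(self, a: str, b: str) -> bool:
        return a == b or bool(self.unigram.get(a, set()) & self.unigram.get(b, set()))


def build_term_index(onto: Ontology, stemmer: Callable[[str], list[str]]) -> TermIndex:
    """Index every description of every concept under its normalized stems."""
    index = TermIndex()
    for cid, concept in onto.concepts.items():
        for term in concept.terms():
            stems: list[str] = []
            for word in term.split():
                stems.extend(stemmer(word))
            index.add(tuple(stems), cid)
    index.freeze()
    return index


# ---------------------------------------------------------------------- load
def load_ontology(path: str | Path) -> Ontology:
    """Load and validate an ontology from its JSON serialization.

    Schema: ``{"concepts": [{"id", "category", "descriptions": [[term, lang]...]}],
    "relations": [{"subject", "predicate", "object", "semantic_label"?}],
    "icd10_map": {code: [label, [concept ids]]}}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise OntologyError(f"{path}: not valid JSON ({exc})") from exc
    return ontology_from_dict(raw)


def ontology_from_dict(raw: dict) -> Ontology:
    if not isinstance(raw, dict) or "concepts" not in raw:
        raise OntologyError("ontology document must be an object with a 'concepts' list")
    concepts: dict[str, Concept] = {}
    for rec in raw.get("concepts", []):
        try:
            concept = Concept(
                id=rec["id"],
                descriptions=tuple((t, lang) for t, lang in rec["descriptions"]),
                category=Category(rec["category"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise OntologyError(f"bad concept record {rec!r}: {exc}") from exc
        if concept.id in concepts:
            raise OntologyError(f"duplicate concept id {concept.id!r}")
        concepts[concept.id] = concept
    relations: list[Relation] = []
    for rec in raw.get("relations", []):
        try:
            relations.append(
                Relation(
                    subject=rec["subject"],
                    predicate=Predicate(rec["predicate"]),
                    object=rec["object"],
                    semantic_label=rec.get("semantic_label"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise OntologyError(f"bad relation record {rec!r}: {exc}") from exc
    icd10_map: dict[str, tuple[str, list[str]]] = {}
    for code, entry in raw.get("icd10_map", {}).items():
        try:
            label, ids = entry
        except (TypeError, ValueError) as exc:
            raise OntologyError(f"bad icd10_map entry {code!r}: {entry!r}") from exc
        icd10_map[code] = (label, list(ids))
    return Ontology(concepts=concepts, relations=relations, icd10_map=icd10_map)
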