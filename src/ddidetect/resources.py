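"""Bundled lexicons, the fixture terminology and resource assembly.

``load_default_resources()`` wires the packaged synthetic miniature
terminology (``wnc_mini.json``), the drug lexicon and the trigger/abbreviation
lexicons into a ready-to-use :class:`Resources` bundle. All components can
also be loaded from external files for custom deployments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

from . import __version__
from .entities import DrugLexiconEntry, load_drug_db
from .ontology import Ontology, TermIndex, build_term_index, load_ontology, normalize_term
from .pipeline import NegationTrigger
from .stemming import GermanStemmer, SpellCorrector

__all__ = ["Resources", "data_path", "load_default_resources"]


def data_path(name: str) -> Path:
    """Path of a packaged data file."""
    return Path(str(importlib_resources.files("ddidetect.data") / name))


def _read_rows(path: Path) -> list[list[str]]:
    rows: list[list[str]] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@dataclass
class Resources:
    """Everything the annotation pipeline needs, assembled and validated."""

    ontology: Ontology
    stemmer: GermanStemmer
    term_index: TermIndex
    corrector: SpellCorrector
    abbreviations: dict[str, str]
    negation_triggers: list[NegationTrigger]
    drug_db: list[DrugLexiconEntry]
    ocr_confusions: tuple[tuple[str, str, float], ...]
    provenance: dict[str, str] = field(default_factory=dict)

    @classmethod
    def assemble(
        cls,
        ontology: Ontology,
        drug_rows: list[list[str]],
        abbreviations: dict[str, str],
        trigger_rows: list[list[str]],
        confusion_rows: list[list[str]],
        extra_stems: set[str] = frozenset(),
        stopwords: set[str] = frozenset(),
        provenance: dict[str, str] | None = None,
    ) -> "Resources":
        # stem lexicon: every description word (and trade name) in canonical
        # normalized form, plus the supplementary compound-part list
        lexicon: set[str] = set(extra_stems)
        vocab: set[str] = set(stopwords) | set(extra_stems)
        for concept in ontology.concepts.values():
            for term in concept.terms():
                for word in term.split():
                    for part in [word, *word.split("-")]:
                        norm = normalize_term(part)
                        if norm:
                            lexicon.add(norm)
                    vocab.add(normalize_term(word))
        for row in drug_rows:
            norm = normalize_term(row[0])
            lexicon.add(norm)
            vocab.add(norm)
        for expansion in abbreviations.values():
            for word in expansion.split():
                vocab.add(normalize_term(word))
        stemmer = GermanStemmer(lexicon=lexicon)
        confusions = tuple(
            (normalize_term(a), normalize_term(b), float(w))
            for a, b, w in confusion_rows
        )
        triggers = [
            NegationTrigger(
                phrase=tuple(normalize_term(w) for w in phrase.split()), kind=kind
            )
            for phrase, kind in trigger_rows
        ]
        return cls(
            ontology=ontology,
            stemmer=stemmer,
            term_index=build_term_index(ontology, stemmer),
            corrector=SpellCorrector(vocabulary=vocab, confusions=confusions),
            abbreviations=dict(abbreviations),
            negation_triggers=triggers,
            drug_db=load_drug_db(drug_rows, ontology),
            ocr_confusions=confusions,
            provenance=provenance or {"pipeline_version": __version__},
        )

    @classmethod
    def from_paths(
        cls,
        ontology_path: Path,
        drug_db_path: Path,
        abbreviations_path: Path,
        triggers_path: Path,
        confusions_path: Path,
        stems_path: Path | None = None,
        stopwords_path: Path | None = None,
    ) -> "Resources":
        ontology = load_ontology(ontology_path)
        drug_rows = _read_rows(drug_db_path)
        abbreviations = {row[0]: row[1] for row in _read_rows(abbreviations_path)}
        trigger_rows = [(row[0], row[1]) for row in _read_rows(triggers_path)]
        confusion_rows = _read_rows(confusions_path)
        extra = set()
        if stems_path is not None:
            extra = {normalize_term(r[0]) for r in _read_rows(stems_path)}
        stop: set[str] = set()
        if stopwords_path is not None:
            for row in _read_rows(stopwords_path):
                stop.update(normalize_term(w) for w in row if w)
        provenance = {"pipeline_version": __version__}
        for label, path in (
            ("ontology", ontology_path),
            ("drug_db", drug_db_path),
            ("abbreviations", abbreviations_path),
            ("negation_triggers", triggers_path),
            ("ocr_confusions", confusions_path),
        ):
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
            provenance[f"lexicon_{label}"] = digest
        return cls.assemble(
            ontology,
            drug_rows,
            abbreviations,
            trigger_rows,
            confusion_rows,
            extra_stems=extra,
            stopwords=stop,
            provenance=provenance,
        )


def load_default_resources() -> Resources:
    """Load the packaged fixture terminology and lexicons."""
    return Resources.from_paths(
        ontology_path=data_path("wnc_mini.json"),
        drug_db_path=data_path("drug_db.tsv"),
        abbreviations_path=data_path("abbreviations.tsv"),
        triggers_path=data_path("negation_triggers.tsv"),
        confusions_path=data_path("ocr_confusions.tsv"),
        stems_path=data_path("stems_extra.tsv"),
        stopwords_path=data_path("stopwords.tsv"),
    )


def default_rules_path() -> Path:
    return data_path("rules_default.yaml")
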