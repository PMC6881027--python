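"""Synthetic German-style discharge letters with document-level ground truth.

Letters follow the section scaffold of epidemiological study discharge
letters (demographics, new/previous diagnoses, medication, examination
results, DXA bone densitometry, discharge summary). Each letter realizes
its gold record through a randomly chosen expression channel: a diagnosis
term drawn from the terminology, a bare ICD-10 code, or a T-score line in
the DXA section; drug exposure appears as a trade name, an active-agent
name, or the bare abbreviation. Negative letters may carry negated mentions
and hedged prevention-recommendation sentences — the false-positive source
of real letters — and the whole text can be corrupted with OCR-typical
character confusions. Generation is a pure function of the parameters and
seed.

The generator emulates letter *structure* and the noise channels relevant
to detection; it does not emulate real clinical prose, laboratory panels
beyond T-scores, or the token statistics of any real corpus.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from .entities import DrugLexiconEntry
from .evaluation import GoldRecord
from .ontology import Ontology
from .pipeline import tokenize
from .rules import OSTEOPENIA, OSTEOPOROSIS, PPI

__all__ = [
    "CorpusStats",
    "GeneratorParams",
    "apply_ocr_noise",
    "corpus_stats",
    "generate_corpus",
    "rounded_average",
    "write_corpus",
]

#: OCR-typical corruption map used by default (h read as n, m as rn, l as 1)
DEFAULT_OCR_MAP: dict[str, str] = {"h": "n", "m": "rn", "l": "1"}

OSTEO_ICD_CODES = ("M80.0", "M81.0", "M81.9", "M82.02", "M85.8")
DISTRACTOR_ICD_CODES = ("E11.9", "I10", "K21.0", "D64.9", "E03.9", "E78.0")
DISTRACTOR_DIAGNOSES = (
    "Arterielle Hypertonie",
    "Diabetes mellitus",
    "Hyperlipidämie",
    "Gastritis",
    "Anämie",
    "Hypothyreose",
    "Gonarthrose",
)
NEUTRAL_SUMMARIES = (
    "Die Untersuchungen ergaben insgesamt altersentsprechende Befunde.",
    "Wir danken für die freundliche Teilnahme an der Studie.",
    "Die Laborwerte lagen weitgehend im Normbereich.",
    "Es ergab sich kein Anhalt für akute Erkrankungen.",
)
HEDGE_DISTRACTORS = (
    "Zur Prävention der Osteoporose empfehlen wir Vitamin D und Calcium.",
    "Bei erhöhtem Risiko für Osteoporose wird körperliche Aktivität empfohlen.",
    "Verdacht auf Osteopenie, eine Kontrolle wird empfohlen.",
)
OSTEO_NEGATIONS = (
    "Kein Hinweis auf Osteoporose.",
    "Keine Osteoporose bekannt.",
)
PPI_NEGATIONS = (
    "Keine Therapie mit Protonenpumpeninhibitoren.",
    "Keine Einnahme von Protonenpumpeninhibitoren.",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of the synthetic corpus.

    Prevalence defaults mirror the gold-standard rates of the reference
    cohort (67.2% bone condition, 7.5% PPI use); the noise probabilities are
    desk-scale defaults documented in docs/methods.md.
    """

    n_docs: int = 200
    prev_osteo: float = 0.672
    prev_ppi: float = 0.075
    p_negation: float = 0.30
    p_hedge_distractor: float = 0.20
    p_icd_code: float = 1.0 / 3.0
    p_abbrev: float = 0.30
    ocr_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        for name in (
            "prev_osteo",
            "prev_ppi",
            "p_negation",
            "p_hedge_distractor",
            "p_icd_code",
            "p_abbrev",
            "ocr_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value!r}")


def apply_ocr_noise(
    text: str,
    confusion_table: dict[str, str] | None = None,
    rate: float = 0.0,
    rng: random.Random | int | None = None,
) -> str:
    """Corrupt characters per an OCR confusion table, each independently.

    Digits are exempt so that numeric findings (T-score values) survive the
    simulated scan.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    table = DEFAULT_OCR_MAP if confusion_table is None else confusion_table
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    if rate == 0.0 or not table:
        return text
    out: list[str] = []
    for ch in text:
        if ch.isdigit():
            out.append(ch)
            continue
        repl = table.get(ch, table.get(ch.lower()))
        if repl is not None and rng.random() < rate:
            out.append(repl.upper() if ch.isupper() else repl)
        else:
            out.append(ch)
    return "".join(out)


def _german_term(onto: Ontology, concept_id: str) -> str:
    for term, lang in onto.concepts[concept_id].descriptions:
        if lang == "de":
            return term
    return onto.concepts[concept_id].descriptions[0][0]


def _letter_text(
    rng: random.Random,
    onto: Ontology,
    drug_db: Sequence[DrugLexiconEntry],
    params: GeneratorParams,
    has_osteo: bool,
    has_ppi: bool,
) -> str:
    osteo_concepts = sorted(
        onto.descendants(OSTEOPOROSIS) | onto.descendants(OSTEOPENIA)
    )
    ppi_concepts = sorted(onto.descendants(PPI))
    ppi_trades = [e for e in drug_db if e.agent_concept in set(ppi_concepts)]
    other_trades = [e for e in drug_db if e.agent_concept not in set(ppi_concepts)]

    age = rng.randint(62, 86)
    sex = rng.choice(("weiblich", "männlich"))
    diag_lines: list[str] = []
    med_lines: list[str] = []
    dxa_lines: list[str] = []
    summary: list[str] = []

    for _ in range(rng.randint(1, 3)):
        if rng.random() < params.p_icd_code:
            diag_lines.append(f"- {rng.choice(DISTRACTOR_ICD_CODES)}")
        else:
            diag_lines.append(f"- {rng.choice(DISTRACTOR_DIAGNOSES)}")

    osteo_channel = None
    if has_osteo:
        r = rng.random()
        if r < params.p_icd_code:
            osteo_channel = "icd"
            diag_lines.append(f"- {rng.choice(OSTEO_ICD_CODES)}")
        elif r < params.p_icd_code + (1.0 - params.p_icd_code) / 2.0:
            osteo_channel = "term"
            concept = rng.choice(osteo_concepts)
            diag_lines.append(f"- {_german_term(onto, concept)}")
        else:
            osteo_channel = "tscore"
            t = rng.uniform(-3.5, -1.1)
            dxa_lines.append(f"T-Score: {t:.1f}")
    if osteo_channel != "tscore" and rng.random() < 0.7:
        t = rng.uniform(-0.8, 1.5)
        dxa_lines.append(f"T-Score: {t:.1f}")

    for _ in range(rng.randint(1, 3)):
        entry = rng.choice(other_trades)
        if rng.random() < 0.5:
            med_lines.append(f"- {entry.trade_name_stem.title()} {rng.choice((5, 10, 50, 100))} mg 1-0-0")
        else:
            med_lines.append(f"- {entry.agent_name} {rng.choice((5, 10, 50, 100))} mg 0-0-1")
    if has_ppi:
        dose = rng.choice((20, 40))
        if rng.random() < params.p_abbrev:
            med_lines.append(f"- PPI {dose} mg 1-0-0")
        elif rng.random() < 0.5:
            entry = rng.choice(ppi_trades)
            med_lines.append(f"- {entry.trade_name_stem.title()} {dose} mg 1-0-0")
        else:
            concept = rng.choice(ppi_concepts[1:] if len(ppi_concepts) > 1 else ppi_concepts)
            med_lines.append(f"- {_german_term(onto, concept)} {dose} mg 1-0-0")

    summary.append(rng.choice(NEUTRAL_SUMMARIES))
    if not has_osteo:
        if rng.random() < params.p_negation:
            summary.append(rng.choice(OSTEO_NEGATIONS))
        if rng.random() < params.p_hedge_distractor:
            summary.append(rng.choice(HEDGE_DISTRACTORS))
    if not has_ppi and rng.random() < params.p_negation:
        summary.append(rng.choice(PPI_NEGATIONS))

    rng.shuffle(summary)
    sections = [
        f"Alter: {age} Jahre, Geschlecht: {sex}",
        "",
        "Neue Diagnosen:",
        *diag_lines,
        "",
        "Medikation:",
        *med_lines,
        "",
        "Dual Energy X-ray Absorptiometrie (DXA):",
        *(dxa_lines or ["ohne Befund"]),
        "",
        "Entlassungsbericht:",
        *summary,
    ]
    return "\n".join(sections) + "\n"


def generate_corpus(
    params: GeneratorParams,
    onto: Ontology,
    drug_db: Sequence[DrugLexiconEntry],
    templates=None,
) -> tuple[list[dict[str, str]], list[GoldRecord]]:
    """Generate letters and their gold records; reproducible given the seed.

    Returns ``(letters, gold)`` where letters are ``{"doc_id", "text"}``
    dictionaries ready for JSONL serialization.
    """
    params.validate()
    rng = random.Random(params.seed)
    letters: list[dict[str, str]] = []
    gold: list[GoldRecord] = []
    width = max(4, len(str(params.n_docs)))
    for i in range(params.n_docs):
        doc_id = f"D{i:0{width}d}"
        has_osteo = rng.random() < params.prev_osteo
        has_ppi = rng.random() < params.prev_ppi
        text = _letter_text(rng, onto, drug_db, params, has_osteo, has_ppi)
        if params.ocr_rate > 0.0:
            text = apply_ocr_noise(text, DEFAULT_OCR_MAP, params.ocr_rate, rng)
        letters.append({"doc_id": doc_id, "text": text})
        gold.append(GoldRecord(doc_id=doc_id, has_osteo=has_osteo, has_ppi=has_ppi))
    return letters, gold


def write_corpus(
    letters: Iterable[dict[str, str]],
    gold: Iterable[GoldRecord],
    letters_path: str | Path,
    gold_path: str | Path,
) -> None:
    """Write letters as JSONL and the gold standard as TSV."""
    with open(letters_path, "w", encoding="utf-8") as fh:
        for rec in letters:
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
    with open(gold_path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\thas_osteo\thas_ppi\thas_event\n")
        for g in gold:
            fh.write(
                f"{g.doc_id}\t{int(g.has_osteo)}\t{int(g.has_ppi)}\t{int(g.has_event)}\n"
            )


def read_gold(path: str | Path) -> list[GoldRecord]:
    out: list[GoldRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("doc_id"):
            raise ValueError("gold TSV must start with a doc_id header line")
        for line in fh:
            doc_id, has_osteo, has_ppi, _has_event = line.rstrip("\n").split("\t")
            out.append(
                GoldRecord(doc_id=doc_id, has_osteo=has_osteo == "1", has_ppi=has_ppi == "1")
            )
    return out


# ------------------------------------------------------------------ statistics
@dataclass(frozen=True)
class CorpusStats:
    n_docs: int
    total_lines: int
    avg_lines: int
    total_tokens: int
    avg_tokens: int
    unique_tokens: int
    avg_token_length: int


def rounded_average(total: int, n_docs: int) -> int:
    """Integer average, half-up — the presentation used for corpus tables."""
    if n_docs < 1:
        raise ValueError("empty corpus")
    ratio = Decimal(total) / Decimal(n_docs)
    return int(ratio.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def corpus_stats(corpus: Sequence[dict[str, str]]) -> CorpusStats:
    """Descriptive statistics of a letter corpus (line/token counts, averages)."""
    if not corpus:
        raise ValueError("empty corpus")
    total_lines = 0
    total_tokens = 0
    total_token_chars = 0
    unique: set[str] = set()
    for rec in corpus:
        text = rec["text"]
        total_lines += len(text.splitlines())
        toks = tokenize(text)
        total_tokens += len(toks)
        total_token_chars += sum(len(t.surface) for t in toks)
        unique.update(t.surface for t in toks)
    n = len(corpus)
    return CorpusStats(
        n_docs=n,
        total_lines=total_lines,
        avg_lines=rounded_average(total_lines, n),
        total_tokens=total_tokens,
        avg_tokens=rounded_average(total_tokens, n),
        unique_tokens=len(unique),
        avg_token_length=rounded_average(total_token_chars, max(total_tokens, 1)),
    )
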