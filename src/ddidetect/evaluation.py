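"""Document-level evaluation against a gold standard.

Detection is scored per document for three columns — the bone condition
(osteoporosis or osteopenia), PPI medication, and their combination (the
drug-disease interaction event) — as precision, recall and F-score with
exact (Clopper-Pearson) binomial confidence intervals. Metrics with a zero
denominator are reported as an explicit undefined marker, never coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy import stats

from . import rules as rules_mod
from .graph import ConceptGraph
from .ontology import Ontology

__all__ = [
    "ConfusionMatrix",
    "GoldRecord",
    "MetricResult",
    "compute_metrics",
    "confusion",
    "evaluate_corpus",
    "exact_binomial_ci",
    "render_report",
]


@dataclass(frozen=True)
class GoldRecord:
    """Document-level truth labels; the event is the conjunction by definition."""

    doc_id: str
    has_osteo: bool
    has_ppi: bool

    @property
    def has_event(self) -> bool:
        return self.has_osteo and self.has_ppi

    def label(self, column: str) -> bool:
        return {"osteo": self.has_osteo, "ppi": self.has_ppi, "event": self.has_event}[
            column
        ]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricResult:
    """Precision/recall/F as proportions; None marks an undefined metric."""

    precision: float | None
    recall: float | None
    f_score: float | None
    precision_ci: tuple[float, float] | None
    recall_ci: tuple[float, float] | None
    ci_level: float = 0.95


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Clopper-Pearson interval for k successes in n trials.

    Beta-quantile form: low = B(alpha/2; k, n-k+1), high = B(1-alpha/2; k+1,
    n-k); the boundary cases k=0 and k=n pin the respective limit to 0 or 1.
    """
    if n < 1 or k < 0 or k > n:
        raise ValueError(f"invalid (k, n) = ({k}, {n})")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return (low, high)


def compute_metrics(cm: ConfusionMatrix, ci_level: float = 0.95) -> MetricResult:
    """Precision, recall and F with exact binomial CIs from a confusion matrix."""
    precision = recall = f_score = None
    precision_ci = recall_ci = None
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
        precision_ci = exact_binomial_ci(cm.tp, cm.tp + cm.fp, ci_level)
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
        recall_ci = exact_binomial_ci(cm.tp, cm.tp + cm.fn, ci_level)
    if precision is not None and recall is not None and (precision + recall) > 0:
        f_score = 2.0 * precision * recall / (precision + recall)
    return MetricResult(
        precision=precision,
        recall=recall,
        f_score=f_score,
        precision_ci=precision_ci,
        recall_ci=recall_ci,
        ci_level=ci_level,
    )


def confusion(
    gold: Sequence[GoldRecord], predicted: set[str], column: str = "event"
) -> ConfusionMatrix:
    """Document-level confusion counts over the full gold universe."""
    known = {g.doc_id for g in gold}
    unknown = predicted - known
    if unknown:
        raise ValueError(f"predicted doc ids absent from gold: {sorted(unknown)[:5]}")
    tp = fp = fn = tn = 0
    for g in gold:
        truth = g.label(column)
        pred = g.doc_id in predicted
        if truth and pred:
            tp += 1
        elif not truth and pred:
            fp += 1
        elif truth and not pred:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def percent(value: float | None) -> str:
    """Render a proportion on the percent scale, two decimals, half-up; 'n/a' if undefined."""
    if value is None:
        return "n/a"
    return str(
        Decimal(value * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


COLUMNS = ("osteo", "ppi", "event")
COLUMN_TITLES = {
    "osteo": "Osteoporosis/osteopenia",
    "ppi": "PPI",
    "event": "Osteoporosis/osteopenia and PPI",
}


def predicted_doc_sets(
    graphs: Iterable[ConceptGraph],
    events: Mapping[str, list],
    onto: Ontology,
    include_speculated: bool = False,
) -> dict[str, set[str]]:
    """Positive document ids per column.

    A document is condition-positive when its graph holds an eligible mention
    subsumed under the osteoporosis or osteopenia concept, drug-positive when
    one is subsumed under the PPI concept, and event-positive when a rule
    fired for it.
    """
    osteo_ids = onto.descendants(rules_mod.OSTEOPOROSIS) | onto.descendants(
        rules_mod.OSTEOPENIA
    )
    ppi_ids = onto.descendants(rules_mod.PPI)
    out: dict[str, set[str]] = {c: set() for c in COLUMNS}
    for graph in graphs:
        positives = graph.positive_concepts(include_speculated=include_speculated)
        if positives & osteo_ids:
            out["osteo"].add(graph.doc_id)
        if positives & ppi_ids:
            out["ppi"].add(graph.doc_id)
    out["event"] = {doc_id for doc_id, evs in events.items() if evs}
    return out


def evaluate_corpus(
    gold: Sequence[GoldRecord],
    graphs: Iterable[ConceptGraph],
    events: Mapping[str, list],
    onto: Ontology,
    include_speculated: bool = False,
    ci_level: float = 0.95,
) -> dict[str, tuple[ConfusionMatrix, MetricResult]]:
    """Per-column confusion matrix and metrics in the three-column layout."""
    graphs = list(graphs)
    known = {g.doc_id for g in gold}
    graph_ids = {g.doc_id for g in graphs}
    missing = graph_ids - known
    if missing:
        raise ValueError(f"annotated doc ids absent from gold: {sorted(missing)[:5]}")
    predicted = predicted_doc_sets(graphs, events, onto, include_speculated)
    report: dict[str, tuple[ConfusionMatrix, MetricResult]] = {}
    for column in COLUMNS:
        cm = confusion(gold, predicted[column], column)
        report[column] = (cm, compute_metrics(cm, ci_level))
    return report


def render_report(
    report: Mapping[str, tuple[ConfusionMatrix, MetricResult]], fmt: str = "tsv"
) -> str:
    """Render the three-column report as TSV or Markdown."""
    headers = [COLUMN_TITLES[c] for c in COLUMNS]
    rows: list[tuple[str, list[str]]] = []
    cms = [report[c][0] for c in COLUMNS]
    mets = [report[c][1] for c in COLUMNS]
    rows.append(("True positives", [str(cm.tp) for cm in cms]))
    rows.append(("False positives", [str(cm.fp) for cm in cms]))
    rows.append(("False negatives", [str(cm.fn) for cm in cms]))
    rows.append(("True negatives", [str(cm.tn) for cm in cms]))

    def with_ci(value: float | None, ci: tuple[float, float] | None) -> str:
        if value is None:
            return "n/a"
        if ci is None:
            return percent(value)
        return f"{percent(value)} ({percent(ci[0])}-{percent(ci[1])})"

    rows.append(("Recall (%)", [with_ci(m.recall, m.recall_ci) for m in mets]))
    rows.append(("Precision (%)", [with_ci(m.precision, m.precision_ci) for m in mets]))
    rows.append(("F-Score (%)", [percent(m.f_score) for m in mets]))
    if fmt == "tsv":
        lines = ["\t".join(["Metric", *headers])]
        lines += ["\t".join([name, *cells]) for name, cells in rows]
        return "\n".join(lines) + "\n"
    if fmt == "markdown":
        lines = ["| Metric | " + " | ".join(headers) + " |"]
        lines.append("|" + "---|" * (len(headers) + 1))
        lines += ["| " + " | ".join([name, *cells]) + " |" for name, cells in rows]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")
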