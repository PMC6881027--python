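"""Metrics, exact binomial confidence intervals and the three-column report."""

import random

import pytest
from scipy import stats

from ddidetect.evaluation import (
    ConfusionMatrix,
    GoldRecord,
    compute_metrics,
    confusion,
    exact_binomial_ci,
    percent,
    render_report,
)


def bisect_clopper_pearson(k, n, level=0.95, tol=1e-12):
    """Independent oracle: bisection on the binomial CDF/SF."""
    alpha = 1.0 - level

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if f(mid):
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2.0

    low = 0.0
    if k > 0:
        # largest p with P(X >= k | p) <= alpha/2
        low = bisect(lambda p: stats.binom.sf(k - 1, n, p) <= alpha / 2.0, 0.0, 1.0)
    high = 1.0
    if k < n:
        # smallest p with P(X <= k | p) <= alpha/2 -> complement search
        high = 1.0 - bisect(
            lambda q: stats.binom.cdf(k, n, 1.0 - q) <= alpha / 2.0, 0.0, 1.0
        )
    return low, high


class TestExactCI:
    def test_zero_successes_closed_form(self):
        low, high = exact_binomial_ci(0, 10, 0.95)
        assert low == 0.0
        assert high == pytest.approx(1.0 - 0.025 ** (1 / 10), abs=1e-12)

    def test_all_successes_closed_form(self):
        low, high = exact_binomial_ci(10, 10, 0.95)
        assert high == 1.0
        assert low == pytest.approx(0.025 ** (1 / 10), abs=1e-12)

    def test_matches_bisection_oracle(self):
        """Beta-quantile interval equals bisection on the binomial CDF to 1e-9."""
        rng = random.Random(123)
        for _ in range(250):
            n = rng.randint(1, 2000)
            k = rng.randint(0, n)
            low, high = exact_binomial_ci(k, n, 0.95)
            olow, ohigh = bisect_clopper_pearson(k, n, 0.95)
            assert low == pytest.approx(olow, abs=1e-9)
            assert high == pytest.approx(ohigh, abs=1e-9)

    def test_invalid_inputs(self):
        for k, n in [(-1, 5), (6, 5), (0, 0)]:
            with pytest.raises(ValueError):
                exact_binomial_ci(k, n)


class TestMetrics:
    @pytest.mark.parametrize(
        "cm, precision, recall, f_score",
        [
            ((1298, 80, 34, 570), "94.19", "97.45", "95.79"),
            ((145, 0, 3, 1834), "100.00", "97.97", "98.98"),
            ((87, 4, 3, 1888), "95.60", "96.67", "96.13"),
        ],
    )
    def test_reference_confusion_matrices(self, cm, precision, recall, f_score):
        m = compute_metrics(ConfusionMatrix(*cm))
        assert percent(m.precision) == precision
        assert percent(m.recall) == recall
        assert percent(m.f_score) == f_score

    def test_perfect_detector(self):
        m = compute_metrics(ConfusionMatrix(12, 0, 0, 88))
        assert m.precision == m.recall == m.f_score == 1.0

    def test_undefined_metrics_are_none_not_zero(self):
        m = compute_metrics(ConfusionMatrix(0, 0, 0, 50))
        assert m.precision is None and m.recall is None and m.f_score is None
        assert percent(m.precision) == "n/a"

    def test_f_is_harmonic_mean(self):
        rng = random.Random(4)
        for _ in range(100):
            cm = ConfusionMatrix(
                rng.randint(1, 500), rng.randint(0, 100), rng.randint(0, 100), 10
            )
            m = compute_metrics(cm)
            assert m.f_score == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall)
            )

    def test_ci_brackets_point_estimate(self):
        m = compute_metrics(ConfusionMatrix(87, 4, 3, 1888))
        assert m.precision_ci[0] <= m.precision <= m.precision_ci[1]
        assert m.recall_ci[0] <= m.recall <= m.recall_ci[1]


class TestConfusion:
    GOLD = [
        GoldRecord("A", True, True),
        GoldRecord("B", False, False),
    ]

    def test_true_positive(self):
        cm = confusion(self.GOLD, {"A"}, "osteo")
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 1)

    def test_false_positive_and_negative(self):
        cm = confusion(self.GOLD, {"B"}, "osteo")
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 1, 1, 0)

    def test_unknown_prediction_rejected(self):
        with pytest.raises(ValueError, match="absent from gold"):
            confusion(self.GOLD, {"Z"}, "osteo")

    def test_document_order_irrelevant(self):
        cm1 = confusion(self.GOLD, {"A"}, "event")
        cm2 = confusion(list(reversed(self.GOLD)), {"A"}, "event")
        assert cm1 == cm2


class TestReportRendering:
    def test_tsv_layout(self):
        report = {
            c: (ConfusionMatrix(5, 0, 0, 5), compute_metrics(ConfusionMatrix(5, 0, 0, 5)))
            for c in ("osteo", "ppi", "event")
        }
        text = render_report(report, "tsv")
        lines = text.strip().split("\n")
        assert lines[0].split("\t")[1] == "Osteoporosis/osteopenia"
        assert lines[1].split("\t") == ["True positives", "5", "5", "5"]
        assert "F-Score (%)" in text
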