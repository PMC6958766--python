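import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

import premirnet as pm
from premirnet.evaluation import ConfusionCounts, SpeciesReport
from premirnet.exceptions import ValidationError

from helpers import concordance_auc, metrics_bruteforce


class TestConfusion:
    def test_direct_tally(self):
        c = pm.confusion([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_all_correct_positive(self):
        c = pm.confusion([1] * 5, [1.0] * 5)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 0, 0, 0)

    def test_threshold_tie_counts_positive(self):
        c = pm.confusion([1], [0.5])
        assert c.tp == 1

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            labels = rng.integers(0, 2, n)
            scores = rng.random(n)
            assert pm.confusion(labels, scores).total == n

    def test_empty_input(self):
        with pytest.raises(ValidationError):
            pm.confusion([], [])


class TestMetrics:
    def test_chance_level_symmetry(self):
        m = pm.metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert m.mcc == 0.0
        assert m.accuracy == 0.5

    def test_hand_worked_example(self):
        m = pm.metrics(ConfusionCounts(tp=90, fn=10, tn=80, fp=20))
        assert m.sensitivity == pytest.approx(0.900, abs=1e-12)
        assert m.specificity == pytest.approx(0.800, abs=1e-12)
        assert m.accuracy == pytest.approx(0.850, abs=1e-12)
        assert m.f1 == pytest.approx(180 / 210, abs=1e-12)
        assert m.mcc == pytest.approx(7000 / math.sqrt(100 * 100 * 90 * 110), abs=1e-12)

    def test_perfect_classifier(self):
        m = pm.metrics(ConfusionCounts(tp=7, tn=9, fp=0, fn=0))
        assert (m.sensitivity, m.specificity, m.f1, m.mcc, m.accuracy) == (1, 1, 1, 1, 1)

    def test_zero_denominator_conventions(self):
        m = pm.metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m.sensitivity)  # no positives evaluated
        assert m.mcc == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            pm.metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    def test_formula_oracle_on_random_tables(self):
        """Agreement with direct formula evaluation to 1e-12; MCC bounded."""
        rng = np.random.default_rng(1)
        for _ in range(10_000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, 4))
            if tp + tn + fp + fn == 0:
                continue
            m = pm.metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            sens, spec, f1, mcc, acc = metrics_bruteforce(tp, tn, fp, fn)
            for got, want in zip(
                (m.sensitivity, m.specificity, m.f1, m.mcc, m.accuracy),
                (sens, spec, f1, mcc, acc),
            ):
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)
            assert -1.0 <= m.mcc <= 1.0

    def test_mcc_against_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            labels = rng.integers(0, 2, 40)
            preds = rng.integers(0, 2, 40)
            if len(set(labels)) < 2 or len(set(preds)) < 2:
                continue
            c = pm.confusion(labels, preds.astype(float))
            assert pm.metrics(c).mcc == pytest.approx(
                matthews_corrcoef(labels, preds), abs=1e-9
            )


class TestRocPrc:
    def test_perfect_separation(self):
        roc, prc = pm.roc_prc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert roc.auc == pytest.approx(1.0, abs=1e-12)
        assert prc.auc == pytest.approx(1.0, abs=1e-12)

    def test_partial_overlap(self):
        # 3 of 4 positive/negative pairs concordant
        roc, _ = pm.roc_prc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert roc.auc == pytest.approx(0.75, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            pm.roc_prc([1, 1], [0.5, 0.6])

    def test_roc_monotone_and_anchored(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 50)
        labels[:2] = (0, 1)
        scores = rng.random(50)
        roc, prc = pm.roc_prc(labels, scores)
        xs = [p[0] for p in roc.points]
        ys = [p[1] for p in roc.points]
        assert xs == sorted(xs) and ys == sorted(ys)
        assert roc.points[0] == (0.0, 0.0)
        assert roc.points[-1] == (1.0, 1.0)
        assert prc.points[0] == (0.0, 1.0)

    def test_auc_equals_pairwise_concordance(self):
        """Trapezoidal ROC AUC == Mann-Whitney concordance (ties half)."""
        rng = np.random.default_rng(4)
        for _ in range(300):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            # quantized scores to force ties
            scores = np.round(rng.random(n), 1)
            roc, _ = pm.roc_prc(labels, scores)
            assert roc.auc == pytest.approx(concordance_auc(labels, scores), abs=1e-12)
            assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 30)
        labels[:2] = (0, 1)
        scores = rng.random(30)
        c = pm.confusion(labels, scores)
        swapped = pm.confusion(1 - labels, 1.0 - scores + 1e-12)
        m, ms = pm.metrics(c), pm.metrics(swapped)
        assert m.sensitivity == pytest.approx(ms.specificity, abs=1e-9)
        assert abs(m.mcc) == pytest.approx(abs(ms.mcc), abs=1e-9)


class TestSummarizeCv:
    def _metrics(self, acc):
        return pm.EvalMetrics(
            sensitivity=acc, specificity=acc, f1=acc, mcc=2 * acc - 1, accuracy=acc
        )

    def test_identical_folds(self):
        s = pm.summarize_cv([self._metrics(0.9)] * 5)
        assert s.mean["accuracy"] == pytest.approx(0.9)
        assert s.se["accuracy"] == 0.0

    def test_two_point_arithmetic(self):
        s = pm.summarize_cv([self._metrics(0.8), self._metrics(0.9)])
        assert s.mean["accuracy"] == pytest.approx(0.85, abs=1e-12)
        # sample SD of (0.8, 0.9) is 0.0707...; SE = SD / sqrt(2) = 0.05
        assert s.se["accuracy"] == pytest.approx(0.05, abs=1e-12)

    def test_single_fold_rejected(self):
        with pytest.raises(ValidationError):
            pm.summarize_cv([self._metrics(0.5)])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=10))
    def test_mean_bounded_by_folds(self, accs):
        s = pm.summarize_cv([self._metrics(a) for a in accs])
        assert min(accs) - 1e-12 <= s.mean["accuracy"] <= max(accs) + 1e-12
        assert s.se["accuracy"] >= 0.0


class TestSpeciesReport:
    def test_accuracy_ratio(self):
        r = SpeciesReport(species="mmu", n=10, n_correct=9)
        assert r.accuracy_percent == pytest.approx(90.0)

    def test_row_shape(self):
        row = SpeciesReport(species="rno", n=414, n_correct=411).as_row()
        assert set(row) == {
            "species", "n_pre_mirnas", "n_correct_prediction", "accuracy_percent"
        }
        assert row["accuracy_percent"] == pytest.approx(99.28, abs=0.005)

    def test_on_trained_model(self, trained_cnn, corpus):
        clf, _ = trained_cnn
        positives = pm.DatasetTable(
            records=tuple(r for r in corpus if r.label == "positive")[:40]
        )
        report = pm.species_report(clf, positives, species="synthetic")
        assert report.n == 40
        assert 0 <= report.n_correct <= 40

    def test_empty_table(self, trained_cnn):
        clf, _ = trained_cnn
        with pytest.raises(ValidationError):
            pm.species_report(clf, pm.DatasetTable(records=()))
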