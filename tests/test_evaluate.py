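import numpy as np
import pytest

import nanobrdu as nb
from nanobrdu.pore_model import CLASS_SYMBOLS


def brute_force_confusion(truth, calls):
    counts = np.zeros((5, 5), dtype=int)
    for t, c in zip(truth, calls):
        counts[CLASS_SYMBOLS.index(t), CLASS_SYMBOLS.index(c)] += 1
    return counts


def brute_force_auprc(scores, truth):
    """Enumerate every distinct threshold; sum precision x recall steps."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    n_pos = truth.sum()
    area = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        tp = int((truth & sel).sum())
        precision = tp / int(sel.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        labels = list("ABCGT") * 3
        cm = nb.confusion(labels, labels)
        assert np.array_equal(cm.counts, np.diag([3, 3, 3, 3, 3]))

    def test_direct_count_example(self):
        cm = nb.confusion(["T", "T", "B"], ["T", "B", "B"])
        t, b = CLASS_SYMBOLS.index("T"), CLASS_SYMBOLS.index("B")
        assert cm.counts[t, t] == 1 and cm.counts[t, b] == 1 and cm.counts[b, b] == 1
        assert cm.total == 3

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(17)
        truth = rng.choice(CLASS_SYMBOLS, 500)
        calls = rng.choice(CLASS_SYMBOLS, 500)
        cm = nb.confusion(truth, calls)
        assert np.array_equal(cm.counts, brute_force_confusion(truth, calls))
        assert cm.total == 500

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            nb.confusion(["A", "X"], ["A", "A"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nb.confusion(["A"], ["A", "T"])


class TestBinaryMetrics:
    def test_perfect_case_all_ones(self):
        m = nb.binary_metrics(nb.BinaryCounts(tp=1, tn=1, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_formula_arithmetic(self):
        m = nb.binary_metrics(nb.BinaryCounts(tp=90, tn=95, fp=5, fn=10))
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.95)
        assert m["accuracy"] == pytest.approx(0.925)
        assert m["precision"] == pytest.approx(90 / 95)

    def test_undefined_precision_is_missing_not_zero(self):
        m = nb.binary_metrics(nb.BinaryCounts(tp=0, tn=5, fp=0, fn=5))
        assert m["precision"] is None
        assert m["specificity"] == 1.0

    def test_collapsed_matrix_agrees_with_direct_binary_count(self):
        rng = np.random.default_rng(3)
        truth = rng.choice(CLASS_SYMBOLS, 500)
        calls = rng.choice(CLASS_SYMBOLS, 500)
        bc = nb.binary_counts(nb.confusion(truth, calls), positive="B")
        assert bc.tp == int(((truth == "B") & (calls == "B")).sum())
        assert bc.fp == int(((truth != "B") & (calls == "B")).sum())
        assert bc.fn == int(((truth == "B") & (calls != "B")).sum())
        assert bc.tn == int(((truth != "B") & (calls != "B")).sum())
        assert bc.total == 500


class TestMulticlassSummary:
    def test_diagonal_matrix_scores_one(self):
        cm = nb.confusion(list("ABCGT"), list("ABCGT"))
        s = nb.multiclass_summary(cm)
        assert s == {"accuracy": 1.0, "precision": 1.0, "recall": 1.0}

    def test_single_class_truth_recall(self):
        cm = nb.confusion(["T", "T", "T", "T"], ["T", "T", "B", "A"])
        s = nb.multiclass_summary(cm)
        assert s["recall"] == pytest.approx(0.5)
        assert s["accuracy"] == pytest.approx(0.5)

    def test_weighted_average_matches_manual_computation(self):
        rng = np.random.default_rng(23)
        truth = rng.choice(CLASS_SYMBOLS, 500, p=[0.4, 0.1, 0.2, 0.1, 0.2])
        calls = rng.choice(CLASS_SYMBOLS, 500)
        cm = nb.confusion(truth, calls)
        s = nb.multiclass_summary(cm, average="weighted")
        # independent per-class computation then support-weighted mean
        prec_num = prec_den = rec_num = rec_den = 0.0
        for c in CLASS_SYMBOLS:
            support = int((truth == c).sum())
            predicted = int((calls == c).sum())
            tp = int(((truth == c) & (calls == c)).sum())
            if predicted > 0:
                prec_num += support * tp / predicted
                prec_den += support
            if support > 0:
                rec_num += support * tp / support
                rec_den += support
        assert s["precision"] == pytest.approx(prec_num / prec_den)
        assert s["recall"] == pytest.approx(rec_num / rec_den)
        assert s["accuracy"] == pytest.approx((truth == calls).mean())

    def test_accuracy_invariant_under_class_permutation(self):
        rng = np.random.default_rng(4)
        truth = rng.choice(CLASS_SYMBOLS, 200)
        calls = rng.choice(CLASS_SYMBOLS, 200)
        perm = dict(zip(CLASS_SYMBOLS, ["T", "G", "C", "B", "A"]))
        a = nb.multiclass_summary(nb.confusion(truth, calls))["accuracy"]
        b = nb.multiclass_summary(
            nb.confusion([perm[t] for t in truth], [perm[c] for c in calls])
        )["accuracy"]
        assert a == b

    def test_macro_option_and_empty_matrix(self):
        cm = nb.confusion(["A", "B"], ["A", "B"])
        assert nb.multiclass_summary(cm, average="macro")["precision"] == 1.0
        with pytest.raises(ValueError):
            nb.multiclass_summary(nb.ConfusionMatrix(np.zeros((5, 5), dtype=int)))


class TestAuprc:
    def test_perfect_ranking_gives_one(self):
        assert nb.auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(8)
        n = 20000
        truth = rng.random(n) < 0.3
        scores = rng.random(n)
        assert nb.auprc(scores, truth) == pytest.approx(0.3, abs=0.02)

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            scores = np.round(rng.random(6), 2)  # provoke ties
            truth = rng.integers(0, 2, 6)
            if truth.sum() in (0, 6):
                continue
            assert nb.auprc(scores, truth) == pytest.approx(
                brute_force_auprc(scores, truth), abs=1e-12
            )

    def test_matches_bruteforce_on_500_item_fixture(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=500)
        truth = rng.integers(0, 2, 500)
        assert nb.auprc(scores, truth) == pytest.approx(
            brute_force_auprc(scores, truth), abs=1e-12
        )

    def test_agrees_with_sklearn_average_precision(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(19)
        scores = rng.normal(size=300)
        truth = rng.integers(0, 2, 300)
        assert nb.auprc(scores, truth) == pytest.approx(
            sklearn_metrics.average_precision_score(truth, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(size=100)
        truth = rng.integers(0, 2, 100)
        a = nb.auprc(scores, truth)
        b = nb.auprc(np.exp(2.0 * scores) + 5, truth)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            nb.auprc([0.1, 0.2], [1, 1])
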