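"""Performance metrics: multiclass confusion, binary rates, AUPRC.

Metrics follow the standard definitions
``accuracy = (TP+TN)/(TP+TN+FP+FN)``, ``precision = TP/(TP+FP)``,
``sensitivity = recall = TP/(TP+FN)``, ``specificity = TN/(TN+FP)``,
evaluated at single-nucleotide resolution on 5-mer window calls.  The
positive class for binary summaries is BrdU (symbol ``B``).

AUPRC uses the average-precision formulation — precision summed over recall
steps at each distinct score threshold, with no linear interpolation, which
avoids the optimistic bias of trapezoidal PR areas.  Metrics with zero
denominators are reported as missing (``None``), never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pore_model import CLASS_SYMBOLS

_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_SYMBOLS)}


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 counts, rows = truth, columns = prediction, classes [A, BrdU, C, G, T]."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_SYMBOLS

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": self.counts.astype(int).tolist(),
        }


@dataclass(frozen=True)
class BinaryCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(truth, calls) -> ConfusionMatrix:
    """Tally truth/call pairs into a 5x5 matrix."""
    truth = np.asarray(truth)
    calls = np.asarray(calls)
    if truth.shape != calls.shape:
        raise ValueError("truth and calls must have equal length")
    counts = np.zeros((len(CLASS_SYMBOLS), len(CLASS_SYMBOLS)), dtype=np.int64)
    for arr in (truth, calls):
        bad = set(np.unique(arr)) - set(CLASS_SYMBOLS)
        if bad:
            raise ValueError(f"unknown class symbol(s): {sorted(bad)}")
    ti = np.vectorize(_CLASS_INDEX.__getitem__, otypes=[np.int64])(truth)
    ci = np.vectorize(_CLASS_INDEX.__getitem__, otypes=[np.int64])(calls)
    np.add.at(counts, (ti, ci), 1)
    return ConfusionMatrix(counts=counts)


def binary_counts(cm: ConfusionMatrix, positive: str = "B") -> BinaryCounts:
    """Collapse a multiclass matrix to one-vs-rest counts for `positive`."""
    i = cm.classes.index(positive)
    c = cm.counts
    tp = int(c[i, i])
    fn = int(c[i].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def binary_metrics(c: BinaryCounts) -> dict[str, float | None]:
    """Accuracy, precision, sensitivity (=recall), specificity.

    A metric whose denominator is zero is returned as ``None`` (undefined).
    """
    return {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "precision": _ratio(c.tp, c.tp + c.fp),
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
    }


def multiclass_summary(cm: ConfusionMatrix, average: str = "weighted") -> dict[str, float | None]:
    """Aggregate accuracy / precision / recall over the five classes.

    ``weighted`` (default) averages per-class one-vs-rest precision and
    recall with class support as weights; ``macro`` averages unweighted.
    Classes with undefined per-class values (zero support, or never
    predicted) are excluded from the average rather than counted as zero.
    """
    if average not in ("weighted", "macro"):
        raise ValueError("average must be 'weighted' or 'macro'")
    c = cm.counts
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    support = c.sum(axis=1)
    predicted = c.sum(axis=0)
    diag = np.diag(c)

    def _avg(values, denoms, weights):
        ok = denoms > 0
        if not ok.any():
            return None
        vals = values[ok] / denoms[ok]
        w = weights[ok]
        if w.sum() == 0:
            return None
        return float(np.average(vals, weights=w))

    weights = support.astype(float) if average == "weighted" else np.ones(len(CLASS_SYMBOLS))
    return {
        "accuracy": float(diag.sum() / total),
        "precision": _avg(diag.astype(float), predicted.astype(float), weights),
        "recall": _avg(diag.astype(float), support.astype(float), weights),
    }


def auprc(scores, truth) -> float:
    """Area under the precision-recall curve (average precision).

    `scores` are positive-class scores, `truth` binary (1 = positive).
    Computed as the sum of precision at each distinct-score threshold times
    the recall gained there (step interpolation).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    if n_pos == 0 or n_pos == truth.size:
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    tp = np.cumsum(t)
    fp = np.cumsum(~t)
    # threshold boundaries: last index of each run of equal scores
    boundary = np.append(s[1:] != s[:-1], True)
    tp_b = tp[boundary]
    fp_b = fp[boundary]
    precision = tp_b / (tp_b + fp_b)
    recall = tp_b / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))
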