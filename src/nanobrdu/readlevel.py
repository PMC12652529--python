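"""Read-level BrdU substitution rates and bimodal-mixture relabeling.

The read-level substitution rate is the fraction of a read's thymidine
candidates — windows whose center was *basecalled* T, since ground truth is
unknown on real data — that the classifier calls BrdU.  In primer-extension
preparations, molecules are a mixture of fully substituted strands and
pristine renatured plasmid, so read rates are bimodal; thresholding the rate
(strictly greater than 12.5% by default) classifies whole reads as fully
BrdU-labeled, and every thymidine-candidate window of a labeled read can then
be relabeled with BrdU truth to build positive training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .featurize import WindowSet, extract_windows

DEFAULT_THRESHOLD = 0.125
HISTOGRAM_BINS = 20


@dataclass(frozen=True)
class ReadRateRecord:
    """Per-read BrdU substitution rate: n_brdu / n_candidates."""

    read_id: str
    n_candidates: int
    n_brdu: int

    @property
    def rate(self) -> float:
        return self.n_brdu / self.n_candidates

    def __post_init__(self) -> None:
        if not 0 <= self.n_brdu <= self.n_candidates or self.n_candidates < 1:
            raise ValueError("need 0 <= n_brdu <= n_candidates with n_candidates >= 1")


@dataclass(frozen=True)
class RelabelDecision:
    read_id: str
    rate: float
    threshold: float = DEFAULT_THRESHOLD

    @property
    def labeled(self) -> bool:
        return self.rate > self.threshold


def read_substitution_rate(calls: pd.DataFrame) -> ReadRateRecord:
    """Rate for one read's thymidine-candidate calls.

    `calls` must come from windows extracted in thymidine-candidate mode
    (center basecalled T) and belong to a single read.
    """
    ids = calls["read_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"calls span {len(ids)} read_ids; expected exactly one")
    n = len(calls)
    if n == 0:
        raise ValueError("no candidate calls for this read")
    return ReadRateRecord(read_id=ids[0], n_candidates=n, n_brdu=int((calls["call"] == "B").sum()))


def read_rates(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-read rates for a multi-read call table.

    Returns columns ``read_id, n_candidates, n_brdu, rate``.  Reads with zero
    candidate windows simply do not appear (they are skipped upstream, not
    assigned rate 0, which would deflate mixture histograms).
    """
    grouped = calls.groupby("read_id", sort=False)
    out = grouped.agg(
        n_candidates=("call", "size"),
        n_brdu=("call", lambda c: int((c == "B").sum())),
    ).reset_index()
    out["rate"] = out["n_brdu"] / out["n_candidates"]
    return out


def classify_reads(rates: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Mark reads with rate strictly greater than `threshold` as fully labeled."""
    if (rates["rate"] < 0).any() or (rates["rate"] > 1).any():
        raise ValueError("rates must lie in [0, 1]")
    out = rates.copy()
    out["labeled"] = out["rate"] > threshold
    return out


def rate_histogram(rates, bins: int = HISTOGRAM_BINS):
    """Equal-width histogram of read rates on [0, 1] for bimodality inspection."""
    return np.histogram(np.asarray(rates, dtype=float), bins=bins, range=(0.0, 1.0))


def bootstrap_relabel(
    model,
    events: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[WindowSet, pd.DataFrame]:
    """Build BrdU-positive training windows from a candidate-positive dataset.

    Featurizes `events` in thymidine-candidate mode, predicts with `model`
    (a :class:`~nanobrdu.model.TrainedModel` or any object/callable exposing
    window-level calls), estimates per-read substitution rates, and keeps the
    windows of reads judged fully labeled — relabeled with BrdU truth.  Reads
    judged unlabeled are dropped from the positive set.

    Returns ``(relabeled_windows, rates)`` where `rates` carries the per-read
    decision (``labeled`` column) for mixture inspection.
    """
    predict_fn = _as_predict_fn(model)
    windows = extract_windows(events, mode="t")
    if len(windows) == 0:
        warnings.warn("no thymidine-candidate windows in input; nothing to relabel")
        return windows, pd.DataFrame(columns=["read_id", "n_candidates", "n_brdu", "rate", "labeled"])
    calls = predict_fn(windows)
    rates = classify_reads(read_rates(calls), threshold=threshold)
    labeled_ids = set(rates.loc[rates["labeled"], "read_id"])
    if not labeled_ids:
        warnings.warn("no read exceeded the relabeling threshold; emitting no positive windows")
        return windows.subset(np.zeros(len(windows), dtype=bool)), rates
    keep = np.fromiter((r in labeled_ids for r in windows.read_ids), dtype=bool, count=len(windows))
    return windows.subset(keep).with_truth("B"), rates


def _as_predict_fn(model) -> Callable[[WindowSet], pd.DataFrame]:
    if callable(model) and not hasattr(model, "network"):
        return model
    from .model import predict  # local import to avoid a cycle

    return lambda ws: predict(model, ws)
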