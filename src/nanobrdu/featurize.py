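"""Feature and label engineering for 5-mer event windows.

Each event becomes a seven-dimensional vector
``[f_m, f_d, f_l, f_A, f_C, f_G, f_T]`` — normalized current mean, standard
deviation, dwell, and the one-hot basecalled identity of that event.  A
training unit is the 5 x 7 matrix of the five consecutive events centered on
one position, labeled (when ground truth exists) by the one-hot true base at
the center over the five classes [A, BrdU, C, G, T].

Two extraction modes mirror the two labeling regimes of real data:
``all`` keeps every interior position (5-class truth available, as with
synthetic reference standards), while ``t`` keeps only windows whose center
was basecalled T — the thymidine candidates, which is all a basecaller can
offer on genomic data where BrdU masquerades as T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .pore_model import CANONICAL_BASES, CLASS_SYMBOLS, KMER_LEN
from .simulate import EVENT_COLUMNS, EventRecord

FEATURE_DIM = 7
N_CLASSES = 5
_FLANK = KMER_LEN // 2

_CALLED_INDEX = {b: i for i, b in enumerate(CANONICAL_BASES)}
_CLASS_INDEX = {b: i for i, b in enumerate(CLASS_SYMBOLS)}


@dataclass
class WindowSet:
    """A batch of 5-mer feature windows.

    Attributes
    ----------
    X
        ``(n, 5, 7)`` feature matrices, rows ordered by position offset -2..+2.
    truth
        ``(n,)`` true center-base symbols over ``A,B,C,G,T``; ``.`` = unknown.
    read_ids, center_pos
        Window provenance (0-based center position along the read).
    """

    X: np.ndarray
    truth: np.ndarray
    read_ids: np.ndarray
    center_pos: np.ndarray

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def y(self) -> np.ndarray:
        """One-hot ``(n, 5)`` labels in class order [A, BrdU, C, G, T].

        Rows with unknown truth are NaN; training rejects those.
        """
        y = np.full((len(self), N_CLASSES), np.nan)
        for sym, j in _CLASS_INDEX.items():
            mask = self.truth == sym
            y[mask] = 0.0
            y[mask, j] = 1.0
        return y

    @property
    def labels_known(self) -> np.ndarray:
        return self.truth != "."

    def subset(self, idx) -> "WindowSet":
        return WindowSet(self.X[idx], self.truth[idx], self.read_ids[idx], self.center_pos[idx])

    def with_truth(self, symbol: str) -> "WindowSet":
        """Copy with every window's truth overwritten (used by relabeling)."""
        if symbol not in _CLASS_INDEX:
            raise ValueError(f"unknown class symbol {symbol!r}")
        return WindowSet(self.X, np.full(len(self), symbol, dtype=self.truth.dtype),
                         self.read_ids, self.center_pos)

    @staticmethod
    def concat(parts: Sequence["WindowSet"]) -> "WindowSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return _empty_windowset()
        return WindowSet(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.truth for p in parts]),
            np.concatenate([p.read_ids for p in parts]),
            np.concatenate([p.center_pos for p in parts]),
        )


def _empty_windowset() -> WindowSet:
    return WindowSet(
        np.empty((0, KMER_LEN, FEATURE_DIM)),
        np.empty(0, dtype="<U1"),
        np.empty(0, dtype=object),
        np.empty(0, dtype=np.int64),
    )


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    mapq: int
    aligned_len: int
    sam_flag: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 60:
            raise ValueError("mapq must be in [0, 60]")


@dataclass(frozen=True)
class SplitSpec:
    """Deterministic 0.80 / 0.10 / 0.10 train/validation/test split."""

    fractions: tuple[float, float, float] = (0.80, 0.10, 0.10)
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


#: (min_mapq, min_len) presets: synthetic 5-mer standards vs genomic reads.
FILTER_PRESETS = {"standards": (20, 270), "genomic": (60, 500)}


def normalize_read_signal(raw_means: np.ndarray) -> np.ndarray:
    """Median-shift, MAD-scale a read's raw event means.

    ``out = (raw - median) / (MAD * 1.4826)``; falls back to standard
    deviation scaling when the MAD is zero, and refuses constant input.
    Only needed when a table carries un-normalized means — resquiggling (and
    the simulator) already emit per-read normalized signal.
    """
    x = np.asarray(raw_means, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 events to normalize a read")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = mad * 1.4826
    if scale == 0:
        scale = x.std()
        if scale == 0:
            raise ValueError("cannot normalize a constant signal (zero spread)")
    return (x - med) / scale


def encode_event(e: EventRecord) -> np.ndarray:
    """Seven-dimensional feature vector ``[f_m, f_d, f_l, f_A, f_C, f_G, f_T]``."""
    if e.base_called not in _CALLED_INDEX:
        raise ValueError(f"base_called must be one of A,C,G,T, got {e.base_called!r}")
    v = np.zeros(FEATURE_DIM)
    v[0], v[1], v[2] = e.norm_mean, e.norm_sd, e.dwell
    v[3 + _CALLED_INDEX[e.base_called]] = 1.0
    return v


def _read_feature_matrix(read: pd.DataFrame, log_dwell: bool) -> np.ndarray:
    L = len(read)
    F = np.zeros((L, FEATURE_DIM))
    F[:, 0] = read["norm_mean"].to_numpy(dtype=float)
    F[:, 1] = read["norm_sd"].to_numpy(dtype=float)
    dwell = read["dwell"].to_numpy(dtype=float)
    F[:, 2] = np.log1p(dwell) if log_dwell else dwell
    called = read["base_called"].to_numpy()
    for b, i in _CALLED_INDEX.items():
        F[called == b, 3 + i] = 1.0
    return F


def extract_windows(
    events: pd.DataFrame,
    mode: Literal["all", "t"] = "all",
    log_dwell: bool = False,
) -> WindowSet:
    """Slide a 5-event window over each read of an event table.

    A read of L events yields L - 4 windows (mode ``all``); mode ``t`` keeps
    the subset whose center event was basecalled T.  Events must be
    contiguous in ``pos`` within each read; reads shorter than 5 events yield
    nothing (with a warning), mirroring the upstream length filters.
    """
    if mode not in ("all", "t"):
        raise ValueError(f"mode must be 'all' or 't', got {mode!r}")
    parts: list[WindowSet] = []
    for read_id, read in events.groupby("read_id", sort=False):
        read = read.sort_values("pos")
        pos = read["pos"].to_numpy()
        L = len(read)
        if L < KMER_LEN:
            warnings.warn(f"read {read_id}: only {L} events, no windows emitted", stacklevel=2)
            continue
        if not np.array_equal(np.diff(pos), np.ones(L - 1, dtype=pos.dtype)):
            raise ValueError(f"read {read_id}: events are not contiguous in pos")
        F = _read_feature_matrix(read, log_dwell)
        X = np.lib.stride_tricks.sliding_window_view(F, KMER_LEN, axis=0)
        X = np.ascontiguousarray(np.swapaxes(X, 1, 2))  # (L-4, 5, 7)
        centers = slice(_FLANK, L - _FLANK)
        truth = read["true_base"].to_numpy(dtype="<U1")[centers]
        ws = WindowSet(
            X=X,
            truth=truth,
            read_ids=np.full(L - 2 * _FLANK, read_id, dtype=object),
            center_pos=pos[centers].astype(np.int64),
        )
        if mode == "t":
            keep = read["base_called"].to_numpy()[centers] == "T"
            ws = ws.subset(keep)
        parts.append(ws)
    return WindowSet.concat(parts)


def filter_alignments(
    records: Iterable[AlignmentRecord] | pd.DataFrame,
    min_mapq: int = 20,
    min_len: int = 270,
    require_flag_zero: bool = False,
):
    """Keep alignments with ``mapq >= min_mapq`` and ``aligned_len >= min_len``.

    ``require_flag_zero`` additionally demands SAM flag 0 (primary forward
    alignment), the rule used to pick the correct strand of 2D
    primer-extension reads.  Presets: :data:`FILTER_PRESETS`.
    """
    if isinstance(records, pd.DataFrame):
        keep = (records["mapq"] >= min_mapq) & (records["aligned_len"] >= min_len)
        if require_flag_zero:
            keep &= records["sam_flag"] == 0
        return records[keep]
    return [
        r
        for r in records
        if r.mapq >= min_mapq
        and r.aligned_len >= min_len
        and (not require_flag_zero or r.sam_flag == 0)
    ]


def split_dataset(windows: WindowSet, spec: SplitSpec = SplitSpec()):
    """Shuffle deterministically and split into (train, validation, test).

    Sizes are ``floor(f_train * n)`` / ``floor(f_val * n)`` / remainder — an
    exact partition with no overlap.
    """
    n = len(windows)
    if n < 10:
        raise ValueError(f"need at least 10 windows to split, got {n}")
    rng = np.random.default_rng(spec.shuffle_seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(spec.fractions[0] * n))
    n_val = int(np.floor(spec.fractions[1] * n))
    return (
        windows.subset(perm[:n_train]),
        windows.subset(perm[n_train : n_train + n_val]),
        windows.subset(perm[n_train + n_val :]),
    )


# ---------------------------------------------------------------------------
# window TSV round trip

_FEATURE_COLS = [f"x{i:02d}" for i in range(KMER_LEN * FEATURE_DIM)]
_LABEL_COLS = ["y_A", "y_BrdU", "y_C", "y_G", "y_T"]


def write_windows(windows: WindowSet, path) -> None:
    """One TSV row per window: read_id, center_pos, 35 features, 5 label floats.

    Label cells are blank for windows without ground truth.
    """
    df = pd.DataFrame(
        windows.X.reshape(len(windows), KMER_LEN * FEATURE_DIM), columns=_FEATURE_COLS
    )
    df.insert(0, "read_id", windows.read_ids)
    df.insert(1, "center_pos", windows.center_pos)
    y = windows.y
    for j, c in enumerate(_LABEL_COLS):
        df[c] = y[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_windows(path) -> WindowSet:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    X = df[_FEATURE_COLS].to_numpy(dtype=float).reshape(-1, KMER_LEN, FEATURE_DIM)
    y = df[_LABEL_COLS].to_numpy(dtype=float)
    truth = np.full(len(df), ".", dtype="<U1")
    known = ~np.isnan(y).any(axis=1)
    if known.any():
        sym = np.array(CLASS_SYMBOLS)
        truth[known] = sym[np.argmax(y[known], axis=1)]
    return WindowSet(
        X=X,
        truth=truth,
        read_ids=df["read_id"].to_numpy(dtype=object),
        center_pos=df["center_pos"].to_numpy(dtype=np.int64),
    )
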