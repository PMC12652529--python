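"""Event-level simulation of R9 nanopore reads with BrdU substitution.

The simulator emulates what Tombo resquiggling produces from real FAST5 data:
one *event* per read position, summarized by the normalized current mean
(``norm_mean``), its standard deviation (``norm_sd``) and the dwell (number of
raw current samples).  A standard basecaller cannot name BrdU, so every B in
the true sequence is basecalled as T; the ground-truth base is carried
alongside for supervised training and evaluation.

Reads are generated under a two-level labeling scheme that mirrors the designs
of real BrdU experiments: a read is *labeled* with probability
``labeled_fraction`` (creating bimodal mixtures of substituted and pristine
molecules, as arises from renatured plasmid DNA in primer-extension
preparations), and within a labeled read each T becomes B independently with
probability ``substitution_rate``.

Event tables are plain TSV with the columns
``read_id, pos, base_called, true_base, norm_mean, norm_sd, dwell``;
``true_base`` is ``.`` when unknown (real data without ground truth).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .pore_model import ALPHABET, KMER_LEN, PoreModel

EVENT_COLUMNS = ("read_id", "pos", "base_called", "true_base", "norm_mean", "norm_sd", "dwell")

_CALLED_OK = frozenset("ACGT")
_TRUE_OK = frozenset("ACGTB.")


@dataclass(frozen=True)
class EventRecord:
    """One resquiggled event: a single base position of a single read."""

    read_id: str
    pos: int
    base_called: str
    true_base: str
    norm_mean: float
    norm_sd: float
    dwell: int


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated sequencing run.

    Parameters
    ----------
    n_reads, read_length
        Number of reads and events per read (``read_length >= 5``).
    substitution_rate
        Probability that each T position of a *labeled* read is replaced by
        BrdU.
    noise_sd
        Event-to-event noise around the pore-model level, in normalized
        current units.  0.3 is a realistic spread for Tombo-normalized R9
        events.
    dwell_mean
        Mean dwell in raw samples; dwells follow ``1 + Poisson(dwell_mean-1)``.
    labeled_fraction
        Fraction of reads that receive substitutions at all.
    basecall_error_rate
        Optional uniform miscall rate of the emulated basecaller (off by
        default: read-level MAPQ filtering keeps residual error low in the
        real pipeline).
    template
        Optional sequence template over ``{A,C,G,T,N}`` tiled to
        ``read_length``; ``N`` positions are drawn uniformly.  ``None`` (the
        default) draws every position uniformly.  Templates emulate designs
        such as synthetic 5-mer reference standards, where variable 5-mers are
        embedded in fixed linker/barcode context.
    """

    n_reads: int = 100
    read_length: int = 300
    substitution_rate: float = 0.5
    noise_sd: float = 0.3
    dwell_mean: float = 8.0
    labeled_fraction: float = 1.0
    seed: int = 0
    basecall_error_rate: float = 0.0
    template: str | None = None
    read_prefix: str = "read"

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "labeled_fraction", "basecall_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < KMER_LEN:
            raise ValueError(f"read_length must be >= {KMER_LEN}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        if self.template is not None and not set(self.template) <= set("ACGTN"):
            raise ValueError("template may only contain A, C, G, T, N")


def simulate_reads(model: PoreModel, config: SimConfig) -> pd.DataFrame:
    """Simulate an event table; one row per event, columns :data:`EVENT_COLUMNS`.

    Every event's ``norm_mean`` is drawn around the pore-model level of the
    true 5-mer centered at its position (reads are padded with A at both ends
    so edge positions still emit events); ``base_called`` is the true base
    with B reported as T.  Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.n_reads, config.read_length

    if config.template is None:
        seq = rng.integers(0, 4, size=(n, L))
    else:
        tiled = (config.template * (L // len(config.template) + 1))[:L]
        base = np.array([("ACGTN".index(c)) for c in tiled], dtype=np.int64)
        seq = np.tile(base, (n, 1))
        n_mask = seq == 4
        seq[n_mask] = rng.integers(0, 4, size=int(n_mask.sum()))

    labeled = rng.random(n) < config.labeled_fraction
    sub_draw = rng.random((n, L)) < config.substitution_rate
    true_seq = np.where((seq == 3) & labeled[:, None] & sub_draw, 4, seq)

    # 5-mer code centered at each position; edges padded with A (code 0).
    padded = np.zeros((n, L + KMER_LEN - 1), dtype=np.int64)
    padded[:, 2 : 2 + L] = true_seq
    codes = np.zeros((n, L), dtype=np.int64)
    for i in range(KMER_LEN):
        codes = codes * 5 + padded[:, i : i + L]

    level_mean = model.mean[codes]
    level_sd = model.sd[codes]
    norm_mean = level_mean + rng.normal(0.0, config.noise_sd, size=(n, L))
    norm_sd = np.abs(rng.normal(level_sd, level_sd / 4.0))
    dwell = 1 + rng.poisson(config.dwell_mean - 1.0, size=(n, L))

    called = np.where(true_seq == 4, 3, true_seq)  # B basecalled as T
    if config.basecall_error_rate > 0:
        err = rng.random((n, L)) < config.basecall_error_rate
        shift = rng.integers(1, 4, size=(n, L))
        called = np.where(err, (called + shift) % 4, called)

    width = max(5, len(str(n - 1)))
    read_ids = np.array([f"{config.read_prefix}_{i:0{width}d}" for i in range(n)], dtype=object)
    alphabet = np.array(list(ALPHABET))
    df = pd.DataFrame(
        {
            "read_id": np.repeat(read_ids, L),
            "pos": np.tile(np.arange(L), n),
            "base_called": alphabet[called.ravel()],
            "true_base": alphabet[true_seq.ravel()],
            "norm_mean": norm_mean.ravel(),
            "norm_sd": norm_sd.ravel(),
            "dwell": dwell.ravel(),
        }
    )
    return df


def iter_records(events: pd.DataFrame) -> Iterator[EventRecord]:
    """View an event table as a stream of :class:`EventRecord`."""
    for row in events.itertuples(index=False):
        yield EventRecord(
            read_id=row.read_id,
            pos=int(row.pos),
            base_called=row.base_called,
            true_base=row.true_base,
            norm_mean=float(row.norm_mean),
            norm_sd=float(row.norm_sd),
            dwell=int(row.dwell),
        )


def _validate_events(events: pd.DataFrame, *, line_offset: int = 0) -> None:
    """Raise ValueError naming the offending table line (1-based, after header)."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")

    def _first_bad(mask: np.ndarray, what: str) -> None:
        if mask.any():
            idx = int(np.flatnonzero(mask)[0])
            raise ValueError(f"line {idx + 2 + line_offset}: {what}")

    _first_bad(~events["base_called"].isin(list(_CALLED_OK)).to_numpy(),
               "base_called must be one of A, C, G, T (a standard basecaller never reports B)")
    _first_bad(~events["true_base"].isin(list(_TRUE_OK)).to_numpy(),
               "true_base must be one of A, C, G, T, B or '.'")
    _first_bad(((events["true_base"] == "B") & (events["base_called"] != "T")).to_numpy(),
               "a true B must be basecalled as T")
    for col in ("pos", "norm_mean", "norm_sd", "dwell"):
        _first_bad(pd.to_numeric(events[col], errors="coerce").isna().to_numpy(),
                   f"non-numeric value in column {col}")
    _first_bad((pd.to_numeric(events["norm_sd"]) < 0).to_numpy(), "norm_sd must be >= 0")
    _first_bad((pd.to_numeric(events["dwell"]) < 1).to_numpy(), "dwell must be >= 1")


def write_event_table(events: pd.DataFrame, path) -> None:
    """Write a validated event table as UTF-8 TSV (floats at full precision)."""
    _validate_events(events)
    events.to_csv(path, sep="\t", index=False, columns=list(EVENT_COLUMNS))


def read_event_table(path) -> pd.DataFrame:
    """Read and validate an event table TSV; errors name the offending line."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"read_id": str, "base_called": str, "true_base": str},
        keep_default_na=False,
        na_values=[],
    )
    _validate_events(df)
    return df.assign(
        pos=pd.to_numeric(df["pos"]).astype(np.int64),
        norm_mean=pd.to_numeric(df["norm_mean"]).astype(float),
        norm_sd=pd.to_numeric(df["norm_sd"]).astype(float),
        dwell=pd.to_numeric(df["dwell"]).astype(np.int64),
    )


def event_table_text(events: pd.DataFrame) -> str:
    """Serialize an event table to its TSV text (for byte-identity checks)."""
    buf = io.StringIO()
    write_event_table(events, buf)
    return buf.getvalue()
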