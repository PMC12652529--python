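"""Synthetic 5-mer pore model for R9-style nanopore signal simulation.

The ionic current measured while DNA transits an R9 nanopore is determined by
the five bases occupying the pore at once (a 5-mer).  A pore model is the
lookup table from each 5-mer to the expected normalized current level and its
spread.  Here the alphabet is {A, C, G, T, B}, where ``B`` is the textual
symbol for BrdU (5-bromo-2'-deoxyuridine), a thymidine analog incorporated
into nascent DNA during replication.  BrdU perturbs the current level of every
5-mer that contains it; the perturbation is strongest when BrdU sits at the
center of the pore.

Real R9 pore models are tabulated from training data.  This module builds a
random-but-reproducible table instead: canonical (B-free) 5-mer levels are
drawn once from a standard normal, and each B-containing 5-mer inherits the
level of its B->T homolog plus a position-weighted displacement
``delta * sum(w[i] for i with B)`` with center weight 1.0 and flank weight
0.25.  This preserves the structure of the learning problem — context
dependence, a class-conditional shift concentrated on the middle base —
without shipping a proprietary level table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

#: Canonical DNA bases, in the fixed alphabetical order used for one-hot encoding.
CANONICAL_BASES = "ACGT"

#: Full simulation alphabet; ``B`` denotes BrdU and is encoded as digit 4.
ALPHABET = "ACGTB"

#: Label/class symbols in model output order [A, BrdU, C, G, T].
CLASS_SYMBOLS = ("A", "B", "C", "G", "T")

KMER_LEN = 5

#: BrdU displacement weight per 5-mer position (center strongest).
POSITION_WEIGHTS = (0.25, 0.25, 1.0, 0.25, 0.25)

_BASE_CODE = {b: i for i, b in enumerate(ALPHABET)}


def kmer_to_code(kmer: str) -> int:
    """Base-5 integer code of a 5-mer over the {A,C,G,T,B} alphabet."""
    if len(kmer) != KMER_LEN:
        raise ValueError(f"expected a {KMER_LEN}-mer, got {kmer!r}")
    code = 0
    for b in kmer:
        try:
            code = code * 5 + _BASE_CODE[b]
        except KeyError:
            raise ValueError(f"unknown base {b!r} in k-mer {kmer!r}") from None
    return code


def code_to_kmer(code: int) -> str:
    digits = []
    for _ in range(KMER_LEN):
        digits.append(ALPHABET[code % 5])
        code //= 5
    return "".join(reversed(digits))


def enumerate_kmers(alphabet: str = ALPHABET, k: int = KMER_LEN) -> list[str]:
    """All k-mers over `alphabet` in lexicographic (alphabet-order) sequence."""
    kmers = [""]
    for _ in range(k):
        kmers = [p + b for p in kmers for b in alphabet]
    return kmers


@dataclass(frozen=True)
class PoreModel:
    """Map from 5-mer to expected normalized current level and spread.

    ``mean`` and ``sd`` are arrays of length 5**5 = 3125 indexed by
    :func:`kmer_to_code`; :attr:`levels` exposes the same table as a plain
    ``{kmer: (level_mean, level_sd)}`` mapping.
    """

    mean: np.ndarray
    sd: np.ndarray
    shift_magnitude: float
    seed: int
    kmer_len: int = KMER_LEN

    def __post_init__(self) -> None:
        n = 5**self.kmer_len
        if self.mean.shape != (n,) or self.sd.shape != (n,):
            raise ValueError(f"level tables must have exactly {n} entries")
        if np.any(self.sd <= 0):
            raise ValueError("level spreads must be positive")

    @cached_property
    def levels(self) -> dict[str, tuple[float, float]]:
        return {
            code_to_kmer(c): (float(self.mean[c]), float(self.sd[c]))
            for c in range(5**self.kmer_len)
        }

    def level(self, kmer: str) -> tuple[float, float]:
        c = kmer_to_code(kmer)
        return float(self.mean[c]), float(self.sd[c])


def build_pore_model(seed: int = 0, shift_magnitude: float = 1.5) -> PoreModel:
    """Construct a reproducible synthetic 5-mer pore model.

    Parameters
    ----------
    seed
        Seeds the canonical level table; the same seed always yields the same
        model.
    shift_magnitude
        BrdU-induced displacement ``delta`` in normalized current units,
        applied per B position with weights :data:`POSITION_WEIGHTS`.  Must be
        non-negative; with ``delta = 0`` every B-containing 5-mer is exactly
        indistinguishable from its B->T homolog (level and spread).
    """
    if shift_magnitude < 0:
        raise ValueError("shift_magnitude must be non-negative")

    rng = np.random.default_rng(seed)
    n_canonical = 4**KMER_LEN
    canon_mean = rng.standard_normal(n_canonical)
    canon_sd = rng.uniform(0.05, 0.15, n_canonical)

    codes = np.arange(5**KMER_LEN)
    # digits[:, i] is the base-5 digit at k-mer position i (0 = leftmost).
    digits = np.empty((codes.size, KMER_LEN), dtype=np.int64)
    rest = codes.copy()
    for i in range(KMER_LEN - 1, -1, -1):
        digits[:, i] = rest % 5
        rest //= 5

    is_b = digits == 4
    homolog_digits = np.where(is_b, 3, digits)  # B -> T
    # index of the homolog in the canonical (base-4 lexicographic) table
    canon_idx = np.zeros(codes.size, dtype=np.int64)
    for i in range(KMER_LEN):
        canon_idx = canon_idx * 4 + homolog_digits[:, i]

    weights = np.asarray(POSITION_WEIGHTS)
    mean = canon_mean[canon_idx] + shift_magnitude * (is_b * weights).sum(axis=1)
    sd = canon_sd[canon_idx]
    return PoreModel(mean=mean, sd=sd, shift_magnitude=float(shift_magnitude), seed=seed)
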