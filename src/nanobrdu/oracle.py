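"""Signal-threshold reference classifier built directly on a pore model.

With the simulator's pore model in hand, a window's center base can be
classified without any learning: reconstruct the basecalled 5-mer from the
window's one-hot rows (BrdU is invisible to the basecaller, so the candidate
k-mer is all-canonical), look up the expected level of that k-mer and of its
center-T -> center-B variant, and call whichever hypothesis lies closer to
the observed center mean.  This is the independent yardstick used for rate
calibration and mixture-recovery checks — never a stand-in for the trained
network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .featurize import WindowSet
from .pore_model import CANONICAL_BASES, KMER_LEN, PoreModel, kmer_to_code


class OracleWindowClassifier:
    """Nearest-expected-level T-vs-BrdU decision for thymidine-candidate windows.

    Windows whose center was not basecalled T are simply called as their
    basecalled base.  ``flip_rate`` optionally corrupts a deterministic,
    seeded fraction of T/B decisions — useful for studying downstream
    behavior under a weaker (but still better-than-0.9 accurate) classifier.
    """

    def __init__(self, pore_model: PoreModel, score_scale: float = 0.3,
                 flip_rate: float = 0.0, seed: int = 0):
        self.pore_model = pore_model
        self.score_scale = score_scale
        self.flip_rate = flip_rate
        self.seed = seed

    def __call__(self, windows: WindowSet) -> pd.DataFrame:
        return self.predict(windows)

    def predict(self, windows: WindowSet) -> pd.DataFrame:
        n = len(windows)
        X = windows.X
        base_idx = X[:, :, 3:].argmax(axis=2)  # (n, 5) indices into ACGT
        bases = np.array(list(CANONICAL_BASES))[base_idx]
        obs = X[:, KMER_LEN // 2, 0]

        calls = np.empty(n, dtype="<U1")
        p_brdu = np.zeros(n)
        center_t = bases[:, 2] == "T"
        for i in range(n):
            if not center_t[i]:
                calls[i] = bases[i, 2]
                continue
            kmer = "".join(bases[i])
            level_t = self.pore_model.mean[kmer_to_code(kmer)]
            level_b = self.pore_model.mean[kmer_to_code(kmer[:2] + "B" + kmer[3:])]
            margin = abs(obs[i] - level_t) - abs(obs[i] - level_b)
            p_brdu[i] = 1.0 / (1.0 + np.exp(-margin / self.score_scale))
            calls[i] = "B" if margin > 0 else "T"
        if self.flip_rate > 0:
            rng = np.random.default_rng(self.seed)
            flip = (rng.random(n) < self.flip_rate) & center_t
            flipped = np.where(calls == "B", "T", "B")
            calls = np.where(flip, flipped, calls)
            p_brdu = np.where(flip, 1.0 - p_brdu, p_brdu)

        p_t = np.where(center_t, 1.0 - p_brdu, 0.0)
        out = pd.DataFrame(
            {
                "read_id": windows.read_ids,
                "center_pos": windows.center_pos,
                "call": calls,
                "p_A": np.where(bases[:, 2] == "A", 1.0, 0.0),
                "p_BrdU": p_brdu,
                "p_C": np.where(bases[:, 2] == "C", 1.0, 0.0),
                "p_G": np.where(bases[:, 2] == "G", 1.0, 0.0),
                "p_T": p_t,
            }
        )
        return out
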