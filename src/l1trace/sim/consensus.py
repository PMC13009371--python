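"""Synthetic L1 consensus sequence.

A deterministic ~6-kb stand-in for the L1HS consensus, generated from a
fixed seed rather than shipped as a copyrighted/real sequence: all
detection code in this package is sequence-agnostic, so the simulator only
needs a consensus with the right structural features — full length inside
the 5700–6700 bp source-element band, a canonical internal polyadenylation
signal (AATAAA) inside the final 50 bp, and CpG dinucleotides in the 5'
promoter region for the methylation generator.  SYNTHETIC: this is not the
biological L1HS consensus.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["synthetic_l1_consensus", "L1_CONSENSUS_LENGTH"]

L1_CONSENSUS_LENGTH = 6019
_CONSENSUS_SEED = 714025  # fixed: the consensus is part of the study conditions


@lru_cache(maxsize=1)
def synthetic_l1_consensus(length: int = L1_CONSENSUS_LENGTH) -> str:
    """Deterministic synthetic consensus with an internal PAS at −26 bp."""
    rng = np.random.default_rng(_CONSENSUS_SEED)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length))
    # CpG-rich 5' promoter region: force a CG every ~12 bp in the first 150 bp
    for pos in range(4, 148, 12):
        seq[pos], seq[pos + 1] = "C", "G"
    # canonical internal PAS inside the final 50 bp
    pas_start = length - 26
    seq[pas_start: pas_start + 6] = list("AATAAA")
    # keep the rest of the tail PAS-free so the internal signal is unique
    s = "".join(seq)
    tail = s[-50:]
    for variant in ("AATAAA", "ATTAAA"):
        idx = tail.find(variant)
        while idx != -1 and (len(s) - 50 + idx) != pas_start:
            absolute = len(s) - 50 + idx
            s = s[:absolute] + "C" + s[absolute + 1:]
            tail = s[-50:]
            idx = tail.find(variant)
    return s
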