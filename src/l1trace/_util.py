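"""Small sequence and interval helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: base -> small integer code used by vectorized scans (N and others -> 4)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def single_linkage_1d(positions: list[int], gap: int) -> list[list[int]]:
    """Group sorted-or-not 1-D positions; indices whose sorted neighbours are
    within ``gap`` share a group.  Returns groups of the original values."""
    if not positions:
        return []
    pos = sorted(positions)
    groups: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - groups[-1][-1] <= gap:
            groups[-1].append(p)
        else:
            groups.append([p])
    return groups
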