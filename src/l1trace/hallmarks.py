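"""Retrotransposition hallmark scoring primitives.

Target-primed reverse transcription (TPRT) leaves three hallmarks at an L1
insertion site: a target-site duplication (TSD) between the two junction
breakpoints, a polyA tail, and an endonuclease (EN) nick at the degenerate
consensus TTTT/AA.  This module holds the shared scoring primitives:

* :func:`polya_sweep` — sweep-line homopolymer scoring (+1 match, −3
  mismatch, running sum floored at zero); a tract is *present* when the best
  window score reaches the detection limit (default 10).
* :func:`en_score` — position-weighted match to TTTT/AA with weights
  (1, 1, 3, 4, 1, 1); score ≥ 6 marks an EN cut site.
* :func:`tsd_from_breakpoints` — signed breakpoint distance (positive =
  duplication, negative = target-site deletion, 0 = blunt).
* :func:`extract_en_flank` — asymmetric 4-up/2-down flank around the initial
  breakpoint, read in insertion orientation.
* :func:`orientation_from_polya` — insertion orientation from the tail base
  (A tract → '+', T tract → '−').
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp
from .params import PipelineParams

__all__ = [
    "HallmarkAnnotation", "polya_sweep", "en_score", "extract_en_flank",
    "tsd_from_breakpoints", "orientation_from_polya",
]


@dataclass
class HallmarkAnnotation:
    """Per-event hallmark annotation; fields are None when undeterminable."""

    breakpoint_a: int | None = None  # 5'-most junction, 0-based reference
    breakpoint_b: int | None = None  # 3'-most junction
    tsd_length: int | None = None    # signed; >0 duplication, <0 deletion
    polya_present: bool = False
    polya_best_score: int = 0
    polya_base: str | None = None    # 'A' or 'T'
    en_flank: str | None = None
    en_score: int | None = None
    en_cut_site: bool = False
    orientation: str = "unknown"     # '+', '-', 'unknown'

    @property
    def hallmark_count(self) -> int:
        n = 0
        if self.tsd_length is not None and self.tsd_length > 0:
            n += 1
        if self.polya_present:
            n += 1
        if self.en_cut_site:
            n += 1
        return n


def polya_sweep(
    seq: str, base: str = "A", params: PipelineParams | None = None,
) -> tuple[int, bool, tuple[int, int] | None]:
    """Best-scoring homopolymer tract of ``base`` in ``seq``.

    Sweep-line scoring: +``polya_match`` per matching base, ``polya_mismatch``
    per other base, running sum reset at zero (Kadane with non-negativity).
    Returns ``(best_score, present, best_interval)`` where ``present`` means
    the score reached ``polya_limit`` and ``best_interval`` is the leftmost
    half-open window attaining the best score (None when best is 0).
    """
    p = params or PipelineParams()
    base = base.upper()
    best = 0
    best_iv: tuple[int, int] | None = None
    run = 0
    start = 0
    for i, ch in enumerate(seq.upper()):
        if run == 0:
            start = i
        run += p.polya_match if ch == base else p.polya_mismatch
        if run < 0:
            run = 0
        elif run > best:
            best = run
            best_iv = (start, i + 1)
    return best, best >= p.polya_limit, best_iv


def en_score(flank: str, params: PipelineParams | None = None) -> int:
    """Positional match score of a junction flank against the EN consensus."""
    p = params or PipelineParams()
    if len(flank) != len(p.en_consensus):
        raise ValueError(
            f"EN flank must be {len(p.en_consensus)} bp, got {len(flank)}")
    flank = flank.upper()
    return sum(w for w, f, c in zip(p.en_weights, flank, p.en_consensus) if f == c)


def extract_en_flank(
    reference: str,
    breakpoint_a: int,
    breakpoint_b: int,
    orientation: str,
    params: PipelineParams | None = None,
) -> str | None:
    """Asymmetric flank (4 bases upstream, 2 downstream) of the initial
    breakpoint, read in the insertion's orientation.

    For '+' insertions the initial nick is at the later breakpoint and the
    flank is taken on the plus strand; for '−' it is at the earlier breakpoint
    and read on the minus strand.  Returns None when the flank would run off
    the contig or orientation is unknown.
    """
    del params
    if orientation == "+":
        bp = breakpoint_b
        if bp - 4 < 0 or bp + 2 > len(reference):
            return None
        return reference[bp - 4: bp + 2].upper()
    if orientation == "-":
        bp = breakpoint_a
        if bp - 2 < 0 or bp + 4 > len(reference):
            return None
        return revcomp(reference[bp - 2: bp + 4]).upper()
    return None


def tsd_from_breakpoints(bp_a: int, bp_b: int) -> int:
    """Signed target-site duplication length: later minus earlier junction.

    The caller passes the 5'-most junction first; a negative value therefore
    records a target-site deletion, zero a blunt insertion.
    """
    return bp_b - bp_a


def orientation_from_polya(
    read_seqs: list[str], params: PipelineParams | None = None,
) -> str:
    """Insertion orientation from tail tracts in plus-strand read sequences.

    An A tract at/above the sweep limit votes '+', a T tract votes '−';
    both or neither yields 'unknown'.
    """
    p = params or PipelineParams()
    has_a = any(polya_sweep(s, "A", p)[1] for s in read_seqs)
    has_t = any(polya_sweep(s, "T", p)[1] for s in read_seqs)
    if has_a and not has_t:
        return "+"
    if has_t and not has_a:
        return "-"
    return "unknown"


def annotate_polya(
    read_seqs: list[str], params: PipelineParams | None = None,
) -> tuple[bool, int, str | None]:
    """Best polyA evidence over a set of read sequences, both tail bases.

    Returns (present, best_score, base) with base the better-scoring of A/T
    (ties favour A, matching the '+' reading of an ambiguous tract only when
    strictly better is impossible — orientation handles the ambiguity).
    """
    p = params or PipelineParams()
    best_a = max((polya_sweep(s, "A", p)[0] for s in read_seqs), default=0)
    best_t = max((polya_sweep(s, "T", p)[0] for s in read_seqs), default=0)
    score = max(best_a, best_t)
    base = None
    if score > 0:
        base = "A" if best_a >= best_t else "T"
    return score >= p.polya_limit, score, base
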