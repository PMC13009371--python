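"""Insertion truth-set generator and donor-haplotype construction.

Somatic insertions are drawn per tumor sample with the configured class mix
(solo / partnered / orphan), TPRT hallmarks and per-source endpoint model:
a configurable fraction of transductions terminate 10–30 bp downstream of
a planted PAS hexamer; the rest follow a geometric tail.  The insertion at
the target site duplicates ``tsd`` bases of target sequence, and for a
configurable fraction of events the target is chosen at an endonuclease
consensus site so that the detector-frame junction flank reads TTTTAA.

``build_donor`` applies a sample's insertions to the reference, returning
both the donor sequence and the segment map used by the read simulator to
compute alignments analytically.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .._util import revcomp
from .config import SimulationConfig, SourceSpec, TruthRecord
from .reference import ReferenceBundle

__all__ = ["simulate_insertions", "build_donor", "DonorMap"]


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _source_downstream(bundle: ReferenceBundle, spec: SourceSpec) -> str:
    row = bundle.annotations[bundle.annotations["name"] == spec.id].iloc[0]
    g = bundle.genome[row["chrom"]]
    if spec.strand == "+":
        return g[row["end"]: row["end"] + 3500]
    return revcomp(g[max(0, row["start"] - 3500): row["start"]])


def _draw_endpoint(rng, spec: SourceSpec, cfg: SimulationConfig) -> int:
    if rng.random() < spec.pas_termination_frac:
        w = np.asarray(spec.pas_weights, dtype=float)
        off = spec.pas_offsets[rng.choice(len(spec.pas_offsets), p=w / w.sum())]
        end = off + int(rng.integers(10, 31))
    else:
        end = cfg.min_transduction_len + int(rng.geometric(spec.geometric_tail_p))
    return max(end, cfg.min_transduction_len)


def _draw_l1_part(rng, cfg: SimulationConfig, consensus: str,
                  spec: SourceSpec) -> tuple[str, int, tuple[int, int] | None]:
    """(l1 sequence in element orientation, l1_bp, inversion breakpoints)."""
    L = len(consensus)
    if rng.random() < cfg.full_length_prob:
        l1_len = L
    else:
        lo, hi = cfg.l1_truncation_range
        l1_len = int(rng.integers(lo, min(hi, L) + 1))
    c_start = L - l1_len
    if rng.random() < spec.inversion_rate and l1_len > 600:
        # twin priming: 5' piece inverted, junction near the per-source hotspot
        d = int(np.clip(rng.normal(spec.inversion_mode, 25), 60, l1_len - 60))
        c2 = L - d
        inv_len = int(rng.integers(200, min(800, c2 - c_start) + 1)) \
            if c2 - c_start > 200 else c2 - c_start
        c1 = c2 - inv_len
        seq = revcomp(consensus[c1:c2]) + consensus[c2:]
        return seq, len(seq), (L - c2, L - c1)
    return consensus[c_start:], l1_len, None


def simulate_insertions(
    cfg: SimulationConfig, bundle: ReferenceBundle,
) -> list[TruthRecord]:
    """Draw the somatic (and optional cascade germline) insertion truth set."""
    rng = np.random.default_rng(cfg.seed + 1)
    consensus = bundle.consensus
    specs = [s for s in cfg.sources if not s.truncated]
    weights = np.array([s.activity for s in specs], dtype=float)
    weights = weights / weights.sum() if weights.sum() else None
    downstream = {s.id: _source_downstream(bundle, s) for s in specs}

    # candidate EN-consensus target sites per chromosome and orientation
    en_sites = {}
    for chrom, g in bundle.genome.items():
        en_sites[chrom] = {"+": _find_all(g, "TTTTAA"),
                           "-": _find_all(g, "TTAAAA")}

    keepout: dict[str, list[tuple[int, int]]] = {
        c: [(max(0, a - 5000), b + 5000) for a, b in iv]
        for c, iv in bundle.element_intervals.items()}
    for c in bundle.genome:
        keepout.setdefault(c, [])

    def position_free(chrom: str, pos: int) -> bool:
        for a, b in keepout[chrom]:
            if a <= pos < b:
                return False
        return True

    def reserve(chrom: str, pos: int) -> None:
        # keep events well apart so clusters and merges stay one-to-one
        keepout[chrom].append((pos - 5000, pos + 5000))

    records: list[TruthRecord] = []
    counter = 0

    def draw_target(orientation: str, tsd: int, want_en: bool,
                    chrom: str) -> tuple[int, str, bool]:
        """Target position (5'-most junction) and detector-frame EN flank."""
        g = bundle.genome[chrom]
        for _ in range(200):
            sites = en_sites[chrom][orientation]
            if want_en and sites:
                o = sites[int(rng.integers(0, len(sites)))]
                pos = (o + 4 - tsd) if orientation == "+" else (o + 2)
            else:
                pos = int(rng.integers(10_000, len(g) - 10_000))
            if 10_000 < pos < len(g) - 10_000 and position_free(chrom, pos):
                if orientation == "+":
                    flank = g[pos + tsd - 4: pos + tsd + 2]
                else:
                    flank = revcomp(g[pos - 2: pos + 4])
                return pos, flank, want_en
            if want_en and rng.random() < 0.2:
                want_en = False  # degrade gracefully if sites are exhausted
        raise RuntimeError("could not place insertion after bounded retries")

    def make_record(sample: str, somatic: bool = True) -> TruthRecord:
        nonlocal counter
        counter += 1
        spec = specs[int(rng.choice(len(specs), p=weights))]
        is_trans = rng.random() < cfg.fraction_transduction
        cls = "solo"
        if is_trans:
            cls = "orphan" if rng.random() < cfg.orphan_fraction else "partnered"
        orientation = "+" if rng.random() < 0.5 else "-"
        tsd = int(rng.integers(cfg.tsd_range[0], cfg.tsd_range[1] + 1))
        polya = int(rng.integers(cfg.polya_range[0], cfg.polya_range[1] + 1))
        want_en = rng.random() < cfg.en_site_fraction
        chrom = f"chr{int(rng.integers(0, cfg.n_chromosomes)) + 1}"

        l1_seq, l1_bp, inv = "", 0, None
        internal_polya = 0
        trans_seq, endpoint = "", None
        if cls in ("solo", "partnered"):
            l1_seq, l1_bp, inv = _draw_l1_part(rng, cfg, consensus, spec)
        if cls in ("partnered", "orphan"):
            endpoint = _draw_endpoint(rng, spec, cfg)
            trans_seq = downstream[spec.id][:endpoint]
        dual = False
        if cls == "partnered" and rng.random() < cfg.dual_polya_prob:
            internal_polya = int(rng.integers(cfg.polya_range[0],
                                              cfg.polya_range[1] + 1))
            dual = True
        seq = (l1_seq + "A" * internal_polya + trans_seq + "A" * polya)
        pos, flank, planted = draw_target(orientation, tsd, want_en, chrom)
        reserve(chrom, pos)
        rec = TruthRecord(
            insertion_id=f"ins{counter:04d}", sample=sample, chrom=chrom,
            pos=pos, source_id=spec.id if cls != "solo" else None,
            cls=cls, seq=seq, l1_bp=l1_bp,
            transduction_bp=len(trans_seq), polya_bp=polya,
            internal_polya_bp=internal_polya, tsd_length=tsd,
            en_flank=flank.upper(), en_planted=planted,
            orientation=orientation, inversion_breakpoints=inv,
            endpoint=endpoint, somatic=somatic, dual_polya=dual)
        return rec

    for t in range(cfg.n_tumors):
        sample = f"tumor{t + 1}"
        n = int(rng.poisson(cfg.mean_somatic_insertions))
        for _ in range(n):
            records.append(make_record(sample))

    if cfg.cascade and cfg.n_tumors >= 1:
        records.extend(_make_cascade(cfg, bundle, rng, specs, downstream,
                                     draw_target, reserve, len(records)))
    return records


def _make_cascade(cfg, bundle, rng, specs, downstream, draw_target, reserve,
                  n_existing) -> list[TruthRecord]:
    """A germline transduction that itself mobilizes somatically.

    The germline parent inserts source S's downstream sequence at locus X;
    the somatic child's transduced sequence then carries both S's original
    tag and the reference flank of X (the parent's own tag)."""
    consensus = bundle.consensus
    spec = specs[0]
    sample = "tumor1"
    tsd_g = 10
    pos_g, flank_g, _ = draw_target("+", tsd_g, False, "chr1")
    reserve("chr1", pos_g)
    t1 = 120
    parent_seq = consensus[-1500:] + downstream[spec.id][:t1] + "A" * 20
    parent = TruthRecord(
        insertion_id=f"ins{n_existing + 1:04d}g", sample=sample, chrom="chr1",
        pos=pos_g, source_id=spec.id, cls="partnered", seq=parent_seq,
        l1_bp=1500, transduction_bp=t1, polya_bp=20, internal_polya_bp=0,
        tsd_length=tsd_g, en_flank=flank_g.upper(), en_planted=False,
        orientation="+", inversion_breakpoints=None, endpoint=t1,
        somatic=False)
    # child: transduced sequence = downstream of the parent's L1 3' end in the
    # donor = parent transduction + parent polyA + reference flank at X
    child_trans = downstream[spec.id][:t1] + "A" * 20 \
        + bundle.genome["chr1"][pos_g: pos_g + 150]
    tsd_c = 12
    pos_c, flank_c, _ = draw_target("+", tsd_c, False, "chr1")
    reserve("chr1", pos_c)
    child_seq = consensus[-1200:] + child_trans + "A" * 25
    child = TruthRecord(
        insertion_id=f"ins{n_existing + 2:04d}c", sample=sample, chrom="chr1",
        pos=pos_c, source_id=spec.id, cls="partnered", seq=child_seq,
        l1_bp=1200, transduction_bp=len(child_trans), polya_bp=25,
        internal_polya_bp=0, tsd_length=tsd_c, en_flank=flank_c.upper(),
        en_planted=False, orientation="+", inversion_breakpoints=None,
        endpoint=None, somatic=True, cascade_parent=parent.insertion_id)
    return [parent, child]


# ---------------------------------------------------------------------------
# donor haplotype


@dataclass
class Segment:
    donor_start: int
    donor_end: int
    kind: str                  # 'ref' | 'ins'
    ref_offset: int = 0        # donor_pos - ref_pos for 'ref' segments
    record: TruthRecord | None = None


@dataclass
class DonorMap:
    chrom: str
    seq: str
    segments: list[Segment]

    def segment_at(self, donor_pos: int) -> Segment:
        starts = [s.donor_start for s in self.segments]
        return self.segments[bisect_right(starts, donor_pos) - 1]


def build_donor(
    reference: dict[str, str], records: list[TruthRecord], sample: str,
) -> dict[str, DonorMap]:
    """Apply one sample's insertions to the reference.

    The TSD is modelled by repeating ``tsd`` reference bases on both sides
    of the inserted sequence: donor = ref[:pos+tsd] + INS + ref[pos:], so
    the junction breakpoints on the reference are pos and pos+tsd.
    """
    per_chrom: dict[str, list[TruthRecord]] = {}
    for r in records:
        if r.sample == sample:
            per_chrom.setdefault(r.chrom, []).append(r)
    donors = {}
    for chrom, ref in reference.items():
        recs = sorted(per_chrom.get(chrom, []), key=lambda r: r.pos)
        parts: list[str] = []
        segments: list[Segment] = []
        dpos = 0
        prev = 0
        for r in recs:
            cut = r.pos + r.tsd_length
            chunk = ref[prev:cut]
            segments.append(Segment(dpos, dpos + len(chunk), "ref",
                                    ref_offset=dpos - prev))
            parts.append(chunk)
            dpos += len(chunk)
            ins = r.genome_seq
            segments.append(Segment(dpos, dpos + len(ins), "ins", record=r))
            parts.append(ins)
            dpos += len(ins)
            prev = r.pos
        chunk = ref[prev:]
        segments.append(Segment(dpos, dpos + len(chunk), "ref",
                                ref_offset=dpos - prev))
        parts.append(chunk)
        donors[chrom] = DonorMap(chrom=chrom, seq="".join(parts),
                                 segments=segments)
    return donors
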