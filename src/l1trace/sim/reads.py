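"""Analytic paired-end read simulator.

Reads are drawn uniformly from the donor haplotype (reference with the
sample's insertions applied) and their alignments are computed from the
donor segment map rather than by running an aligner:

* reads fully inside a reference segment map at the homologous reference
  position (MAPQ 60; MAPQ 5 when the read lies in an L1 element copy);
* reads fully inside an insertion map at the corresponding source locus —
  L1 content at the source element (repeat MAPQ), transduced sequence at
  the unique downstream region (MAPQ 60), polyA at its flank with MAPQ 0;
* junction-spanning reads anchor on the larger reference side and soft-clip
  the inserted part at the breakpoint (the smaller side needs ≥ 12 aligned
  bases, otherwise the read is treated as insertion-interior);
* mates separated by an insertion acquire discordant insert sizes and lose
  the proper-pair flag by construction.

Output is a coordinate-sorted, indexed BAM.
"""

from __future__ import annotations

import tempfile
from bisect import bisect_right
from pathlib import Path

import numpy as np
import pysam

from .._util import revcomp
from .config import SimulationConfig, TruthRecord
from .insertions import DonorMap, build_donor
from .reference import ReferenceBundle

__all__ = ["simulate_reads", "count_tag_support"]

_MIN_ANCHOR = 12  # bp of reference match required to anchor a junction read


def _components(record: TruthRecord, bundle: ReferenceBundle):
    """Genome-orientation component map of one insertion.

    Each entry is (g_start, g_end, ref_chrom, ref_start, strand, mapq_kind)
    with mapq_kind in {'repeat', 'unique', 'polya'}; the linear mapping for
    strand '-' runs backwards from the component's reference end.
    """
    cached = getattr(record, "_components", None)
    if cached is not None:
        return cached
    ann = bundle.annotations
    if record.source_id is not None:
        row = ann[ann["name"] == record.source_id].iloc[0]
    else:  # solo: all L1 copies are equivalent; use the first element
        row = ann.iloc[0]
    src_chrom, src_start, src_end = row["chrom"], int(row["start"]), int(row["end"])
    L = len(bundle.consensus)
    comps = []  # element-orientation first
    off = 0
    if record.l1_bp:
        if record.inversion_breakpoints:
            d2, d1 = record.inversion_breakpoints  # (L-c2, L-c1)
            c2, c1 = L - d2, L - d1
            inv_len = c2 - c1
            comps.append((off, off + inv_len, src_chrom, src_start + c1,
                          "-", "repeat"))
            off += inv_len
            fwd = record.l1_bp - inv_len
            comps.append((off, off + fwd, src_chrom, src_start + c2,
                          "+", "repeat"))
            off += fwd
        else:
            comps.append((off, off + record.l1_bp, src_chrom,
                          src_start + (L - record.l1_bp), "+", "repeat"))
            off += record.l1_bp
    if record.internal_polya_bp:
        comps.append((off, off + record.internal_polya_bp, src_chrom,
                      src_end, "+", "polya"))
        off += record.internal_polya_bp
    if record.transduction_bp:
        comps.append((off, off + record.transduction_bp, src_chrom,
                      src_end, "+", "unique"))
        off += record.transduction_bp
    if record.polya_bp:
        comps.append((off, off + record.polya_bp, src_chrom,
                      src_end + record.transduction_bp, "+", "polya"))
        off += record.polya_bp
    if record.orientation == "-":
        total = off
        flipped = []
        for (a, b, ch, rs, st, kind) in comps:
            flipped.append((total - b, total - a, ch, rs,
                            "-" if st == "+" else "+", kind))
        comps = sorted(flipped)
    record._components = comps  # noqa: attr-defined (cache)
    return comps


def _interior_mapping(record, bundle, cfg, ins_off_a, ins_off_b):
    """Mapping of a read interval inside an insertion segment."""
    comps = _components(record, bundle)
    mid = (ins_off_a + ins_off_b) // 2
    for (a, b, ch, rs, st, kind) in comps:
        if a <= mid < b:
            if st == "+":
                pos = rs + (ins_off_a - a)
            else:
                pos = rs + (b - ins_off_b)
            mapq = {"repeat": cfg.mapq_repeat, "unique": cfg.mapq_unique,
                    "polya": 0}[kind]
            length = ins_off_b - ins_off_a
            return ch, max(0, pos), f"{length}M", mapq, st == "-"
    return None


def _map_read(dm: DonorMap, a: int, b: int, record_lookup, bundle, cfg,
              element_bounds):
    """Analytic alignment of donor interval [a, b): returns
    (chrom, pos, cigar, mapq, flip_strand)."""
    segs = dm.segments
    starts = [s.donor_start for s in segs]
    i = bisect_right(starts, a) - 1
    j = bisect_right(starts, b - 1) - 1
    if i == j:
        seg = segs[i]
        if seg.kind == "ref":
            pos = a - seg.ref_offset
            mapq = cfg.mapq_unique
            lo, hi = element_bounds
            k = bisect_right(lo, pos) - 1
            if k >= 0 and pos < hi[k]:
                mapq = cfg.mapq_repeat
            return dm.chrom, pos, f"{b - a}M", mapq, False
        off = seg.donor_start
        return _interior_mapping(seg.record, bundle, cfg, a - off, b - off)
    # junction-spanning: anchor on the larger flanking ref part
    left = segs[i]
    right = segs[j]
    left_len = left.donor_end - a if left.kind == "ref" else 0
    right_len = b - right.donor_start if right.kind == "ref" else 0
    n = b - a
    if max(left_len, right_len) >= _MIN_ANCHOR:
        if left_len >= right_len:
            pos = a - left.ref_offset
            return dm.chrom, pos, f"{left_len}M{n - left_len}S", \
                cfg.mapq_unique, False
        pos = right.donor_start - right.ref_offset
        return dm.chrom, pos, f"{n - right_len}S{right_len}M", \
            cfg.mapq_unique, False
    # no usable ref anchor: use the insertion segment with the most overlap
    best = None
    for k in range(i, j + 1):
        seg = segs[k]
        if seg.kind != "ins":
            continue
        ov = min(b, seg.donor_end) - max(a, seg.donor_start)
        if best is None or ov > best[0]:
            best = (ov, seg)
    if best is None:
        seg = left if left.kind == "ref" else right
        pos = max(0, a - seg.ref_offset)
        return dm.chrom, pos, f"{n}M", 0, False
    seg = best[1]
    aa = max(a, seg.donor_start) - seg.donor_start
    bb = min(b, seg.donor_end) - seg.donor_start
    m = _interior_mapping(seg.record, bundle, cfg, aa, max(bb, aa + 1))
    if m is None:
        return dm.chrom, 0, f"{n}M", 0, False
    ch, pos, _, mapq, flip = m
    pre = max(a, seg.donor_start) - a
    post = b - min(b, seg.donor_end)
    parts = [(f"{pre}S" if pre else ""), f"{bb - aa}M",
             (f"{post}S" if post else "")]
    if flip:  # reverse-strand alignment stores the CIGAR reversed
        parts.reverse()
    return ch, pos, "".join(parts), mapq, flip


def simulate_reads(
    cfg: SimulationConfig,
    bundle: ReferenceBundle,
    records: list[TruthRecord],
    sample: str,
    out_bam: str | Path,
    sample_index: int = 0,
) -> str:
    """Emit one sample's coordinate-sorted, indexed BAM."""
    rng = np.random.default_rng([cfg.seed, 7, sample_index])
    donors = build_donor(bundle.genome, records, sample)
    chroms = list(bundle.genome)
    lens = {c: len(s) for c, s in bundle.genome.items()}
    header_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in chroms:
        header_lines.append(f"@SQ\tSN:{c}\tLN:{lens[c]}")
    rl = cfg.read_length

    element_bounds: dict[str, tuple[list[int], list[int]]] = {}
    for c in chroms:
        iv = sorted(bundle.element_intervals.get(c, []))
        element_bounds[c] = ([a for a, _ in iv], [b for _, b in iv])

    tmp_fh = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
    tmp = tmp_fh.name
    tmp_fh.write("\n".join(header_lines) + "\n")
    lines: list[str] = []
    frag_id = 0
    for chrom, dm in donors.items():
        n_frags = int(round(cfg.depth * len(dm.seq) / (2 * rl)))
        flens = np.clip(rng.normal(cfg.insert_mean, cfg.insert_sd, n_frags),
                        rl + 20, None).astype(int)
        starts = rng.integers(0, np.maximum(1, len(dm.seq) - flens),
                              size=n_frags)
        seq = dm.seq
        eb = element_bounds[chrom]
        for s, fl in zip(starts.tolist(), flens.tolist()):
            frag_id += 1
            name = f"{sample}.f{frag_id:07d}"
            a1, b1 = s, s + rl
            a2, b2 = s + fl - rl, s + fl
            r1 = seq[a1:b1]
            r2 = revcomp(seq[a2:b2])
            m1 = _map_read(dm, a1, b1, None, bundle, cfg, eb)
            m2 = _map_read(dm, a2, b2, None, bundle, cfg, eb)
            if m1 is None or m2 is None:
                continue
            ch1, p1, c1, q1, f1 = m1
            ch2, p2, c2, q2, f2 = m2
            # drawn orientation: mate1 forward, mate2 reverse; a component
            # mapped in reverse flips the emitted strand (and the SEQ)
            rev1 = f1
            rev2 = not f2
            # SAM SEQ is always the forward-strand projection
            s1 = revcomp(r1) if rev1 else r1
            s2 = revcomp(r2) if rev2 else r2
            same = ch1 == ch2
            if same:
                lo = min(p1, p2)
                hi = max(p1 + rl, p2 + rl)
                tlen = hi - lo
                proper = (tlen <= cfg.insert_mean + 6 * cfg.insert_sd
                          and rev1 != rev2)
                t1 = tlen if p1 <= p2 else -tlen
                t2 = -t1
            else:
                proper = False
                t1 = t2 = 0
            flag1 = 0x1 | 0x40 | (0x2 if proper else 0) | \
                (0x10 if rev1 else 0) | (0x20 if rev2 else 0)
            flag2 = 0x1 | 0x80 | (0x2 if proper else 0) | \
                (0x10 if rev2 else 0) | (0x20 if rev1 else 0)
            rn2 = "=" if same else ch2
            rn1 = "=" if same else ch1
            lines.append(f"{name}\t{flag1}\t{ch1}\t{p1 + 1}\t{q1}\t{c1}\t"
                         f"{rn2}\t{p2 + 1}\t{t1}\t{s1}\t*")
            lines.append(f"{name}\t{flag2}\t{ch2}\t{p2 + 1}\t{q2}\t{c2}\t"
                         f"{rn1}\t{p1 + 1}\t{t2}\t{s2}\t*")
            if len(lines) >= 20000:
                tmp_fh.write("\n".join(lines) + "\n")
                lines.clear()

    out_bam = str(out_bam)
    if lines:
        tmp_fh.write("\n".join(lines) + "\n")
    tmp_fh.close()
    pysam.sort("-O", "bam", "-o", out_bam, tmp, catch_stdout=False)
    Path(tmp).unlink()
    pysam.index(out_bam)
    return out_bam


def count_tag_support(
    bam_path: str | Path,
    records: list[TruthRecord],
    bundle: ReferenceBundle,
    tag_length: int = 30,
    min_mapq: int = 37,
    window: int = 2000,
) -> dict[str, int]:
    """Supporting tag pairs per truth insertion, by direct read scan.

    A pair supports an event when one mate's sequence contains the event
    source's tag (either orientation) and the other mate maps with
    MAPQ ≥ ``min_mapq`` within ``window`` bp of the true target position.
    Independent of the detection pipeline's clustering and filters.
    """
    tags = {}
    ann = bundle.annotations
    for r in records:
        if r.source_id is None or r.cls == "solo":
            continue
        row = ann[ann["name"] == r.source_id].iloc[0]
        g = bundle.genome[row["chrom"]]
        if row["strand"] == "+":
            tag = g[row["end"]: row["end"] + tag_length]
        else:
            tag = revcomp(g[row["start"] - tag_length: row["start"]])
        tags[r.insertion_id] = (r, tag.upper(), revcomp(tag.upper()))
    support = {rid: 0 for rid in tags}
    pending: dict[str, tuple] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            rec = (read.query_sequence or "", read.reference_name,
                   read.reference_start, read.mapping_quality)
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = rec
                continue
            for rid, (truth, tag, rc) in tags.items():
                for x, y in ((mate, rec), (rec, mate)):
                    if tag in x[0] or rc in x[0]:
                        if (y[3] >= min_mapq and y[1] == truth.chrom
                                and abs(y[2] - truth.pos) <= window):
                            support[rid] += 1
                        break
    return support
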