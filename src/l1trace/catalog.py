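"""Source-L1 catalog: tag extraction, uniqueness filtering, similar sites.

A *source* L1 is a full-length (5700–6700 bp) element able to generate new
insertions.  Its fingerprint is the *tag*: the exact 30-bp sequence
immediately 3' of the element end on the element strand.  A tag is only
usable for detection when it is close to unique genome-wide: tags occurring
at more than 1000 loci allowing up to 3 edits are excluded.  For the
remaining sources, loci matching the tag with up to 6 mismatches are
recorded as *similar sites* and later used to discard read clusters that
could be explained by the repeat structure of the reference rather than by
a new insertion.  Truncated elements are retained as potential *proxies*:
reference copies that carry another (non-reference) source's transduced
sequence downstream and would otherwise soak up its insertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from ._util import encode, revcomp
from .params import PipelineParams
from .pas import PWM, PASHit, find_internal_pas

__all__ = [
    "SourceL1", "build_catalog", "count_approximate_hits",
    "find_similar_sites", "annotate_internal_pas",
    "write_catalog", "read_catalog",
]


@dataclass
class SourceL1:
    id: str
    chrom: str
    start: int            # 0-based half-open
    end: int
    strand: str
    length: int
    is_full_length: bool
    provenance: str = "reference"   # reference | polymorphic | somatic-novel
    allele_status: str = "fixed"    # fixed | polymorphic | unknown
    downstream_seq: str = ""        # 3' flank on element strand
    element_seq: str = ""
    tag: str | None = None
    tag_genomic_hit_count: int | None = None
    tag_usable: bool = False
    similar_sites: list[tuple[str, int, str]] = field(default_factory=list)
    internal_pas: PASHit | None = None
    proxy_of: str | None = None

    @property
    def three_prime(self) -> int:
        """Reference coordinate of the element's 3' end."""
        return self.end if self.strand == "+" else self.start


def _genome_seqs(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        return reference
    fa = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    return {name: str(fa[name][:]) for name in fa.keys()}


def count_approximate_hits(
    tag: str, reference, max_edits: int = 3,
) -> int:
    """Distinct genome loci (both strands) matching ``tag`` with edit
    distance ≤ ``max_edits``; overlapping hits within one tag length
    collapse to a single locus.

    Uses pigeonhole seeding — the tag is split into ``max_edits + 1`` parts,
    one of which must match exactly at any locus within the edit budget —
    with edlib infix verification of each candidate window.  Exact for the
    stated edit budget.
    """
    if not tag or any(c not in "ACGTN" for c in tag.upper()):
        raise ValueError("tag must be non-empty over ACGTN")
    tag = tag.upper()
    if "N" in tag:
        return 0
    genomes = _genome_seqs(reference)
    k = max_edits
    nparts = k + 1
    L = len(tag)
    bounds = [round(i * L / nparts) for i in range(nparts + 1)]
    seeds = [(tag[bounds[i]: bounds[i + 1]], bounds[i]) for i in range(nparts)]
    total = 0
    for chrom, seq in genomes.items():
        seq = seq.upper()
        for strand_seq in (seq, revcomp(seq)):
            cand_starts: set[int] = set()
            for part, offset in seeds:
                start = strand_seq.find(part)
                while start != -1:
                    cand_starts.add(start - offset)
                    start = strand_seq.find(part, start + 1)
            hit_starts = []
            for s in sorted(cand_starts):
                lo = max(0, s - k)
                hi = min(len(strand_seq), s + L + k)
                res = edlib.align(tag, strand_seq[lo:hi], mode="HW", k=k,
                                  task="locations")
                if res["editDistance"] != -1:
                    for loc_start, _ in res["locations"]:
                        hit_starts.append(lo + (loc_start or 0))
            # collapse loci overlapping within one tag length
            last = None
            for s in sorted(set(hit_starts)):
                if last is None or s - last >= L:
                    total += 1
                    last = s
    return total


def find_similar_sites(
    tag: str, reference, max_mismatches: int = 6,
    exclude: tuple[str, int] | None = None, tag_length: int | None = None,
) -> list[tuple[str, int, str]]:
    """Loci matching ``tag`` with ≤ ``max_mismatches`` Hamming mismatches,
    both strands, as (chrom, 0-based start on plus strand, strand).

    ``exclude`` drops hits within one tag length of the source's own tag
    locus.  Vectorized positional comparison over the whole genome.
    """
    tag = tag.upper()
    L = len(tag)
    tcodes = encode(tag)
    out = []
    for chrom, seq in _genome_seqs(reference).items():
        g = encode(seq.upper())
        if len(g) < L:
            continue
        n_windows = len(g) - L + 1
        for strand in "+-":
            q = tcodes if strand == "+" else encode(revcomp(tag))
            mism = np.zeros(n_windows, dtype=np.int16)
            for i in range(L):
                mism += g[i: i + n_windows] != q[i]
            for start in np.nonzero(mism <= max_mismatches)[0]:
                start = int(start)
                if exclude and chrom == exclude[0] and abs(start - exclude[1]) < L:
                    continue
                out.append((chrom, start, strand))
    return sorted(out)


def build_catalog(
    reference,
    annotations: pd.DataFrame | str | Path,
    extra_sources: pd.DataFrame | None = None,
    params: PipelineParams | None = None,
    pwm: PWM | None = None,
    check_uniqueness: bool = True,
) -> list[SourceL1]:
    """Build the source catalog from a reference and a BED of L1 elements.

    ``annotations``: BED6 frame/path with columns chrom, start, end, name,
    score, strand (0-based half-open).  ``extra_sources``: optional TSV-like
    frame of supplemental sources with the same columns plus ``provenance``,
    ``allele_status`` and optional ``proxy_of``.  Full-length elements get
    tags, uniqueness counts and similar sites; truncated elements are kept
    as potential proxies but excluded from tag detection.
    """
    p = params or PipelineParams()
    genomes = _genome_seqs(reference)
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(
            annotations, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"])
    frames = [annotations.assign(provenance="reference", allele_status="fixed",
                                 proxy_of=None)
              if "provenance" not in annotations.columns else annotations]
    if extra_sources is not None and len(extra_sources):
        frames.append(extra_sources)
    ann = pd.concat(frames, ignore_index=True)

    catalog: list[SourceL1] = []
    for _, row in ann.iterrows():
        chrom, start, end = str(row["chrom"]), int(row["start"]), int(row["end"])
        if chrom not in genomes:
            raise ValueError(f"annotation {row['name']}: unknown contig {chrom}")
        seq = genomes[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"annotation {row['name']}: interval out of bounds")
        strand = str(row["strand"])
        length = end - start
        full = p.full_length_min <= length <= p.full_length_max
        flank_len = p.source_window + 50
        if strand == "+":
            element_seq = seq[start:end]
            downstream = seq[end: end + flank_len]
        else:
            element_seq = revcomp(seq[start:end])
            downstream = revcomp(seq[max(0, start - flank_len): start])
        src = SourceL1(
            id=str(row["name"]), chrom=chrom, start=start, end=end,
            strand=strand, length=length, is_full_length=full,
            provenance=str(row.get("provenance", "reference")),
            allele_status=str(row.get("allele_status", "fixed")),
            downstream_seq=downstream, element_seq=element_seq,
            proxy_of=(None if pd.isna(row.get("proxy_of", None))
                      else str(row["proxy_of"])),
        )
        if full:
            tag = downstream[: p.tag_length]
            if len(tag) == p.tag_length and "N" not in tag.upper():
                src.tag = tag.upper()
            # a truncated flank at a contig end leaves the source unusable
        catalog.append(src)

    for src in catalog:
        if src.tag is None:
            continue
        if check_uniqueness:
            src.tag_genomic_hit_count = count_approximate_hits(
                src.tag, genomes, p.tag_hit_max_edits)
            src.tag_usable = src.tag_genomic_hit_count <= p.tag_max_genomic_hits
        else:
            src.tag_usable = True
        if src.tag_usable:
            tag_locus = (src.chrom,
                         src.end if src.strand == "+" else src.start - p.tag_length)
            src.similar_sites = find_similar_sites(
                src.tag, genomes, p.similar_site_max_mismatches,
                exclude=tag_locus)
        if pwm is not None:
            annotate_internal_pas(src, pwm, p)
    return catalog


def annotate_internal_pas(
    source: SourceL1, pwm: PWM, params: PipelineParams | None = None,
) -> SourceL1:
    """Attach the strongest PAS in the element's final 50 bp (element strand)."""
    p = params or PipelineParams()
    if source.element_seq:
        source.internal_pas = find_internal_pas(source.element_seq, pwm, p)
    return source


_CATALOG_COLUMNS = [
    "id", "chrom", "start", "end", "strand", "length", "is_full_length",
    "provenance", "allele_status", "tag", "tag_genomic_hit_count",
    "tag_usable", "n_similar_sites", "internal_pas_hexamer",
    "internal_pas_score", "internal_pas_strength", "proxy_of",
]


def write_catalog(catalog: list[SourceL1], path: str | Path) -> None:
    """Catalog TSV, loci 1-based inclusive."""
    rows = []
    for s in catalog:
        pas = s.internal_pas
        rows.append({
            "id": s.id, "chrom": s.chrom, "start": s.start + 1, "end": s.end,
            "strand": s.strand, "length": s.length,
            "is_full_length": s.is_full_length, "provenance": s.provenance,
            "allele_status": s.allele_status, "tag": s.tag or "",
            "tag_genomic_hit_count": s.tag_genomic_hit_count,
            "tag_usable": s.tag_usable,
            "n_similar_sites": len(s.similar_sites),
            "internal_pas_hexamer": pas.hexamer if pas else "",
            "internal_pas_score": pas.score if pas else "",
            "internal_pas_strength": pas.strength if pas else "none",
            "proxy_of": s.proxy_of or "",
        })
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
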