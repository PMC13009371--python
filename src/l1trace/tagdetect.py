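"""Tag-based transduction detection in short-read alignments.

A read pair supports a 3' transduction when one mate *contains* a source
tag (the exact 30-bp sequence downstream of a source L1, in either
orientation) while the other mate — the *anchor* — maps confidently
(MAPQ ≥ 37) at the insertion locus.  Anchors are single-linkage clustered
per source within 1 kbp; a cluster is called a transduction when it holds
≥ 3 anchors and is neither within 2 kbp of a site similar to the tag nor of
the source locus itself.  Calls are merged across samples (same source,
≤ 2 kbp apart) and an event present in exactly one tumor and no normal is
somatic.  Called clusters are then characterized from reads within 500 bp
of the anchors: split reads (clip ≥ 10 bp) vote for breakpoints, the TSD is
the signed breakpoint distance, polyA and orientation come from the sweep
over split/discordant read sequences, and the EN flank is scored against
TTTT/AA on the reference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from ._util import revcomp, single_linkage_1d
from .hallmarks import (HallmarkAnnotation, annotate_polya, en_score,
                        extract_en_flank, orientation_from_polya,
                        tsd_from_breakpoints)
from .params import PipelineParams

__all__ = [
    "TagHit", "AnchorCluster", "MergedEvent", "scan_reads", "cluster_anchors",
    "filter_clusters", "merge_across_samples", "call_somatic",
    "characterize_cluster", "detect_sample", "run_short_read_detection",
]


@dataclass
class TagHit:
    sample: str
    source_id: str
    read_id: str
    tag_mate: int            # 1 or 2: which mate carries the tag
    anchor_chrom: str
    anchor_pos: int          # 0-based leftmost
    anchor_mapq: int         # recorded even below threshold, for audit
    anchor_strand: str
    tag_orientation: str     # '+' tag seen as-is, '-' reverse complement


@dataclass
class AnchorCluster:
    sample: str
    source_id: str
    chrom: str
    start: int               # min anchor position
    end: int                 # max anchor position
    n_anchor_reads: int
    min_reads_pass: bool = False
    repeat_exclusion_pass: bool = False
    hallmarks: HallmarkAnnotation | None = None
    locus: int = 0           # modal breakpoint if known, else anchor midpoint

    @property
    def called(self) -> bool:
        return self.min_reads_pass and self.repeat_exclusion_pass


@dataclass
class MergedEvent:
    event_id: str
    source_id: str
    chrom: str
    locus: int
    samples: list[str]
    clusters: list[AnchorCluster]
    somatic: bool | None = None


def scan_reads(
    alignments: str | pysam.AlignmentFile,
    catalog,
    sample: str,
    params: PipelineParams | None = None,
) -> list[TagHit]:
    """One pass over a coordinate-sorted BAM collecting tag-carrying pairs.

    Both mates of a pair are needed, so pairs are buffered by name; pairs
    where both mates carry a tag are dropped (no usable anchor).  Sources
    whose tag failed the genome-wide uniqueness filter are skipped.
    """
    p = params or PipelineParams()
    own = isinstance(alignments, (str, Path))
    bam = pysam.AlignmentFile(str(alignments)) if own else alignments
    tags = {}
    for src in catalog:
        if src.tag and src.tag_usable:
            tags[src.id] = (src.tag, revcomp(src.tag))
    hits: list[TagHit] = []
    # buffer one lightweight record per pending mate; coordinate-sorted
    # input means mates arrive far apart, so keep only what the hit needs
    pending: dict[str, tuple] = {}
    for read in bam.fetch(until_eof=True):
        if read.is_secondary or read.is_supplementary or not read.is_paired:
            continue
        name = read.query_name
        rec = (read.query_sequence or "", read.reference_name,
               read.reference_start, read.mapping_quality,
               "-" if read.is_reverse else "+", read.is_unmapped)
        mate = pending.pop(name, None)
        if mate is None:
            pending[name] = rec
            continue
        pair = (mate, rec)
        for source_id, (tag, rc) in tags.items():
            carrier = []
            orient = []
            for i, (s, *_rest) in enumerate(pair):
                if tag in s:
                    carrier.append(i)
                    orient.append("+")
                elif rc in s:
                    carrier.append(i)
                    orient.append("-")
            if len(carrier) != 1:
                continue  # no tag, or both mates carry one
            _seq, chrom, pos, mapq, strand, unmapped = pair[1 - carrier[0]]
            if unmapped:
                continue
            hits.append(TagHit(
                sample=sample, source_id=source_id, read_id=name,
                tag_mate=carrier[0] + 1,
                anchor_chrom=chrom, anchor_pos=pos, anchor_mapq=mapq,
                anchor_strand=strand, tag_orientation=orient[0]))
    if own:
        bam.close()
    return hits


def cluster_anchors(
    hits: list[TagHit], params: PipelineParams | None = None,
) -> list[AnchorCluster]:
    """Single-linkage clustering of anchor positions per (source, chrom).

    Only anchors at/above the MAPQ threshold participate.
    """
    p = params or PipelineParams()
    clusters = []
    by_key: dict[tuple[str, str, str], list[int]] = {}
    for h in hits:
        if h.anchor_mapq < p.anchor_min_mapq:
            continue
        by_key.setdefault((h.sample, h.source_id, h.anchor_chrom), []).append(
            h.anchor_pos)
    for (sample, source_id, chrom), positions in sorted(by_key.items()):
        for group in single_linkage_1d(positions, p.anchor_cluster_gap):
            clusters.append(AnchorCluster(
                sample=sample, source_id=source_id, chrom=chrom,
                start=group[0], end=group[-1], n_anchor_reads=len(group),
                locus=(group[0] + group[-1]) // 2))
    return clusters


def filter_clusters(
    clusters: list[AnchorCluster], catalog, params: PipelineParams | None = None,
) -> list[AnchorCluster]:
    """Apply the minimum-read and repeat-exclusion filters (flags only).

    A cluster fails repeat exclusion when any recorded similar site of its
    source — or the source locus itself — lies within 2 kbp of the cluster
    interval.
    """
    p = params or PipelineParams()
    by_id = {s.id: s for s in catalog}
    for cl in clusters:
        cl.min_reads_pass = cl.n_anchor_reads >= p.cluster_min_reads
        src = by_id[cl.source_id]
        near = False
        for chrom, pos, _strand in src.similar_sites:
            if chrom == cl.chrom and _dist(cl, pos) <= p.repeat_exclusion_dist:
                near = True
                break
        if not near and src.chrom == cl.chrom:
            # the source's own tag locus recruits reference-derived pairs
            for pos in (src.start, src.end):
                if _dist(cl, pos) <= p.repeat_exclusion_dist:
                    near = True
                    break
        cl.repeat_exclusion_pass = not near
    return clusters


def _dist(cluster: AnchorCluster, pos: int) -> int:
    if pos < cluster.start:
        return cluster.start - pos
    if pos > cluster.end:
        return pos - cluster.end
    return 0


def merge_across_samples(
    per_sample_clusters: list[AnchorCluster],
    params: PipelineParams | None = None,
) -> list[MergedEvent]:
    """Merge called clusters across samples: same source, loci ≤ 2 kbp apart
    (single linkage).  Different sources never merge."""
    p = params or PipelineParams()
    called = [c for c in per_sample_clusters if c.called]
    events: list[MergedEvent] = []
    by_key: dict[tuple[str, str], list[AnchorCluster]] = {}
    for c in called:
        by_key.setdefault((c.source_id, c.chrom), []).append(c)
    for (source_id, chrom), group in sorted(by_key.items()):
        group.sort(key=lambda c: c.locus)
        bins: list[list[AnchorCluster]] = [[group[0]]]
        for c in group[1:]:
            if c.locus - bins[-1][-1].locus <= p.cross_sample_merge_dist:
                bins[-1].append(c)
            else:
                bins.append([c])
        for members in bins:
            locus = members[0].locus
            events.append(MergedEvent(
                event_id=f"{source_id}:{chrom}:{locus}",
                source_id=source_id, chrom=chrom, locus=locus,
                samples=sorted({m.sample for m in members}),
                clusters=members))
    return events


def call_somatic(
    events: list[MergedEvent], sample_labels: dict[str, str],
) -> list[MergedEvent]:
    """Somatic ⇔ supported by exactly one tumor and zero normals."""
    for ev in events:
        labels = []
        for s in ev.samples:
            if s not in sample_labels:
                raise ValueError(f"sample {s} missing from the sample sheet")
            labels.append(sample_labels[s])
        n_tumor = sum(1 for x in labels if x == "tumor")
        n_normal = sum(1 for x in labels if x == "normal")
        ev.somatic = n_tumor == 1 and n_normal == 0 and len(ev.samples) == 1
    return events


def characterize_cluster(
    alignments: str | pysam.AlignmentFile,
    cluster: AnchorCluster,
    reference: dict[str, str],
    params: PipelineParams | None = None,
) -> HallmarkAnnotation:
    """Hallmark annotation from reads around a called cluster.

    Split positions are soft/hard-clip boundaries of reads in the window;
    the two most common split positions become the breakpoints (ties to the
    leftmost).  polyA/orientation use the sequences of split and discordant
    reads; the EN flank is read from the reference at the initial breakpoint.
    Hallmarks are annotation, never filters: missing evidence leaves fields
    unset and the event stands.
    """
    p = params or PipelineParams()
    own = isinstance(alignments, (str, Path))
    bam = pysam.AlignmentFile(str(alignments)) if own else alignments
    w_start = max(0, cluster.start - p.characterization_window)
    w_end = cluster.end + p.characterization_window
    split_positions: list[int] = []
    evidence_seqs: list[str] = []
    for read in bam.fetch(cluster.chrom, w_start, w_end):
        if read.is_secondary or read.is_supplementary or read.is_unmapped:
            continue
        cig = read.cigartuples or []
        clipped = False
        if cig and cig[0][0] in (4, 5) and cig[0][1] >= p.min_clip_len:
            split_positions.append(read.reference_start)
            clipped = True
        if cig and cig[-1][0] in (4, 5) and cig[-1][1] >= p.min_clip_len:
            split_positions.append(read.reference_end)
            clipped = True
        discordant = (
            read.is_paired and not read.mate_is_unmapped
            and (read.reference_id != read.next_reference_id
                 or abs(read.template_length) > p.discordant_min_insert
                 or read.is_reverse == read.mate_is_reverse))
        if clipped or discordant:
            if read.query_sequence:
                evidence_seqs.append(read.query_sequence)
    if own:
        bam.close()

    ann = HallmarkAnnotation()
    if split_positions:
        counts = Counter(split_positions)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top = [ranked[0][0]]
        if len(ranked) > 1:
            top.append(ranked[1][0])
        bp_a, bp_b = min(top), max(top)
        ann.breakpoint_a, ann.breakpoint_b = bp_a, bp_b
        ann.tsd_length = tsd_from_breakpoints(bp_a, bp_b)
        cluster.locus = bp_a
    present, score, base = annotate_polya(evidence_seqs, p)
    ann.polya_present, ann.polya_best_score, ann.polya_base = present, score, base
    ann.orientation = orientation_from_polya(evidence_seqs, p)
    if (ann.breakpoint_a is not None and ann.orientation in "+-"
            and cluster.chrom in reference):
        flank = extract_en_flank(reference[cluster.chrom], ann.breakpoint_a,
                                 ann.breakpoint_b, ann.orientation, p)
        if flank is not None:
            ann.en_flank = flank
            ann.en_score = en_score(flank, p)
            ann.en_cut_site = ann.en_score >= p.en_min_score
    cluster.hallmarks = ann
    return ann


def detect_sample(
    bam_path: str,
    catalog,
    sample: str,
    reference: dict[str, str],
    params: PipelineParams | None = None,
    characterize: bool = True,
) -> list[AnchorCluster]:
    """Scan → cluster → filter → characterize one sample's alignments."""
    p = params or PipelineParams()
    hits = scan_reads(bam_path, catalog, sample, p)
    clusters = filter_clusters(cluster_anchors(hits, p), catalog, p)
    if characterize:
        with pysam.AlignmentFile(bam_path) as bam:
            for cl in clusters:
                if cl.called:
                    characterize_cluster(bam, cl, reference, p)
    return clusters


def run_short_read_detection(
    sample_sheet: pd.DataFrame,
    catalog,
    reference: dict[str, str],
    params: PipelineParams | None = None,
) -> tuple[list[AnchorCluster], list[MergedEvent]]:
    """Whole-cohort short-read detection.

    ``sample_sheet`` columns: sample, path (BAM), label (tumor|normal).
    Returns all per-sample clusters and the merged, somatic-flagged events.
    """
    p = params or PipelineParams()
    clusters: list[AnchorCluster] = []
    for _, row in sample_sheet.iterrows():
        clusters.extend(detect_sample(
            str(row["path"]), catalog, str(row["sample"]), reference, p))
    events = merge_across_samples(clusters, p)
    labels = dict(zip(sample_sheet["sample"].astype(str),
                      sample_sheet["label"].astype(str)))
    call_somatic(events, labels)
    return clusters, events
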