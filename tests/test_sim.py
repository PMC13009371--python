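"""Synthetic-study generator: determinism, planting contracts, class mix,
read alignments and truth conservation."""

from collections import Counter

import numpy as np
import pysam
import pytest

from l1trace._util import revcomp
from l1trace.sim import (SimulationConfig, SourceSpec, build_donor,
                         simulate_insertions, simulate_longread_calls,
                         simulate_methylation, simulate_reads,
                         simulate_reference)


def test_reference_deterministic_under_seed():
    cfg = SimulationConfig(seed=7, chrom_length=120_000,
                           sources=[SourceSpec(id="s1")])
    a = simulate_reference(cfg)
    b = simulate_reference(cfg)
    assert a.genome == b.genome
    assert a.annotations.equals(b.annotations)


def test_pas_planting_contract():
    """AATAAA planted at +9 of a source is present at that exact offset."""
    cfg = SimulationConfig(
        seed=3, chrom_length=120_000,
        sources=[SourceSpec(id="s1", pas_offsets=(9,), pas_weights=(1.0,))])
    bundle = simulate_reference(cfg)
    row = bundle.annotations.iloc[0]
    g = bundle.genome[row["chrom"]]
    assert g[row["end"] + 9: row["end"] + 15] == "AATAAA"


def test_zero_sources_valid_reference():
    cfg = SimulationConfig(seed=3, chrom_length=80_000, sources=[])
    bundle = simulate_reference(cfg)
    assert len(bundle.genome["chr1"]) == 80_000
    assert len(bundle.annotations) == 0


def test_overlapping_sources_raise():
    cfg = SimulationConfig(
        seed=3, chrom_length=120_000,
        sources=[SourceSpec(id="a", position=20_000),
                 SourceSpec(id="b", position=21_000)])
    with pytest.raises(ValueError, match="overlap"):
        simulate_reference(cfg)


def test_minus_strand_source_planting():
    cfg = SimulationConfig(
        seed=3, chrom_length=120_000,
        sources=[SourceSpec(id="m", strand="-", pas_offsets=(9,))])
    bundle = simulate_reference(cfg)
    row = bundle.annotations.iloc[0]
    g = bundle.genome[row["chrom"]]
    downstream = revcomp(g[row["start"] - 3000: row["start"]])
    assert downstream[9:15] == "AATAAA"


def test_class_mix_within_binomial_error():
    """Transduction fraction over ~2,000 insertions stays within 3 SD."""
    cfg = SimulationConfig(seed=3, chrom_length=30_000_000,
                           n_tumors=25, mean_somatic_insertions=80,
                           fraction_transduction=0.25)
    bundle = simulate_reference(cfg)
    records = simulate_insertions(cfg, bundle)
    n = len(records)
    frac = sum(r.cls in ("partnered", "orphan") for r in records) / n
    sd = (0.25 * 0.75 / n) ** 0.5
    assert abs(frac - 0.25) <= 3 * sd


def test_zero_inversion_rate_produces_none(small_cfg):
    cfg = SimulationConfig(
        seed=5, chrom_length=600_000, n_tumors=2,
        mean_somatic_insertions=25, fraction_transduction=0.5,
        sources=[SourceSpec(id=f"s{i}", inversion_rate=0.0)
                 for i in range(3)])
    bundle = simulate_reference(cfg)
    records = simulate_insertions(cfg, bundle)
    assert all(r.inversion_breakpoints is None for r in records)


def test_truth_sequence_composition(small_truth):
    for r in small_truth:
        expected = (r.l1_bp + r.internal_polya_bp + r.transduction_bp
                    + r.polya_bp)
        assert len(r.seq) == expected


def test_donor_roundtrip_recovers_reference(small_cfg, small_bundle,
                                            small_truth):
    """Removing the applied insertions (and their TSD copies) restores the
    reference chromosome exactly."""
    donors = build_donor(small_bundle.genome, small_truth, "tumor1")
    dm = donors["chr1"]
    rebuilt = []
    for seg in dm.segments:
        if seg.kind == "ref":
            chunk = dm.seq[seg.donor_start: seg.donor_end]
            rec_pos = seg.donor_start - seg.ref_offset
            rebuilt.append((rec_pos, chunk))
    genome = small_bundle.genome["chr1"]
    out = []
    prev_end = 0
    for pos, chunk in rebuilt:
        start = max(pos, prev_end)
        offset = start - pos
        out.append(chunk[offset:])
        prev_end = pos + len(chunk)
    assert "".join(out) == genome


def test_reads_deterministic(small_cfg, small_bundle, small_truth, tmp_path):
    a = tmp_path / "a.bam"
    b = tmp_path / "b.bam"
    simulate_reads(small_cfg, small_bundle, small_truth, "tumor1", a, 0)
    simulate_reads(small_cfg, small_bundle, small_truth, "tumor1", b, 0)
    with pysam.AlignmentFile(a) as fa, pysam.AlignmentFile(b) as fb:
        ra = [r.to_string() for r in fa.fetch(until_eof=True)]
        rb = [r.to_string() for r in fb.fetch(until_eof=True)]
    assert ra == rb


def test_insertion_free_sample_is_clean(small_cfg, small_bundle, small_truth,
                                        tmp_path):
    """The normal control has only proper pairs and no junction clips."""
    out = tmp_path / "n.bam"
    simulate_reads(small_cfg, small_bundle, small_truth, "normal1", out, 9)
    clipped = 0
    improper = 0
    with pysam.AlignmentFile(out) as bam:
        for read in bam.fetch(until_eof=True):
            cig = read.cigartuples or []
            if any(op in (4, 5) for op, _ in cig):
                clipped += 1
            if not read.is_proper_pair:
                improper += 1
    assert clipped == 0
    assert improper == 0


def test_junction_loci_match_truth_count(small_cfg, small_bundle, small_truth,
                                         small_bam):
    """Soft-clip hotspots in the BAM correspond 1:1 to planted insertions."""
    positions = []
    with pysam.AlignmentFile(small_bam) as bam:
        for read in bam.fetch(until_eof=True):
            cig = read.cigartuples or []
            if cig and cig[0][0] == 4 and cig[0][1] >= 10:
                positions.append(read.reference_start)
            if cig and cig[-1][0] == 4 and cig[-1][1] >= 10:
                positions.append(read.reference_end)
    hot = {p for p, n in Counter(positions).items() if n >= 3}
    truth = [r for r in small_truth if r.sample == "tumor1"]
    # collapse each insertion's two breakpoints to one locus
    loci = set()
    for r in truth:
        loci.add(r.pos)
        loci.add(r.pos + r.tsd_length)
    matched_truth = sum(
        any(abs(p - r.pos) <= 1 or abs(p - (r.pos + r.tsd_length)) <= 1
            for p in hot) for r in truth)
    assert matched_truth == len(truth)
    for p in hot:
        assert any(abs(p - x) <= 1 for x in loci), f"orphan hotspot at {p}"


def test_longread_calls_noise_free_equals_truth(small_cfg, small_truth):
    df = simulate_longread_calls(small_cfg, small_truth)
    by_id = dict(zip(df["insertion_id"], df["sequence"]))
    for r in small_truth:
        assert by_id[r.insertion_id] == r.seq


def test_longread_noise_rate_within_binomial():
    cfg = SimulationConfig(seed=5, chrom_length=600_000, n_tumors=1,
                           mean_somatic_insertions=10, basecall_error=0.01)
    bundle = simulate_reference(cfg)
    records = simulate_insertions(cfg, bundle)
    df = simulate_longread_calls(cfg, records)
    by_id = dict(zip(df["insertion_id"], df["sequence"]))
    total = diffs = 0
    for r in records:
        noisy = by_id[r.insertion_id]
        total += len(r.seq)
        diffs += sum(a != b for a, b in zip(r.seq, noisy))
    sd = (total * 0.01 * 0.99) ** 0.5
    assert abs(diffs - 0.01 * total) <= 3 * sd


def test_longread_empty_truth_empty_table(small_cfg):
    assert len(simulate_longread_calls(small_cfg, [])) == 0


def test_methylation_contrast_and_determinism(small_cfg, small_bundle):
    active = {"tumor1": {"src1", "src2"}, "normal1": set()}
    t1 = simulate_methylation(small_cfg, small_bundle, active)
    t2 = simulate_methylation(small_cfg, small_bundle, active)
    for s in t1:
        assert t1[s].equals(t2[s])
    tum = t1["tumor1"]
    # active sources (the first two elements by position) are hypomethylated
    m_active = tum[tum["pos"] <= small_bundle.annotations.iloc[1]["end"]][
        "methylated_fraction"].mean()
    m_inactive = tum[tum["pos"] > small_bundle.annotations.iloc[1]["end"]][
        "methylated_fraction"].mean()
    assert m_active < m_inactive - 0.2
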