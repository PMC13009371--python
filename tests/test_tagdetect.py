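"""Short-read tag detection: clustering, filters, merging, somatic calls,
and characterization on a small synthetic BAM."""

from dataclasses import dataclass, field

import pytest

from l1trace.params import PipelineParams
from l1trace.tagdetect import (AnchorCluster, TagHit, call_somatic,
                               cluster_anchors, detect_sample,
                               filter_clusters, merge_across_samples)


def hit(pos, mapq=60, sample="s1", source="src1", chrom="chr1"):
    return TagHit(sample=sample, source_id=source, read_id=f"r{pos}",
                  tag_mate=1, anchor_chrom=chrom, anchor_pos=pos,
                  anchor_mapq=mapq, anchor_strand="+", tag_orientation="+")


@dataclass
class Src:
    id: str
    chrom: str = "chr9"           # far from any test cluster
    start: int = 1_000_000
    end: int = 1_006_000
    similar_sites: list = field(default_factory=list)
    tag: str = "A" * 30
    tag_usable: bool = True


def test_single_linkage_clustering(params):
    clusters = cluster_anchors([hit(p) for p in (1000, 1500, 1900, 5000)],
                               params)
    assert [(c.start, c.end, c.n_anchor_reads) for c in clusters] == \
        [(1000, 1900, 3), (5000, 5000, 1)]


def test_gap_just_over_threshold_splits(params):
    clusters = cluster_anchors([hit(1000), hit(2100)], params)
    assert len(clusters) == 2  # gap 1100 > 1000


def test_low_mapq_anchor_excluded(params):
    clusters = cluster_anchors([hit(1000), hit(1100, mapq=30)], params)
    assert clusters[0].n_anchor_reads == 1


def test_filter_min_reads_and_repeat_exclusion(params):
    src = Src("src1")
    far = Src("src2", similar_sites=[("chr1", 6500, "+")])   # 5 kb away
    near = Src("src3", similar_sites=[("chr1", 3000, "+")])  # 1.5 kb away
    c_ok = AnchorCluster("s1", "src2", "chr1", 1000, 1500, 3)
    c_few = AnchorCluster("s1", "src1", "chr1", 1000, 1500, 2)
    c_rep = AnchorCluster("s1", "src3", "chr1", 1000, 1500, 5)
    filter_clusters([c_ok, c_few, c_rep], [src, far, near], params)
    assert c_ok.called
    assert not c_few.min_reads_pass
    assert not c_rep.repeat_exclusion_pass


def test_cluster_near_source_locus_excluded(params):
    src = Src("src1", chrom="chr1", start=10_000, end=16_000)
    cl = AnchorCluster("s1", "src1", "chr1", 16_500, 16_900, 8)
    filter_clusters([cl], [src], params)
    assert not cl.repeat_exclusion_pass


def _cluster(sample, source, locus, n=5):
    c = AnchorCluster(sample, source, "chr1", locus, locus + 100, n,
                      locus=locus)
    c.min_reads_pass = True
    c.repeat_exclusion_pass = True
    return c


def test_merge_same_source_within_2kb(params):
    events = merge_across_samples(
        [_cluster("s1", "src1", 10_000), _cluster("s2", "src1", 11_500)],
        params)
    assert len(events) == 1
    assert events[0].samples == ["s1", "s2"]


def test_merge_beyond_2kb_stays_separate(params):
    events = merge_across_samples(
        [_cluster("s1", "src1", 10_000), _cluster("s2", "src1", 12_500)],
        params)
    assert len(events) == 2


def test_merge_different_sources_never(params):
    events = merge_across_samples(
        [_cluster("s1", "src1", 10_000), _cluster("s2", "src2", 10_000)],
        params)
    assert len(events) == 2


def test_somatic_calling_rules(params):
    labels = {"t1": "tumor", "t2": "tumor", "n1": "normal"}
    only_t1 = merge_across_samples([_cluster("t1", "src1", 10_000)], params)
    two_tumors = merge_across_samples(
        [_cluster("t1", "src1", 20_000), _cluster("t2", "src1", 20_500)],
        params)
    with_normal = merge_across_samples(
        [_cluster("t1", "src1", 30_000), _cluster("n1", "src1", 30_200)],
        params)
    call_somatic(only_t1 + two_tumors + with_normal, labels)
    assert only_t1[0].somatic
    assert not two_tumors[0].somatic
    assert not with_normal[0].somatic


def test_unknown_sample_label_raises(params):
    events = merge_across_samples([_cluster("mystery", "src1", 1000)], params)
    with pytest.raises(ValueError, match="mystery"):
        call_somatic(events, {"t1": "tumor"})


# --- end-to-end on the small synthetic study -------------------------------


@pytest.fixture(scope="module")
def small_clusters(small_bam, small_catalog, small_bundle, params):
    return detect_sample(small_bam, small_catalog, "tumor1",
                         small_bundle.genome, params)


def test_detection_recovers_planted_events(small_clusters, small_truth):
    truth = [r for r in small_truth
             if r.sample == "tumor1" and r.cls in ("partnered", "orphan")]
    called = [c for c in small_clusters if c.called]
    assert len(truth) > 0
    for r in truth:
        assert any(c.source_id == r.source_id and c.chrom == r.chrom
                   and abs(c.locus - r.pos) <= 2000 for c in called), \
            f"planted event {r.insertion_id} not recovered"


def test_no_spurious_calls_beyond_truth(small_clusters, small_truth):
    truth = [r for r in small_truth
             if r.sample == "tumor1" and r.cls in ("partnered", "orphan")]
    called = [c for c in small_clusters if c.called]
    assert len(called) == len(truth)


def _nearest_truth(cluster, truth_records):
    return min((r for r in truth_records
                if r.chrom == cluster.chrom
                and r.source_id == cluster.source_id),
               key=lambda r: abs(cluster.locus - r.pos))


def test_breakpoints_and_tsd_match_truth(small_clusters, small_truth):
    truth = [r for r in small_truth
             if r.sample == "tumor1" and r.cls in ("partnered", "orphan")]
    for c in (c for c in small_clusters if c.called):
        r = _nearest_truth(c, truth)
        h = c.hallmarks
        assert h.breakpoint_a is not None
        assert abs(h.breakpoint_a - r.pos) <= 1
        assert abs(h.tsd_length - r.tsd_length) <= 1
        assert h.orientation == r.orientation


def test_planted_en_site_scores_as_cut_site(small_clusters, small_truth):
    truth = [r for r in small_truth
             if r.sample == "tumor1" and r.cls in ("partnered", "orphan")]
    seen = 0
    for c in (c for c in small_clusters if c.called):
        r = _nearest_truth(c, truth)
        if r.en_planted:
            seen += 1
            assert c.hallmarks.en_score >= 6
    # the fixture seed plants at least one consensus cut site
    assert seen >= 1 or not any(r.en_planted for r in truth)
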