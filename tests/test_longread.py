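"""Long-read insertion annotation: classification, source assignment,
dual polyA, inversions, proxies and cascades on constructed fixtures."""

from dataclasses import dataclass, field

import numpy as np
import pytest

from l1trace._util import revcomp
from l1trace.longread import (InsertionCall, assign_source, classify_insertion,
                              detect_dual_polya, detect_inversion,
                              resolve_proxy, resolve_cascade)
from l1trace.params import PipelineParams

from conftest import random_dna


@dataclass
class Src:
    id: str
    downstream_seq: str
    proxy_of: str | None = None
    chrom: str = "chr1"
    start: int = 0
    end: int = 0


@pytest.fixture(scope="module")
def consensus():
    return random_dna(np.random.default_rng(51), 6000)


@pytest.fixture(scope="module")
def downstream():
    return random_dna(np.random.default_rng(52), 3100)


def test_partnered_fixture(consensus, downstream, params):
    seq = consensus[-500:] + downstream[:80] + "A" * 30
    call = classify_insertion(seq, consensus, params)
    assert call.cls == "partnered"
    assert abs(call.l1_bp - 500) <= 5
    assert abs(call.transduction_bp - 80) <= 5
    # adjacent A's in the transduced segment make the tract boundary
    # ambiguous by a few bases
    assert abs(call.polya_bp - 30) <= 5


def test_orphan_fixture(consensus, downstream, params):
    call = classify_insertion(downstream[:80] + "A" * 30, consensus, params)
    assert call.cls == "orphan"
    assert call.l1_bp == 0


def test_solo_fixture(consensus, params):
    call = classify_insertion(consensus[-1200:] + "A" * 25, consensus, params)
    assert call.cls == "solo"
    assert call.transduction_bp == 0


def test_minus_strand_sequence_is_normalized(consensus, downstream, params):
    seq = revcomp(consensus[-500:] + downstream[:80] + "A" * 30)
    call = classify_insertion(seq, consensus, params)
    assert call.cls == "partnered"
    assert call.orientation == "-"


def test_full_length_flag_threshold(consensus, params):
    call = classify_insertion(consensus + "A" * 30, consensus, params)
    assert call.total_length > params.somatic_full_length_min
    assert call.full_length
    short = classify_insertion(consensus[-3000:] + "A" * 30, consensus, params)
    assert not short.full_length


def test_assign_source_and_endpoint(consensus, downstream, params):
    """A segment matching 9-89 bp downstream is assigned with transduction
    length 89 (measured from the source 3' end)."""
    other = Src("far", random_dna(np.random.default_rng(53), 3100))
    near = Src("near", downstream)
    call = classify_insertion(downstream[9:89] + "A" * 20, consensus, params)
    call = assign_source(call, [near, other], params)
    assert call.assign_status == "assigned"
    assert call.source_id == "near"
    assert call.endpoint == 89
    assert call.transduction_bp == 89


def test_assign_far_match_is_unassigned(consensus, params):
    rng = np.random.default_rng(54)
    long_flank = random_dna(rng, 6000)
    src = Src("s", long_flank[:3100])  # window covers only the first 3 kbp
    segment = long_flank[5000:5200]    # matches 5 kbp downstream
    call = classify_insertion(segment + "A" * 20, consensus, params)
    call = assign_source(call, [src], params)
    assert call.assign_status == "unassigned"
    assert call.source_id is None


def test_assign_identical_windows_ambiguous(consensus, downstream, params):
    twin_a = Src("a", downstream)
    twin_b = Src("b", downstream)
    call = classify_insertion(downstream[:120] + "A" * 20, consensus, params)
    call = assign_source(call, [twin_a, twin_b], params)
    assert call.assign_status == "ambiguous"
    assert call.source_id is None


def test_dual_polya_detection(consensus, downstream, params):
    dual = consensus[-400:] + "A" * 20 + downstream[:80] + "A" * 25
    single = consensus[-400:] + downstream[:80] + "A" * 25
    weak = consensus[-400:] + "A" * 5 + downstream[:80] + "A" * 25
    assert detect_dual_polya(classify_insertion(dual, consensus, params),
                             params)
    assert not detect_dual_polya(classify_insertion(single, consensus,
                                                    params), params)
    assert not detect_dual_polya(classify_insertion(weak, consensus, params),
                                 params)


def test_inversion_detected_with_breakpoints(consensus, params):
    """5' 400 bp reverse-complemented + forward 3' piece: twin priming."""
    c2 = len(consensus) - 1000
    c1 = c2 - 400
    seq = revcomp(consensus[c1:c2]) + consensus[c2:] + "A" * 20
    present, bps = detect_inversion(seq, consensus, params=params)
    assert present
    junction, terminus = bps
    assert abs(junction - 1000) <= 5
    assert abs(terminus - 1400) <= 5


def test_uninverted_has_no_inversion(consensus, params):
    present, bps = detect_inversion(consensus[-1500:] + "A" * 20, consensus,
                                    params=params)
    assert not present and bps is None


def test_orphan_inversion_in_downstream_coordinates(consensus, downstream,
                                                    params):
    seq = revcomp(downstream[100:300]) + downstream[300:420] + "A" * 20
    present, bps = detect_inversion(seq, consensus,
                                    reference_window=downstream[:3000],
                                    params=params)
    assert present
    assert min(bps) <= 310  # breakpoints reported in downstream coordinates


def _call(source_id, somatic=True, cls="partnered", trans=""):
    c = InsertionCall(insertion_id=f"i-{source_id}", sample="t1",
                      cls=cls, source_id=source_id, somatic=somatic)
    c._trans_seq = trans
    return c


def test_proxy_reassignment_and_idempotence():
    catalog = [Src("T", "", proxy_of="S"), Src("S", "")]
    calls = [_call("T"), _call("S")]
    resolve_proxy(calls, catalog)
    assert calls[0].source_id == "S" and calls[0].proxy_reassigned
    assert calls[1].source_id == "S" and not calls[1].proxy_reassigned
    resolve_proxy(calls, catalog)  # idempotent
    assert calls[0].source_id == "S"


def test_proxy_chain_raises():
    catalog = [Src("T", "", proxy_of="S"), Src("S", "", proxy_of="U"),
               Src("U", "")]
    with pytest.raises(ValueError, match="chain"):
        resolve_proxy([], catalog)


def test_cascade_links_child_to_parent_and_grandparent_source(params):
    rng = np.random.default_rng(60)
    ref = {"chr1": random_dna(rng, 20_000)}
    s_down = random_dna(rng, 300)
    catalog = [Src("S", s_down)]
    parent = _call("S", somatic=False)
    parent.insertion_id = "parent"
    parent.chrom, parent.pos = "chr1", 5000
    child = _call(None, somatic=True,
                  trans=s_down[:120] + "A" * 20 + ref["chr1"][5000:5150])
    child.insertion_id = "child"
    calls = resolve_cascade([parent, child], catalog, ref, params)
    assert calls[1].cascade_parent == "parent"
    assert calls[1].source_id == "S"


def test_cascade_partial_evidence_links_parent_only(params):
    rng = np.random.default_rng(61)
    ref = {"chr1": random_dna(rng, 20_000)}
    catalog = [Src("S", random_dna(rng, 300))]
    parent = _call("S", somatic=False)
    parent.insertion_id = "parent"
    parent.chrom, parent.pos = "chr1", 5000
    child = _call(None, somatic=True,
                  trans=random_dna(rng, 80) + ref["chr1"][5000:5120])
    calls = resolve_cascade([parent, child], catalog, ref, params)
    assert calls[1].cascade_parent == "parent"
    assert calls[1].source_id == "parent"


def test_component_conservation_noise_free(consensus, downstream, params):
    """l1 + transduction + polyA components reconstruct the total length."""
    fixtures = [
        consensus[-800:] + downstream[:120] + "A" * 30,
        consensus[-2000:] + "A" * 18 + downstream[:60] + "A" * 22,
        downstream[:200] + "A" * 40,
        consensus[-1500:] + "A" * 25,
    ]
    for seq in fixtures:
        c = classify_insertion(seq, consensus, params)
        total = c.l1_bp + c.transduction_bp + c.internal_polya_bp + c.polya_bp
        assert abs(total - len(seq)) <= 5
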