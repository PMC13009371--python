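"""Source catalog: tag extraction, approximate-hit counting, similar sites."""

import numpy as np
import pandas as pd
import pytest

from l1trace._util import revcomp
from l1trace.catalog import (build_catalog, count_approximate_hits,
                             find_similar_sites)
from l1trace.params import PipelineParams

from conftest import random_dna


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(21)
    elem = random_dna(rng, 6000)
    g = random_dna(rng, 4000) + elem + random_dna(rng, 4000)
    return {"chr1": g}, 4000, 10000  # genome, element start, element end


def test_plus_strand_tag_is_downstream_30mer(toy_genome, params):
    genome, s, e = toy_genome
    cat = build_catalog(genome, bed([("chr1", s, e, "L1", 0, "+")]),
                        params=params, check_uniqueness=False)
    assert cat[0].tag == genome["chr1"][e: e + 30].upper()
    assert cat[0].is_full_length


def test_minus_strand_tag_is_revcomp_upstream(toy_genome, params):
    genome, s, e = toy_genome
    cat = build_catalog(genome, bed([("chr1", s, e, "L1", 0, "-")]),
                        params=params, check_uniqueness=False)
    assert cat[0].tag == revcomp(genome["chr1"][s - 30: s]).upper()


def test_tag_extraction_strand_involution(toy_genome, params):
    """Reverse-complementing the genome and flipping strand labels yields
    the identical tag."""
    genome, s, e = toy_genome
    g = genome["chr1"]
    flipped = {"chr1": revcomp(g)}
    n = len(g)
    cat_f = build_catalog(genome, bed([("chr1", s, e, "L1", 0, "+")]),
                          params=params, check_uniqueness=False)
    cat_r = build_catalog(flipped, bed([("chr1", n - e, n - s, "L1", 0, "-")]),
                          params=params, check_uniqueness=False)
    assert cat_f[0].tag == cat_r[0].tag


def test_truncated_element_not_full_length(toy_genome, params):
    genome, s, _ = toy_genome
    cat = build_catalog(genome, bed([("chr1", s, s + 5000, "T", 0, "+")]),
                        params=params, check_uniqueness=False)
    assert not cat[0].is_full_length
    assert cat[0].tag is None  # excluded from tag detection


def test_out_of_bounds_interval_raises(toy_genome, params):
    genome, _, _ = toy_genome
    with pytest.raises(ValueError, match="bad"):
        build_catalog(genome, bed([("chr1", 0, 10 ** 7, "bad", 0, "+")]),
                      params=params, check_uniqueness=False)


def naive_hit_count(tag, genome, max_edits):
    """Sliding-window edlib oracle: O(L) prefix alignments per strand."""
    import edlib
    total = 0
    L = len(tag)
    for seq in (genome, revcomp(genome)):
        hits = []
        for i in range(len(seq) - L + max_edits + 1):
            window = seq[i: i + L + max_edits]
            res = edlib.align(tag, window, mode="SHW", k=max_edits)
            if res["editDistance"] != -1:
                hits.append(i)
        last = None
        for h in hits:
            if last is None or h - last >= L:
                total += 1
                last = h
    return total


def test_count_hits_single_planted_tag():
    rng = np.random.default_rng(33)
    tag = random_dna(rng, 30)
    g = random_dna(rng, 100_000)
    g = g[:50_000] + tag + g[50_000:]
    assert count_approximate_hits(tag, {"chr1": g}, 3) >= 1


def test_count_hits_agrees_with_naive_oracle():
    rng = np.random.default_rng(34)
    g = random_dna(rng, 30_000)
    # plant one exact copy, one 2-edit copy, one 4-edit copy
    tag = random_dna(rng, 30)
    near = tag[:10] + "A" + tag[11:28] + "C" + tag[29:]
    far = list(tag)
    for i in (2, 9, 16, 23):
        far[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[far[i]]
    g = tag + g[:10_000] + near + g[10_000:20_000] + "".join(far) \
        + g[20_000:]
    ours = count_approximate_hits(tag, {"chr1": g}, 3)
    oracle = naive_hit_count(tag, g, 3)
    assert ours == oracle
    assert ours >= 2  # the exact and the 2-edit copy at minimum


def test_overabundant_tag_excluded(params):
    """A tag occurring at >1000 loci fails the uniqueness filter."""
    rng = np.random.default_rng(35)
    tag = random_dna(rng, 30)
    spacer = random_dna(rng, 40)
    g = spacer.join([tag] * 1100) + random_dna(rng, 5000)
    count = count_approximate_hits(tag, {"chr1": g}, params.tag_hit_max_edits)
    assert count > params.tag_max_genomic_hits


def test_all_n_tag_counts_zero():
    assert count_approximate_hits("N" * 30, {"chr1": "ACGT" * 100}, 3) == 0


def test_similar_sites_hamming_threshold():
    rng = np.random.default_rng(36)
    tag = random_dna(rng, 30)
    four = list(tag)
    seven = list(tag)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for i in (1, 8, 15, 22):
        four[i] = flip[four[i]]
    for i in (1, 5, 9, 13, 17, 21, 25):
        seven[i] = flip[seven[i]]
    g = random_dna(rng, 5000) + "".join(four) + random_dna(rng, 5000) \
        + "".join(seven) + random_dna(rng, 5000)
    sites = find_similar_sites(tag, {"chr1": g}, 6)
    assert [s[1] for s in sites] == [5000]  # only the 4-mismatch copy
    assert find_similar_sites(tag, {"chr1": random_dna(rng, 5000)}, 6) == []


def test_similar_sites_found_on_minus_strand():
    rng = np.random.default_rng(37)
    tag = random_dna(rng, 30)
    g = random_dna(rng, 2000) + revcomp(tag) + random_dna(rng, 2000)
    sites = find_similar_sites(tag, {"chr1": g}, 6)
    assert ("chr1", 2000, "-") in sites
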