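"""Promoter-window aggregation, element filters, activity classes, tests."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from l1trace.methylation import (classify_activity, filter_elements,
                                 load_methylation_table, summarize_all,
                                 window_average)
from l1trace.methylation import test_association as association_test
from l1trace.params import PipelineParams


@dataclass
class El:
    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    provenance: str = "reference"
    allele_status: str = "fixed"


def frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "coverage",
                                       "methylated_fraction"])


def test_window_average_coverage_filter_and_min_cpgs(params):
    el = El("e1", "chr1", 1000, 7000)  # '+': window [900, 1100)
    records = frame([
        ("s1", "chr1", 950, 2, 0.9),    # below min coverage
        ("s1", "chr1", 960, 10, 0.8),
        ("s1", "chr1", 970, 20, 0.6),
        ("s1", "chr1", 980, 100, 0.1),  # above max coverage
    ])
    s = window_average(records, el, params)
    assert s.n_cpgs_used == 2
    assert s.avg_methylation == pytest.approx(70.0)
    assert not s.included  # needs >= 3 CpGs


def test_window_average_three_cpgs_included(params):
    el = El("e1", "chr1", 1000, 7000)
    records = frame([("s1", "chr1", p, 10, 0.5) for p in (950, 990, 1050)])
    s = window_average(records, el, params)
    assert s.included and s.avg_methylation == pytest.approx(50.0)


def test_window_average_empty_window(params):
    el = El("e1", "chr1", 50_000, 56_000)
    s = window_average(frame([("s1", "chr1", 10, 10, 0.5)]), el, params)
    assert s.n_cpgs_used == 0 and s.avg_methylation is None
    assert not s.included


def test_window_average_minus_strand_uses_element_5prime(params):
    el = El("e1", "chr1", 1000, 7000, strand="-")  # 5' end at 7000
    records = frame([("s1", "chr1", p, 10, 0.4) for p in (6950, 7010, 7080)])
    s = window_average(records, el, params)
    assert s.n_cpgs_used == 3


def test_window_average_deduplicates_and_ignores_order(params):
    el = El("e1", "chr1", 1000, 7000)
    rows = [("s1", "chr1", p, 10, 0.5) for p in (950, 990, 1050)]
    dup = frame(rows + rows[:1])
    rev = frame(rows[::-1])
    assert window_average(dup, el, params).avg_methylation == \
        window_average(rev, el, params).avg_methylation


def test_load_normalizes_percent_scale(tmp_path):
    path = tmp_path / "m.tsv"
    frame([("s1", "chr1", 5, 10, 85.0)]).to_csv(path, sep="\t", index=False)
    df = load_methylation_table(path)
    assert df["methylated_fraction"].iloc[0] == pytest.approx(0.85)


def test_filter_elements_sample_fraction_and_autosome(params):
    els = [El("keep", "chr1", 1000, 7000), El("drop", "chr1", 50000, 56000),
           El("sexchr", "chrX", 1000, 7000)]
    rows = []
    for i in range(12):
        for el, frac_included in (("keep", 9), ("drop", 8), ("sexchr", 12)):
            rows.append({"element_id": el, "sample": f"s{i}",
                         "n_cpgs_used": 5, "avg_methylation": 50.0,
                         "included": i < frac_included})
    kept = filter_elements(pd.DataFrame(rows), els, params)
    assert kept == ["keep"]  # 9/12 = 75% passes; 8/12 fails; chrX excluded


def test_classify_activity_bands(params):
    counts = {"a": 17, "b": 4, "c": 2, "d": 0, "e": 0}
    pas = {"e": "weak", "d": "strong"}
    cls = classify_activity(counts, pas, params)
    assert cls == {"a": "active", "b": "active", "c": "minor",
                   "d": "inactive", "e": "inactive_weak_pas"}


def _planted_summaries(rng, n_samples=30, gap=40.0):
    """Element-sample methylation with a planted active/inactive gap."""
    rows, counts = [], []
    for el, active in (("hot", True), ("cold", False)):
        for i in range(n_samples):
            is_pos = active and i < n_samples // 2
            mean = 75.0 - gap if is_pos else 75.0
            rows.append({"element_id": el, "sample": f"s{i}",
                         "n_cpgs_used": 6,
                         "avg_methylation": float(rng.normal(mean, 10)),
                         "included": True})
            counts.append({"element_id": el, "sample": f"s{i}",
                           "count": int(is_pos) * int(rng.integers(1, 4))})
    return pd.DataFrame(rows), pd.DataFrame(counts)


def test_association_detects_planted_gap(params):
    summaries, counts = _planted_summaries(np.random.default_rng(8))
    res = association_test(summaries, counts, params)
    w = res["welch"]
    assert w["p"] < 1e-3
    assert w["difference"] < 0  # positive samples are hypomethylated
    r = res["per_element"]["hot"]["r"]
    assert r is not None and r < 0


def test_association_identical_groups_near_one(params):
    rows, counts = [], []
    for i in range(20):
        rows.append({"element_id": "e", "sample": f"s{i}", "n_cpgs_used": 5,
                     "avg_methylation": 50.0 + (i % 2), "included": True})
        counts.append({"element_id": "e", "sample": f"s{i}",
                       "count": i % 2})
    res = association_test(pd.DataFrame(rows), pd.DataFrame(counts), params)
    w = res["welch"]
    assert abs(w["difference"]) <= 1.0


def test_association_degenerate_reported(params):
    rows = [{"element_id": "e", "sample": "s0", "n_cpgs_used": 5,
             "avg_methylation": 50.0, "included": True}]
    counts = [{"element_id": "e", "sample": "s0", "count": 1}]
    res = association_test(pd.DataFrame(rows), pd.DataFrame(counts), params)
    assert res["welch"]["p"] is None and res["welch"]["reason"]
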