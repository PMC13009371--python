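"""End-to-end orchestration of the synthetic study and analysis stages.

``run_synthetic_study`` wires the whole pipeline together on generated
data: reference + catalog -> per-sample short-read detection -> long-read
annotation -> PAS endpoint association -> inversion clustering ->
methylation association -> per-source summaries.  It is the engine behind
the ``run-all`` CLI command, the worked example and the reproduction
script; every stage is also callable on its own with real inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import report
from .catalog import SourceL1, build_catalog
from .inversions import cluster_breakpoints
from .longread import InsertionCall, annotate_calls
from .methylation import classify_activity, summarize_all, test_association
from .params import PipelineParams
from .pas import build_default_pwm, scan_sequence, associate_endpoints
from .sim import (SimulationConfig, simulate_insertions, simulate_longread_calls,
                  simulate_methylation, simulate_reads, simulate_reference)
from .sim.reads import count_tag_support
from .tagdetect import run_short_read_detection

__all__ = ["StudyResult", "run_synthetic_study"]


@dataclass
class StudyResult:
    cfg: SimulationConfig
    params: PipelineParams
    bundle: object
    truth: list
    catalog: list[SourceL1]
    sample_sheet: pd.DataFrame
    clusters: list
    events: list
    tag_support: dict[str, dict[str, int]]
    longread_calls: list[InsertionCall]
    endpoint_associations: list
    inversion_clusters: list
    methylation_stats: dict | None
    source_table: list

    def somatic_events(self):
        return [e for e in self.events if e.somatic]


def run_synthetic_study(
    cfg: SimulationConfig,
    params: PipelineParams | None = None,
    workdir: str | Path = ".",
    short_reads: bool = True,
    methylation: bool = True,
) -> StudyResult:
    """Generate a seeded synthetic study and run every analysis stage."""
    p = params or PipelineParams()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_reference(cfg)
    truth = simulate_insertions(cfg, bundle)
    pwm = build_default_pwm()
    catalog = build_catalog(bundle.genome, bundle.annotations, params=p, pwm=pwm)

    # --- short-read arm ---
    clusters, events = [], []
    support: dict[str, dict[str, int]] = {}
    rows = []
    if short_reads:
        for i, sample in enumerate(cfg.sample_names):
            bam = workdir / f"{sample}.bam"
            simulate_reads(cfg, bundle, truth, sample, bam, sample_index=i)
            rows.append({"sample": sample, "path": str(bam),
                         "label": cfg.sample_labels[sample]})
            support[sample] = count_tag_support(
                bam, [r for r in truth if r.sample == sample], bundle,
                tag_length=p.tag_length, min_mapq=p.anchor_min_mapq)
        sheet = pd.DataFrame(rows)
        clusters, events = run_short_read_detection(sheet, catalog,
                                                    bundle.genome, p)
    else:
        sheet = pd.DataFrame(columns=["sample", "path", "label"])

    # --- long-read arm ---
    calls_df = simulate_longread_calls(cfg, truth)
    lr_calls = annotate_calls(
        calls_df.to_dict("records"),
        dict(zip(calls_df["insertion_id"], calls_df["sequence"])),
        catalog, bundle.consensus, bundle.genome, p)

    # --- PAS association (per source, downstream coordinates) ---
    associations = []
    for src in catalog:
        endpoints = [(c.insertion_id, c.endpoint) for c in lr_calls
                     if c.source_id == src.id and c.endpoint is not None]
        if not endpoints:
            continue
        scan_len = max(e for _, e in endpoints) + 50
        hits = scan_sequence(pwm, src.downstream_seq[:scan_len],
                             min_report_score=0.0, params=p)
        associations.extend(associate_endpoints(endpoints, hits, p))

    # --- 5' inversion breakpoint clustering ---
    points = []
    for c in lr_calls:
        if c.inversion and c.inversion_breakpoints:
            points.extend(c.inversion_breakpoints)
    inv_clusters = (cluster_breakpoints(points, p.inversion_bandwidth)
                    if points else [])

    # --- methylation ---
    meth_stats = None
    if methylation:
        pos_counts: dict[str, dict[str, int]] = {}
        for c in lr_calls:
            if c.somatic and c.source_id and c.cls != "solo":
                pos_counts.setdefault(c.source_id, {})
                pos_counts[c.source_id][c.sample] = \
                    pos_counts[c.source_id].get(c.sample, 0) + 1
        active_by_sample: dict[str, set[str]] = {
            s: set() for s in cfg.sample_names}
        for src_id, per_sample in pos_counts.items():
            for sample in per_sample:
                active_by_sample.setdefault(sample, set()).add(src_id)
        tables = simulate_methylation(cfg, bundle, active_by_sample)
        summaries = summarize_all(tables, catalog, p)
        counts = pd.DataFrame(
            [{"element_id": sid, "sample": sm, "count": n}
             for sid, per in pos_counts.items() for sm, n in per.items()],
            columns=["element_id", "sample", "count"])
        meth_stats = test_association(summaries, counts, p)
        meth_stats["summaries"] = summaries

    source_table = report.per_source_table(
        [c for c in lr_calls if c.somatic])
    return StudyResult(
        cfg=cfg, params=p, bundle=bundle, truth=truth, catalog=catalog,
        sample_sheet=sheet, clusters=clusters, events=events,
        tag_support=support, longread_calls=lr_calls,
        endpoint_associations=associations, inversion_clusters=inv_clusters,
        methylation_stats=meth_stats, source_table=source_table)


def detection_metrics(result: StudyResult) -> dict:
    """Truth-based recall/precision metrics of the short-read arm.

    Recall is computed over somatic transduction events with ≥3 supporting
    tag pairs in the emitted reads (counted by direct read scan); a truth
    event is recovered when a called somatic event of the same source lies
    within 2 kbp of it.  Source accuracy is the fraction of called somatic
    events matching a truth event of the same source at their locus.
    """
    called = result.somatic_events()
    truth_events = [r for r in result.truth
                    if r.somatic and r.cls in ("partnered", "orphan")]
    support = result.tag_support

    def supported(r):
        return support.get(r.sample, {}).get(r.insertion_id, 0) >= 3

    eligible = [r for r in truth_events if supported(r)]
    recovered = 0
    for r in eligible:
        for ev in called:
            if (ev.source_id == r.source_id and ev.chrom == r.chrom
                    and abs(ev.locus - r.pos) <= 2000):
                recovered += 1
                break
    correct_src = 0
    for ev in called:
        for r in truth_events:
            if ev.chrom == r.chrom and abs(ev.locus - r.pos) <= 2000:
                correct_src += ev.source_id == r.source_id
                break
    return {
        "n_truth_transductions": len(truth_events),
        "n_eligible": len(eligible),
        "n_called_somatic": len(called),
        "recall": recovered / len(eligible) if eligible else float("nan"),
        "source_accuracy": correct_src / len(called) if called else
        float("nan"),
    }


def hallmark_metrics(result: StudyResult) -> dict:
    """Truth-based hallmark recovery of characterized somatic events."""
    truth_by_locus = {}
    for r in result.truth:
        if r.somatic and r.cls in ("partnered", "orphan"):
            truth_by_locus[(r.sample, r.chrom)] = \
                truth_by_locus.get((r.sample, r.chrom), []) + [r]
    tsd_ok = tsd_n = 0
    polya_ok = polya_n = 0
    en_ok = en_n = 0
    for ev in result.somatic_events():
        cl = ev.clusters[0]
        h = cl.hallmarks
        if h is None:
            continue
        match = None
        for r in truth_by_locus.get((cl.sample, cl.chrom), []):
            if abs(cl.locus - r.pos) <= 2000:
                match = r
                break
        if match is None:
            continue
        if h.tsd_length is not None:
            tsd_n += 1
            tsd_ok += abs(h.tsd_length - match.tsd_length) <= 2
        if match.polya_bp >= 15:
            polya_n += 1
            polya_ok += h.polya_present
        if match.en_planted:
            en_n += 1
            en_ok += bool(h.en_cut_site)
    return {
        "tsd_within_2bp": tsd_ok / tsd_n if tsd_n else float("nan"),
        "polya_detected": polya_ok / polya_n if polya_n else float("nan"),
        "en_detected": en_ok / en_n if en_n else float("nan"),
        "n_tsd": tsd_n, "n_polya": polya_n, "n_en": en_n,
    }
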