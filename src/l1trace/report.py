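"""Cohort summary statistics over annotated insertion calls.

Per-source summary tables (counts, median insertion length, median L1
content, 5' inversion and orphan rates, modal unique-sequence length),
the solo-vs-transduction activity correlation, Kruskal–Wallis insertion
length tests with optional inversion stratification, and relative activity
(somatic transductions per sample in the detection set).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SourceSummary", "per_source_table", "correlate_activity",
    "length_tests", "relative_activity",
]


@dataclass
class SourceSummary:
    source_id: str
    n_somatic: int
    median_length: float
    median_l1_content_pct: float
    inversion_rate_pct: float
    orphan_rate_pct: float
    mode_unique_bp: int | None      # None when all unique lengths distinct
    mode_count: int | None


def _mode_smallest(values: list[int]) -> tuple[int | None, int | None]:
    """Most frequent value (ties -> smallest); None when all are distinct."""
    if not values:
        return None, None
    counts = Counter(values)
    top = max(counts.values())
    if top == 1:
        return None, None
    return min(v for v, c in counts.items() if c == top), top


def per_source_table(calls) -> list[SourceSummary]:
    """Table-style per-source summary of somatic transduction calls.

    ``calls`` is an iterable of annotated insertion calls (source_id,
    total_length, l1_content_pct, inversion, cls, transduction_bp).  Only
    somatic calls with an assigned source are counted; each call belongs to
    exactly one row.
    """
    by_source: dict[str, list] = {}
    for c in calls:
        if c.source_id is not None and c.somatic:
            by_source.setdefault(c.source_id, []).append(c)
    out = []
    for source_id in sorted(by_source):
        group = by_source[source_id]
        lengths = [c.total_length for c in group]
        uniq = [c.transduction_bp for c in group if c.transduction_bp > 0]
        mode, mode_n = _mode_smallest(uniq)
        out.append(SourceSummary(
            source_id=source_id,
            n_somatic=len(group),
            median_length=float(np.median(lengths)),
            median_l1_content_pct=float(np.median(
                [c.l1_content_pct for c in group])),
            inversion_rate_pct=100.0 * sum(c.inversion for c in group)
            / len(group),
            orphan_rate_pct=100.0 * sum(c.cls == "orphan" for c in group)
            / len(group),
            mode_unique_bp=mode, mode_count=mode_n))
    return out


def correlate_activity(
    solo_counts: list[int], transduction_counts: list[int],
) -> dict:
    """Two-sided Pearson correlation of per-sample counts."""
    if len(solo_counts) != len(transduction_counts):
        raise ValueError("count vectors must have equal length")
    if len(solo_counts) < 3:
        raise ValueError("need at least 3 samples")
    x = np.asarray(solo_counts, float)
    y = np.asarray(transduction_counts, float)
    if x.std() == 0 or y.std() == 0:
        return {"r": None, "p": None, "reason": "zero variance in one vector"}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "reason": None}


def length_tests(
    groups: dict[str, list[float]],
    inversion_status: dict[str, list[bool]] | None = None,
) -> dict:
    """Kruskal–Wallis rank test of insertion lengths across groups.

    With ``inversion_status`` the test is additionally run within the
    inverted and non-inverted strata.  Groups with fewer than 2 members are
    skipped (reported); fewer than 2 usable groups raises.  Tie-corrected
    chi-square approximation (scipy).
    """
    def _run(gdict):
        usable = {k: v for k, v in gdict.items() if len(v) >= 2}
        skipped = sorted(set(gdict) - set(usable))
        if len(usable) < 2:
            raise ValueError("need >=2 groups with >=2 members")
        h, p = stats.kruskal(*usable.values())
        return {"H": float(h), "p": float(p),
                "medians": {k: float(np.median(v)) for k, v in usable.items()},
                "skipped_groups": skipped}

    out = {"overall": _run(groups)}
    if inversion_status is not None:
        for label, flag in (("inverted", True), ("non_inverted", False)):
            strat = {}
            for k, lengths in groups.items():
                flags = inversion_status.get(k, [])
                sel = [x for x, f in zip(lengths, flags) if f is flag]
                if sel:
                    strat[k] = sel
            try:
                out[label] = _run(strat)
            except ValueError as exc:
                out[label] = {"H": None, "p": None, "reason": str(exc)}
    return out


def relative_activity(
    event_counts: dict[tuple[str, str], int],
    n_samples: dict[str, int],
) -> pd.DataFrame:
    """Somatic transductions per source per dataset, scaled by sample count.

    ``event_counts`` maps (source id, dataset) -> number of somatic events;
    ``n_samples`` maps dataset -> samples used in detection.
    """
    rows = []
    for (source_id, dataset), n in sorted(event_counts.items()):
        total = n_samples[dataset]
        if total <= 0:
            raise ValueError(f"dataset {dataset} has no samples")
        rows.append({"source_id": source_id, "dataset": dataset,
                     "n_events": n, "n_samples": total,
                     "relative_activity": n / total})
    return pd.DataFrame(
        rows, columns=["source_id", "dataset", "n_events", "n_samples",
                       "relative_activity"])
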