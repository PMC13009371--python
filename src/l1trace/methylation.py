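"""Promoter methylation aggregation and activity association.

L1 retrotransposition is licensed by promoter hypomethylation.  For each
catalogued source element this module averages per-CpG methylation over the
200-bp window centred on the element's 5' end (100 bp inside, 100 bp
outside, in element orientation), applies the inclusion filters (CpG
coverage 3–75 reads; ≥3 usable CpGs; element present in ≥75% of samples;
autosomal, reference, fixed elements only), classifies per-element activity
from transduction-positive sample counts (active: ≥4 samples; minor: 1–3;
inactive: 0, with a weak-internal-PAS subclass), and tests the
methylation–activity association (per-element Pearson correlation with
Fisher-z CI; pooled two-sided Welch's t-test).

Input records follow a bedMethyl-like TSV dialect with explicit columns
``sample, chrom, pos, coverage, methylated_fraction`` (0-based positions;
fractions in [0, 1], percentages normalized at load).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import PipelineParams

__all__ = [
    "MethylationSummary", "load_methylation_table", "window_average",
    "summarize_all", "filter_elements", "classify_activity",
    "test_association",
]

REQUIRED_COLUMNS = ["sample", "chrom", "pos", "coverage", "methylated_fraction"]


@dataclass
class MethylationSummary:
    element_id: str
    sample: str
    n_cpgs_used: int
    avg_methylation: float | None  # percent, 0–100; None when no CpGs used
    included: bool


def load_methylation_table(path) -> pd.DataFrame:
    """Read a bedMethyl-like TSV; percent-scale fractions are normalized."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"methylation table missing column(s): {missing}")
    frac = df["methylated_fraction"].astype(float)
    if (frac > 1).any():
        frac = frac / 100.0
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("methylated_fraction outside [0, 1] after normalization")
    df = df.copy()
    df["methylated_fraction"] = frac
    return df


def _promoter_window(element, halfwidth: int) -> tuple[int, int]:
    """200-bp window on the element's 5' end, in element orientation."""
    if element.strand == "+":
        five_prime = element.start
    else:
        five_prime = element.end
    return five_prime - halfwidth, five_prime + halfwidth


def window_average(
    records: pd.DataFrame, element, params: PipelineParams | None = None,
) -> MethylationSummary:
    """Average methylation (percent) of coverage-filtered CpGs in the
    element's promoter window for one sample's records."""
    p = params or PipelineParams()
    lo, hi = _promoter_window(element, p.meth_window_halfwidth)
    sub = records[(records["chrom"] == element.chrom)
                  & (records["pos"] >= lo) & (records["pos"] < hi)]
    # duplicate calls for one CpG collapse to a single record
    sub = sub.drop_duplicates(subset=["sample", "chrom", "pos"])
    sub = sub[(sub["coverage"] >= p.meth_cov_min)
              & (sub["coverage"] <= p.meth_cov_max)]
    n = len(sub)
    sample = records["sample"].iloc[0] if len(records) else ""
    avg = float(sub["methylated_fraction"].mean() * 100.0) if n else None
    return MethylationSummary(
        element_id=element.id, sample=sample, n_cpgs_used=n,
        avg_methylation=avg, included=n >= p.meth_min_cpgs)


def summarize_all(
    tables: dict[str, pd.DataFrame], elements, params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Per (element, sample) summaries as a tidy frame."""
    p = params or PipelineParams()
    rows = []
    for sample, df in tables.items():
        for el in elements:
            s = window_average(df, el, p)
            rows.append({"element_id": el.id, "sample": sample,
                         "n_cpgs_used": s.n_cpgs_used,
                         "avg_methylation": s.avg_methylation,
                         "included": s.included})
    return pd.DataFrame(rows)


def filter_elements(
    summaries: pd.DataFrame, elements, params: PipelineParams | None = None,
) -> list[str]:
    """Elements retained for averaged analyses: included in ≥75% of samples
    and autosomal, reference, fixed (per catalog flags)."""
    p = params or PipelineParams()
    by_id = {el.id: el for el in elements}
    n_samples = summaries["sample"].nunique()
    kept = []
    for el_id, grp in summaries.groupby("element_id"):
        el = by_id.get(el_id)
        if el is None:
            continue
        autosomal = not str(el.chrom).lstrip("chr").upper().startswith(("X", "Y"))
        eligible = (autosomal
                    and getattr(el, "provenance", "reference") == "reference"
                    and getattr(el, "allele_status", "fixed") == "fixed")
        if not eligible:
            continue
        if grp["included"].sum() / n_samples >= p.meth_min_sample_frac:
            kept.append(el_id)
    return sorted(kept)


def classify_activity(
    positive_sample_counts: dict[str, int],
    internal_pas_strength: dict[str, str] | None = None,
    params: PipelineParams | None = None,
) -> dict[str, str]:
    """Activity class per element from transduction-positive sample counts.

    active: ≥4 positive samples; minor: 1–3; inactive: 0, refined to
    'inactive_weak_pas' when the element's strongest internal PAS is weak.
    """
    p = params or PipelineParams()
    pas = internal_pas_strength or {}
    lo, hi = p.activity_minor_range
    out = {}
    for el_id, count in positive_sample_counts.items():
        if count >= p.activity_active_min_samples:
            out[el_id] = "active"
        elif lo <= count <= hi:
            out[el_id] = "minor"
        elif pas.get(el_id) == "weak":
            out[el_id] = "inactive_weak_pas"
        else:
            out[el_id] = "inactive"
    return out


def test_association(
    summaries: pd.DataFrame,
    transduction_counts: pd.DataFrame,
    params: PipelineParams | None = None,
) -> dict:
    """Methylation–activity association statistics.

    ``transduction_counts`` is tidy with columns element_id, sample, count
    (somatic transductions from that element in that sample; absent pairs
    count 0).  Returns a dict with

    * ``per_element``: element_id → (pearson r, two-sided p, 95% CI via
      Fisher z) of avg methylation vs per-sample transduction count;
    * ``welch``: pooled two-sided Welch's t-test of element–sample
      methylation, transduction-positive vs transduction-negative pairs,
      with the positive-minus-negative mean difference and its 95% CI;
    * degenerate inputs are reported as None with a reason string.
    """
    del params
    counts = transduction_counts.set_index(["element_id", "sample"])["count"]
    df = summaries[summaries["included"]].copy()
    df["count"] = [
        int(counts.get((e, s), 0))
        for e, s in zip(df["element_id"], df["sample"])
    ]
    per_element = {}
    for el_id, grp in df.groupby("element_id"):
        x, y = grp["avg_methylation"].to_numpy(), grp["count"].to_numpy(float)
        if len(grp) < 3 or np.std(x) == 0 or np.std(y) == 0:
            per_element[el_id] = {"r": None, "p": None, "ci": None,
                                  "reason": "degenerate (n<3 or zero variance)"}
            continue
        r, pval = stats.pearsonr(x, y)
        if abs(r) >= 1.0:  # Fisher z is undefined at |r| = 1
            ci = (float(r), float(r))
        else:
            z = np.arctanh(r)
            se = 1.0 / np.sqrt(len(grp) - 3)
            ci = (float(np.tanh(z - 1.959964 * se)),
                  float(np.tanh(z + 1.959964 * se)))
        per_element[el_id] = {"r": float(r), "p": float(pval), "ci": ci,
                              "reason": None}
    pos = df.loc[df["count"] > 0, "avg_methylation"].to_numpy()
    neg = df.loc[df["count"] == 0, "avg_methylation"].to_numpy()
    if len(pos) < 2 or len(neg) < 2:
        welch = {"t": None, "p": None, "difference": None, "ci": None,
                 "reason": "need >=2 element-sample pairs per group"}
    else:
        res = stats.ttest_ind(pos, neg, equal_var=False)
        diff = float(pos.mean() - neg.mean())
        ci_obj = res.confidence_interval(0.95)
        welch = {"t": float(res.statistic), "p": float(res.pvalue),
                 "difference": diff,
                 "ci": (float(ci_obj.low), float(ci_obj.high)),
                 "reason": None,
                 "n_positive": int(len(pos)), "n_negative": int(len(neg))}
    return {"per_element": per_element, "welch": welch}


def class_distribution(
    summaries: pd.DataFrame, activity: dict[str, str],
) -> pd.DataFrame:
    """Per-activity-class methylation distribution table."""
    df = summaries[summaries["included"]].copy()
    df["activity"] = df["element_id"].map(activity)
    return (df.groupby("activity")["avg_methylation"]
              .agg(["count", "mean", "median", "std"]).reset_index())
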