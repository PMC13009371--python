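"""Reconstructed-insertion and methylation table generators.

``simulate_longread_calls`` emits each truth insertion's sequence with
i.i.d. substitution noise at the configured rate, the shape a long-read SV
caller's reconstructed insertion sequences arrive in.

``simulate_methylation`` enumerates CpG (CG dinucleotide) sites in each
source element's promoter window and draws per-CpG methylated fractions
from Beta distributions: sources active in a sample use the hypomethylated
mean, everything else the background/inactive mean.  Coverage is Poisson.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig, TruthRecord
from .reference import ReferenceBundle

__all__ = ["simulate_longread_calls", "simulate_methylation"]

_BASES = "ACGT"


def simulate_longread_calls(
    cfg: SimulationConfig, records: list[TruthRecord],
) -> pd.DataFrame:
    """Insertion-call table: id, sample, chrom, pos, somatic, sequence.

    Sequences carry substitution noise at ``cfg.basecall_error``; positions
    are the truth target positions (1 bp long-read breakpoint jitter is not
    modelled).  Deterministic under the seed.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    rows = []
    for r in records:
        seq = r.seq
        if cfg.basecall_error > 0 and seq:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = rng.random(len(arr)) < cfg.basecall_error
            if hit.any():
                idx = np.nonzero(hit)[0]
                subs = rng.integers(1, 4, size=len(idx))
                lut = {65: "ACGT", 67: "CGTA", 71: "GTAC", 84: "TACG"}
                chars = list(seq)
                for i, s in zip(idx.tolist(), subs.tolist()):
                    chars[i] = lut.get(arr[i], "ACGT")[s % 4]
                seq = "".join(chars)
        rows.append({"insertion_id": r.insertion_id, "sample": r.sample,
                     "chrom": r.chrom, "pos": r.pos, "somatic": r.somatic,
                     "sequence": seq})
    return pd.DataFrame(
        rows, columns=["insertion_id", "sample", "chrom", "pos", "somatic",
                       "sequence"])


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta parameters, clipped to a valid variance."""
    var = min(sd * sd, mean * (1 - mean) * 0.95)
    nu = mean * (1 - mean) / var - 1
    return max(mean * nu, 1e-3), max((1 - mean) * nu, 1e-3)


def simulate_methylation(
    cfg: SimulationConfig,
    bundle: ReferenceBundle,
    active_by_sample: dict[str, set[str]],
    samples: list[str] | None = None,
    window_halfwidth: int = 100,
) -> dict[str, pd.DataFrame]:
    """Per-sample per-CpG methylation tables over source promoter windows.

    ``active_by_sample`` maps sample -> set of source ids active in it
    (their promoter CpGs draw from the hypomethylated Beta).  Returns
    sample -> frame with columns sample, chrom, pos, coverage,
    methylated_fraction (positions 0-based).
    """
    rng = np.random.default_rng([cfg.seed, 13])
    samples = samples if samples is not None else cfg.sample_names
    a_act = _beta_params(cfg.meth_active_mean, cfg.meth_sd)
    a_ina = _beta_params(cfg.meth_inactive_mean, cfg.meth_sd)

    # CpG sites per source promoter window (5' end, element orientation)
    site_map: list[tuple[str, str, int]] = []  # (source id, chrom, pos)
    for _, row in bundle.annotations.iterrows():
        chrom = row["chrom"]
        g = bundle.genome[chrom]
        five = row["start"] if row["strand"] == "+" else row["end"]
        lo, hi = max(0, five - window_halfwidth), five + window_halfwidth
        for i in range(lo, min(hi, len(g) - 1)):
            if g[i] == "C" and g[i + 1] == "G":
                site_map.append((row["name"], chrom, i))

    out = {}
    for sample in samples:
        active = active_by_sample.get(sample, set())
        rows = []
        for src_id, chrom, pos in site_map:
            a, b = a_act if src_id in active else a_ina
            frac = float(rng.beta(a, b))
            cov = int(rng.poisson(cfg.meth_coverage_mean)) + 1
            rows.append({"sample": sample, "chrom": chrom, "pos": pos,
                         "coverage": cov, "methylated_fraction": frac})
        out[sample] = pd.DataFrame(
            rows, columns=["sample", "chrom", "pos", "coverage",
                           "methylated_fraction"])
    return out
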