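"""Reference-genome generator: random background with planted source L1s.

Each source is a full consensus copy followed (3' of the element, on the
element strand) by unique random sequence into which AATAAA hexamers are
planted at the configured offsets.  Optionally a truncated element and a
proxy element (a truncated L1 whose downstream flank carries another
source's transduced sequence) are placed the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .._util import revcomp
from .config import SimulationConfig, SourceSpec
from .consensus import synthetic_l1_consensus

__all__ = ["ReferenceBundle", "simulate_reference", "write_fasta"]

_PAS = "AATAAA"


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    annotations: pd.DataFrame          # BED6: chrom start end name score strand
    source_specs: dict[str, SourceSpec]
    consensus: str
    element_intervals: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict)

    def chrom_names(self) -> list[str]:
        return list(self.genome)


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _scrub_pas(arr: list[str], start: int, end: int) -> None:
    """Remove chance AATAAA/ATTAAA occurrences from arr[start:end]."""
    window = "".join(arr[start:end])
    for variant in ("AATAAA", "ATTAAA"):
        idx = window.find(variant)
        while idx != -1:
            arr[start + idx + 2] = "C"
            window = "".join(arr[start:end])
            idx = window.find(variant)


def simulate_reference(cfg: SimulationConfig) -> ReferenceBundle:
    """Deterministic reference genome + BED annotations + source specs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    consensus = synthetic_l1_consensus()
    L = len(consensus)
    genome: dict[str, str] = {}
    rows = []
    element_intervals: dict[str, list[tuple[int, int]]] = {}
    per_chrom: dict[int, list[SourceSpec]] = {}
    for spec in cfg.sources:
        per_chrom.setdefault(spec.chrom, []).append(spec)

    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        arr = list(_to_str(_random_dna(rng, cfg.chrom_length)))
        specs = per_chrom.get(ci, [])
        n = len(specs)
        placed: list[tuple[int, int]] = []
        for si, spec in enumerate(specs):
            elem_len = spec.truncated_length if spec.truncated else L
            pos = spec.position
            if pos is None:
                pos = int((si + 1) * cfg.chrom_length / (n + 1))
            end = pos + elem_len
            flank = 4000  # element + downstream PAS region stay private
            for (a, b) in placed:
                if pos < b + flank and a < end + flank:
                    raise ValueError(
                        f"source {spec.id} overlaps another element layout")
            if end + flank > cfg.chrom_length or pos < flank:
                raise ValueError(f"source {spec.id} does not fit the contig")
            placed.append((pos, end))
            elem_seq = (consensus[-elem_len:] if spec.truncated
                        else consensus)
            if spec.strand == "-":
                elem_seq = revcomp(elem_seq)
            arr[pos:end] = list(elem_seq)
            # plant downstream PAS hexamers on the element strand
            if spec.strand == "+":
                _scrub_pas(arr, end, min(len(arr), end + 3500))
                for off in spec.pas_offsets:
                    arr[end + off: end + off + 6] = list(_PAS)
            else:
                _scrub_pas(arr, max(0, pos - 3500), pos)
                for off in spec.pas_offsets:
                    start = pos - off - 6
                    arr[start: start + 6] = list(revcomp(_PAS))
            rows.append({"chrom": chrom, "start": pos, "end": end,
                         "name": spec.id, "score": 0, "strand": spec.strand})
            element_intervals.setdefault(chrom, []).append((pos, end))
        genome[chrom] = "".join(arr)

    bundle = ReferenceBundle(
        genome=genome,
        annotations=pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]),
        source_specs={s.id: s for s in cfg.sources},
        consensus=consensus,
        element_intervals=element_intervals,
    )
    # proxy elements copy their target source's downstream sequence
    by_id = {r["name"]: r for r in rows}
    for spec in cfg.sources:
        if spec.proxy_of:
            target = bundle.source_specs[spec.proxy_of]
            t_row, p_row = by_id[target.id], by_id[spec.id]
            t_chrom, p_chrom = t_row["chrom"], p_row["chrom"]
            src_down = bundle.genome[t_chrom][t_row["end"]: t_row["end"] + 400]
            g = bundle.genome[p_chrom]
            e = p_row["end"]
            bundle.genome[p_chrom] = g[:e] + src_down + g[e + len(src_down):]
    return bundle


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
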