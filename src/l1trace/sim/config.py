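"""Simulation configuration and truth records.

Defaults mirror the statistical structure the detection methods assume in
colorectal-cancer cohorts: roughly a quarter of somatic L1 insertions carry
a traceable 3' transduction; each source produces transductions with
characteristic modal unique-sequence lengths set by planted downstream
polyadenylation signals (10–30 bp upstream of the endpoint), plus a
geometric tail of non-PAS terminations; per-source 5' inversion rates vary
widely; and promoters of sources active in a sample are hypomethylated
relative to inactive ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SourceSpec:
    """One planted source L1 and its activity model."""

    id: str
    chrom: int = 0                 # chromosome index
    position: int | None = None    # element start; None -> evenly spaced
    strand: str = "+"
    activity: float = 1.0          # relative draw weight among sources
    pas_offsets: tuple[int, ...] = (60,)   # AATAAA starts, bp downstream of 3' end
    pas_weights: tuple[float, ...] = (1.0,)
    pas_termination_frac: float = 0.85  # endpoints 10-30 bp past a planted PAS
    geometric_tail_p: float = 0.01      # non-PAS endpoint tail
    inversion_rate: float = 0.15
    inversion_mode: int = 250      # hotspot distance of the junction to the 3' end
    truncated: bool = False        # truncated element (proxy candidate)
    truncated_length: int = 2500
    proxy_of: str | None = None


def default_sources(n: int = 5) -> list[SourceSpec]:
    """Five active sources with distinct modal transduction lengths."""
    presets = [
        ("src1", (58,), 0.10), ("src2", (317,), 0.40), ("src3", (48,), 0.05),
        ("src4", (800,), 0.50), ("src5", (65, 650), 0.20),
    ]
    out = []
    for i, (name, offsets, inv) in enumerate(presets[:n]):
        out.append(SourceSpec(
            id=name, chrom=0, strand="+", pas_offsets=offsets,
            pas_weights=tuple(1.0 for _ in offsets), inversion_rate=inv))
    return out


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 3_000_000
    sources: list[SourceSpec] = field(default_factory=default_sources)

    # cohort
    n_tumors: int = 2
    n_normals: int = 1             # insertion-free controls
    mean_somatic_insertions: float = 20.0

    # insertion class mix
    fraction_transduction: float = 0.25   # of all somatic L1 insertions
    orphan_fraction: float = 0.25         # of transductions
    dual_polya_prob: float = 0.5
    min_transduction_len: int = 40        # must cover the 30-bp tag

    # TPRT hallmarks
    tsd_range: tuple[int, int] = (5, 20)
    polya_range: tuple[int, int] = (12, 60)
    en_site_fraction: float = 0.7
    l1_truncation_range: tuple[int, int] = (300, 5000)  # L1 bp when truncated
    full_length_prob: float = 0.05

    # short reads
    read_length: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    depth: float = 30.0
    mapq_unique: int = 60
    mapq_repeat: int = 5

    # long-read reconstruction
    basecall_error: float = 0.0

    # cascades
    cascade: bool = False

    # methylation model (Beta-distributed per-CpG fractions)
    meth_active_mean: float = 0.35
    meth_inactive_mean: float = 0.75
    meth_background_mean: float = 0.75
    meth_sd: float = 0.10
    meth_coverage_mean: float = 20.0

    def validate(self) -> None:
        for name in ("fraction_transduction", "orphan_fraction",
                     "dual_polya_prob", "en_site_fraction", "full_length_prob",
                     "basecall_error", "meth_active_mean",
                     "meth_inactive_mean", "meth_background_mean"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chrom_length < 70_000:
            raise ValueError("chrom_length must exceed 10x the L1 length")

    @property
    def sample_names(self) -> list[str]:
        return ([f"tumor{i+1}" for i in range(self.n_tumors)]
                + [f"normal{i+1}" for i in range(self.n_normals)])

    @property
    def sample_labels(self) -> dict[str, str]:
        d = {f"tumor{i+1}": "tumor" for i in range(self.n_tumors)}
        d.update({f"normal{i+1}": "normal" for i in range(self.n_normals)})
        return d


@dataclass
class TruthRecord:
    """Ground truth for one planted insertion."""

    insertion_id: str
    sample: str
    chrom: str
    pos: int                      # 0-based target position (5'-most junction)
    source_id: str | None
    cls: str                      # solo | partnered | orphan
    seq: str                      # inserted sequence, element orientation
    l1_bp: int
    transduction_bp: int
    polya_bp: int
    internal_polya_bp: int
    tsd_length: int
    en_flank: str                 # 6-mer at the initial breakpoint (detector frame)
    en_planted: bool
    orientation: str              # '+' | '-'
    inversion_breakpoints: tuple[int, int] | None
    endpoint: int | None          # transduction end, bp from the source 3' end
    somatic: bool = True
    cascade_parent: str | None = None
    dual_polya: bool = False

    def __post_init__(self) -> None:
        if self.cls == "orphan":
            assert self.l1_bp == 0
        if self.cls == "solo":
            assert self.transduction_bp == 0

    @property
    def genome_seq(self) -> str:
        from .._util import revcomp
        return self.seq if self.orientation == "+" else revcomp(self.seq)
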