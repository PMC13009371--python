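"""Pipeline parameter set.

Every numeric constant used by the detection, annotation, PAS, inversion and
methylation stages lives here, as one explicit, serializable object.  All
stages take a :class:`PipelineParams` so a run is fully described by its
parameter file plus its inputs.

Conventions: genomic intervals are 0-based half-open internally; emitted BED
is 0-based half-open and emitted TSVs use 1-based inclusive coordinates.
Thresholds written with a strict inequality in their name/docs (PAS strong
score, somatic full-length) are exclusive; the rest (anchor MAPQ, minimum
cluster reads, EN score, minimum CpGs) are inclusive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineParams", "load_params", "save_params", "ParamError"]


class ParamError(ValueError):
    """Raised for unknown keys or invariant violations in a parameter file."""


@dataclass
class PipelineParams:
    # --- tag extraction & genome-wide uniqueness ---
    tag_length: int = 30            # bp immediately 3' of the source L1 end
    tag_max_genomic_hits: int = 1000  # sources whose tag occurs at more loci are excluded
    tag_hit_max_edits: int = 3      # edits allowed when counting genomic tag occurrences
    similar_site_max_mismatches: int = 6  # Hamming, for the repeat-exclusion site list

    # --- short-read anchor clustering ---
    anchor_min_mapq: int = 37
    anchor_cluster_gap: int = 1000  # bp, single-linkage gap between anchors
    cluster_min_reads: int = 3
    repeat_exclusion_dist: int = 2000  # bp to nearest similar site (or the source itself)
    cross_sample_merge_dist: int = 2000

    # --- cluster characterization ---
    characterization_window: int = 500  # bp around anchors to collect reads from
    discordant_min_insert: int = 2000   # bp; |TLEN| above this is discordant
    min_clip_len: int = 10              # bp of soft/hard clip that makes a split read

    # --- polyA sweep ---
    polya_match: int = 1
    polya_mismatch: int = -3
    polya_limit: int = 10  # detection threshold on the sweep score

    # --- endonuclease cut-site scoring (consensus TTTT/AA) ---
    en_weights: tuple[int, ...] = (1, 1, 3, 4, 1, 1)
    en_consensus: str = "TTTTAA"
    en_min_score: int = 6

    # --- long-read source assignment ---
    source_window: int = 3000  # bp downstream of the source 3' end searched
    assign_min_margin: int = 5  # best-vs-second local-alignment score margin
    l1_min_identity: float = 0.8  # identity for calling L1 content
    l1_min_span: int = 30         # bp of aligned L1 content required

    # --- element length classes ---
    full_length_min: int = 5700
    full_length_max: int = 6700
    somatic_full_length_min: int = 5990  # exclusive

    # --- polyadenylation signals ---
    pas_strong_threshold: float = 8.1  # exclusive (score > 8.1 is strong)
    pas_weak_threshold: float = 8.0    # exclusive below (score < 8 is weak)
    pas_endpoint_window: tuple[int, int] = (10, 30)  # bp upstream of the endpoint
    internal_pas_window: int = 50  # final bp of the element scanned for internal PAS

    # --- 5' inversion breakpoint clustering ---
    inversion_bandwidth: int = 10  # bp, rectangular kernel half-width

    # --- promoter methylation ---
    meth_window_halfwidth: int = 100  # bp each side of the 5' end (200 bp total)
    meth_cov_min: int = 3
    meth_cov_max: int = 75
    meth_min_cpgs: int = 3
    meth_min_sample_frac: float = 0.75

    # --- activity classes ---
    activity_active_min_samples: int = 4
    activity_minor_range: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "tag_length", "tag_max_genomic_hits", "anchor_cluster_gap",
            "cluster_min_reads", "repeat_exclusion_dist",
            "cross_sample_merge_dist", "characterization_window",
            "discordant_min_insert", "min_clip_len", "polya_match",
            "polya_limit", "en_min_score", "source_window", "full_length_min",
            "full_length_max", "somatic_full_length_min",
            "internal_pas_window", "inversion_bandwidth",
            "meth_window_halfwidth", "meth_cov_min", "meth_cov_max",
            "meth_min_cpgs", "activity_active_min_samples",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be strictly positive")
        for name in ("tag_hit_max_edits", "similar_site_max_mismatches",
                     "anchor_min_mapq", "assign_min_margin"):
            if getattr(self, name) < 0:
                raise ParamError(f"{name} must be non-negative")
        if self.polya_mismatch >= 0:
            raise ParamError("polya_mismatch must be negative")
        if not (self.full_length_min < self.somatic_full_length_min
                < self.full_length_max):
            raise ParamError(
                "require full_length_min < somatic_full_length_min < full_length_max")
        if self.pas_weak_threshold > self.pas_strong_threshold:
            raise ParamError("pas_weak_threshold must be <= pas_strong_threshold")
        if self.meth_cov_min > self.meth_cov_max:
            raise ParamError("meth_cov_min must be <= meth_cov_max")
        if not 0 < self.meth_min_sample_frac <= 1:
            raise ParamError("meth_min_sample_frac must be in (0, 1]")
        if len(self.en_weights) != len(self.en_consensus):
            raise ParamError("en_weights and en_consensus lengths differ")
        lo, hi = self.pas_endpoint_window
        if not 0 <= lo <= hi:
            raise ParamError("pas_endpoint_window must be an increasing pair")
        lo, hi = self.activity_minor_range
        if not 1 <= lo <= hi < self.activity_active_min_samples:
            raise ParamError("activity_minor_range must sit below the active minimum")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("en_weights", "pas_endpoint_window", "activity_minor_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParamError(f"unknown parameter key(s): {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("en_weights", "pas_endpoint_window", "activity_minor_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_params(config_file: str | Path | None = None) -> PipelineParams:
    """Return defaults overlaid with overrides from a YAML config file.

    An empty or absent file yields the defaults.  Unknown keys and invariant
    violations raise :class:`ParamError` naming the offending key.
    """
    if config_file is None:
        return PipelineParams()
    text = Path(config_file).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParamError(f"malformed parameter file {config_file}: {exc}") from exc
    if data is None:
        return PipelineParams()
    if not isinstance(data, dict):
        raise ParamError("parameter file must contain a mapping")
    return PipelineParams.from_dict(data)


def save_params(params: PipelineParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
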