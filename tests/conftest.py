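"""Shared fixtures: parameters, small genomes, and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from l1trace.params import PipelineParams
from l1trace.sim import (SimulationConfig, simulate_insertions,
                         simulate_reference)


@pytest.fixture(scope="session")
def params() -> PipelineParams:
    return PipelineParams()


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Small, fast study: 0.6 Mb, one tumor, enriched for transductions."""
    return SimulationConfig(seed=11, chrom_length=600_000, n_tumors=1,
                            n_normals=1, mean_somatic_insertions=15,
                            fraction_transduction=0.5)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_bundle):
    return simulate_insertions(small_cfg, small_bundle)


@pytest.fixture(scope="session")
def small_bam(small_cfg, small_bundle, small_truth, tmp_path_factory):
    from l1trace.sim import simulate_reads
    out = tmp_path_factory.mktemp("bam") / "tumor1.bam"
    simulate_reads(small_cfg, small_bundle, small_truth, "tumor1", out, 0)
    return str(out)


@pytest.fixture(scope="session")
def small_catalog(small_bundle, params):
    from l1trace.catalog import build_catalog
    from l1trace.pas import build_default_pwm
    return build_catalog(small_bundle.genome, small_bundle.annotations,
                         params=params, pwm=build_default_pwm())
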