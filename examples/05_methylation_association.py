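"""Promoter methylation vs transduction activity.

Simulates per-CpG methylation for 30 samples over four source promoters
(two sources hypomethylated in half the samples), aggregates the 200-bp
5'-end windows with the coverage (3-75x) and >=3-CpG filters, and runs the
pooled Welch's t-test of transduction-positive vs negative element-sample
pairs.
"""

import pandas as pd

from l1trace import build_catalog
from l1trace.methylation import summarize_all
from l1trace.methylation import test_association as association_test
from l1trace.params import PipelineParams
from l1trace.sim import (SimulationConfig, SourceSpec, simulate_methylation,
                         simulate_reference)

params = PipelineParams()
sources = [SourceSpec(id=f"s{i}", position=40_000 * (i + 1)) for i in range(4)]
cfg = SimulationConfig(seed=7, chrom_length=220_000, sources=sources,
                       n_tumors=30, n_normals=0)
bundle = simulate_reference(cfg)
samples = cfg.sample_names
active = {s: ({"s0", "s1"} if i < 15 else set())
          for i, s in enumerate(samples)}
tables = simulate_methylation(cfg, bundle, active, samples)
catalog = build_catalog(bundle.genome, bundle.annotations, params=params,
                        check_uniqueness=False)
summaries = summarize_all(tables, catalog, params)
counts = pd.DataFrame([{"element_id": e, "sample": s, "count": 1}
                       for s in samples[:15] for e in ("s0", "s1")])

res = association_test(summaries, counts, params)
w = res["welch"]
print(f"element-sample pairs: {w['n_positive']} transduction-positive, "
      f"{w['n_negative']} negative")
print(f"Welch's t-test: difference = {w['difference']:.1f} percentage "
      f"points, p = {w['p']:.3g}, 95% CI [{w['ci'][0]:.1f}, {w['ci'][1]:.1f}]")

print("""
Promoters of sources active in a sample were generated ~40 percentage
points less methylated than inactive ones; the window aggregation and the
pooled Welch's t-test recover that planted hypomethylation with a strongly
negative active-minus-inactive difference.""")
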