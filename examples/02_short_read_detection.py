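"""Tag-based transduction detection on a small synthetic cohort.

Simulates a 0.6-Mb genome with five source L1s, plants somatic insertions
in one tumor (half of them 3' transductions), emits 30x paired-end reads,
and runs the full short-read arm: tag scan -> anchor clustering ->
filters -> hallmark characterization.  Prints each called transduction
next to its planted truth.
"""

import tempfile

from l1trace import build_catalog
from l1trace.params import PipelineParams
from l1trace.sim import (SimulationConfig, simulate_insertions,
                         simulate_reads, simulate_reference)
from l1trace.tagdetect import detect_sample

cfg = SimulationConfig(seed=11, chrom_length=600_000, n_tumors=1,
                       mean_somatic_insertions=15, fraction_transduction=0.5)
params = PipelineParams()

bundle = simulate_reference(cfg)
truth = simulate_insertions(cfg, bundle)
with tempfile.TemporaryDirectory() as tmp:
    bam = simulate_reads(cfg, bundle, truth, "tumor1", f"{tmp}/tumor1.bam", 0)
    catalog = build_catalog(bundle.genome, bundle.annotations, params=params)
    clusters = detect_sample(bam, catalog, "tumor1", bundle.genome, params)

planted = [r for r in truth if r.cls in ("partnered", "orphan")]
print(f"planted transductions: {len(planted)}  "
      f"(+{sum(r.cls == 'solo' for r in truth)} solo-L1, undetectable by tags)")
print(f"{'source':<6} {'locus':>8} {'reads':>5} {'TSD':>4} {'polyA':>5} "
      f"{'EN':>3} {'ori':>3}   truth")
for c in (c for c in clusters if c.called):
    h = c.hallmarks
    t = min((r for r in planted if r.source_id == c.source_id),
            key=lambda r: abs(c.locus - r.pos))
    print(f"{c.source_id:<6} {c.locus:>8} {c.n_anchor_reads:>5} "
          f"{h.tsd_length!s:>4} {h.polya_best_score:>5} "
          f"{h.en_score!s:>3} {h.orientation:>3}   "
          f"pos={t.pos} tsd={t.tsd_length} {t.cls}")

print("""
Each called cluster sits at a planted insertion locus: the breakpoint-
derived TSD matches the planted duplication, the sweep detects the polyA
tract (A tract -> '+', T tract -> '-'), and events planted at a TTTT/AA
site score >= 6.  Clusters of reference-derived pairs at the source loci
themselves are removed by the 2-kbp repeat/self exclusion.""")
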