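"""Polyadenylation signals and 5'-inversion breakpoint clustering.

Scans a downstream sequence with the shipped PAS position weight matrix
(AATAAA calibrated to 10.0; strong means score > 8.1), associates
transduction endpoints with signals 10-30 bp upstream, and clusters
inversion breakpoints (distances to the L1 3' end) with a rectangular
kernel of bandwidth 10.
"""

import numpy as np

from l1trace import (associate_endpoints, build_default_pwm,
                     cluster_breakpoints, rect_kde_integral, scan_sequence)

rng = np.random.default_rng(5)
pwm = build_default_pwm()
flank = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
flank = flank[:60] + "AATAAA" + flank[66:200] + "ATTAAA" + flank[206:]

hits = scan_sequence(pwm, flank, min_report_score=5.0)
for h in hits:
    print(f"PAS {h.hexamer} at +{h.position}  score={h.score:.2f} "
          f"({h.strength})")

endpoints = [("t1", 80), ("t2", 215), ("t3", 300)]
for a in associate_endpoints(endpoints, hits):
    where = (f"PAS at +{a.hit.position}, {a.distance} bp upstream"
             if a.hit else "no strong PAS in the 10-30 bp window")
    print(f"endpoint {a.insertion_id} (+{a.endpoint}): {where}")

print()
points = np.concatenate([rng.normal(250, 3, 30),
                         rng.normal(600, 3, 30)]).astype(int).tolist()
for c in cluster_breakpoints(points, bandwidth=10):
    print(f"breakpoint cluster [{c.start}, {c.end}]  n={c.n}  mode={c.mode}")
print(f"density integral = {rect_kde_integral(points, 10):.6f}")

print("""
Endpoint t1 terminates 10-30 bp past the canonical AATAAA and is linked to
it; t2 sits over the weaker ATTAAA variant, which scores below the strong
threshold (8.1) and therefore does not explain the termination; t3 has no
nearby signal.  The two planted inversion hot-spots come back as two
clusters with modes at the planted distances.""")
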