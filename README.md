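# l1trace

Detection and characterization of **somatic LINE-1 (L1) 3' transductions**
from short- and long-read sequencing data.

L1 is the only active autonomous human retrotransposon. When transcription
of a source element reads through its polyadenylation signal (PAS), the
downstream genomic sequence is co-mobilized and inserted elsewhere — a 3'
transduction. That unique downstream sequence is a fingerprint of the
source locus, so transductions reveal which of the genome's L1 copies are
active in a tumor. `l1trace` implements the computational machinery for
this analysis:

- **Source catalog** — full-length (5 700–6 700 bp) L1 elements with their
  30-bp downstream *tags*, filtered by genome-wide tag uniqueness
  (excluded when the tag occurs at > 1 000 loci allowing ≤ 3 edits, via
  edlib) and annotated with similar sites (≤ 6 mismatches) and internal
  PAS.
- **Tag-based short-read detection** — read pairs where one mate contains
  a tag verbatim and the other (the *anchor*, MAPQ ≥ 37) localizes the
  insertion; anchors are single-linkage clustered within 1 kbp, clusters
  with ≥ 3 reads that are not within 2 kbp of a similar site (or of the
  source itself) are called, merged across samples within 2 kbp, and
  flagged somatic when present in exactly one tumor.
- **Hallmark scoring** — target-site duplication from the two modal split
  positions, sweep-line polyA detection (+1 match / −3 mismatch, limit
  10), and the weighted endonuclease motif TTTT/AA
  (weights 1,1,3,4,1,1; cut site at score ≥ 6).
- **Long-read annotation** — reconstructed insertion sequences decomposed
  into L1 / transduced / polyA components; class (solo, partnered,
  orphan); source assignment through 3-kbp downstream windows; dual polyA
  tails; 5' inversions; proxy-element reassignment; multigenerational
  transduction cascades.
- **PAS model** — position-weight-matrix scoring of PAS hexamers
  (strong > 8.1, weak < 8) and association of transduction endpoints with
  signals 10–30 bp upstream.
- **Inversion clustering** — rectangular-kernel (bandwidth 10) clustering
  of 5'-inversion breakpoints as distances to the L1 3' end.
- **Methylation** — 200-bp promoter-window averages of per-CpG calls
  (coverage 3–75×, ≥ 3 CpGs, ≥ 75 % of samples), activity classes
  (active ≥ 4 samples; minor 1–3), Pearson and Welch's-t association
  tests.
- **Synthetic studies** — a fully seeded generator (genome, insertions
  with TPRT hallmarks, analytically aligned paired-end reads, noisy
  long-read sequences, methylation tables) so every stage is testable
  without patient data. The packaged L1 consensus is synthetic.

## Worked example

`examples/02_short_read_detection.py` simulates a 0.6-Mb genome with five
source L1s and one tumor, and runs the short-read arm end to end:

```
planted transductions: 4  (+7 solo-L1, undetectable by tags)
source    locus reads  TSD polyA  EN ori   truth
src1      14106    16   16    36   1   -   pos=14106 tsd=16 partnered
src2     281525     6    7    55   2   +   pos=281525 tsd=7 partnered
src5     553283    20   15    58   5   -   pos=553283 tsd=15 orphan
src5     578132    17   20    58  11   -   pos=578132 tsd=20 orphan
```

All four planted transductions are recovered at their exact loci with the
correct source; the TSD column (breakpoint distance) matches the planted
duplication lengths, the polyA sweep scores show detected tails (the
tract base giving the orientation), and the one event planted at a
TTTT/AA endonuclease site scores 11 (≥ 6 ⇒ cut site). The other
`examples/*.py` scripts demonstrate hallmark scoring, long-read
annotation, PAS/inversion analysis and the methylation association the
same way; each prints a short interpretation of its numbers.

A thin CLI mirrors the library (`l1trace simulate | catalog |
detect-short | annotate-long | inversions | run-all`), each subcommand
wrapping one library call.

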