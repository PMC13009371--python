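# Methods

## The problem

Somatic L1 retrotransposition in tumors produces three insertion classes:
*solo-L1* (L1 sequence + polyA only), *partnered 3' transductions* (L1 +
downstream genomic sequence) and *orphan transductions* (downstream
sequence only). Because the transduced sequence is unique in the genome,
it identifies the source element; solo-L1s do not. `l1trace` implements
two complementary detectors — an exact-tag search in short-read
alignments and a sequence-decomposition annotator for long-read insertion
calls — plus the downstream analyses that characterize source activity:
polyadenylation-signal scanning, 5'-inversion breakpoint clustering and
promoter-methylation association.

## Models and procedures

### Tag-based short-read detection

The *tag* of a source is the exact `tag_length` = 30 bp immediately 3' of
the annotated element end, on the element strand (offset 0 from the end;
the minimal-assumption reading of "downstream"). Tags are screened for
genome-wide uniqueness: a source is excluded when its tag matches more
than 1 000 loci allowing up to 3 edits. Counting uses pigeonhole seeding
(4 exact seed parts, one of which must survive any 3 edits) with edlib
infix verification; overlapping hits within one tag length collapse to
one locus, and both strands are searched. Loci matching the tag with ≤ 6
Hamming mismatches are kept as *similar sites* for later filtering.

Detection then scans every read pair: if exactly one mate contains a
usable tag (either orientation) the other mate is the anchor. Anchors
with MAPQ ≥ 37 are clustered per source by single linkage at gap
≤ 1 000 bp. A cluster is called when it has ≥ 3 anchors and is not within
2 000 bp of a similar site of its source *or of the source locus itself*
(reference-derived pairs covering the source's own downstream region
otherwise produce a self-cluster in every sample). Calls are merged
across samples (same source, ≤ 2 000 bp); an event supported by exactly
one tumor and no normal is somatic.

Called clusters are characterized from reads within 500 bp: soft/hard
clips ≥ 10 bp vote for split positions, the two modal positions are the
breakpoints (ties to the leftmost), and the signed breakpoint distance is
the TSD (negative values — target-site deletions — are preserved rather
than clamped). PolyA evidence comes from the sweep over split and
discordant reads (pair distance > 2 000 bp, cross-chromosome, or
same-strand orientation); an A tract marks '+' orientation, a T tract
'−'. The endonuclease flank is read from the reference around the initial
breakpoint (later junction for '+', earlier for '−', on the insertion
strand; 4 bases upstream + 2 downstream) and scored against TTTT/AA.
Hallmarks are annotation, never filters.

### Hallmark scores

*PolyA sweep*: running sum over the sequence, +1 per matching base, −3
per mismatch, floored at zero (Kadane with non-negativity); "10 as the
limit" is read as the detection threshold, not a score cap — the only
interpretation under which short disrupted tracts fail detection. The
leftmost window attaining the best score breaks ties. *EN score*: a
position-weighted match to TTTT/AA with weights (1, 1, 3, 4, 1, 1) — the
nick-flanking third and fourth positions dominate — and cut sites at
score ≥ 6.

### Long-read annotation

Each reconstructed insertion sequence is normalized to element
orientation (a leading T tract with no trailing A tract flips it), its
terminal polyA is trimmed with a dip-tolerant tail scan, and L1 content
is located by tiling the consensus into 100-bp seeds matched with edlib
and greedily extending the covered interval (stop at 3 mismatches per
10 bp; short 3' leftovers matching the consensus continuation are
re-absorbed). The practical detection floor for an L1 fragment is
~200 bp with the default tiling. What remains 3' of the L1 region, minus
an internal polyA, is the transduced candidate; it must hold ≥ 10 bases
of which ≥ max(5, 25 %) are non-A to rule out polyA residue.

Source assignment aligns the transduced candidate against the 3 000-bp
downstream window of every catalogued source (edlib, infix). The score is
segment length − 2·edits; assignment requires ≥ 80 % identity and a
best-versus-runner-up margin of ≥ 5 score units — the window-restricted
equivalent of demanding non-zero mapping quality against the whole
genome. Identical windows therefore yield *ambiguous*, and matches beyond
the window are unassigned. The endpoint is the alignment's 3' terminus in
downstream coordinates and the transduction length is measured from the
source 3' end (coordinate 0) to the endpoint. Insertions totalling
> 5 990 bp are flagged full length (the somatic full-length threshold is
exclusive; the catalog's 5 700–6 700 band is inclusive).

5' inversions (twin priming) are recognized when the unexplained 5'
prefix aligns to the consensus in reverse orientation; the two
template-switch points are reported as distances to the L1 3' end. For
orphans, the same check runs against the source's downstream window with
breakpoints in downstream coordinates.

*Proxies*: a truncated reference L1 whose flank carries a non-reference
source's transduced sequence soaks up that source's insertions. Catalog
`proxy_of` links relabel such calls (idempotent; chains are rejected).
*Cascades*: a germline transduction that itself mobilizes leaves a child
whose transduced sequence contains both the original source's tag and the
reference flank of the germline insertion site; tags are matched
approximately (edit distance ≤ length/15) so basecall noise cannot break
the link. With both tags present the child's source is the ultimate
reference source; with only the parent tag, the parent stands.

### Polyadenylation signals

The PAS matrix ships as log2-odds over a uniform background derived from
the human cleavage-site hexamer variant frequencies of Beaudoing et
al. (Genome Res. 2000), linearly scaled so the canonical AATAAA — the
per-column argmax — scores exactly 10.0. On this scale the strong
(> 8.1) and weak (< 8) thresholds are meaningful: AATAAA is the only
strong hexamer, ATTAAA lands in the (8, 8.1] gap, which is labelled
*intermediate* rather than silently binned. Any user matrix can be
supplied as a plain-text file; strength classes are only comparable
within one matrix, so every PWM carries a provenance label that outputs
record. Scanning is single-strand in transcript direction. An endpoint is
associated with the strongest strong-class PAS starting 10–30 bp upstream
of it; the internal PAS of an element is the strongest hit in its final
50 bp.

### Inversion clustering

All inversion breakpoints (both per event) pool into one set of distances
to the L1 3' end. Density is a rectangular kernel of bandwidth h = 10:
density(x) = #{p : |x − p| ≤ h} / (2hn). Clusters are maximal runs of
positive density — equivalently single-linkage groups at gap ≤ 2h — the
unique parameter-free reading of "rectangular-kernel clustering"; the
mode is the most frequent member (ties to the smallest). Because the
density is a step function with jumps at p ± h, its exact integral is
computed by midpoint evaluation on unit cells (`rect_kde_integral`),
which is 1 to machine precision.

### Methylation

Per-CpG records (bedMethyl-like TSV: sample, chrom, 0-based pos,
coverage, methylated fraction; percent scales normalized at load) are
averaged over the 200-bp window centred on the element's 5' end in
element orientation. CpGs with coverage outside 3–75× are dropped,
duplicates are collapsed, and a summary is *included* at ≥ 3 usable CpGs.
Averaged analyses keep autosomal, reference, fixed elements included in
≥ 75 % of samples. Activity classes: active (≥ 4 positive samples), minor
(1–3), inactive (0), and inactive-with-weak-PAS. Association tests:
per-element Pearson correlation of window methylation with per-sample
transduction counts (95 % CI via Fisher z) and a pooled two-sided Welch's
t-test of transduction-positive vs negative element–sample pairs.
Haplotype-resolved methylation is out of scope; records are
haplotype-collapsed.

### Cohort statistics

Per-source tables report somatic counts, median insertion length, median
L1 content (l1_bp / total × 100, measured against the consensus), 5'
inversion and orphan rates, and the modal unique-sequence length
(ties → smallest; omitted when all lengths are distinct). Insertion
lengths across groups are compared by tie-corrected Kruskal–Wallis, with
optional stratification by inversion status; solo/transduction activity
by Pearson correlation; relative activity is somatic transductions
divided by samples used in detection.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume: a
random-background genome with planted full-length source L1s whose unique
downstream flanks carry AATAAA hexamers at configured offsets; somatic
insertions drawn per tumor with ~25 % transductions (a quarter of which
are orphans), TSDs of 5–20 bp, polyA tails of 12–60 bp, dual tails in
half of partnered events, ~70 % of targets placed at genomic TTTT/AA
sites, per-source inversion rates with a breakpoint hot-spot, and
transduction endpoints of which 85 % terminate 10–30 bp past a planted
PAS (the remainder follow a geometric tail) — giving each source a
characteristic modal unique-sequence length. Separation of planted events
(≥ 5 kbp) keeps truth-to-call matching one-to-one.

Short reads are drawn from the donor haplotype (reference with the
sample's insertions applied; the TSD duplicates target bases on both
sides of the insert, putting the junction breakpoints at pos and
pos + tsd) and their alignments are computed *analytically* from the
segment map rather than by an external aligner: reference reads map at
their homologous position (MAPQ 60; 5 inside L1 copies), insertion-
interior reads map to the corresponding source-locus component (L1 →
repeat MAPQ, transduced → 60, polyA → 0), junction reads anchor on the
larger reference side (≥ 12 aligned bases) with the inserted part
soft-clipped, and mate geometry produces proper/discordant flags and
insert sizes. Long-read tables carry the truth sequences with i.i.d.
substitution noise. Methylation fractions are Beta-distributed
(method-of-moments from mean/sd; defaults 0.35 active vs 0.75 inactive,
sd 0.10) over CpGs enumerated from the actual reference sequence, with
Poisson coverage. All five generators are byte-deterministic under the
configured seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing errors in short reads, indel errors
in long reads, alignment ambiguity beyond the L1-copy MAPQ convention,
tumor purity and subclonality, polymorphic source genotypes across
individuals, and a biological mechanism for the germline/somatic length
difference (only separate length scales are exposed). The packaged L1
consensus is a deterministic synthetic sequence with the right structural
features (length, internal PAS in the final 50 bp, CpG-rich 5' end), not
the biological L1HS consensus; all detection code is sequence-agnostic,
so this affects only simulator realism. Minus-strand sources are fully
supported in the catalog and annotation paths; the read simulator's
source-locus placement of insertion-interior reads assumes plus-strand
sources (interior reads of minus-strand sources are placed coarsely),
which does not affect target-side detection.

## Numerical and design choices

- Intervals are 0-based half-open internally; BED output 0-based
  half-open, TSV output 1-based inclusive.
- Thresholds printed with ">" (PAS 8.1, full length 5 990) are exclusive;
  "≥" thresholds (MAPQ 37, 3 reads, EN 6, 3 CpGs) inclusive.
- Parameter files are YAML; unknown keys are rejected and the parameter
  set round-trips losslessly.
- Ties break deterministically everywhere: leftmost polyA window,
  smallest mode, leftmost modal split position, lexicographic source
  order on equal assignment scores.
- Degenerate inputs are reported, not silently dropped: zero-variance
  correlations and undersized test groups come back as undefined with a
  reason; all-N sequences are unclassifiable; empty breakpoint sets raise.
- Problem sizes in the tests and the reproduction script (3-Mb genome at
  30×, 200-insertion long-read benchmark, 30-sample methylation cohort,
  1 000-replicate null calibration) were chosen as the smallest scales at
  which the binomial/rank statistics being checked are stable.

## Known limitations

- Tag detection cannot see transductions shorter than the 30-bp tag, and
  short-read events within 2 kbp of a similar site are deliberately
  discarded — a deliberate specificity-over-sensitivity trade-off.
- The PWM is calibrated, not fitted: absolute scores have no
  probabilistic interpretation beyond the strong/weak thresholds.
- Orphan-inversion breakpoints are found by a coarse 10-bp split search.
- The somatic rule (exactly one tumor, no normal) cannot distinguish a
  shared early-clonal event from germline when only tumors are sequenced.
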