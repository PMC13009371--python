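"""Score TPRT hallmarks: polyA sweep and endonuclease cut-site motif.

Builds a few junction sequences by hand, runs the sweep-line polyA scorer
(+1 match, -3 mismatch, detection limit 10) and the weighted TTTT/AA match
(weights 1,1,3,4,1,1; cut site at score >= 6), and prints the scores.
"""

from l1trace import en_score, polya_sweep

for seq in ("AAAAAAAAAA", "AAAAACAAAAA", "AAAAAACAAAAAAA", "CCCCCCCC"):
    score, present, window = polya_sweep(seq, "A")
    print(f"polyA  {seq:<16} score={score:<3} tract_detected={present}")

print()
for flank in ("TTTTAA", "AATTAA", "TTAAAA", "GGGGGG"):
    s = en_score(flank)
    print(f"EN     {flank} score={s:<3} cut_site={s >= 6}")

print("""
A polyA tract counts as detected once a window reaches score 10, so a
10-bp pure tract passes while a disrupted 11-mer (score 7) does not.  The
EN consensus TTTT/AA weights the two bases flanking the nick (3 and 4), so
AATTAA (9) is a plausible cut site while TTAAAA (4) is not.""")
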