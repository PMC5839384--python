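"""Representation factors for the published cross-diet gene-set overlaps.

RF = k*N/(n1*n2): observed overlap over the overlap expected for independent
sets in a background of N genes.  The published values use a ~17,600-gene
expressed-gene universe; infer_background inverts the formula to audit which
universe sizes are consistent with each printed RF.
"""

from wormtx.overlap import OverlapStat, infer_background

N = 17611
cases = [
    ("exclusively hot (71 of 183 x 147)", 71, 183, 147),
    ("false cold     (255 of 630 x 630)", 255, 630, 630),
    ("false hot      (139 of 387 x 758)", 139, 387, 758),
]
for name, k, n1, n2 in cases:
    s = OverlapStat.from_counts(k, n1, n2, N)
    print(f"{name}: RF = {s.rf:.1f}, p = {s.p:.2e}  (log10 p = {s.log10_p:.1f})")

print("\nbackground sizes consistent with each printed RF (1-decimal rounding):")
for name, k, n1, n2, rf in [("hot", 71, 183, 147, 46.5),
                            ("false cold", 255, 630, 630, 11.3),
                            ("false hot", 139, 387, 758, 8.3)]:
    exact, (lo, hi) = infer_background(k, n1, n2, rf)
    print(f"  {name}: exact N = {exact:.0f}, interval [{lo}, {hi}]")
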