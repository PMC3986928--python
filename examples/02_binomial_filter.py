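"""The binomial false-positive rationale on two worked configurations.

With two diploid genotypes pooled, four gametes are sequenced and a
true variant has expected pool frequency at least p = 1/4.  A minor
state seen improbably rarely for that frequency is a likely artifact.
"""

from contigvar import binom_cum_p, binom_point_p

p = 0.25  # 1 / (2 * 2 genotypes)

cum = binom_cum_p(3, 29, p)
print(f"P(X <= 3 | n=29, p=0.25) = {cum:.4f}  -> {'discard' if cum < 0.05 else 'keep'}")
# 0.0455 < 0.05: three minor reads among 29 is too few for a real
# variant at frequency 1/4, so the site is flagged as a false positive.

point = binom_point_p(2, 8, p)
cum28 = binom_cum_p(2, 8, p)
print(f"P(X  = 2 | n=8,  p=0.25) = {point:.4f} (cumulative {cum28:.4f}) -> keep")
# 0.31 — the minimal configuration at the 8-read depth cutoff (2 minor
# reads, since singletons are masked earlier) is entirely plausible,
# which is why an 8x depth floor is a coherent companion threshold.
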