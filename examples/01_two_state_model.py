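"""The two-state colonization-extinction chain and its trade-off curve.

A taxon colonizes a community at rate c and goes extinct at rate e.
This script prints the stationary occupancy, transition probabilities
over a sampling gap, and the fitness-equalized trade-off curve.
"""

import numpy as np

from colext import RatePair, TradeoffCurve, stationary_occupancy, transition_matrix

rates = RatePair(c=0.2, e=0.1)  # per month
print(f"rates: c={rates.c}, e={rates.e}  ->  k = c/e = {rates.k:.1f}, "
      f"persistence = 1/e = {rates.persistence:.0f} months")

pi = stationary_occupancy(rates)
print(f"stationary occupancy pi* = k/(1+k) = {pi:.4f}")
print("(the long-run fraction of samples in which the taxon is detected)")

for dt in (1.0, 6.0, 60.0):
    p = transition_matrix(rates, dt)
    print(f"P(absent -> present | dt={dt:>4}) = {p[0, 1]:.4f}   "
          f"P(present -> present | dt={dt:>4}) = {p[1, 1]:.4f}")
print("over long gaps both rows converge to (1-pi*, pi*): the chain mixes")

curve = TradeoffCurve(k=2.0, alpha=-1.0)
c = np.logspace(-2, 0, 5)
print("\nfitness-equalized trade-off p = k/c (every taxon has equal k):")
for ci, pi_ in zip(c, curve.persistence(c)):
    print(f"  c = {ci:.3f}/month  ->  p = {pi_:8.1f} months   (c*p = {ci * pi_:.1f})")
print("on log axes these points fall on a line of slope -1 with intercept log k")
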