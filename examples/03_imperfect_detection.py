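"""Rates under imperfect detection, from replicated surveys.

With replicate samples per survey, a latent-state likelihood separates
true absence from detection failure: presence follows the two-state
chain and each replicate detects a present taxon with probability d.
"""

from colext import fit_rates, fit_rates_detectability, simulate_presence
from colext.synthetic import SyntheticSpec

spec = SyntheticSpec(
    n_taxa=400, times=tuple(float(t) for t in range(24)),
    rate_model="fixed", c=0.2, e=0.1,
    replicates=3, detection="bernoulli", d=0.8, seed=7,
)
series, _ = simulate_presence(spec)

naive = fit_rates(series.collapse_replicates())[0]
latent = fit_rates_detectability(series)[0]

print("truth: c=0.200 e=0.100 d=0.80")
print(f"ignoring detectability: c={naive.c:.3f} e={naive.e:.3f}")
print(f"latent-state model:     c={latent.c:.3f} e={latent.e:.3f} d={latent.d:.3f}")
print("detection failures masquerade as extinction/colonization events, so the")
print("naive extinction rate is biased up; the latent model absorbs them into d")
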