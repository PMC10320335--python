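"""Testing the fitness-equalization prediction: slope -1 on log axes.

Constructs rate pairs on and off the trade-off curve, fits the log-log
regression, tests the slope against -1, compares two components, and
checks taxonomic coherence.
"""

import numpy as np

from colext import (
    compare_slopes,
    exclude_taxa_and_correlate,
    loglog_tradeoff_fit,
    taxonomic_coherence,
)
from colext.tradeoff import test_slope_equals

rng = np.random.default_rng(0)

# equalized component: c*p scattered around k = 2
c_sat = np.exp(rng.uniform(-4, 0, 90))
p_sat = 2.0 / c_sat * np.exp(rng.normal(0, 0.4, 90))
satellite = loglog_tradeoff_fit(c_sat, p_sat, "satellite")

# a flatter component (weak trade-off, exponent -0.3)
c_core = np.exp(rng.uniform(-4, 0, 60))
p_core = 2.0 * c_core**-0.3 * np.exp(rng.normal(0, 0.4, 60))
core = loglog_tradeoff_fit(c_core, p_core, "core")

for fit in (satellite, core):
    t, df, p = test_slope_equals(fit, -1.0)
    print(f"{fit.component:>9}: slope {fit.slope:+.3f} "
          f"[{fit.ci_lower:+.3f}, {fit.ci_upper:+.3f}], n={fit.n}, "
          f"Spearman rho {fit.spearman_rho:+.2f}; H0 slope=-1: t={t:+.2f}, p={p:.2g}")

comp = compare_slopes(core, satellite)
print(f"\nslope equality (pooled interaction test): t={comp.t:+.2f}, "
      f"df={comp.df}, p={comp.p:.2g}")
print("small p: core and satellite follow different colonization-persistence laws")

# taxonomic coherence: are same-group taxa closer in (log c, log p)?
groups = np.repeat([f"phylum{i}" for i in range(6)], 15)
h, p = taxonomic_coherence(c_sat[:90], p_sat[:90], groups)
print(f"\ncoherence (random labels, expect no signal): Kruskal-Wallis p = {p:.2f}")

# sensitivity: excluding a noisy subset should sharpen the correlation
taxa = [f"t{i}" for i in range(90)]
noisy = taxa[:20]
p_noisy = p_sat.copy()
p_noisy[:20] = np.exp(rng.uniform(-1, 6, 20))
before, after, p_after = exclude_taxa_and_correlate(c_sat, p_noisy, taxa, noisy)
print(f"Spearman rho before/after excluding the noisy taxa: "
      f"{before:+.3f} -> {after:+.3f} (p = {p_after:.2g})")
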