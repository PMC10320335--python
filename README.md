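# colext

Colonization–extinction dynamics for temporally sampled communities:
estimate per-taxon colonization and extinction rates from irregular
presence–absence time series, compare site groupings by AIC, split a
community into core and satellite components at an occupancy structural
break, and test the fitness-equalization prediction of a
colonization–persistence trade-off.

`colext` is written for microbial ecologists working with temporal
OTU/ASV tables (taxa × samples plus sample metadata and taxonomy), but
the machinery applies to any community observed as presence–absence
snapshots at known, possibly irregular, times.

## The model

Each taxon occupies a local community as a two-state continuous-time
Markov chain — the stochastic kernel of island biogeography: absent
taxa colonize at rate *c*, present taxa go extinct at rate *e*.
Occupancy π obeys

    dπ/dt = c (1 − π) − e π,      π* = k / (1 + k),   k = c / e.

The ratio *k* is a fitness measure (expected colonizations per
residence time), and persistence is the mean residence time
*p* = 1/*e*. If equalizing mechanisms drive the community, *k* is
roughly constant across taxa, which forces the trade-off

    p = k c^(−1),   i.e.   log p = log k − log c,

a line of slope −1 on log axes. A generic trade-off `p = k c^α` with
α < 0 relaxes this; α = −1 is the quantitative signature of fitness
equalization under independent colonization–extinction dynamics.

Rates are estimated by maximum likelihood over observed transitions:
each consecutive sample pair contributes the exact transition
probability of the chain over its own interval, so irregular sampling
needs no interpolation. With replicated surveys, an imperfect-detection
variant treats presence as latent and estimates a per-replicate
detection probability *d* by the forward algorithm.

## A worked example

```python
from colext import fit_rates, simulate_presence
from colext.synthetic import SyntheticSpec

spec = SyntheticSpec(n_taxa=300, times=tuple(float(t) for t in range(24)),
                     rate_model="fixed", c=0.2, e=0.1, seed=42)
series, truth = simulate_presence(spec)
fit = fit_rates(series)[0]          # one joint pair for the whole community
print(f"c={fit.c:.3f} e={fit.e:.3f} ({fit.n_transitions} transitions)")
```

prints

```
c=0.205 e=0.100 (6900 transitions)
```

— a community of 300 taxa sharing *c* = 0.2, *e* = 0.1 per month,
sampled monthly for two years, and the joint maximum-likelihood
estimate recovered from its presence–absence transitions: ĉ = 0.205,
ê = 0.100, i.e. stationary occupancy ≈ 2/3 and persistence ≈ 10 months.

The `examples/` directory walks through each capability: the closed-form
chain (`01`), rate estimation on regular and irregular schedules (`02`),
imperfect detection with replicates (`03`), AIC partition selection over
sites (`04`), the Chow-scan core/satellite split and lognormal
rank-abundance fit (`05`), the trade-off regressions and tests (`06`),
and the sequencing-depth null (`07`). Each script prints the numbers it
computes with a line on what they mean. A thin CLI
(`colext simulate|estimate|select-partitions|core-satellite|tradeoff|pipeline`)
chains the stages on TSV/CSV inputs.

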